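# secrgrid

Spatially explicit capture–recapture (SECR) density estimation and
trap-design evaluation for small-mammal grid trapping.

`secrgrid` is aimed at wildlife monitoring programs that run annual
live-trapping grids (the motivating system is an 18-year salt-marsh harvest
mouse, *Reithrodontomys raviventris*, monitoring series in Suisun Marsh,
California: a 10×10 grid of traps at 9.43 m spacing trapped four consecutive
nights each year) and want to know **how much trapping effort they can cut —
fewer traps, wider spacing, fewer nights — without degrading their density
estimates**. It provides:

- maximum-likelihood SECR fitting for multi-catch trap grids, with
  half-normal / negative-exponential / hazard-rate detection functions,
  time and behavioral covariates, and an observed two-class (sex) mixture;
- a spatial capture–recapture simulator that doubles as a study emulator;
- design-evaluation tools: subsample a design from observed data and refit,
  or run Monte Carlo simulate-and-refit experiments summarized as relative
  bias and RMSE.

## The model

Animals hold fixed activity centers distributed as a homogeneous Poisson
process of intensity *D* (individuals ha⁻¹) over a habitat mask: the trap
bounding box buffered widely enough (≥ 4σ) that animals beyond it are
effectively undetectable. Detection at a trap at distance *d* from a center
follows a detection function, e.g. negative-exponential

    g(d) = g0 · exp(−d/σ),

with baseline detection probability g0 and spatial scale σ (a home-range
index). Within an occasion, traps compete for each animal: trap *k*
contributes hazard h_k = −ln(1 − g(d_k)), the animal is caught with
probability 1 − e^(−H) (H = Σ h_k), and lands in trap *k* with probability
h_k/H. With mask cells X_m of area *a*, mixture classes *u* (here sex,
observed on capture) with proportions π_u, and capture histories ω_i for
the n detected animals, the full (Poisson-n) log likelihood is

    ln L = −Λ + Σ_i ln( D·a·π_{u_i} Σ_m Pr(ω_i | X_m, u_i) ) − ln n!,
    Λ = D·a·Σ_m Σ_u π_u p·(X_m; u),

where p· is the probability of at least one capture during the session.
Parameters are maximized on link scales (log D, logit g0, log σ, logit π);
standard errors come from the inverse Hessian with delta-method
back-transformation, and models are compared by AIC.

Reduced designs are judged two ways: *subsampling* (delete traps/occasions
from the observed histories, refit, compare to the full-design estimate —
a design "replicates" a year when its estimate falls within one SE of the
full-design estimate) and *Monte Carlo* (simulate at known truth under the
candidate design, refit, and summarize RB_j = (D̂_j − D_j)/D_j and
RMSE = √(Σ_j (D̂_j − D_j)²/n)).

## Worked example

```python
import numpy as np
import secrgrid as sg

# 10x10 grid at 9.43 m, 50 m buffered mask at 5 m resolution
traps = sg.build_grid(10, 10, 9.43)
mask = sg.build_mask(traps, buffer=50.0, mask_spacing=5.0)

# simulate one annual session at 30 mice/ha with sex-specific detection
truth = sg.SessionTruth("2024", D=30.0, g0_F=0.30, g0_M=0.22,
                        sigma_F=6.0, sigma_M=9.0, pmix=0.5)
rng = np.random.default_rng(202)
pop = sg.simulate_population(truth.D, mask, truth.pmix, rng)
session = sg.simulate_capthist(pop, traps, 4, truth.params("EX"), seed=rng)
print(f"captured {session.n} of {pop.size} mice, "
      f"{session.n_captures} capture events")

# maximum-likelihood SECR fit with sex-specific g0 and sigma
spec = sg.ModelSpec("EX", g0_effects=frozenset({"sex"}),
                    sigma_effects=frozenset({"sex"}))
fit = sg.fit_secr(session, traps, mask, spec)
print(f"D = {fit.D_hat:.2f} +/- {fit.SE_D:.2f} mice/ha "
      f"(truth 30.0), AIC = {fit.AIC:.1f}")
print(fit.estimates.round(3).to_string(index=False))
```

Output:

```
captured 45 of 98 mice, 89 capture events
D = 35.09 +/- 5.88 mice/ha (truth 30.0), AIC = 1015.7
parameter level  estimate    se
        D          35.087 5.877
       g0     F     0.243 0.089
       g0     M     0.276 0.074
    sigma     F     7.140 1.413
    sigma     M     7.404 0.975
     pmix     F     0.396 0.083
```

The density estimate (35.1 ± 5.9 mice ha⁻¹) brackets the simulated truth of
30; with ~45 animals in one session the sex-specific detection parameters
are individually noisy, which is exactly why design comparisons below are
run as ensembles.

A reduced design is evaluated in two lines:

```python
scen = sg.DesignScenario("7x7", ("n_by_n", 7, "NW"))
result = sg.monte_carlo_eval(truth, scen, n_reps=100, seed=1)
print(result.mean_rb, result.rmse, result.n_excluded)
```

The same pipeline is scriptable from the shell:

```bash
secrgrid simulate --seed 3 --out study-sim          # 18-session emulator
secrgrid fit --traps study-sim/traps.txt --captures study-sim/captures.txt \
             --session 2005 --out fit_2005.txt
secrgrid subsample --traps study-sim/traps.txt \
                   --captures study-sim/captures.txt --out sub-out
secrgrid montecarlo --truth study-sim/truth.csv --scenario full \
                    --scenario 7x7 --reps 100 --seed 1 --out mc.csv
```

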