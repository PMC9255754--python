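"""Full-likelihood SECR fitting for multi-catch trapping grids.

The model: animals hold fixed activity centers; a homogeneous Poisson
process of intensity D (individuals/ha) governs how many centers fall in
the habitat mask; detection at a trap declines with distance from the
center according to a half-normal (HN), negative-exponential (EX) or
hazard-rate (HR) detection function; within an occasion traps compete for
each animal via the multi-catch hazard construction.

With mask points X_m of common cell area ``a`` (ha), mixture classes u with
proportions pi_u, and observed histories omega_i for the n detected
individuals, the full (Poisson-n) log likelihood is

    ln L = -Lambda + sum_i ln( D a pi_{u_i} sum_m Pr(omega_i | X_m, u_i) )
           - ln n!
    Lambda = D a sum_m sum_u pi_u p.(X_m; u)

where p. is the probability of at least one capture during the session.
Detection parameters may vary by occasion (time effect ``t``), switch
permanently after an individual's first capture (behavioral effect ``b``),
or differ between sexes (observed two-class hybrid mixture ``h2``); sex
classes are observed for captured animals while pi is estimated from the
likelihood, and unknown-sex individuals marginalize over the classes.

Parameters are maximized on link scales (log D, logit g0, log sigma,
log(z-1), logit pi). D has a closed-form conditional maximum given the
detection parameters (D = n / esa with esa the effective sampling area
``a sum_m sum_u pi_u p.``), and is profiled out during optimisation.
Standard errors come from the inverse Hessian of the full negative log
likelihood with delta-method back-transformation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .geometry import HabitatMask, TrapArray, mean_nearest_trap_distance

__all__ = [
    "CaptureHistory",
    "ModelSpec",
    "SECRFit",
    "negloglik",
    "fit_secr",
    "aic_rank",
    "summarize_densities",
]

SEXES = ("F", "M")
_TINY = 1e-300


# ---------------------------------------------------------------------------
# capture histories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaptureHistory:
    """Multi-catch capture records for one trapping session.

    records are (individual_id, occasion, trap_id) triples with 1-based
    occasions; each individual may be caught in at most one trap per
    occasion. ``sex`` maps individual ids to 'F', 'M' or 'unknown'.
    """

    records: tuple[tuple[str, int, str], ...]
    n_occasions: int
    sex: Mapping[str, str] = field(default_factory=dict)
    session_label: str = "session"

    def __post_init__(self) -> None:
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be positive")
        recs = tuple(
            (str(ind), int(occ), str(trap)) for ind, occ, trap in self.records
        )
        seen: set[tuple[str, int]] = set()
        for ind, occ, trap in recs:
            if not 1 <= occ <= self.n_occasions:
                raise ValueError(
                    f"occasion {occ} outside 1..{self.n_occasions} for {ind!r}"
                )
            if (ind, occ) in seen:
                raise ValueError(
                    f"individual {ind!r} has two captures on occasion {occ} "
                    "(multi-catch allows at most one)"
                )
            seen.add((ind, occ))
        sex = dict(self.sex)
        for ind in {r[0] for r in recs}:
            sex.setdefault(ind, "unknown")
        for ind, s in sex.items():
            if s not in ("F", "M", "unknown"):
                raise ValueError(f"bad sex label {s!r} for {ind!r}")
        object.__setattr__(self, "records", recs)
        object.__setattr__(self, "sex", sex)

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(sorted({r[0] for r in self.records}))

    @property
    def n(self) -> int:
        return len({r[0] for r in self.records})

    @property
    def n_captures(self) -> int:
        return len(self.records)

    def n_spatial_recaptures(self) -> int:
        """Count recapture events at a trap different from any earlier one."""
        by_ind: dict[str, list[tuple[int, str]]] = {}
        for ind, occ, trap in self.records:
            by_ind.setdefault(ind, []).append((occ, trap))
        count = 0
        for caps in by_ind.values():
            caps.sort()
            seen_traps = {caps[0][1]}
            for _, trap in caps[1:]:
                if trap not in seen_traps:
                    count += 1
                    seen_traps.add(trap)
        return count

    def validate_against(self, traps: TrapArray) -> None:
        known = set(traps.trap_id)
        for ind, occ, trap in self.records:
            if trap not in known:
                raise ValueError(
                    f"record ({ind}, {occ}, {trap}) references an unknown trap"
                )

    def data_key(self) -> str:
        payload = repr((sorted(self.records), self.n_occasions, sorted(self.sex.items())))
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model specification and parameter layout
# ---------------------------------------------------------------------------

_EFFECTS = frozenset({"time", "behavior", "sex"})


@dataclass(frozen=True)
class ModelSpec:
    """Which detection function and which covariate effects to fit.

    ``g0_effects`` / ``sigma_effects`` are subsets of {"time", "behavior",
    "sex"}; time and behavior are mutually exclusive on the same parameter.
    ``mixture`` controls whether the class proportion pi is estimated; by
    default it is on exactly when a sex effect is present.
    """

    detectfn: str = "EX"
    g0_effects: frozenset[str] = frozenset()
    sigma_effects: frozenset[str] = frozenset()
    mixture: bool | None = None

    def __post_init__(self) -> None:
        if self.detectfn not in ("HN", "EX", "HR"):
            raise ValueError(f"unknown detection function {self.detectfn!r}")
        g0_eff = frozenset(self.g0_effects)
        sig_eff = frozenset(self.sigma_effects)
        for name, eff in (("g0", g0_eff), ("sigma", sig_eff)):
            if not eff <= _EFFECTS:
                raise ValueError(f"unknown {name} effects: {set(eff) - _EFFECTS}")
            if {"time", "behavior"} <= eff:
                raise ValueError(
                    f"time and behavior effects are mutually exclusive on {name}"
                )
        object.__setattr__(self, "g0_effects", g0_eff)
        object.__setattr__(self, "sigma_effects", sig_eff)
        has_sex = "sex" in g0_eff or "sex" in sig_eff
        mixture = has_sex if self.mixture is None else bool(self.mixture)
        if has_sex and not mixture:
            raise ValueError("sex effects require the mixture proportion")
        object.__setattr__(self, "mixture", mixture)

    @property
    def n_classes(self) -> int:
        return 2 if self.mixture else 1

    def label(self) -> str:
        def fmt(eff: frozenset[str]) -> str:
            codes = {"time": "t", "behavior": "b", "sex": "h2"}
            return "+".join(codes[e] for e in sorted(eff)) or "1"

        return (
            f"{self.detectfn} g0~{fmt(self.g0_effects)} "
            f"sigma~{fmt(self.sigma_effects)}"
        )


class _ParamLayout:
    """Maps the flat link-scale parameter vector to detection parameters."""

    def __init__(self, spec: ModelSpec, n_occasions: int):
        self.spec = spec
        self.S = n_occasions

        def dims(effects: frozenset[str]) -> tuple[int, int, int]:
            return (
                2 if "sex" in effects else 1,
                n_occasions if "time" in effects else 1,
                2 if "behavior" in effects else 1,
            )

        self.g0_dims = dims(spec.g0_effects)
        self.sig_dims = dims(spec.sigma_effects)
        self.n_g0 = int(np.prod(self.g0_dims))
        self.n_sig = int(np.prod(self.sig_dims))
        self.has_z = spec.detectfn == "HR"
        self.has_pi = spec.mixture
        # theta = [logD | g0 block | sigma block | log(z-1)? | logit pi?]
        self.i_g0 = 1
        self.i_sig = self.i_g0 + self.n_g0
        self.i_z = self.i_sig + self.n_sig
        self.i_pi = self.i_z + (1 if self.has_z else 0)
        self.n_params = self.i_pi + (1 if self.has_pi else 0)

    @staticmethod
    def _flat(dims: tuple[int, int, int], u: int, s: int, b: int) -> int:
        cu = u if dims[0] > 1 else 0
        cs = s if dims[1] > 1 else 0
        cb = b if dims[2] > 1 else 0
        return (cu * dims[1] + cs) * dims[2] + cb

    def g0(self, theta: np.ndarray, u: int, s: int, b: int) -> float:
        x = theta[self.i_g0 + self._flat(self.g0_dims, u, s, b)]
        return 1.0 / (1.0 + np.exp(-x))

    def sigma(self, theta: np.ndarray, u: int, s: int, b: int) -> float:
        return float(np.exp(theta[self.i_sig + self._flat(self.sig_dims, u, s, b)]))

    def z(self, theta: np.ndarray) -> float | None:
        return float(1.0 + np.exp(theta[self.i_z])) if self.has_z else None

    def pi(self, theta: np.ndarray) -> np.ndarray:
        if not self.has_pi:
            return np.array([1.0])
        p = 1.0 / (1.0 + np.exp(-theta[self.i_pi]))
        return np.array([p, 1.0 - p])

    def labels(self) -> list[tuple[str, str]]:
        """(parameter, level) pairs aligned with the theta vector."""
        out = [("D", "")]
        for name, dims, eff in (
            ("g0", self.g0_dims, self.spec.g0_effects),
            ("sigma", self.sig_dims, self.spec.sigma_effects),
        ):
            for u in range(dims[0]):
                for s in range(dims[1]):
                    for b in range(dims[2]):
                        parts = []
                        if "sex" in eff:
                            parts.append(SEXES[u])
                        if "time" in eff:
                            parts.append(f"t{s + 1}")
                        if "behavior" in eff:
                            parts.append("post" if b else "naive")
                        out.append((name, ":".join(parts)))
        if self.has_z:
            out.append(("z", ""))
        if self.has_pi:
            out.append(("pmix", "F"))
        return out


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------


class _FitData:
    """Precomputed, theta-independent quantities for one dataset."""

    def __init__(
        self,
        ch: CaptureHistory,
        traps: TrapArray,
        mask: HabitatMask,
        spec: ModelSpec,
    ):
        ch.validate_against(traps)
        self.ch = ch
        self.traps = traps
        self.mask = mask
        self.spec = spec
        self.layout = _ParamLayout(spec, ch.n_occasions)
        diff = mask.points[:, None, :] - traps.coords[None, :, :]
        self.dist = np.sqrt((diff**2).sum(axis=2))  # (M, K)
        self.a = mask.cell_area
        self.S = ch.n_occasions
        self.M, self.K = self.dist.shape

        inds = ch.individuals
        self.n = len(inds)
        idx = {ind: i for i, ind in enumerate(inds)}
        tidx = {t: k for k, t in enumerate(traps.trap_id)}
        self.occ_trap = -np.ones((self.n, self.S), dtype=int)
        for ind, occ, trap in ch.records:
            self.occ_trap[idx[ind], occ - 1] = tidx[trap]
        # behavior state: 1 on occasions strictly after the first capture
        self.b_state = np.zeros((self.n, self.S), dtype=int)
        for i in range(self.n):
            caught = np.flatnonzero(self.occ_trap[i] >= 0)
            if caught.size:
                self.b_state[i, caught[0] + 1 :] = 1
        sex_to_class = {"F": 0, "M": 1, "unknown": -1}
        self.cls = np.array([sex_to_class[ch.sex[ind]] for ind in inds], dtype=int)
        if spec.n_classes == 1:
            self.cls = np.zeros(self.n, dtype=int)
        self.simple = not (
            {"time", "behavior"} & (spec.g0_effects | spec.sigma_effects)
        )

    # -- per-configuration detection matrices -------------------------------

    def _config(self, cache: dict, g0: float, sigma: float, z) -> dict:
        key = (g0, sigma, z)
        cfg = cache.get(key)
        if cfg is None:
            if self.spec.detectfn == "HN":
                g = g0 * np.exp(-(self.dist**2) / (2 * sigma**2))
            elif self.spec.detectfn == "EX":
                g = g0 * np.exp(-self.dist / sigma)
            else:
                with np.errstate(divide="ignore", over="ignore"):
                    ratio = np.where(
                        self.dist > 0, (self.dist / sigma) ** (-z), np.inf
                    )
                g = g0 * -np.expm1(-ratio)
            h = -np.log1p(-np.minimum(g, 1 - 1e-12))
            H = h.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                # log p_k = log h_k - log H + log(1 - e^-H)
                log_pcap = np.where(H > 0, np.log(-np.expm1(-np.maximum(H, _TINY))), -np.inf)
                logpk = np.where(
                    h > 0,
                    np.log(np.maximum(h, _TINY))
                    - np.log(np.maximum(H, _TINY))[:, None]
                    + log_pcap[:, None],
                    -np.inf,
                )
            cfg = {"H": H, "logpk": logpk}
            cache[key] = cfg
        return cfg

    def _class_params(self, theta: np.ndarray, u: int, s: int, b: int):
        lay = self.layout
        return lay.g0(theta, u, s, b), lay.sigma(theta, u, s, b), lay.z(theta)

    def nll(self, theta: np.ndarray) -> float:
        """Negative log likelihood at a full link-scale parameter vector."""
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite parameter vector")
        lay = self.layout
        D = float(np.exp(theta[0]))
        pi = lay.pi(theta)
        nc = self.spec.n_classes
        cache: dict = {}

        # session-level escape hazard per class (naive state, for Lambda)
        H_tot = np.zeros((nc, self.M))
        for u in range(nc):
            for s in range(self.S):
                cfg = self._config(cache, *self._class_params(theta, u, s, 0))
                H_tot[u] += cfg["H"]
        pdot = -np.expm1(-H_tot)  # (nc, M)
        esa = self.a * float(pi @ pdot.sum(axis=1))
        Lam = D * esa

        if self.n == 0:
            return Lam

        # per-individual, per-class log sum over mask of Pr(omega | X_m)
        log_pi = np.log(np.maximum(pi, _TINY))
        li = np.full((self.n, nc), -np.inf)
        if self.simple:
            for u in range(nc):
                rows = np.flatnonzero((self.cls == u) | (self.cls == -1))
                if rows.size == 0:
                    continue
                cfg = self._config(cache, *self._class_params(theta, u, 0, 0))
                counts = np.zeros((rows.size, self.K))
                n_null = np.zeros(rows.size)
                for j, i in enumerate(rows):
                    for s in range(self.S):
                        k = self.occ_trap[i, s]
                        if k >= 0:
                            counts[j, k] += 1.0
                        else:
                            n_null[j] += 1.0
                with np.errstate(invalid="ignore"):
                    Z = np.where(
                        np.isfinite(cfg["logpk"]), cfg["logpk"], -1e30
                    )  # finite stand-in for log 0: avoids nan from 0 * -inf
                logP = counts @ Z.T - np.outer(n_null, cfg["H"])  # (r, M)
                li[rows, u] = logsumexp(logP, axis=1)
        else:
            for i in range(self.n):
                classes = [self.cls[i]] if self.cls[i] >= 0 else list(range(nc))
                for u in classes:
                    acc = np.zeros(self.M)
                    for s in range(self.S):
                        b = self.b_state[i, s]
                        cfg = self._config(
                            cache, *self._class_params(theta, u, s, b)
                        )
                        k = self.occ_trap[i, s]
                        acc = acc + (cfg["logpk"][:, k] if k >= 0 else -cfg["H"])
                    li[i, u] = logsumexp(acc)

        # observed class: only that component; unknown: marginalize
        contrib = np.empty(self.n)
        known = self.cls >= 0
        if known.any():
            contrib[known] = (
                log_pi[self.cls[known]] + li[np.flatnonzero(known), self.cls[known]]
            )
        unk = np.flatnonzero(~known)
        if unk.size:
            contrib[unk] = logsumexp(li[unk] + log_pi[None, :], axis=1)

        ll = -Lam + np.sum(np.log(D * self.a) + contrib) - gammaln(self.n + 1)
        return float(-ll)

    def esa(self, theta_r: np.ndarray) -> float:
        """Effective sampling area (ha) from a reduced vector (no log D)."""
        theta = np.concatenate([[0.0], theta_r])
        lay = self.layout
        pi = lay.pi(theta)
        cache: dict = {}
        H_tot = np.zeros((self.spec.n_classes, self.M))
        for u in range(self.spec.n_classes):
            for s in range(self.S):
                cfg = self._config(cache, *self._class_params(theta, u, s, 0))
                H_tot[u] += cfg["H"]
        return self.a * float(pi @ (-np.expm1(-H_tot)).sum(axis=1))


def negloglik(
    ch: CaptureHistory,
    traps: TrapArray,
    mask: HabitatMask,
    spec: ModelSpec,
    theta: Sequence[float],
) -> float:
    """Negative log likelihood of a full link-scale parameter vector.

    theta is ``[log D, g0 block (logit), sigma block (log), log(z-1) if HR,
    logit pi if mixture]`` with block layouts given by the model spec.
    """
    data = _FitData(ch, traps, mask, spec)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (data.layout.n_params,):
        raise ValueError(
            f"expected {data.layout.n_params} parameters, got {theta.shape}"
        )
    return data.nll(theta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class SECRFit:
    """Maximum-likelihood SECR fit for one session."""

    label: str
    D_hat: float
    SE_D: float
    estimates: pd.DataFrame  # columns: parameter, level, estimate, se
    pmix_hat: float | None
    log_likelihood: float
    n_parameters: int
    AIC: float
    converged: bool
    flags: tuple[str, ...]
    n: int
    spec: ModelSpec
    data_key: str
    theta: np.ndarray
    cov: np.ndarray | None
    gradient_norm: float
    session_label: str = "session"

    @property
    def unstable(self) -> bool:
        return "unstable" in self.flags or "non-identifiable" in self.flags

    def param(self, name: str, level: str = "") -> float:
        df = self.estimates
        row = df[(df.parameter == name) & (df.level == level)]
        if row.empty:
            raise KeyError(f"no estimate for {name!r} level {level!r}")
        return float(row.estimate.iloc[0])


def _default_starts(
    ch: CaptureHistory, traps: TrapArray, mask: HabitatMask, spec: ModelSpec
) -> np.ndarray:
    """Deterministic data-driven starting values on the link scales."""
    lay = _ParamLayout(spec, ch.n_occasions)
    n = max(ch.n, 1)
    D0 = max(n / mask.area, 0.1)
    # sigma: half the mean displacement between an individual's successive
    # capture locations; fall back to the trap spacing when no movements.
    coords = {t: traps.coords[k] for k, t in enumerate(traps.trap_id)}
    by_ind: dict[str, list[tuple[int, str]]] = {}
    for ind, occ, trap in ch.records:
        by_ind.setdefault(ind, []).append((occ, trap))
    moves = []
    for caps in by_ind.values():
        caps.sort()
        for (_, t1), (_, t2) in zip(caps[:-1], caps[1:]):
            moves.append(float(np.hypot(*(coords[t1] - coords[t2]))))
    positive = [m for m in moves if m > 0]
    if positive:
        sigma0 = 0.5 * float(np.mean(positive))
    elif len(traps) > 1:
        sigma0 = 0.5 * mean_nearest_trap_distance(traps)
    else:
        sigma0 = 10.0
    sigma0 = float(np.clip(sigma0, 1.0, 200.0))
    g0_0 = float(np.clip(ch.n_captures / (n * ch.n_occasions), 0.05, 0.8))
    sexes = [ch.sex[i] for i in ch.individuals]
    n_known = sum(s in SEXES for s in sexes)
    pi0 = (
        float(np.clip(sum(s == "F" for s in sexes) / n_known, 0.1, 0.9))
        if n_known
        else 0.5
    )
    theta = np.empty(lay.n_params)
    theta[0] = np.log(D0)
    theta[lay.i_g0 : lay.i_g0 + lay.n_g0] = np.log(g0_0 / (1 - g0_0))
    theta[lay.i_sig : lay.i_sig + lay.n_sig] = np.log(sigma0)
    if lay.has_z:
        theta[lay.i_z] = np.log(2.5 - 1.0)
    if lay.has_pi:
        theta[lay.i_pi] = np.log(pi0 / (1 - pi0))
    return theta


def _hessian(f, x: np.ndarray, step: float = 5e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    p = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_secr(
    ch: CaptureHistory,
    traps: TrapArray,
    mask: HabitatMask,
    spec: ModelSpec | None = None,
    starts: Sequence[float] | None = None,
    compute_se: bool = True,
    label: str | None = None,
) -> SECRFit:
    """Maximize the SECR likelihood for one session.

    D is profiled out during optimisation (its conditional MLE is
    ``n / esa``); SEs are delta-method transforms of the inverse Hessian of
    the full negative log likelihood. Fits on sparse data (fewer than 15
    individuals or 5 spatial recaptures) are flagged ``unstable``; data with
    no spatial recaptures are flagged ``non-identifiable``.
    """
    spec = spec or ModelSpec()
    if ch.n == 0:
        raise ValueError("cannot fit an empty capture history")
    data = _FitData(ch, traps, mask, spec)
    lay = data.layout

    flags: list[str] = []
    spatial_recaps = ch.n_spatial_recaptures()
    if spatial_recaps == 0:
        flags.append("non-identifiable")
    if ch.n < 15 or spatial_recaps < 5:
        flags.append("unstable")

    theta0 = (
        np.asarray(starts, dtype=float)
        if starts is not None
        else _default_starts(ch, traps, mask, spec)
    )
    if theta0.shape != (lay.n_params,):
        raise ValueError(f"starts must have length {lay.n_params}")

    n = data.n

    def profile_nll(theta_r: np.ndarray) -> float:
        esa = data.esa(theta_r)
        if not np.isfinite(esa) or esa <= 0:
            return 1e10
        theta = np.concatenate([[np.log(n / esa)], theta_r])
        try:
            val = data.nll(theta)
        except (FloatingPointError, ValueError):
            return 1e10
        return val if np.isfinite(val) else 1e10

    # loose box bounds on the link scales keep the optimizer off the
    # non-identifiable ridge (g0 -> 0 with pi -> 1 and D -> inf) that sparse
    # mixture data can open up; an optimum on a bound is flagged, not trusted
    sigma0 = float(np.exp(theta0[lay.i_sig]))
    bounds = []
    for name, _ in lay.labels()[1:]:
        if name == "g0":
            bounds.append((-11.5, 6.9))  # g0 in [1e-5, 0.999]
        elif name == "sigma":
            bounds.append((np.log(max(0.2, sigma0 / 50)), np.log(sigma0 * 50)))
        elif name == "z":
            bounds.append((np.log(0.05), np.log(25.0)))
        else:  # pmix
            bounds.append((-5.3, 5.3))  # pi in [0.005, 0.995]

    res = minimize(
        profile_nll,
        theta0[1:],
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxfun": 600, "ftol": 1e-10, "gtol": 1e-6},
    )
    if not res.success:
        res2 = minimize(
            profile_nll, res.x, method="Powell", bounds=bounds,
            options={"maxiter": 4000, "ftol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
    at_bound = any(
        min(x - lo, hi - x) < 1e-3 for x, (lo, hi) in zip(res.x, bounds)
    )
    if at_bound:
        flags.append("boundary")
    converged = bool(res.success) and np.isfinite(res.fun) and not at_bound

    theta_r = np.asarray(res.x, dtype=float)
    esa = data.esa(theta_r)
    D_hat = n / esa
    theta = np.concatenate([[np.log(D_hat)], theta_r])
    nll_min = data.nll(theta)
    grad_norm = float(np.linalg.norm(res.jac)) if getattr(res, "jac", None) is not None else np.nan

    k = lay.n_params
    loglik = -nll_min
    aic = 2 * nll_min + 2 * k

    cov = None
    se_link = np.full(k, np.nan)
    if compute_se:
        try:
            H = _hessian(data.nll, theta)
            cov = np.linalg.pinv(H)
            diag = np.diag(cov).copy()
            se_link = np.sqrt(np.where(diag > 0, diag, np.nan))
        except Exception:
            flags.append("se-failed")

    # back-transform estimates and delta-method SEs
    labels = lay.labels()
    est_rows = []
    for j, (name, level) in enumerate(labels):
        x, se = theta[j], se_link[j]
        if name in ("D", "sigma"):
            val = float(np.exp(x))
            se_bt = val * se
        elif name in ("g0", "pmix"):
            val = 1.0 / (1.0 + np.exp(-x))
            se_bt = val * (1 - val) * se
        else:  # z
            val = 1.0 + float(np.exp(x))
            se_bt = float(np.exp(x)) * se
        est_rows.append((name, level, val, float(se_bt) if np.isfinite(se_bt) else np.nan))
    estimates = pd.DataFrame(est_rows, columns=["parameter", "level", "estimate", "se"])

    SE_D = float(estimates.loc[estimates.parameter == "D", "se"].iloc[0])
    pmix = (
        float(estimates.loc[estimates.parameter == "pmix", "estimate"].iloc[0])
        if lay.has_pi
        else None
    )
    if np.isfinite(SE_D) and D_hat > 0 and SE_D / D_hat > 1:
        flags.append("cv-exceeds-1")

    return SECRFit(
        label=label or spec.label(),
        D_hat=float(D_hat),
        SE_D=SE_D,
        estimates=estimates,
        pmix_hat=pmix,
        log_likelihood=float(loglik),
        n_parameters=k,
        AIC=float(aic),
        converged=converged,
        flags=tuple(flags),
        n=n,
        spec=spec,
        data_key=ch.data_key(),
        theta=theta,
        cov=cov,
        gradient_norm=grad_norm,
        session_label=ch.session_label,
    )


# ---------------------------------------------------------------------------
# model selection and density summaries
# ---------------------------------------------------------------------------


def aic_rank(fits: Sequence[SECRFit]) -> pd.DataFrame:
    """Rank fits of the same data by AIC with delta-AIC and Akaike weights."""
    if not fits:
        raise ValueError("no fits to rank")
    keys = {f.data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("aic_rank requires fits of the same dataset")
    df = pd.DataFrame(
        {
            "model": [f.label for f in fits],
            "n_parameters": [f.n_parameters for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "AIC": [f.AIC for f in fits],
        }
    ).sort_values("AIC", kind="stable", ignore_index=True)
    df["dAIC"] = df.AIC - df.AIC.iloc[0]
    rel = np.exp(-0.5 * df.dAIC.to_numpy())
    df["weight"] = rel / rel.sum()
    return df


def summarize_densities(
    fits_by_year: Mapping[int, "SECRFit | float"],
    periods: Iterable[tuple[int, int]],
) -> pd.DataFrame:
    """Mean and range of annual density estimates within year periods.

    ``fits_by_year`` maps year to either a fit or a plain density value;
    ``periods`` is an iterable of inclusive (first, last) year ranges.
    """
    dens = {
        int(y): (f.D_hat if isinstance(f, SECRFit) else float(f))
        for y, f in fits_by_year.items()
    }
    rows = []
    for first, last in periods:
        years = sorted(y for y in dens if first <= y <= last)
        if not years:
            raise ValueError(f"no years in period {first}-{last}")
        vals = np.array([dens[y] for y in years])
        rows.append(
            {
                "period": f"{first}-{last}",
                "n_years": len(years),
                "mean_D": vals.mean(),
                "min_D": vals.min(),
                "min_year": years[int(vals.argmin())],
                "max_D": vals.max(),
                "max_year": years[int(vals.argmax())],
            }
        )
    return pd.DataFrame(rows)
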