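"""Trap-design evaluation: subsampling scenarios and Monte Carlo RB/RMSE.

Two complementary routes for judging a reduced trapping design against the
full one:

1. *Subsampling*: delete traps and/or occasions from observed (or
   simulated) capture histories, refit, and compare density estimates
   session by session. A reduced design "replicates" a session when its
   estimate falls within one standard error of the full-design estimate.
2. *Monte Carlo*: simulate populations and captures under a candidate
   design using known truth, refit each replicate, and summarize relative
   bias RB_j = (Dhat_j - D_j) / D_j and RMSE = sqrt(mean((Dhat_j - D_j)^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    TrapArray,
    build_grid,
    build_mask,
    checkerboard_halve,
    subgrid,
)
from .likelihood import CaptureHistory, ModelSpec, SECRFit, fit_secr
from .synthetic import SessionTruth, simulate_capthist, simulate_population

__all__ = [
    "DesignScenario",
    "ComparisonRecord",
    "DesignComparison",
    "MonteCarloResult",
    "standard_scenarios",
    "apply_trap_rule",
    "subsample_capthist",
    "compare_to_full",
    "comparison_from_values",
    "summarize_comparisons",
    "relative_bias",
    "rmse",
    "monte_carlo_eval",
    "capture_efficiency",
    "trap_nights",
]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DesignScenario:
    """One reduced-design rule: a trap subset plus retained occasions.

    ``rule`` is one of ``("full",)``, ``("n_by_n", n, anchor)``,
    ``("checkerboard_half",)`` or ``("respaced", spacing, mode)`` with mode
    ``"count"`` (keep trap count, rescale extent — the default) or
    ``"extent"`` (keep extent, change trap count). ``occasions`` lists the
    retained 1-based occasion indices (None keeps all).
    """

    label: str
    rule: tuple = ("full",)
    occasions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        kinds = {"full", "n_by_n", "checkerboard_half", "respaced"}
        if not self.rule or self.rule[0] not in kinds:
            raise ValueError(f"unknown trap-subset rule {self.rule!r}")
        if self.occasions is not None:
            occ = tuple(sorted(set(int(o) for o in self.occasions)))
            if not occ or any(o < 1 for o in occ):
                raise ValueError("retained occasions must be a non-empty 1-based set")
            object.__setattr__(self, "occasions", occ)

    def retained_occasions(self, n_occasions: int) -> tuple[int, ...]:
        if self.occasions is None:
            return tuple(range(1, n_occasions + 1))
        if max(self.occasions) > n_occasions:
            raise ValueError(
                f"scenario {self.label!r} retains occasion {max(self.occasions)} "
                f"but the session has only {n_occasions}"
            )
        return self.occasions


def standard_scenarios(n_occasions: int = 4) -> list[DesignScenario]:
    """The evaluated battery: n x n reductions, half density, 3-night.

    The 3-night scenario drops the final occasion; pass explicit
    ``occasions`` to a custom scenario to test other choices. Sub-grids are
    anchored NW by default (the five-placement variants cover the rest).
    """
    scen = [DesignScenario("full")]
    scen += [
        DesignScenario(f"{n}x{n}", ("n_by_n", n, "NW")) for n in (9, 8, 7, 6, 5, 4)
    ]
    scen.append(DesignScenario("half", ("checkerboard_half",)))
    scen.append(
        DesignScenario("3day", ("full",), tuple(range(1, n_occasions)))
    )
    return scen


def apply_trap_rule(traps: TrapArray, scenario: DesignScenario) -> TrapArray:
    """Materialize a scenario's trap subset from the base design."""
    kind = scenario.rule[0]
    if kind == "full":
        return traps
    if kind == "n_by_n":
        _, n, anchor = scenario.rule
        return subgrid(traps, n, anchor)
    if kind == "checkerboard_half":
        return checkerboard_halve(traps)
    # respaced: regular grid at a new spacing
    _, spacing, mode = scenario.rule
    from .geometry import _lattice_indices  # reuse lattice validation

    rows, cols, step, _ = _lattice_indices(traps)
    n_rows, n_cols = rows.max() + 1, cols.max() + 1
    if mode == "count":
        return build_grid(n_cols, n_rows, spacing)
    if mode == "extent":
        width, height = (n_cols - 1) * step, (n_rows - 1) * step
        return build_grid(int(width // spacing) + 1, int(height // spacing) + 1, spacing)
    raise ValueError(f"unknown respace mode {mode!r}")


def subsample_capthist(
    ch: CaptureHistory, traps: TrapArray, scenario: DesignScenario
) -> tuple[CaptureHistory, TrapArray]:
    """Restrict a capture history to a scenario's traps and occasions.

    Records at removed traps or occasions are deleted, retained occasions
    are renumbered consecutively, and individuals left with no records are
    dropped, exactly as if the reduced design had been run in the field.
    """
    sub_traps = apply_trap_rule(traps, scenario)
    if scenario.rule[0] == "respaced":
        raise ValueError("respaced designs cannot be subsampled from field data")
    keep_traps = set(sub_traps.trap_id)
    occ = scenario.retained_occasions(ch.n_occasions)
    occ_map = {o: i + 1 for i, o in enumerate(occ)}
    records = tuple(
        (ind, occ_map[o], trap)
        for ind, o, trap in ch.records
        if trap in keep_traps and o in occ_map
    )
    kept_inds = {r[0] for r in records}
    sex = {i: s for i, s in ch.sex.items() if i in kept_inds}
    sub_ch = CaptureHistory(records, len(occ), sex, ch.session_label)
    return sub_ch, sub_traps


# ---------------------------------------------------------------------------
# full-vs-reduced comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRecord:
    """Per-session comparison of a reduced design against the full one."""

    session: str
    D_full: float
    SE_full: float
    D_sub: float
    difference: float  # D_full - D_sub
    abs_difference: float
    pct_abs_difference: float
    within_se: bool | None  # None when SE_full is unavailable


@dataclass(frozen=True)
class DesignComparison:
    """Summary of per-session comparisons for one scenario."""

    label: str
    records: tuple[ComparisonRecord, ...]
    mean_difference: float
    mean_abs_difference: float
    max_abs_difference: float
    replication_rate: float | None  # percent of sessions within 1 SE_full


def comparison_from_values(
    session: str, D_full: float, D_sub: float, SE_full: float = np.nan
) -> ComparisonRecord:
    """Build a comparison record from raw density values."""
    diff = D_full - D_sub
    return ComparisonRecord(
        session=str(session),
        D_full=float(D_full),
        SE_full=float(SE_full),
        D_sub=float(D_sub),
        difference=float(diff),
        abs_difference=abs(float(diff)),
        pct_abs_difference=100.0 * abs(diff) / D_full if D_full else np.nan,
        within_se=bool(abs(diff) <= SE_full) if np.isfinite(SE_full) else None,
    )


def compare_to_full(full: SECRFit, sub: SECRFit) -> ComparisonRecord:
    """Compare a reduced-design fit with the full-design fit of a session."""
    if full.session_label != sub.session_label:
        raise ValueError(
            f"session mismatch: {full.session_label!r} vs {sub.session_label!r}"
        )
    return comparison_from_values(
        full.session_label, full.D_hat, sub.D_hat, full.SE_D
    )


def summarize_comparisons(
    records: Sequence[ComparisonRecord], label: str = ""
) -> DesignComparison:
    """Mean / absolute-mean / absolute-max difference and replication rate."""
    if not records:
        raise ValueError("no comparison records to summarize")
    diffs = np.array([r.difference for r in records])
    flags = [r.within_se for r in records]
    rate = (
        100.0 * sum(bool(f) for f in flags) / len(flags)
        if all(f is not None for f in flags)
        else None
    )
    return DesignComparison(
        label=label,
        records=tuple(records),
        mean_difference=float(diffs.mean()),
        mean_abs_difference=float(np.abs(diffs).mean()),
        max_abs_difference=float(np.abs(diffs).max()),
        replication_rate=rate,
    )


# ---------------------------------------------------------------------------
# Monte Carlo evaluation
# ---------------------------------------------------------------------------


def relative_bias(estimate: float, truth: float) -> float:
    """RB = (estimate - truth) / truth."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    return (estimate - truth) / truth


def rmse(estimates: Sequence[float], truths: "Sequence[float] | float") -> float:
    """Root mean square error of estimates against truth(s)."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    tru = np.asarray(truths, dtype=float)
    if tru.ndim == 0:
        tru = np.full_like(est, float(tru))
    if tru.shape != est.shape:
        raise ValueError("estimates and truths differ in length")
    return float(np.sqrt(np.mean((est - tru) ** 2)))


@dataclass(frozen=True)
class MonteCarloResult:
    """Replicate density estimates and RB/RMSE summary for one scenario."""

    label: str
    true_D: tuple[float, ...]
    estimates: tuple[float, ...]  # converged replicates only
    rb: tuple[float, ...]
    mean_rb: float
    rmse: float
    n_reps: int
    n_excluded: int
    excluded_reasons: tuple[str, ...] = field(default=())
    detail: tuple[dict, ...] = field(default=())  # per-replicate estimates

    @property
    def rb_sd(self) -> float:
        return float(np.std(self.rb, ddof=1)) if len(self.rb) > 1 else np.nan

    def detail_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.detail))


def monte_carlo_eval(
    truth: SessionTruth,
    scenario: DesignScenario,
    n_reps: int,
    seed: int,
    base_traps: TrapArray | None = None,
    n_occasions: int = 4,
    detectfn: str = "EX",
    buffer: float = 50.0,
    mask_spacing: float | None = None,
    fit_spec: ModelSpec | None = None,
    progress: bool = False,
) -> MonteCarloResult:
    """Simulate-and-refit evaluation of one design scenario.

    Each replicate draws a population at the true density over the
    scenario design's buffered mask extent, simulates captures with the
    true detection parameters, and refits the generating model
    (sex-specific detection by default). Replicates that fail to converge
    or carry no spatial recaptures are excluded from the summaries but
    counted and reported.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    base = base_traps if base_traps is not None else build_grid(10, 10, 9.43)
    traps = apply_trap_rule(base, scenario)
    occ = scenario.retained_occasions(n_occasions)
    S = len(occ)
    mask = build_mask(traps, buffer, mask_spacing)
    spec = fit_spec or ModelSpec(
        detectfn=detectfn,
        g0_effects=frozenset({"sex"}),
        sigma_effects=frozenset({"sex"}),
    )
    params = truth.params(detectfn)

    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    estimates: list[float] = []
    reasons: list[str] = []
    detail: list[dict] = []
    iterator = range(n_reps)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=scenario.label or "mc")
    for j in iterator:
        rng = np.random.default_rng(seeds[j])
        pop = simulate_population(truth.D, mask, truth.pmix, rng)
        ch = simulate_capthist(
            pop, traps, S, params, seed=rng, session_label=f"rep{j}"
        )
        if ch.n < 2 or ch.n_spatial_recaptures() == 0:
            reasons.append(f"rep{j}: too sparse ({ch.n} individuals)")
            continue
        try:
            fit = fit_secr(ch, traps, mask, spec, compute_se=False)
        except Exception as exc:  # pragma: no cover - defensive
            reasons.append(f"rep{j}: fit error ({exc})")
            continue
        if not fit.converged or not np.isfinite(fit.D_hat):
            reasons.append(f"rep{j}: non-converged")
            continue
        estimates.append(fit.D_hat)
        row = {"rep": j, "n": fit.n, "D_hat": fit.D_hat}
        for r in fit.estimates.itertuples():
            if r.parameter != "D":
                key = f"{r.parameter}_{r.level}" if r.level else r.parameter
                row[key] = r.estimate
        detail.append(row)
    if not estimates:
        raise RuntimeError(
            f"all {n_reps} replicates failed for scenario {scenario.label!r}"
        )
    rb = [relative_bias(d, truth.D) for d in estimates]
    return MonteCarloResult(
        label=scenario.label,
        true_D=tuple([truth.D] * len(estimates)),
        estimates=tuple(estimates),
        rb=tuple(rb),
        mean_rb=float(np.mean(rb)),
        rmse=rmse(estimates, truth.D),
        n_reps=n_reps,
        n_excluded=len(reasons),
        excluded_reasons=tuple(reasons),
        detail=tuple(detail),
    )


# ---------------------------------------------------------------------------
# effort bookkeeping
# ---------------------------------------------------------------------------


def trap_nights(
    traps: "TrapArray | int", n_occasions: int, n_sessions: int = 1
) -> int:
    """Total effort: traps x occasions x sessions."""
    k = len(traps) if isinstance(traps, TrapArray) else int(traps)
    if k < 1 or n_occasions < 1 or n_sessions < 1:
        raise ValueError("all effort factors must be positive")
    return k * int(n_occasions) * int(n_sessions)


def capture_efficiency(ch: CaptureHistory, trap_nights: int) -> float:
    """Distinct individuals per 100 trap nights.

    A simple field index of catch per effort; defined here as
    100 x (distinct individuals) / trap-nights.
    """
    if trap_nights <= 0:
        raise ValueError("trap_nights must be positive")
    return 100.0 * ch.n / trap_nights
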