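"""Detection functions and multi-catch capture-probability machinery.

A detection function g(d) gives the per-occasion probability that an animal
whose activity center is distance d from a trap is caught *by that trap in
isolation*. With several traps competing for the same animal the per-trap
probabilities follow the standard competing-hazards construction for
multi-catch detectors: each trap contributes hazard h_k = -ln(1 - g(d_k)),
the animal is caught with probability 1 - exp(-H) where H = sum_k h_k, and
conditional on capture the trap is chosen with probability h_k / H.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .geometry import TrapArray

__all__ = [
    "DetectionParams",
    "detect_g",
    "trap_hazard",
    "multicatch_probs",
    "p_dot",
]

DetectFn = Literal["HN", "EX", "HR"]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of one detection function.

    g0 is the capture probability at distance zero, sigma the spatial scale
    in meters (a home-range size index), z the hazard-rate shape (used only
    when ``kind == "HR"``). g0 = 0 is tolerated as a degenerate value for
    simulation; fitted values are strictly interior.
    """

    g0: float
    sigma: float
    kind: DetectFn = "EX"
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.g0 < 1.0:
            raise ValueError("g0 must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kind not in ("HN", "EX", "HR"):
            raise ValueError(f"unknown detection function {self.kind!r}")
        if self.kind == "HR":
            if self.z is None or self.z <= 1:
                raise ValueError("hazard-rate shape z must exceed 1")


def detect_g(d, params: DetectionParams):
    """Evaluate the detection function at distance(s) ``d`` (meters).

    HN: g0 exp(-d^2 / (2 sigma^2));  EX: g0 exp(-d / sigma);
    HR: g0 (1 - exp(-(d / sigma)^(-z))).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    s = params.sigma
    if params.kind == "HN":
        g = params.g0 * np.exp(-(d**2) / (2 * s**2))
    elif params.kind == "EX":
        g = params.g0 * np.exp(-d / s)
    else:  # HR
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(d > 0, (d / s) ** (-params.z), np.inf)
        g = params.g0 * (-np.expm1(-ratio))
    return g if g.ndim else float(g)


def trap_hazard(g):
    """Competing-risk hazard h = -ln(1 - g) of a per-occasion probability."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("capture probability must be non-negative")
    if np.any(g >= 1):
        raise OverflowError("hazard is infinite for capture probability >= 1")
    h = -np.log1p(-g)
    return h if h.ndim else float(h)


def multicatch_probs(
    center: Sequence[float], traps: TrapArray, params: DetectionParams
) -> np.ndarray:
    """Per-occasion outcome probabilities for one animal and one trap set.

    Returns an array of length ``n_traps + 1``: capture probability at each
    trap, with the not-caught probability exp(-H) in the final slot. The
    entries sum to one.
    """
    center = np.asarray(center, dtype=float)
    d = np.hypot(*(traps.coords - center).T)
    h = trap_hazard(detect_g(d, params))
    H = h.sum()
    out = np.empty(len(traps) + 1)
    if H == 0.0:
        out[:-1] = 0.0
        out[-1] = 1.0
        return out
    out[:-1] = h / H * -np.expm1(-H)
    out[-1] = np.exp(-H)
    return out


def p_dot(
    center: Sequence[float],
    traps: TrapArray,
    n_occasions: int,
    params_per_occasion: DetectionParams | Sequence[DetectionParams],
) -> float:
    """Probability of at least one capture over a session.

    ``params_per_occasion`` may be a single parameter set (applied to every
    occasion) or one set per occasion. Because per-occasion escape
    probability is exp(-H_s), the session-level escape is
    exp(-sum_s H_s) and p. = 1 - exp(-sum_s H_s).
    """
    if n_occasions < 1:
        raise ValueError("n_occasions must be positive")
    if isinstance(params_per_occasion, DetectionParams):
        params_seq = [params_per_occasion] * n_occasions
    else:
        params_seq = list(params_per_occasion)
        if len(params_seq) != n_occasions:
            raise ValueError("need one parameter set per occasion")
    center = np.asarray(center, dtype=float)
    d = np.hypot(*(traps.coords - center).T)
    H_total = 0.0
    for p in params_seq:
        H_total += trap_hazard(detect_g(d, p)).sum()
    return float(-np.expm1(-H_total))
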