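"""Independent brute-force oracles for the SECR likelihood.

Everything here is deliberately naive: detection probabilities are computed
with scalar arithmetic, session probabilities by exhaustive enumeration of
all per-occasion outcome sequences at every mask point. Feasible only for
a handful of traps/occasions; used to pin the vectorized likelihood.
"""

import itertools
import math


def detect_g_scalar(d, g0, sigma, kind="EX", z=None):
    if kind == "HN":
        return g0 * math.exp(-(d**2) / (2 * sigma**2))
    if kind == "EX":
        return g0 * math.exp(-d / sigma)
    if d == 0:
        return g0
    return g0 * (1.0 - math.exp(-((d / sigma) ** (-z))))


def outcome_probs(center, trap_coords, g0, sigma, kind="EX", z=None):
    """Multi-catch outcome distribution: one entry per trap plus not-caught."""
    h = []
    for tx, ty in trap_coords:
        d = math.hypot(center[0] - tx, center[1] - ty)
        g = detect_g_scalar(d, g0, sigma, kind, z)
        h.append(-math.log(1.0 - g))
    H = sum(h)
    if H == 0.0:
        return [0.0] * len(h) + [1.0]
    pcap = 1.0 - math.exp(-H)
    return [hk / H * pcap for hk in h] + [math.exp(-H)]


def pr_history(occ_traps, center, trap_coords, params_per_occasion):
    """Pr(observed history | center) by enumerating joint outcome sequences.

    occ_traps: per-occasion trap index, -1 for not caught.
    params_per_occasion: per-occasion (g0, sigma, kind, z) tuples.
    """
    S, K = len(occ_traps), len(trap_coords)
    probs = [
        outcome_probs(center, trap_coords, *params_per_occasion[s]) for s in range(S)
    ]
    none = K  # index of the not-caught outcome
    total = 0.0
    for seq in itertools.product(range(K + 1), repeat=S):
        target = tuple(none if t == -1 else t for t in occ_traps)
        if seq == target:
            p = 1.0
            for s in range(S):
                p *= probs[s][seq[s]]
            total += p
    return total


def pdot_enum(center, trap_coords, params_per_occasion):
    """P(caught at least once) by enumeration (complement of all-none)."""
    S, K = len(params_per_occasion), len(trap_coords)
    probs = [
        outcome_probs(center, trap_coords, *params_per_occasion[s]) for s in range(S)
    ]
    total = 0.0
    for seq in itertools.product(range(K + 1), repeat=S):
        if any(o != K for o in seq):
            p = 1.0
            for s in range(S):
                p *= probs[s][seq[s]]
            total += p
    return total


def oracle_negloglik(histories, classes, pi, D, mask_points, cell_area,
                     trap_coords, params_by_class, history_params=None):
    """Full Poisson-n SECR negative log likelihood by brute force.

    histories: list of per-occasion trap-index tuples (-1 = not caught).
    classes: class index per individual; -1 marginalizes over classes
    (unknown sex). pi: class proportions. params_by_class: per class, per
    occasion (g0, sigma, kind, z) tuples, used for the exposure term
    Lambda and, unless overridden, for the histories. history_params
    optionally gives per-individual, per-class, per-occasion parameters
    (e.g. switched after first capture for a behavioral response).
    """
    n = len(histories)
    lam = 0.0
    for u, pu in enumerate(pi):
        for m in mask_points:
            lam += D * cell_area * pu * pdot_enum(m, trap_coords, params_by_class[u])
    ll = -lam
    for i in range(n):
        def class_term(u):
            params = (
                history_params[i][u] if history_params is not None
                else params_by_class[u]
            )
            return pi[u] * sum(
                pr_history(histories[i], m, trap_coords, params)
                for m in mask_points
            )

        if classes[i] == -1:
            s = sum(class_term(u) for u in range(len(pi)))
        else:
            s = class_term(classes[i])
        ll += math.log(D * cell_area * s)
    ll -= math.lgamma(n + 1)
    return -ll
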