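"""Plain-text readers and writers for trap layouts, capture histories,
truth ledgers, masks, and fit reports.

All formats are delimited text (whitespace or comma), with ``#`` comment
lines and 1-based occasions, mirroring typical field data sheets. Readers
validate and reject malformed rows with line numbers; nothing is silently
repaired. Floats are written with six significant digits.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import HabitatMask, TrapArray
from .likelihood import CaptureHistory, SECRFit

__all__ = [
    "read_traps",
    "write_traps",
    "read_capthist",
    "write_capthist",
    "write_mask",
    "write_truth_ledger",
    "read_truth_ledger",
    "write_fit_report",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _tokenize(path: str | os.PathLike) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            rows.append((lineno, tokens))
    return rows


# ---------------------------------------------------------------------------
# traps
# ---------------------------------------------------------------------------


def read_traps(path: str | os.PathLike, detector_kind: str = "multi_catch") -> TrapArray:
    """Read a trap file with columns ``trap_id x y`` (meters)."""
    ids: list[str] = []
    coords: list[tuple[float, float]] = []
    for lineno, tokens in _tokenize(path):
        if tokens[0].lower() == "trap_id":
            continue  # optional header
        if len(tokens) != 3:
            raise ParseError(f"{path}:{lineno}: expected 'trap_id x y', got {tokens}")
        try:
            x, y = float(tokens[1]), float(tokens[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
        if tokens[0] in ids:
            raise ParseError(f"{path}:{lineno}: duplicate trap_id {tokens[0]!r}")
        ids.append(tokens[0])
        coords.append((x, y))
    if not ids:
        raise ParseError(f"{path}: no trap rows found")
    return TrapArray(tuple(ids), np.array(coords), detector_kind)


def write_traps(traps: TrapArray, path: str | os.PathLike) -> None:
    """Write a trap file in deterministic (input) order, full precision."""
    with open(path, "w") as fh:
        fh.write("# trap_id x y\n")
        for tid, (x, y) in zip(traps.trap_id, traps.coords):
            fh.write(f"{tid} {float(x)!r} {float(y)!r}\n")


# ---------------------------------------------------------------------------
# capture histories
# ---------------------------------------------------------------------------


def read_capthist(
    path: str | os.PathLike,
    traps: TrapArray,
    n_occasions: int | None = None,
    session: str | None = None,
) -> "CaptureHistory | dict[str, CaptureHistory]":
    """Read capture records ``session individual occasion trap_id sex``.

    The file may carry a ``# n_occasions = S`` metadata line; otherwise
    pass ``n_occasions`` (default: the largest occasion seen). Returns a
    single history when the file holds one session (or ``session`` selects
    one), else a dict keyed by session label.
    """
    meta_occ = None
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") and "n_occasions" in raw:
                meta_occ = int(raw.split("=", 1)[1])
    rows: dict[str, list[tuple[str, int, str]]] = {}
    sex: dict[str, dict[str, str]] = {}
    known = set(traps.trap_id)
    max_occ = 0
    for lineno, tokens in _tokenize(path):
        if tokens[0].lower() == "session":
            continue
        if len(tokens) != 5:
            raise ParseError(
                f"{path}:{lineno}: expected 'session individual occasion trap_id sex'"
            )
        ses, ind, occ_s, trap, sx = tokens
        try:
            occ = int(occ_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer occasion {occ_s!r}") from None
        if trap not in known:
            raise ParseError(f"{path}:{lineno}: unknown trap_id {trap!r}")
        if sx not in ("F", "M", "unknown"):
            raise ParseError(f"{path}:{lineno}: bad sex label {sx!r}")
        prev = sex.setdefault(ses, {}).get(ind)
        if prev is not None and prev != sx:
            raise ParseError(f"{path}:{lineno}: conflicting sex for {ind!r}")
        sex[ses][ind] = sx
        rows.setdefault(ses, []).append((ind, occ, trap))
        max_occ = max(max_occ, occ)
    if not rows:
        raise ParseError(f"{path}: no capture rows found")
    S = n_occasions or meta_occ or max_occ
    out: dict[str, CaptureHistory] = {}
    for ses, recs in rows.items():
        for ind, occ, trap in recs:
            if occ > S:
                raise ParseError(
                    f"{path}: occasion {occ} exceeds n_occasions={S} in session {ses}"
                )
        try:
            out[ses] = CaptureHistory(tuple(recs), S, sex[ses], ses)
        except ValueError as exc:
            raise ParseError(f"{path}: session {ses}: {exc}") from None
    if session is not None:
        return out[session]
    return next(iter(out.values())) if len(out) == 1 else out


def write_capthist(
    histories: "CaptureHistory | Sequence[CaptureHistory]",
    path: str | os.PathLike,
) -> None:
    """Write one or more sessions to a single capture-history file."""
    if isinstance(histories, CaptureHistory):
        histories = [histories]
    S = max(ch.n_occasions for ch in histories)
    with open(path, "w") as fh:
        fh.write(f"# n_occasions = {S}\n")
        fh.write("# session individual occasion trap_id sex\n")
        for ch in histories:
            for ind, occ, trap in sorted(ch.records, key=lambda r: (r[0], r[1])):
                fh.write(f"{ch.session_label} {ind} {occ} {trap} {ch.sex[ind]}\n")


# ---------------------------------------------------------------------------
# masks, truth ledgers, fit reports
# ---------------------------------------------------------------------------


def write_mask(mask: HabitatMask, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_area_ha = {mask.cell_area!r}\n")
        fh.write(f"# buffer_m = {mask.buffer_width!r}\n")
        fh.write("# x y\n")
        for x, y in mask.points:
            fh.write(f"{x:.6g} {y:.6g}\n")


def write_truth_ledger(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, index=False, float_format="%.6g")


def read_truth_ledger(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_fit_report(fit: SECRFit, path: str | os.PathLike) -> None:
    """Machine-readable key-value fit report plus the estimate table."""
    lines = [
        f"session = {fit.session_label}",
        f"model = {fit.label}",
        f"n = {fit.n}",
        f"D_hat = {fit.D_hat:.6g}",
        f"SE_D = {fit.SE_D:.6g}",
        f"log_likelihood = {fit.log_likelihood:.10g}",
        f"n_parameters = {fit.n_parameters}",
        f"AIC = {fit.AIC:.6g}",
        f"converged = {fit.converged}",
        f"flags = {','.join(fit.flags) or 'none'}",
    ]
    if fit.pmix_hat is not None:
        lines.append(f"pmix_F = {fit.pmix_hat:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n\n")
        fh.write(fit.estimates.to_string(index=False, float_format="%.6g"))
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline configuration, loadable from a YAML file.

    Every output artifact records the seed, so any result table is
    reproducible from the config plus seed alone.
    """

    traps: str | None = None
    captures: str | None = None
    out_dir: str = "secrgrid-out"
    detectfn: str = "EX"
    g0_effects: tuple[str, ...] = ("sex",)
    sigma_effects: tuple[str, ...] = ("sex",)
    buffer: float | None = None  # explicit meters; None -> sigma rule
    buffer_sigma: float = 12.5  # initial sigma for the buffer rule
    buffer_multiplier: float = 4.0
    mask_spacing: float | None = None
    scenarios: tuple[str, ...] = ("9x9", "8x8", "7x7", "6x6", "half", "3day")
    n_reps: int = 100
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("g0_effects", "sigma_effects", "scenarios"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def buffer_width(self) -> float:
        if self.buffer is not None:
            return float(self.buffer)
        return self.buffer_multiplier * self.buffer_sigma

    def ensure_out_dir(self) -> Path:
        p = Path(self.out_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p
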