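"""Sequence-level design evaluation: recovery, identity and similarity.

* ``nsr`` — native sequence recovery, the fraction of positions at which a
  design reproduces the native residue: ``nsr = (1/N) sum_i
  ident(design[i], native[i])``. Restricting the sum to a position subset
  (e.g. the coupled-network residues) gives the subset recovery nsr_CN.
* ``seqsim`` — mean per-position BLOSUM62 score between design and native:
  ``seqsim = (1/N) sum_i BLOSUM62(design[i], native[i])``.

The standard BLOSUM62 half-bit integer table is vendored as a package data
file and integrity-checked at load, so scores cannot drift with an external
dependency's matrix edition. Positions where either sequence carries the
ambiguity letter X are excluded from both denominators; the number of scored
positions is reported by :func:`evaluate_designs`.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from ._common import ParameterError, RescueError

__all__ = [
    "SubstitutionMatrix",
    "blosum62",
    "ident",
    "nsr",
    "seqsim",
    "evaluate_designs",
    "summarize_report",
]

_BLOSUM62_SHA256 = (
    "6807253e203d5c0bfca7176afaf33b6cc611966c81b9cc21c04219d1d2218bf2"
)


class SubstitutionMatrix:
    """Integer substitution score table (symmetric over the 20 canonical
    amino-acid letters; ambiguity rows B/Z/X included)."""

    def __init__(self, name: str, letters: str, table: np.ndarray):
        self.name = name
        self.letters = letters
        self._index = {c: k for k, c in enumerate(letters)}
        self.table = table

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.table[self._index[a.upper()],
                                  self._index[b.upper()]])
        except KeyError as exc:
            raise RescueError(
                f"letter {exc.args[0]!r} absent from {self.name}")

    def __contains__(self, a: str) -> bool:
        return a.upper() in self._index


def _load_blosum62() -> SubstitutionMatrix:
    text = (resources.files("rescue") / "data" / "blosum62.txt").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _BLOSUM62_SHA256:
        raise RescueError("vendored BLOSUM62 file failed its integrity check")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    letters = "".join(lines[0].split())
    table = np.array([[int(v) for v in ln.split()[1:]] for ln in lines[1:]])
    return SubstitutionMatrix("BLOSUM62", letters, table)


_BLOSUM62: SubstitutionMatrix | None = None


def blosum62() -> SubstitutionMatrix:
    """The vendored standard BLOSUM62 matrix (cached)."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _load_blosum62()
    return _BLOSUM62


def ident(a: str, b: str) -> int:
    """1 iff the two residue letters are identical (case-insensitive)."""
    return int(a.upper() == b.upper())


def _scored_positions(seq_design: str, seq_native: str, subset=None):
    if len(seq_design) != len(seq_native):
        raise RescueError("design and native sequences differ in length")
    n = len(seq_native)
    if subset is None:
        positions = range(n)
    else:
        positions = sorted(set(int(p) for p in subset))
        if not positions:
            raise ParameterError("position subset is empty")
        if positions[0] < 0 or positions[-1] >= n:
            raise ParameterError("subset positions outside sequence range")
    kept = [p for p in positions
            if seq_design[p].upper() != "X" and seq_native[p].upper() != "X"]
    if not kept:
        raise RescueError("no scorable positions (all ambiguous)")
    return kept


def nsr(seq_design: str, seq_native: str, subset=None) -> float:
    """Native sequence recovery: mean identity over positions.

    ``subset`` (0-based positions) restricts the mean, giving the coupled-
    network variant nsr_CN when the subset is a residue network.
    """
    kept = _scored_positions(seq_design, seq_native, subset)
    return float(np.mean([ident(seq_design[p], seq_native[p]) for p in kept]))


def seqsim(seq_design: str, seq_native: str, subset=None) -> float:
    """Mean per-position BLOSUM62 score between design and native."""
    kept = _scored_positions(seq_design, seq_native, subset)
    m = blosum62()
    return float(np.mean([m.score(seq_design[p], seq_native[p])
                          for p in kept]))


def evaluate_designs(designs, native: str, model=None, subset=None,
                     ids=None) -> pd.DataFrame:
    """Per-design evaluation table.

    One row per design with nsr, seqsim, the coupling strength cs and
    recovery crs versus ``native`` (when a model is given), the subset
    recovery nsr_subset (when a subset is given), and the number of scored
    positions. Use :func:`summarize_report` for ensemble mean +- sd.
    """
    from .scoring import coupling_strength  # local: avoid import cycle

    designs = list(designs)
    if not designs:
        raise ParameterError("no designs to evaluate")
    if ids is None:
        ids = [f"design_{k + 1}" for k in range(len(designs))]
    cs_nat = coupling_strength(model, native) if model is not None else None
    rows = []
    for name, seq in zip(ids, designs):
        row = {
            "id": name,
            "nsr": nsr(seq, native),
            "seqsim": seqsim(seq, native),
            "n_scored": len(_scored_positions(seq, native)),
        }
        if model is not None:
            cs = coupling_strength(model, seq)
            row["cs"] = cs
            row["crs"] = cs / cs_nat if cs_nat else np.nan
        if subset is not None:
            row["nsr_subset"] = nsr(seq, native, subset=subset)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Ensemble mean and standard deviation of every numeric column."""
    num = report.select_dtypes("number")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
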