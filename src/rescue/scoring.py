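"""Coupling scores for sequences under a Potts model.

Three scores quantify how well a sequence realizes the co-evolutionary
couplings of a model:

* ``cc(i)`` — the per-residue coupling constraint, the sum of tensor entries
  linking position ``i`` (with the sequence's amino acid there) to every
  other position ``j`` with its amino acid: ``cc(i) = sum_{j!=i}
  DC_ij(seq[i], seq[j])``.
* ``cs(seq)`` — the coupling strength, ``sum_i cc(i)``. Each unordered pair
  is deliberately counted twice (once in ``cc(i)``, once in ``cc(j)``),
  exactly as the per-residue sums compose; the ratio below cancels the
  factor.
* ``crs`` — the coupling recovery score of a design versus the native
  sequence, ``cs(design) / cs(native)``; it may exceed 1 when a design
  realizes couplings found in homologs but not in the native sequence.

Gap ('-') and ambiguity ('X') letters contribute zero: a gap/X at ``j``
adds nothing to ``cc(i)``, and ``cc(i) = 0`` when position ``i`` itself is
gap/X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._common import GAP, RescueError, UndefinedScoreError
from .potts import PottsModel

__all__ = [
    "CCProfile",
    "coupling_constraint",
    "coupling_strength",
    "coupling_recovery",
    "cc_profile",
]


@dataclass
class CCProfile:
    """Per-position coupling constraints cc(i) of one sequence."""

    sequence: str
    values: np.ndarray
    model: PottsModel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.model.L:
            raise RescueError("profile length does not match model L")
        if not np.all(np.isfinite(self.values)):
            raise RescueError("cc values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _encode_masked(model: PottsModel, seq: str):
    """States plus a validity mask; gap and X are masked out (score zero)."""
    seq = seq.upper()
    if len(seq) != model.L:
        raise RescueError(
            f"sequence length {len(seq)} does not match model L={model.L}")
    idx = model.state_index()
    states = np.zeros(model.L, dtype=np.int64)
    mask = np.zeros(model.L, dtype=bool)
    for k, c in enumerate(seq):
        if c == GAP or c == "X":
            continue
        if c not in idx:
            raise RescueError(f"letter {c!r} not in model alphabet")
        states[k] = idx[c]
        mask[k] = True
    return states, mask


def cc_profile(model: PottsModel, seq: str) -> CCProfile:
    """Vectorized cc(i) for every position of ``seq`` (Potts tensor row sums
    selected by the sequence's amino acids)."""
    states, mask = _encode_masked(model, seq)
    L = model.L
    pair = model.couplings[
        np.arange(L)[:, None], np.arange(L)[None, :],
        states[:, None], states[None, :],
    ]
    pair[~mask, :] = 0.0
    pair[:, ~mask] = 0.0
    np.fill_diagonal(pair, 0.0)
    return CCProfile(sequence=seq, values=pair.sum(axis=1), model=model)


def coupling_constraint(model: PottsModel, seq: str, i: int) -> float:
    """cc(i) = sum over j != i of DC_ij(seq[i], seq[j])."""
    if not 0 <= i < model.L:
        raise RescueError(f"position {i} outside [0, {model.L})")
    return float(cc_profile(model, seq).values[i])


def coupling_strength(model: PottsModel, seq: str) -> float:
    """cs(seq) = sum_i cc(i); each unordered pair counted twice."""
    return float(cc_profile(model, seq).values.sum())


def coupling_recovery(model: PottsModel, seq_design: str,
                      seq_native: str) -> float:
    """crs = cs(design) / cs(native); raises when cs(native) == 0."""
    cs_nat = coupling_strength(model, seq_native)
    if cs_nat == 0.0:
        raise UndefinedScoreError(
            "cs(native) is zero; coupling recovery is undefined")
    if cs_nat < 0.0:
        warnings.warn("cs(native) < 0: the sign of crs inverts its meaning")
    return coupling_strength(model, seq_design) / cs_nat
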