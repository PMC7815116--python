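"""Potts (Markov random field) models over aligned sequence positions.

A Potts model assigns each sequence ``s`` of length ``L`` over ``q`` states a
score

    S(s) = sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j)

where ``h`` are per-position fields (amino-acid preferences) and ``J`` is the
4-D coupling tensor DC_{i,j}(aa_x, aa_y): large positive entries mark amino
acid pairs that co-occur in evolution, negative entries mark incompatible
pairs. Models are inferred from a weighted multiple sequence alignment by
L2-regularized pseudolikelihood maximization (the plmDCA/GREMLIN family of
estimators) and brought into the zero-sum gauge so that downstream coupling
scores are uniquely defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.optimize
from scipy.special import logsumexp, softmax

from ._common import (
    GAP,
    FormatError,
    NumericalError,
    ParameterError,
    RescueError,
    default_alphabet,
)

__all__ = [
    "PottsModel",
    "CouplingMatrix",
    "infer_potts",
    "coupling_magnitudes",
    "import_tensor",
    "export_tensor",
]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class PottsModel:
    """Fields and pairwise coupling tensor of a Potts model.

    Attributes
    ----------
    fields : ndarray, shape (L, q)
        Per-position state preferences h_i(a), dimensionless.
    couplings : ndarray, shape (L, L, q, q)
        Coupling tensor J with ``J[i, j, a, b]`` the strength of observing
        state ``a`` at position ``i`` together with state ``b`` at ``j``.
        Symmetric in the sense ``J[i, j, a, b] == J[j, i, b, a]``; diagonal
        blocks are zero.
    alphabet : str
        One letter per state, in tensor order.
    provenance : str
        ``"inferred"``, ``"imported"`` or ``"synthetic"``.
    meta : dict
        Free-form diagnostics (convergence report, generation parameters).
    """

    fields: np.ndarray
    couplings: np.ndarray
    alphabet: str
    provenance: str = "inferred"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        L, q = self.fields.shape
        if self.couplings.shape != (L, L, q, q):
            raise ParameterError(
                f"couplings shape {self.couplings.shape} does not match "
                f"fields shape {self.fields.shape}"
            )
        if len(self.alphabet) != q:
            raise ParameterError("alphabet length does not match q")
        if len(set(self.alphabet)) != q:
            raise ParameterError("alphabet letters must be unique")

    # -- basic geometry ----------------------------------------------------
    @property
    def L(self) -> int:
        return self.fields.shape[0]

    @property
    def q(self) -> int:
        return self.fields.shape[1]

    @property
    def aa_states(self) -> np.ndarray:
        """Indices of genuine amino-acid states (everything but the gap)."""
        return np.array([k for k, c in enumerate(self.alphabet) if c != GAP])

    def state_index(self) -> dict[str, int]:
        return {c: k for k, c in enumerate(self.alphabet)}

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence string to state indices; unknown letters raise."""
        idx = self.state_index()
        try:
            return np.array([idx[c] for c in seq.upper()], dtype=np.int64)
        except KeyError as exc:
            raise RescueError(f"letter {exc.args[0]!r} not in model alphabet")

    def decode(self, states: np.ndarray) -> str:
        return "".join(self.alphabet[k] for k in states)

    # -- invariants --------------------------------------------------------
    def symmetry_error(self) -> float:
        J = self.couplings
        return float(np.abs(J - J.transpose(1, 0, 3, 2)).max())

    def symmetrize(self) -> "PottsModel":
        J = 0.5 * (self.couplings + self.couplings.transpose(1, 0, 3, 2))
        J[np.arange(self.L), np.arange(self.L)] = 0.0
        return PottsModel(self.fields.copy(), J, self.alphabet,
                          self.provenance, dict(self.meta))

    def zero_sum_gauge(self) -> "PottsModel":
        """Return an equivalent model in the zero-sum gauge.

        Row/column means of every coupling block are shifted into the fields
        so that ``sum_a J[i,j,a,b] = sum_b J[i,j,a,b] = 0`` per pair; the
        Boltzmann distribution is unchanged (up to an additive constant in
        the score). Fields are also centered per position.
        """
        J = self.couplings
        row = J.mean(axis=3, keepdims=True)          # mean over b
        col = J.mean(axis=2, keepdims=True)          # mean over a
        grand = J.mean(axis=(2, 3), keepdims=True)
        Jg = J - row - col + grand
        # h_i(a) absorbs sum_{j != i} mean_b J[i,j,a,b]
        h = self.fields + (row - grand)[:, :, :, 0].sum(axis=1)
        h = h - h.mean(axis=1, keepdims=True)
        # re-symmetrize exactly: the mean reductions above can differ in the
        # last bit between the two orientations of a pair block
        Jg = 0.5 * (Jg + Jg.transpose(1, 0, 3, 2))
        Jg[np.arange(self.L), np.arange(self.L)] = 0.0
        return PottsModel(h, Jg, self.alphabet, self.provenance,
                          dict(self.meta))

    # -- scoring -----------------------------------------------------------
    def sequence_score(self, states: np.ndarray) -> float:
        """S(s) = sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j)."""
        states = np.asarray(states)
        L = self.L
        s = float(self.fields[np.arange(L), states].sum())
        iu, ju = np.triu_indices(L, k=1)
        s += float(self.couplings[iu, ju, states[iu], states[ju]].sum())
        return s


@dataclass
class CouplingMatrix:
    """L x L pair coupling magnitudes (Frobenius norm of amino-acid blocks)."""

    values: np.ndarray
    apc: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def top_pairs(self, k: int) -> list[tuple[int, int]]:
        """The k highest-magnitude position pairs (i < j), strongest first."""
        iu, ju = np.triu_indices(self.L, k=1)
        order = np.argsort(self.values[iu, ju])[::-1][:k]
        return [(int(iu[o]), int(ju[o])) for o in order]


def coupling_magnitudes(model: PottsModel, apc: bool = True) -> CouplingMatrix:
    """Summarize the coupling tensor as pairwise magnitudes.

    Entry (i, j) is the Frobenius norm of the amino-acid block (gap state
    excluded) of ``J[i, j]``; with ``apc`` the average product correction
    ``mean_i * mean_j / grand mean`` (computed over off-diagonal entries) is
    subtracted, the standard background correction before ranking pairs.
    """
    aa = model.aa_states
    block = model.couplings[:, :, aa[:, None], aa[None, :]]
    mags = np.sqrt((block ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(mags, 0.0)
    if apc and model.L > 1:
        L = model.L
        off = ~np.eye(L, dtype=bool)
        row_mean = (mags.sum(axis=1)) / (L - 1)
        grand = mags[off].mean()
        if grand > 0:
            corr = np.outer(row_mean, row_mean) / grand
            mags = mags - corr
            np.fill_diagonal(mags, 0.0)
    return CouplingMatrix(values=mags, apc=apc)


# ---------------------------------------------------------------------------
# Pseudolikelihood inference
# ---------------------------------------------------------------------------

def _encode_alignment(aln, alphabet: str) -> np.ndarray:
    """Integer-encode alignment records; letters outside the alphabet
    (notably X) fall into the gap state when one exists."""
    idx = {c: k for k, c in enumerate(alphabet)}
    fallback = idx.get(GAP)
    rows = []
    for _, seq in aln.records:
        row = []
        for c in seq.upper():
            k = idx.get(c, fallback)
            if k is None:
                raise RescueError(
                    f"letter {c!r} not in alphabet and no gap state to absorb it"
                )
            row.append(k)
        rows.append(row)
    return np.array(rows, dtype=np.int64)


def _plm_objective(theta, X, X3, w, L, q, lambda_h, lambda_j):
    """Weighted negative log-pseudolikelihood + L2 penalty.

    The likelihood is the weighted sum over sequences (not normalized by
    Meff), matching the convention under which the default penalties
    lambda_h = 0.01 and lambda_J = 0.01 * (L - 1) are standard.

    X : (M, L*q) one-hot; X3 : (M, L, q) one-hot view; w : (M,) weights.
    The coupling parameters are kept symmetric by construction: the raw
    tensor is symmetrized before use and the gradient mapped back.
    """
    M = X.shape[0]
    h = theta[: L * q].reshape(L, q)
    Jr = theta[L * q:].reshape(L, L, q, q)
    Js = 0.5 * (Jr + Jr.transpose(1, 0, 3, 2))
    Js[np.arange(L), np.arange(L)] = 0.0

    W = Js.transpose(1, 3, 0, 2).reshape(L * q, L * q)
    logits = (X @ W).reshape(M, L, q) + h[None, :, :]
    lse = logsumexp(logits, axis=2)
    ll = float((w[:, None] * ((logits * X3).sum(axis=2) - lse)).sum())

    P = softmax(logits, axis=2)
    D = (P - X3) * w[:, None, None]
    gh = D.sum(axis=0)
    gW = X.T @ D.reshape(M, L * q)
    # gW[(j,b),(i,a)] -> gJs[i,j,a,b]
    gJs = np.ascontiguousarray(gW.reshape(L, q, L, q).transpose(2, 0, 3, 1))
    gJs[np.arange(L), np.arange(L)] = 0.0

    f = -ll + lambda_h * float((h ** 2).sum()) + lambda_j * float(
        (Js ** 2).sum())
    gh = gh + 2.0 * lambda_h * h
    gJs = gJs + 2.0 * lambda_j * Js
    gJr = 0.5 * (gJs + gJs.transpose(1, 0, 3, 2))
    if not np.isfinite(f):
        raise NumericalError("pseudolikelihood objective became non-finite")
    return f, np.concatenate([gh.ravel(), gJr.ravel()])


def infer_potts(
    aln,
    lambda_h: float = 0.01,
    lambda_j: float | None = None,
    max_iter: int = 300,
    tol: float = 1e-5,
    alphabet: str | None = None,
) -> PottsModel:
    """Infer a Potts model from a weighted alignment.

    Maximizes the sequence-weighted pseudolikelihood with an L2 penalty
    ``lambda_h`` on fields and ``lambda_j`` on couplings (default
    ``0.01 * (L - 1)``, the customary length scaling). ``tol`` is the
    convergence tolerance on the gradient norm per effective sequence.
    The returned model is symmetrized and in the zero-sum gauge;
    ``model.meta["converged"]`` reports optimizer status.

    Parameters are deterministic given identical input and tolerances.
    """
    M = len(aln.records)
    if M < 2:
        raise ParameterError("inference requires at least two sequences")
    L = len(aln.records[0][1])
    if L < 2:
        raise ParameterError("inference requires L >= 2")
    if alphabet is None:
        letters = set("".join(s for _, s in aln.records).upper())
        # use the reduced synthetic alphabet when the MSA clearly comes from
        # one, otherwise the full 21-state protein alphabet
        for qq in range(2, 21):
            cand = default_alphabet(qq)
            if letters <= set(cand):
                alphabet = cand
                break
        else:
            alphabet = default_alphabet(21)
    q = len(alphabet)
    if lambda_j is None:
        lambda_j = 0.01 * (L - 1)

    S = _encode_alignment(aln, alphabet)
    w = (np.asarray(aln.weights, dtype=float)
         if aln.weights is not None else np.ones(M))
    meff = float(w.sum())
    if meff <= 0:
        raise ParameterError("effective alignment size must be positive")

    X3 = np.zeros((M, L, q))
    X3[np.arange(M)[:, None], np.arange(L)[None, :], S] = 1.0
    X = X3.reshape(M, L * q)

    theta0 = np.zeros(L * q + L * L * q * q)
    res = scipy.optimize.minimize(
        _plm_objective,
        theta0,
        args=(X, X3, w, L, q, lambda_h, lambda_j),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * meff, "ftol": 1e-12,
                 "maxcor": 10},
    )
    h = res.x[: L * q].reshape(L, q)
    Jr = res.x[L * q:].reshape(L, L, q, q)
    J = 0.5 * (Jr + Jr.transpose(1, 0, 3, 2))
    J[np.arange(L), np.arange(L)] = 0.0
    model = PottsModel(
        h, J, alphabet, provenance="inferred",
        meta={
            "converged": bool(res.success),
            "n_iter": int(res.nit),
            "grad_norm": float(np.abs(res.jac).max()),
            "objective": float(res.fun),
            "lambda_h": lambda_h,
            "lambda_j": float(lambda_j),
            "meff": meff,
        },
    )
    return model.zero_sum_gauge()


# ---------------------------------------------------------------------------
# Tensor archive (HDF5)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def export_tensor(model: PottsModel, path) -> None:
    """Write a model to an HDF5 archive (datasets ``fields``, ``couplings``;
    attributes ``alphabet``, ``provenance``, ``format_version``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fields", data=model.fields)
        f.create_dataset("couplings", data=model.couplings)
        f.attrs["alphabet"] = model.alphabet
        f.attrs["provenance"] = model.provenance
        f.attrs["format_version"] = _FORMAT_VERSION


def import_tensor(path) -> PottsModel:
    """Read a model from an HDF5 archive written by :func:`export_tensor`
    (or any GREMLIN-style export using the same layout).

    An asymmetric coupling tensor is symmetrized by averaging
    ``J[i,j,a,b]`` with ``J[j,i,b,a]``, with a warning.
    """
    try:
        with h5py.File(path, "r") as f:
            if "fields" not in f or "couplings" not in f:
                raise FormatError("archive lacks fields/couplings datasets")
            fields = f["fields"][()]
            couplings = f["couplings"][()]
            alphabet = str(f.attrs.get("alphabet", ""))
            provenance = str(f.attrs.get("provenance", "imported"))
    except OSError as exc:
        raise FormatError(f"cannot read tensor archive {path}: {exc}")
    if fields.ndim != 2:
        raise FormatError("fields dataset must be 2-D (L, q)")
    L, q = fields.shape
    if couplings.shape != (L, L, q, q):
        raise FormatError(
            f"couplings shape {couplings.shape} inconsistent with fields "
            f"(L={L}, q={q})"
        )
    if not alphabet:
        alphabet = default_alphabet(q)
    if len(alphabet) != q:
        raise FormatError("alphabet length does not match tensor q")
    model = PottsModel(fields, couplings, alphabet, provenance="imported",
                       meta={"source": str(path), "orig_provenance": provenance})
    if model.symmetry_error() > 1e-8:
        warnings.warn("imported coupling tensor is asymmetric; symmetrizing "
                      "by averaging J[i,j,a,b] with J[j,i,b,a]")
        model = model.symmetrize()
    else:
        model = model.symmetrize()  # also zeroes any stray diagonal entries
    return model


def export_edge_list(cm: CouplingMatrix, path, column_map=None) -> None:
    """Plain-text edge list of pair magnitudes: ``i<TAB>j<TAB>magnitude``
    with 1-based positions (mapped through ``column_map`` when given)."""
    iu, ju = np.triu_indices(cm.L, k=1)
    with open(path, "w") as f:
        f.write("# i\tj\tmagnitude (1-based positions)\n")
        for i, j in zip(iu, ju):
            pi = (column_map[i] if column_map is not None else i) + 1
            pj = (column_map[j] if column_map is not None else j) + 1
            f.write(f"{pi}\t{pj}\t{cm.values[i, j]:.6g}\n")
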