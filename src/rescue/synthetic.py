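"""Synthetic Potts landscapes: ground-truth models, sampled MSAs, oracles.

The generator emulates the inputs the toolkit consumes in production — an
MSA of homologs and a designated native sequence — from a known ground
truth, so inference, scoring, design and network analysis are all testable
end to end. A model is drawn with Gaussian fields and a sparse set of
coupled position pairs carrying dense random amino-acid coupling blocks;
sequences are drawn from its Boltzmann distribution P(s) proportional to
exp(S(s)) by single-site Gibbs sampling; the alignment size defaults to
10 x L, the customary sufficiency level for reliable coupling inference.
The native sequence is the lowest-energy (most probable) gap-free sample,
which makes "natives sit near the optimum of the landscape" true by
construction. For systems with q^L <= 1e6 the exact Boltzmann distribution
is enumerable and serves as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from ._common import GAP, ParameterError, default_alphabet
from .msa_io import Alignment
from .potts import PottsModel

__all__ = [
    "SyntheticBenchmark",
    "sample_model",
    "gibbs_sample",
    "enumerate_exact",
    "ExactDistribution",
    "make_benchmark",
]


def sample_model(
    L: int,
    q: int,
    n_pairs: int,
    field_scale: float = 0.5,
    coupling_scale: float = 1.0,
    seed: int = 0,
    alphabet: str | None = None,
) -> PottsModel:
    """Draw a random ground-truth Potts model.

    Fields are N(0, field_scale^2); ``n_pairs`` distinct position pairs
    receive dense N(0, coupling_scale^2) coupling blocks over the
    amino-acid states (the gap state, when present, stays uncoupled). The
    model is symmetrized and zero-sum gauged; the coupled pairs are recorded
    in ``meta["contacts"]``.

    The defaults put the model in a strong-coupling regime (pairwise mutual
    information of a coupled pair around 0.2-0.4 bits) where inference from
    a 10 x L alignment is feasible.
    """
    if L < 2 or q < 2:
        raise ParameterError("need L >= 2 and q >= 2")
    max_pairs = L * (L - 1) // 2
    if not 0 <= n_pairs <= max_pairs:
        raise ParameterError(f"n_pairs must be in [0, {max_pairs}]")
    if alphabet is None:
        alphabet = default_alphabet(q)
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, q))
    J = np.zeros((L, L, q, q))
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    aa = np.array([k for k, c in enumerate(alphabet) if c != GAP])
    contacts = []
    for c in sorted(chosen):
        i, j = all_pairs[c]
        block = rng.normal(0.0, coupling_scale, size=(len(aa), len(aa)))
        J[np.ix_([i], [j], aa, aa)] = block[None, None]
        J[np.ix_([j], [i], aa, aa)] = block.T[None, None]
        contacts.append((i, j))
    model = PottsModel(
        h, J, alphabet, provenance="synthetic",
        meta={
            "contacts": contacts, "seed": seed, "field_scale": field_scale,
            "coupling_scale": coupling_scale, "n_pairs": n_pairs,
        },
    )
    return model.zero_sum_gauge()


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def _gibbs_sweeps(model: PottsModel, states: np.ndarray, n_sweeps: int,
                  rng: np.random.Generator) -> None:
    """In-place single-site Gibbs sweeps on a (C, L) chain array."""
    h, J, L = model.fields, model.couplings, model.L
    Jt = J.transpose(0, 1, 3, 2)  # Jt[i, j, b, a] = J[i, j, a, b]
    cols = np.arange(L)[None, :]
    for _ in range(n_sweeps):
        for i in range(L):
            # logits[c, a] = h[i, a] + sum_j J[i, j, a, s_cj]
            g = Jt[i][cols, states, :]          # (C, L, q) gather
            logits = g.sum(axis=1) + h[i]
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(states.shape[0])
            states[:, i] = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)


def gibbs_sample(
    model: PottsModel,
    n_sequences: int,
    burn_in: int = 100,
    thinning: int = 10,
    seed: int = 0,
    n_chains: int | None = None,
) -> Alignment:
    """Sample an alignment from the model's Boltzmann distribution.

    Runs ``n_chains`` parallel single-site Gibbs chains (default: one chain
    per requested sequence) from uniform random starts for ``burn_in``
    full sweeps, then records one sequence per chain, with ``thinning``
    sweeps between successive records when a chain contributes more than
    one. Deterministic per seed.
    """
    if n_sequences < 1:
        raise ParameterError("n_sequences must be >= 1")
    if n_chains is None:
        n_chains = n_sequences
    n_chains = min(n_chains, n_sequences)
    rng = np.random.default_rng(seed)
    states = rng.integers(0, model.q, size=(n_chains, model.L))
    _gibbs_sweeps(model, states, burn_in, rng)
    records: list[tuple[str, str]] = []
    while True:
        for c in range(n_chains):
            if len(records) >= n_sequences:
                break
            records.append((f"sample_{len(records) + 1:05d}",
                            model.decode(states[c])))
        if len(records) >= n_sequences:
            break
        _gibbs_sweeps(model, states, max(thinning, 1), rng)
    return Alignment(records=records, query_index=0)


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class ExactDistribution:
    """Exact Boltzmann distribution over all q^L sequences of a small model."""

    model: PottsModel
    states: np.ndarray          # (q^L, L) every sequence
    scores: np.ndarray          # S(s) per sequence
    probabilities: np.ndarray   # softmax(scores)
    cs_values: np.ndarray = field(repr=False, default=None)

    def marginal_1(self, i: int) -> np.ndarray:
        p = np.zeros(self.model.q)
        np.add.at(p, self.states[:, i], self.probabilities)
        return p

    def marginal_2(self, i: int, j: int) -> np.ndarray:
        p = np.zeros((self.model.q, self.model.q))
        np.add.at(p, (self.states[:, i], self.states[:, j]),
                  self.probabilities)
        return p

    def argmax_score(self) -> np.ndarray:
        """The most probable (lowest-energy) sequence."""
        return self.states[int(np.argmax(self.scores))]

    def argmax_cs(self, gap_free: bool = True) -> np.ndarray:
        """The sequence maximizing the coupling strength cs."""
        cs = self.cs_values
        if gap_free and GAP in self.model.alphabet:
            gap_state = self.model.alphabet.index(GAP)
            ok = (self.states != gap_state).all(axis=1)
            return self.states[ok][int(np.argmax(cs[ok]))]
        return self.states[int(np.argmax(cs))]


def enumerate_exact(model: PottsModel, max_size: int = 10 ** 6
                    ) -> ExactDistribution:
    """Enumerate the exact Boltzmann distribution (requires q^L <= 1e6)."""
    size = model.q ** model.L
    if size > max_size:
        raise ParameterError(
            f"state space {model.q}^{model.L} = {size} exceeds {max_size}")
    states = np.array(list(itertools.product(range(model.q),
                                             repeat=model.L)), dtype=np.int64)
    n = states.shape[0]
    scores = model.fields[np.arange(model.L), states].sum(axis=1)
    cs = np.zeros(n)
    for i in range(model.L):
        for j in range(i + 1, model.L):
            pair = model.couplings[i, j][states[:, i], states[:, j]]
            scores += pair
            cs += 2.0 * pair  # cs double-counts each unordered pair
    return ExactDistribution(model=model, states=states, scores=scores,
                             probabilities=softmax(scores), cs_values=cs)


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBenchmark:
    """Ground-truth model, sampled alignment and designated native."""

    model: PottsModel
    alignment: Alignment
    native: str
    contacts: list[tuple[int, int]]
    seed: int
    params: dict

    def __post_init__(self) -> None:
        if self.native not in (s for _, s in self.alignment.records):
            raise ParameterError("native must appear in the alignment")


def make_benchmark(
    L: int,
    q: int,
    n_pairs: int,
    M: int | None = None,
    seed: int = 0,
    field_scale: float = 0.5,
    coupling_scale: float = 1.0,
    burn_in: int = 100,
) -> SyntheticBenchmark:
    """Compose a full benchmark: model + sampled MSA + native.

    ``M`` defaults to 10 x L sequences, the customary sufficiency level for
    coupling inference. The native is the lowest-energy gap-free sample
    (lowest-energy overall if every sample contains a gap) and becomes the
    alignment's query record.
    """
    if M is None:
        M = 10 * L
    ss = np.random.SeedSequence(seed)
    s_model, s_msa = (int(s.generate_state(1)[0] % 2 ** 31)
                      for s in ss.spawn(2))
    model = sample_model(L, q, n_pairs, field_scale=field_scale,
                         coupling_scale=coupling_scale, seed=s_model)
    aln = gibbs_sample(model, M, burn_in=burn_in, seed=s_msa)
    scores = np.array([model.sequence_score(model.encode(s))
                       for _, s in aln.records])
    gap_free = np.array([GAP not in s for _, s in aln.records])
    pool = np.where(gap_free)[0] if gap_free.any() else np.arange(aln.M)
    native_idx = int(pool[np.argmax(scores[pool])])
    aln = Alignment(records=aln.records, query_index=native_idx)
    return SyntheticBenchmark(
        model=model,
        alignment=aln,
        native=aln.records[native_idx][1],
        contacts=list(model.meta["contacts"]),
        seed=seed,
        params={"L": L, "q": q, "n_pairs": n_pairs, "M": M,
                "field_scale": field_scale,
                "coupling_scale": coupling_scale, "burn_in": burn_in},
    )
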