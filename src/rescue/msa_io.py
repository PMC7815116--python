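"""Reading, filtering and weighting multiple sequence alignments.

The preprocessing pipeline mirrors standard co-evolution practice: sequences
that do not cover at least 75% of the query length are dropped, alignment
columns with more than 75% gaps are removed (boundaries inclusive/strict in
exactly that way), and each remaining sequence is down-weighted by the
number of its >= 80%-identical neighbors (inverse-neighbor weighting; the
weight sum is the effective alignment size Meff).

Alignments are normalized to query coordinates on reading: A3M insert
states (lowercase letters) are removed, and for every format the columns at
which the query itself is gapped are dropped, so column k always maps to an
original query position through ``column_map``. Internally positions are
0-based; user-facing exports are 1-based query positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import AlignIO, SeqIO

from ._common import AA20, GAP, FormatError, ParameterError

__all__ = [
    "Alignment",
    "Profile",
    "read_msa",
    "write_msa",
    "filter_coverage",
    "filter_gap_columns",
    "compute_weights",
    "dedupe_by_query_identity",
    "read_pssm",
    "profile_from_alignment",
]

logger = logging.getLogger(__name__)

_VALID = set(AA20) | {GAP, "X"}


@dataclass
class Alignment:
    """A filtered, optionally weighted MSA in query coordinates.

    ``records`` holds (identifier, aligned sequence) pairs over the 20
    amino-acid letters plus '-' (gap) and 'X' (ambiguity); ``query_index``
    points at the native/query record; ``column_map[k]`` is the 0-based
    original query position of retained column k; ``query_length`` is the
    full (unfiltered) query length N.
    """

    records: list[tuple[str, str]]
    query_index: int = 0
    column_map: list[int] = field(default_factory=list)
    query_length: int = 0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
        L = lengths.pop()
        if not self.column_map:
            self.column_map = list(range(L))
        if len(self.column_map) != L:
            raise FormatError("column_map length does not match alignment")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise FormatError("column_map must be strictly increasing")
        if not self.query_length:
            self.query_length = L
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.records) or np.any(
                    self.weights <= 0):
                raise FormatError("weights must be positive, one per record")

    @property
    def M(self) -> int:
        return len(self.records)

    @property
    def L(self) -> int:
        return len(self.records[0][1])

    @property
    def query(self) -> str:
        return self.records[self.query_index][1]

    @property
    def meff(self) -> float:
        if self.weights is None:
            return float(self.M)
        return float(self.weights.sum())

    def matrix(self) -> np.ndarray:
        """Records as a (M, L) array of single characters."""
        return np.array([list(s) for _, s in self.records])


def _normalize(seq: str) -> str:
    """Uppercase; '.' to gap; non-standard letters (B, Z, U, O, J...) to X."""
    out = []
    for c in seq.upper():
        if c == ".":
            c = GAP
        out.append(c if c in _VALID else "X")
    return "".join(out)


def _from_records(records: list[tuple[str, str]], query_index: int) -> Alignment:
    if not records:
        raise FormatError("empty alignment file")
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")
    records = [(name, _normalize(seq)) for name, seq in records]
    query = records[query_index][1]
    keep = [k for k, c in enumerate(query) if c != GAP]
    if len(keep) < len(query):
        logger.info("dropping %d columns gapped in the query",
                    len(query) - len(keep))
        records = [(n, "".join(s[k] for k in keep)) for n, s in records]
    return Alignment(records=records, query_index=query_index,
                     column_map=list(range(len(keep))),
                     query_length=len(keep))


def read_msa(path, format: str | None = None, query_index: int = 0) -> Alignment:
    """Read an MSA in FASTA, A3M or Stockholm format.

    The format is inferred from the file suffix when not given. A3M insert
    states (lowercase letters and '.') are removed relative to the query
    columns; in every format, columns where the query record is gapped are
    dropped so the alignment lives in query coordinates.
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"a3m": "a3m", "sto": "stockholm", "stk": "stockholm",
                  "stockholm": "stockholm"}.get(suffix, "fasta")
    if format not in ("fasta", "a3m", "stockholm"):
        raise ParameterError(f"unknown MSA format {format!r}")
    try:
        if format == "stockholm":
            aln = AlignIO.read(path, "stockholm")
            records = [(r.id, str(r.seq)) for r in aln]
        elif format == "fasta":
            records = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        else:  # a3m: fasta-shaped, ragged before removing inserts
            records = [
                (r.id, "".join(c for c in str(r.seq)
                               if not c.islower() and c != "."))
                for r in SeqIO.parse(path, "fasta")
            ]
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path} as {format}: {exc}")
    aln = _from_records(records, query_index)
    logger.info("read %d sequences x %d columns from %s", aln.M, aln.L, path)
    return aln


def write_msa(aln: Alignment, path) -> None:
    """Write the alignment as FASTA."""
    with open(path, "w") as f:
        for name, seq in aln.records:
            f.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_coverage(aln: Alignment, min_coverage: float = 0.75) -> Alignment:
    """Drop records covering less than ``min_coverage`` of the query length.

    Coverage is the fraction of non-gap positions over query columns,
    relative to the full query length N; records at exactly the threshold
    are retained ("at least 75%"). The query record is never removed.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ParameterError("min_coverage must be in (0, 1]")
    mat = aln.matrix()
    coverage = (mat != GAP).sum(axis=1) / aln.query_length
    keep = [k for k in range(aln.M)
            if coverage[k] >= min_coverage or k == aln.query_index]
    logger.info("coverage filter (>= %.0f%%): dropped %d of %d sequences",
                100 * min_coverage, aln.M - len(keep), aln.M)
    return Alignment(
        records=[aln.records[k] for k in keep],
        query_index=keep.index(aln.query_index),
        column_map=list(aln.column_map),
        query_length=aln.query_length,
    )


def filter_gap_columns(aln: Alignment,
                       max_gap_fraction: float = 0.75) -> Alignment:
    """Remove columns whose gap fraction strictly exceeds
    ``max_gap_fraction`` ("more than 75% gaps"); ``column_map`` keeps
    mapping retained columns to original query positions."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ParameterError("max_gap_fraction must be in [0, 1]")
    mat = aln.matrix()
    gap_frac = (mat == GAP).mean(axis=0)
    keep = [k for k in range(aln.L) if gap_frac[k] <= max_gap_fraction]
    logger.info("gap-column filter (> %.0f%%): removed %d of %d columns",
                100 * max_gap_fraction, aln.L - len(keep), aln.L)
    return Alignment(
        records=[(n, "".join(s[k] for k in keep)) for n, s in aln.records],
        query_index=aln.query_index,
        column_map=[aln.column_map[k] for k in keep],
        query_length=aln.query_length,
    )


def _identity_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise fraction of identical symbols (gap-to-gap matches count)."""
    M = mat.shape[0]
    codes = np.frombuffer("".join("".join(r) for r in mat).encode(),
                          dtype=np.uint8).reshape(M, -1)
    ident = np.empty((M, M))
    for r in range(M):
        ident[r] = (codes == codes[r]).mean(axis=1)
    return ident


def compute_weights(aln: Alignment,
                    identity_threshold: float = 0.80) -> Alignment:
    """Attach inverse-neighbor sequence weights.

    weight(r) = 1 / |{s : identity(r, s) >= identity_threshold}| (self
    included); the weight sum is the effective alignment size Meff. This is
    the standard redundancy correction for co-evolution inference at the
    80% identity level.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError("identity_threshold must be in (0, 1]")
    ident = _identity_matrix(aln.matrix())
    neighbors = (ident >= identity_threshold).sum(axis=1)
    weights = 1.0 / neighbors
    logger.info("sequence weighting at %.0f%% identity: Meff = %.1f of M = %d",
                100 * identity_threshold, weights.sum(), aln.M)
    return replace(aln, weights=weights)


def dedupe_by_query_identity(aln: Alignment,
                             identity_threshold: float = 0.80) -> Alignment:
    """Remove records sharing more than ``identity_threshold`` identity with
    the query record (the query itself is kept).

    Exposed separately because redundancy can alternatively be handled by
    :func:`compute_weights`; both behaviors are available.
    """
    mat = aln.matrix()
    ident = (mat == mat[aln.query_index]).mean(axis=1)
    keep = [k for k in range(aln.M)
            if ident[k] <= identity_threshold or k == aln.query_index]
    logger.info("query-identity dedupe (> %.0f%%): dropped %d of %d",
                100 * identity_threshold, aln.M - len(keep), aln.M)
    return Alignment(
        records=[aln.records[k] for k in keep],
        query_index=keep.index(aln.query_index),
        column_map=list(aln.column_map),
        query_length=aln.query_length,
    )


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Position-specific log-odds scores (N x 20, dimensionless).

    ``alphabet`` fixes the column order (canonical ACDEFGHIKLMNPQRSTVWY).
    """

    scores: np.ndarray
    alphabet: str = AA20

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.alphabet):
            raise FormatError("profile must be N x len(alphabet)")

    @property
    def N(self) -> int:
        return self.scores.shape[0]

    def score(self, i: int, letter: str) -> float:
        return float(self.scores[i, self.alphabet.index(letter.upper())])


def read_pssm(path) -> Profile:
    """Read a PSI-BLAST ASCII position-specific scoring matrix.

    Expects the standard dialect: a header carrying the 20 column letters,
    then one row per query position beginning with the position number and
    the query letter, followed by (at least) 20 integer log-odds scores.
    Scores are re-ordered into the canonical alphabet.
    """
    with open(path) as f:
        lines = [ln.rstrip("\n") for ln in f]
    header_letters: list[str] = []
    rows: list[list[float]] = []
    numbers: list[int] = []
    for ln in lines:
        parts = ln.split()
        if not parts:
            continue
        if not header_letters:
            if len(parts) >= 20 and all(p in AA20 for p in parts[:20]):
                header_letters = parts[:20]
            continue
        if not parts[0].isdigit():
            continue  # trailing statistics block
        if len(parts) < 22:
            raise FormatError(f"PSSM row too short: {ln!r}")
        try:
            scores = [float(v) for v in parts[2:22]]
        except ValueError:
            raise FormatError(f"non-numeric PSSM cell in row: {ln!r}")
        numbers.append(int(parts[0]))
        rows.append(scores)
    if not header_letters:
        raise FormatError("no PSI-BLAST header line with 20 letters found")
    if not rows:
        raise FormatError("PSSM contains a header but no score rows")
    if numbers != list(range(1, len(numbers) + 1)):
        raise FormatError("PSSM rows are not consecutively numbered from 1")
    raw = np.array(rows)
    order = [header_letters.index(c) for c in AA20]
    return Profile(scores=raw[:, order], alphabet=AA20)


def profile_from_alignment(aln: Alignment, pseudocount: float = 1.0) -> Profile:
    """Log-odds profile from (weighted) alignment column frequencies.

    score(i, a) = log2 of the regularized frequency of amino acid a in
    column i over a uniform 1/20 background; gaps and X are ignored in the
    counts. A convenience for profile-biased design when no external PSSM
    is supplied.
    """
    mat = aln.matrix()
    w = (aln.weights if aln.weights is not None
         else np.ones(aln.M))
    counts = np.zeros((aln.L, 20))
    for k, c in enumerate(AA20):
        counts[:, k] = ((mat == c) * w[:, None]).sum(axis=0)
    freq = (counts + pseudocount / 20.0)
    freq /= freq.sum(axis=1, keepdims=True)
    return Profile(scores=np.log2(freq * 20.0), alphabet=AA20)
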