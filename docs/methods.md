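# Methods

This note documents the models, algorithms, defaults and design choices of
the `rescue` toolkit, and what its synthetic benchmarks do and do not show.

## Alignment preprocessing (`msa_io`)

Alignments are normalized to query coordinates on reading: A3M insert
states (lowercase, '.') are removed, and columns where the query record is
gapped are dropped in every format, so retained column *k* always maps to
an original query position through `column_map` (0-based internally;
1-based in all exports). Non-standard letters (B, Z, U, O, J) become 'X',
which downstream behaves as a gap-equivalent state.

Filters, applied coverage-first:

- **Coverage**: a record is kept iff its non-gap fraction over the query
  length N is **at least** `min_coverage` (default 0.75; the boundary is
  inclusive). The query is never dropped. 'X' counts as coverage — it is a
  residue, just an ambiguous one.
- **Gap columns**: a column is removed iff its gap fraction is **strictly
  greater** than `max_gap_fraction` (default 0.75).

Redundancy is handled by inverse-neighbor weighting: weight(r) = 1 / (number
of records with pairwise identity ≥ 0.80 to r, itself included), identity
being the fraction of identical symbols over current columns (gap–gap
matches count; this is the common convention and is stable under the
gap-column filter). The weight sum is the effective size Meff. An optional
`dedupe_by_query_identity` drops records >80% identical to the query
instead — both behaviors exist because redundancy removal can be meant
globally or only relative to the query; weighting is the default used by
inference.

The PSI-BLAST ASCII PSSM reader accepts the standard dialect (header with
20 column letters, rows numbered from 1 with ≥20 integer log-odds) and
re-orders columns into the canonical ACDEFGHIKLMNPQRSTVWY order.
`profile_from_alignment` provides a log-odds profile (base-2, uniform 1/20
background, pseudocount 1) when no external PSSM is available.

## Potts inference (`potts`)

The estimator is sequence-weighted pseudolikelihood maximization with L2
penalties, minimizing

  f(h, J) = − Σ_m w_m Σ_i log P(s_i^m | s_{\i}^m) + λ_h‖h‖² + λ_J‖J‖²,

over the full (L, L, q, q) tensor kept symmetric by construction
(J_ij(a,b) = J_ji(b,a); diagonal blocks zero). The likelihood is the
weighted **sum** over sequences — not normalized by Meff — which is the
convention under which the defaults λ_h = 0.01 and λ_J = 0.01·(L−1) are
the customary absolute penalties; normalizing by Meff would silently
multiply the effective regularization by the alignment depth. Optimization
uses L-BFGS-B on the analytic gradient (finite-difference–verified in the
tests); `tol` is interpreted as a per-effective-sequence projected-gradient
tolerance. Convergence status, iteration count and gradient norm are
recorded in `model.meta`.

Gaps are an explicit 21st state during inference (GREMLIN-style); 'X' is
folded into the gap state. Gap-state couplings stay in the tensor but are
excluded from the amino-acid-block Frobenius norms used for pair ranking.

After optimization the model is placed in the **zero-sum gauge**: per pair,
row/column block means are shifted into the fields, so Σ_a J_ij(a,b) =
Σ_b J_ij(a,b) = 0 and the Boltzmann distribution is unchanged. The gauge
matters because cc/cs sum raw tensor entries and are gauge-dependent;
fixing it makes all downstream scores uniquely defined and gives random
sequences an exact expected cs of zero. The gauge step ends with an exact
re-symmetrization (bit-level), so archive round trips are bit-exact.

Inferred null models are not numerically zero: with the default penalties,
an independent-sites MSA of 2000 sequences leaves amino-acid-block norms of
roughly 2.5–3.5 — ordinary pseudolikelihood overfitting noise, several-fold
below the ≈8 block norm that genuine unit-scale couplings carry, and
removed from pair rankings by the average product correction (APC,
subtracting rowmean·colmean/grandmean over off-diagonal entries). The
regression tests freeze these empirically verified noise floors.

The tensor archive is HDF5: datasets `fields` (L×q) and `couplings`
(L×L×q×q), attributes `alphabet`, `provenance`, `format_version`.
Asymmetric imported tensors are symmetrized by averaging with a warning.

## Coupling scores (`scoring`)

cc(i) reads the amino acids from the scored sequence at both ends:
cc(i) = Σ_{j≠i} J_ij(seq[i], seq[j]) — the only reading under which the
native sequence's own crs is meaningful. cs(seq) = Σ_i cc(i) counts every
unordered pair twice, exactly as the per-residue sums compose; the factor
cancels in crs = cs(design)/cs(native). Gap or X at position j contributes
0 to cc(i); gap/X at i makes cc(i) = 0 (designs are gap-free; native
queries may contain X). cs(native) = 0 raises an error rather than
returning NaN; a negative cs(native) triggers a warning because the ratio's
sign then inverts its meaning.

## Design (`design`)

The design optimizer is simulated annealing over fixed-length sequences:
uniformly random designable position, uniformly random alternative amino
acid (gap is never proposed), Metropolis acceptance, geometric cooling.
Each design in an ensemble is an independent chain with its own child seed,
so ensembles are embarrassingly reproducible. The best-seen sequence is
returned; term energies are recomputed fresh on it, and the breakdown sums
to the reported total.

Energy terms (lower is better):

| term          | energy                          | incremental cost |
|---------------|---------------------------------|------------------|
| coupling      | −w · cs(seq)                    | O(1) delta via a local-field cache F[p,a] = Σ_j J_pj(a, s_j); O(L·q) per accepted move |
| profile       | −w · Σ_i profile[i][seq[i]]     | O(1) |
| native bias   | −w · #\{i : seq[i] = native[i]\} | O(1) |
| user-supplied | any `EnergyTerm` subclass       | contract-tested |

Every term obeys the delta-consistency contract: incremental updates along
any mutation path equal a full recompute to 1e-9 (property-tested).

**Default schedule**: geometric cooling from T = 2.5 to T = 0.02 over
600·L proposals. The schedule was calibrated once against exhaustive
enumeration — on batches of 20 random small landscapes (L ≤ 5, q ≤ 4) the
annealer must reach the global optimum in ≥ 18/20 runs; the chosen default
scored 20/20 on five independent batches, where a faster 200·L /
T 2.0→0.05 schedule scored 15–19/20. All schedule parameters are exposed.

The four protocol analogs — `plain` (no bias), `profile`, `favornative`,
`rescue` (coupling bias) — run under identical schedules for comparison.
The coupling weight has no external calibration target here (there is no
physical base energy in the default setup), so the default is 1.0 and
`weight_sweep`/`pick_plateau_weight` choose the smallest weight whose mean
ensemble crs is within 2% of the sweep maximum. Mean crs rises with weight
on the low flank and plateaus; at large weights it declines slightly
because scaling the energy relative to a fixed temperature schedule makes
the search greedier, so the sweep picks the plateau's left edge.

## Networks (`networks`)

"Highly coupled" residues are those with cc(i) strictly above the
(1 − 0.20) empirical quantile of the native's cc profile (the rescc20 set).
The percentile convention is deliberately the *top* 20%: the complementary
reading (everything above the 20th percentile, i.e. 80% of residues) would
select most of a protein and cannot yield the small functional networks
this analysis is for. The fraction is configurable and the rule is recorded
in the output metadata.

A sliding window (size 10, step 1 by default) over the cc profile marks
regions of high mean coupling; windows above the 80th percentile of window
means (kept symmetric with the node-selection convention; absolute
thresholds accepted) merge into maximal half-open intervals. Both the
percentile set and the window regions are exposed — either can feed network
construction.

Network edges join selected residues whose APC-corrected coupling magnitude
is among the top 1.5·L pairs model-wide (the usual length-scaled
contact-list size), or pass an absolute threshold when one is given.
Connected components are reported largest-first. Logo matrices are
row-stochastic position × 20 frequency tables over a design ensemble,
consumable by standard logo renderers.

## Synthetic benchmarks (`synthetic`)

`sample_model` draws fields from N(0, 0.5²) and gives `n_pairs` random
position pairs dense N(0, 1²) amino-acid coupling blocks (the gap state
stays uncoupled), then gauges the model. At these defaults an isolated
coupled pair carries ≈ 0.2–0.4 bits of mutual information (measured by
exact enumeration, mean ≈ 0.38 at q = 8) — a strong-coupling regime in
which inference succeeds at the customary 10·L alignment depth, which is
the default M of `make_benchmark`.

`gibbs_sample` runs parallel single-site Gibbs chains (one per requested
sequence by default) from uniform starts with a 100-sweep burn-in;
correctness is checked against exact Boltzmann marginals on enumerable
models (pairwise frequencies within 0.01 at 100,000 samples). The native
sequence is the lowest-energy **gap-free** sample (lowest-energy overall if
none is gap-free): natives must be valid protein sequences, and this makes
"natives sit near the landscape optimum" true by construction, which is
what makes protocol-ordering comparisons well-posed.

Problem sizes used by the test suite and the acceptance script — inference
recovery at L=30, q=8, 20 pairs, M=5000; protocol ordering at L=20, q=8,
M=200 over 5 seeds; the headline design run at L=50, q=21, 40 pairs, M=500
with 100 designs — were chosen as the smallest systems in which the
corresponding effects are comfortably resolved.

## What the synthetic results do and do not show

The generator reproduces the *statistical* structure the method consumes —
sparse pairwise couplings, redundancy, gaps — but not phylogenetic
correlation between sequences, realistic amino-acid background
frequencies, or any structural base energy. Passing benchmarks therefore
demonstrate that inference recovers planted couplings, that the coupling
bias steers design toward them (mean ensemble crs ≥ 100%, exceeding the
unbiased and profile protocols), and that the scores and networks are
internally consistent — not that designed sequences would fold or function.
On real proteins the bias is meant to be added to a physical base energy
through the `EnergyTerm` contract, and the balance between the two (the
coupling weight) must be recalibrated in that context.

## Numerical conventions

- Zero-sum gauge and symmetry are exact to 1e-10 after inference (tested).
- Ties in top-k pair ranking break by `argsort` order (deterministic).
- crs with cs(native) = 0 is an error; all-X comparisons are errors rather
  than silent zeros.
- All randomness flows through `numpy` `SeedSequence` spawning; identical
  seeds give bit-identical models, alignments, designs and output files.
- BLOSUM62 is vendored (half-bit integer table) and sha256-checked at
  load; the test suite cross-checks every canonical entry against
  Biopython's copy.
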