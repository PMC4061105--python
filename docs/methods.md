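# Methods

## Score reconstruction

The score of a model-to-sequence alignment is rebuilt from the HMMER2
ASCII save file alone: per-state match/insert emission scores,
per-state transitions (M→M, M→I, M→D, I→M, I→I, D→M, D→D plus the entry
column B→M and exit column M→E), the begin line (B→M₁, B→D₁), and the
special XT transitions. File integers are 1/1000-bit units; `*` is the
impossible-score sentinel (−∞). The fixed score for a single-domain hit
is `f = XT(N→B) + XT(E→C) + XT(C→T)`; the J loop and the per-residue
N→N/C→C flank terms do not occur in a single-domain alignment and are
omitted. `f` enters the total score and its E-value but neither segment
class, since it carries no positional information.

Term anchoring, which makes the partition total and exactly
conservative (`fold + remnant + f = total` holds bit-for-bit because the
total is *defined* as that sum): an emission at match position `k`
belongs to `k`; a transition into position `k` belongs to `k`; the exit
transition belongs to the fragment's last position; insert emissions
and I→I self-transitions belong to the last match/delete position
visited.

Models converted from the local-alignment formulation lack entry/exit
scores for interior states (their b→m / m→e columns are `*`). A local
fragment entering or leaving the model at such a state therefore has no
recoverable parameter; those two terms contribute 0 bits and per-hit
sums (fragment scores summed before E-value computation) are the
supported quantity, while per-fragment sums are approximate. Interior
`*` emissions or transitions, by contrast, genuinely mean "impossible"
and propagate −∞ through the total.

## E-values

`E = N·(1 − exp(−exp(−λ(v−μ))))` under the maximum Gumbel distribution,
with `(μ, λ)` from the model's EVD line and `N` the database size
(default 540261 sequences, a UniProt/SwissProt-scale count; override by
flag). Sub-scores reuse the same `(μ, λ)`; no per-segment recalibration
is attempted. Numerics: for `λ(v−μ) > 30` the survival probability is
evaluated as `exp(−λ(v−μ))` (equal to double precision, no premature
underflow); for `λ(v−μ) < −30` it saturates at 1 exactly, so E-values
below that point are tied at `N` and strict monotonicity in `v` holds
only above saturation. Models without an EVD line parse but are flagged
uncalibrated; E-value calls then require explicit `(μ, λ)`.

The E₁/E₂ verdict bands are a factor of 10 on either side of parity:
ratio < 0.1 "homology-supporting", > 10 "spurious", otherwise "on-par".
The band width is a reporting convention only; the ratio itself is the
statistic.

## Quality score

Per column `j` of a seed alignment of `M` sequences: consensus vector
`X_j = F_jᵀC/M` (F = residue counts, C = BLOSUM62); per-residue distance
`D_ij = ‖X_j − C[:,a_ij]‖₂` for non-gap residues (the Euclidean norm
follows the CLUSTALX source; a signed-sum variant, in which opposite
deviations cancel, is available via `distance="signed_sum"`); column
quality `Q_j = Σᵢ D_ij / M` — the sum runs over non-gap rows but the
divisor stays `M`, so sparse columns are already down-weighted once
before the explicit `k/M` factor; inversion `Q̂ = 1 − (Q − min)/(max −
min)` over the alignment's columns, so the most conserved column scores
1 and the least 0; and `Q̃_j = (k_j/M)·Q̂_j` with `k_j` the non-gap
count. Degenerate case max Q = min Q (perfectly homogeneous alignment):
all `Q̂ = 1`, since uniform consensus is maximal consensus.

Positions with `Q̃ ≥ cutoff` are fold-critical. Default cutoffs 0.06
(SMART-like) and 0.14 (Pfam-like) correspond to a 5% column
false-positive rate in the published calibration, where columns with ≥5
non-gap residues form the positive class and sparser columns the null
class; `calibrate_cutoff` reproduces that tabulation for any score
lists. The ≥5 rule comes from the binomial power argument: the smallest
attainable tail probability `P(X ≥ M)` at p = 0.5 is 0.0625 for M = 4,
so columns with fewer than 5 residues can never reach α = 0.05.

## SEG-derived segmentation

SEG itself is external; the module consumes per-residue 0/1 masks
(1 = high-complexity) projected from ungapped sequences back to
alignment columns. Per column, the binomial tail `p = P(X ≥ k)` is
tested at α = 0.05; on rejection `k_exp = p·k`, else 0; the column
probability is `p_exp = k_exp/M`, floored at 0.01 when `k_exp = 0`, and
columns with `p_exp ≥ 0.8` count as high-complexity. This literal form
has a counter-intuitive consequence — a unanimously high-complexity
column (M = 8, k = 8) gets `p_exp ≈ 0.004` and is *not* called
high-complexity — so the complement weighting `k_exp = (1 − p)·k`,
which scores confident columns high, is available as `literal=False`.
The literal form is the default; no claim is made about which behaviour
is "right", and the quality score is the recommended surrogate.

## Structural annotation

DSSP codes H, B, E, G, I, T, S are structural; blank (loop) and `-`
(gap) are unstructured. Delete-state positions and positions outside
the alignment are labelled gap and counted with the unstructured set.
Enrichment of structural residues in fold-critical segments is tested
with the one-tailed hypergeometric tail `P(X > f11)` — strictly
greater, as opposed to the conventional Fisher `P(X ≥ f11)`, which is
available via `inclusive=True`. A control direction (enrichment of
unstructured residues in fold segments) is provided for sanity checks.
p-values are raw; multiplicity correction across domains is left to the
caller.

## Reconstruction diagnostics

Per domain, reconstructed scores are regressed on original scores
without intercept after adding a point at the origin (one domain's seed
scores cluster tightly; the origin point anchors the fit): slope
`β̂ = Σwv/Σv²` and r² as the squared product-moment correlation of the
augmented set. The additive error model `W = v + ε` is summarized by
the mean error, the population variance (divisor P, not P−1), and the
relative error `ε_r = μ_ε/μ_v`.

## Hit classification and comparison

With significance threshold 0.1 on all three E-values (total,
high-quality, low-quality): TP = total and high both significant; TN =
both insignificant; FP = total significant but only the low-quality
part is; FN = total insignificant although the high-quality part is
significant on its own. The two remaining patterns — where only the
fixed score flips the total — are undefined and excluded from rates.

Hits from two engines pair when they share a sequence id and ≥1
overlapping position (a minimum overlap fraction of the shorter hit is
configurable); many-to-many overlaps resolve greedily by longest
overlap with deterministic tie-breaks. Paired hits classify as positive
concordance (both labels in {TP, FN}), negative concordance (both in
{TN, FP}), or discordance types 1/2. Rates are percentages over paired
hits (the three concordance/discordance percentages sum to exactly
100); orphans never enter a denominator. The FN rate counts TPFN, FNTP
and FNFN pairs; the FP rate counts FPTN, TNFP and FPFP.

## Synthetic data

The fixture generator emulates, under a fixed seed:

* **models** — integer-milli-bit parameter tables with valid XT/EVD
  lines; glocal-style by default (interior entry/exit `*`), optionally
  with local entries;
* **alignment paths** — full-model walks with random deletions and
  insert runs (never an insert directly before a delete, as no I→D edge
  exists), plus renderers for both hmmsearch text layouts;
* **seed alignments** — planted FOLD blocks draw one consensus residue
  with probability 0.9, REMNANT columns draw uniformly with 20% gaps,
  over 8 sequences (the minimum-power regime of the column test);
* **annotations/masks** — DSSP-style labels and SEG-style masks
  agreeing with the planted truth up to 5% label noise;
* **hit populations** — a seed-space-like regime: 99% of hits true,
  5% of true hits obscured (insignificant total), engines assessed
  independently.

The independent scoring oracle is a naive per-term loop over the file's
integers in exact rational arithmetic, kept in the fixture module so
oracle-vs-production comparisons share no code path.

What the fixtures do *not* emulate: realistic protein evolution,
residue composition bias, correlated columns, or the score
distributions of real domain libraries. Passing the planted-recovery
test (quality segmentation at the `Q̃ = 0.5` midpoint of the normalized
range recovers two-level planted blocks at ≥90% position agreement over
50 seeds) shows the score separates a strong two-level conservation
signal, not that the published library-scale cutoffs are optimal for
any particular real alignment.

## Problem sizes and numerical choices

The test suite and the acceptance script use small problem sizes chosen
to exercise every code path with plenty of replication: models of 3–25
states, alignments of ≤8×20, 120 seeded reconstruction fixtures, 200
random alignments for the quality-score oracle, exhaustive Fisher
enumeration for margins N ≤ 20 plus 300 random margin sets up to
N = 60, and hit populations of a few hundred. Oracle-equivalence
tolerances are 1e-9 (absolute, on bit scores and probabilities);
conservation of the dissected sums is exact by construction. Ties at
the quality cutoff (`Q̃ = cutoff`) go to FOLD; the E-value significance
threshold is inclusive (`E ≤ 0.1`).

## Known limitations

* Only the HMMER2 save-file dialect is parsed; native HMMER3 files must
  be converted externally, with the documented loss of interior local
  entry/exit scores.
* Per-fragment scores of heavily fragmented local hits are approximate
  (entry/exit terms unrecoverable); per-hit sums are the supported
  quantity.
* Sub-score E-values reuse the whole-model Gumbel calibration; segment
  score distributions are not recalibrated.
* The hmmsearch text parser recognizes the two standard layouts as
  rendered by the fixture generator and by the engines' defaults;
  exotic wrapping or annotated consensus lines may need the explicit
  path-TSV interface instead.
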