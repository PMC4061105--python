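# hmmdissect

Dissection of profile-HMM alignment scores into fold-critical and
remnant segment contributions.

## The problem

Sequence similarity searches (HMMER-style profile HMMs against protein
databases) report a single total log-odds score per alignment and judge
homology by its E-value. But a statistically significant total can be
carried entirely by non-globular regions — low-complexity stretches,
long loops, linkers, transmembrane segments — whose similarity says
nothing about a shared fold. Conversely, a genuine homology can be
drowned when a divergent non-globular region drags the total score below
significance. Homology, strictly, is evidence of common ancestry, and
that evidence lives in the residues that build the tertiary fold.

`hmmdissect` addresses this for anyone running domain-library searches
(SMART/Pfam-style models, HMMER2 or converted HMMER3 parameter files):
it reconstructs the alignment score from model parameters, splits it
between *fold-critical* and *remnant* model segments, and evaluates each
part's significance on its own.

## The method

For an alignment path through a model with match states `1..K`, the
total bit score is

```
v = Σ log2 e(Y_i | X_i) + Σ log2 t(X_i | X_{i-1}) + log2 t(X_0) + f
```

— emission scores, transition scores (including the B→M entry and M→E
exit), and a position-invariant fixed score `f` from the model's special
(XT) transitions. Every positional term is anchored to a model
coordinate, so given a segmentation of `1..K` into FOLD/REMNANT classes
the total splits exactly: `fold + remnant + f = v`. Each sum gets a
Gumbel E-value

```
E = N · (1 − exp(−exp(−λ (v − μ))))
```

with the model's calibrated `(μ, λ)` and database size `N` (default
540261). The ratio `E₁/E₂` of the fold-critical to the remnant E-value
is the diagnostic: `≪ 1` supports homology, `≫ 1` flags a hit carried by
non-globular similarity.

Segmentations come from three schemes: DSSP secondary-structure labels
(`H,B,E,G,I,T,S` = fold-critical), a CLUSTALX-style per-column alignment
quality score `Q̃` thresholded at a calibrated cutoff (0.06 for
SMART-like, 0.14 for Pfam-like seed alignments), or SEG-derived
low-complexity column probabilities. Hits labelled from the three
E-values (TP/FN/FP/TN) can be paired across two search engines and
summarized as concordance, discordance, and FN/FP rates.

## Worked example

Generate a self-contained synthetic bundle and dissect it:

```
$ hmmdissect fixtures --seed 7 --model-length 12 --outdir bundle
$ hmmdissect dissect --model bundle/model.hmm --alignment bundle/paths.tsv \
      --dssp bundle/structure.dssp
hit_id  total    fold     remnant  fixed   E_total  E_fold    E_remnant  ratio  verdict
hit7    -38.612  -24.031  -11.927  -2.654  5.4e+05  3.04e+05  1.66e+04   18.3   spurious
```

The total score of −38.612 bits splits into −24.031 bits over the
structurally annotated (fold-critical) positions and −11.927 bits over
the rest, plus the fixed score −2.654; the sums are conserved exactly.
The fold-critical E-value (3.04e+05) is ~18 times *less* significant
than the remnant one, so whatever similarity this alignment has is
carried by non-fold segments — the hit is flagged `spurious`. A
homology-supporting hit shows the opposite pattern (ratio ≪ 1).

Per-column quality scores and the cross-engine comparison work the same
way:

```
$ hmmdissect quality --alignment bundle/seed.sto | head -3
column  Q       Q_hat   Q_tilde  valid  class
1       5.2118  0.4759  0.4759   8      FOLD
2       2.6612  0.9324  0.9324   8      FOLD

$ hmmdissect classify --hits-a bundle/hits_a.tsv --hits-b bundle/hits_b.tsv
metric                    value
paired_hits               200
positive_concordance_pct  99.50
fn_rate_pct               11.00
...
```

The same operations are available as library functions
(`hmmdissect.reconstruct_score`, `dissect`, `quality_profile`,
`segment_by_dssp`, `pair_hits`, `domain_rates`, ...).

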