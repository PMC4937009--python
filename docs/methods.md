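# Methods

## Model

A peptide is described by eight physicochemical descriptors aggregated
from per-residue values. For the count- and energy-like descriptors (AM,
AC, ROT, HBA, IP, NON) the sequence value is the occurrence-weighted sum
Σᵢ SPᵢ·nᵢ over residue types i. For the permeability and solubility
descriptors (QPCaco, QPlogS) the weighted sum is divided by N. The
denominator N is taken as the number of *distinct* residue types in the
sequence (DISTINCT mode); dividing by sequence length (LENGTH mode)
remains selectable because the two readings of "non-repeated amino
acids" cannot be distinguished on repeat-free sequences. On the
packaged reference data the DISTINCT system has the smaller fitting
residual for both mean descriptors, which is why it is the default.

The scoring expression is AEx = ln(AM − IP + AC·ROT) − (QPCaco − NON),
with the natural logarithm (only base e reproduces the published scores,
e.g. ln(24.95) − 4.41 = −1.19 for ALLVN). AEx is undefined when
AM − IP + AC·ROT ≤ 0; that case is reported as NaN with a warning rather
than an exception, so window scanners degrade gracefully. Classes are
assigned by the ordered quadrant rules A, B, C, D given in the README;
ordered evaluation resolves the C/D overlap at AEx = 0, QPlogS < 0 in
favour of C — the only resolution that reproduces the published control
class counts (2/22/17/1) given the VVSVL row. The rule gap QPlogS > 0
with AEx = 0 returns U (unclassifiable) rather than guessing; no
reference row occupies it.

Reproduction mode classifies from the published sequence-level columns
verbatim; scoring mode recomputes descriptors from per-residue tables.
The two are never mixed within one run.

## Reference data

The packaged table has 148 rows: 84 APR peptides, 22 tregitopes and 42
control 5-mers. The control set is derived, not curated: residues 1–5
and 6–10 of each tregitope, with both occurrences of the doubly-selected
window VSWYQ removed (44 − 2 = 42). Duplicate windows from distinct
tregitopes (GGLVQ, MHWVR) are separate records. The VVSVL row is
retained exactly as published although its printed AEx (0.00) does not
follow from its own descriptor columns (recomputation gives −2.46); it
is the single known anomaly and is flagged by every consistency check.
All coordinates are 1-based inclusive. Loading recomputes group counts
and column sums against frozen checksums and fails loudly on mismatch.

## Per-residue table recovery

Only sequence-level descriptor values are published, so per-residue
tables are recovered by inverting the aggregation rules. Both rules are
linear in the residue-composition matrix C: SUM descriptors satisfy
C·v = s and MEAN descriptors C·v = s·N. Minimum-norm least squares
(`numpy.linalg.lstsq`) solves each system; the matrix built from all 148
sequences has full column rank (all 20 residues observed). For the
integer-count descriptors (AM, AC, ROT, NON) the solution is rounded to
the nearest integer; the rounded tables reproduce every published
sequence value exactly, and tables fitted on a random 120-row subset
predict the 28 held-out rows without error — these descriptors are
exactly additive in composition. HBA is exactly linear as well; IP
carries residuals up to ~0.006 from two-decimal print rounding. The
mean descriptors are only approximately linear (max residual ≈ 10 nm/s
for QPCaco): the published values evidently come from whole-peptide
property predictions, not from an additive per-residue model, so
recovered tables are calibration constants for the scoring model, not
chemically interpretable quantities. Residues absent from a training set
get no value, and scoring a sequence containing them is an error, not an
extrapolation. The fixed default seed for randomized splits is 20160707.

## Validation statistics

Group summaries report the arithmetic mean, sample SD (n−1 denominator),
SE = SD/√n with each group's own n, and the normal 95 % interval
m ± 1.96·SE. The per-group n (not the pooled total) and the 1.96
multiplier are the only conventions that reconcile the published class-D
interval (−1.629 ± 1.96·1.167/√67 → −1.909/−1.350). The published
group SDs for AEx (2.02 for APR, 3.40 for tregitopes) match the
population (n-denominator) formula; the sample-SD values reported here
are larger by √(n/(n−1)). The published control-group mean AEx (2.23)
matches neither convention — the printed rows average 2.20 — and is
reported as a discrepancy rather than matched.

The two-group comparison is the Mann-Whitney test with midranks,
tie-corrected variance and no continuity correction; |Z| is reported.
On the printed two-decimal columns this gives |Z| = 7.137 for AEx and
6.089 for QPlogS (APR vs controls), slightly below the originally
published 7.172 and 6.270: rounding the scores to two decimals before
ranking perturbs a handful of cross-group rank comparisons, and no
tie/continuity convention recovers the original values from the printed
columns. Both comparisons remain significant beyond p < 1e-9 either way.

The normal approximation is adequate at the reference sample sizes
(84 vs 42) but degrades at very small n: exhaustively over all tie-free
rank configurations with n₁+n₂ ≤ 9, the worst absolute gap between the
asymptotic and the exact-enumeration two-sided p is 0.236 (e.g. 2-vs-2
samples one rank step from the centre). The test suite measures this
honestly; exact enumeration should be preferred below roughly n₁+n₂ = 20.

The Cooper statistics implement their standard defining ratios; the
"proportion of active chemicals" statistic follows its published
defining equation Tn/(Tn+Fp), which makes it identical to specificity
(97.62 % on the reference data) — the separately published 85.71 %
equals accuracy and contradicts that equation, so it is reported, not
patched. The Toplis ratio check uses 84 training sequences over 7
descriptors (the six AEx terms plus QPlogS), ratio 12 > 5.

## Scanner

`scan_protein` slides a window (default 5, the dominant APR length:
39/84 reference APRs are 5-mers) in steps of 1 and classifies each
window from recomputed descriptors. Windows containing non-canonical
residues (B, J, O, U, X, Z), residues missing from the parameter
tables, or an undefined AEx are reported as class U and summarized in
the log; they never abort a run. Class-D windows carry the APR flag.
Long sequences scored whole (e.g. full tregitopes) can mask the
behaviour of their 5-mer constituents, which is why the scanner, not
whole-sequence scoring, is the intended screening interface.

## Synthetic data in the tests

Property tests draw peptides uniformly over the 20 canonical residues
(5–10-mers, seeded), which matches the inference problem's structure —
composition matrices of short peptides — but not the residue-usage bias,
hydrophobicity clustering or length distribution of real therapeutic
proteins. Passing recovery tests therefore demonstrates correctness of
the linear-algebraic procedure, not predictive validity on new
proteins; the latter rests on the reference-set validation statistics
above.

## Known limitations

- Per-residue descriptor computation from chemical structure is out of
  scope; tables must be recovered from, or supplied alongside, labelled
  sequence-level data.
- The recovered mean-rule tables inherit the ~10 nm/s QPCaco fitting
  residuals; window scores for QPCaco-sensitive calls are accordingly
  approximate.
- The model classifies 5-mer-scale windows; it does not model
  aggregation kinetics, 3D structure, or immunogenicity beyond the
  quadrant rule.
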