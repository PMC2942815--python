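# Methods

This note documents the models, conventions and numerical choices behind
`dupevol`, and what the synthetic-data validation does and does not
establish.

## Pairwise rates (NG86 + Jukes–Cantor)

`rates` implements Nei–Gojobori (1986) counting:

- **Sites.** For each sense codon, the synonymous-site count at a position
  is the synonymous fraction of the single-nucleotide changes at that
  position *excluding stop-producing changes* (the per-position
  denominator is reduced accordingly). Site counts per codon sum to 3
  exactly; a pair's site counts are averaged over the two sequences.
- **Differences.** Codons differing at d positions are scored by averaging
  the synonymous/non-synonymous step classification over all d! orderings
  of single steps; orderings passing through a stop codon are discarded
  and the average renormalized. If every ordering is blocked (does not
  occur between sense codons under the standard code, but the code path
  exists) the differences are scored non-synonymous with a warning.
- **Correction.** d = −(3/4)·ln(1 − (4/3)·p) applied to pS and pN.
  p ≥ 3/4 is flagged *saturated* instead of raising; downstream selection
  treats saturated pairs as dS > 3 and skips them.
- Gap/ambiguity codon columns are dropped per pair (not listwise).

All 61×61 pathway-averaged counts are precomputed at import and verified
in the test suite against an independent exact-rational enumerator.

This counting estimator deliberately replaces ML codon models (codeml):
it is self-contained and exactly testable. On data at moderate divergence
the two differ slightly; `import_rates` lets users substitute any external
pairwise table (columns id_a, id_b, dN, dS) and rerun everything else
unchanged.

**Known estimator bias.** On simulator-generated data the replicate-mean
NG86 dS sits ≈1% below the true divergence at dS ≈ 0.2 and ≈1.7% below at
dS ≈ 0.4 (pathway averaging and the JC correction are both approximations
at multiple-hit divergences). Tests that compare a replicate-mean NG86
estimate against a true tree distance therefore allow
max(3 SE, 5% relative); the generator itself is held to the sharper
truth-level check below. The bias largely cancels in the three-point
decomposition (it is approximately multiplicative and the i–k and j–k
paths have equal depth), which is why individual-rate recovery passes a
plain 3-SE unbiasedness test.

## Family construction

Replaces the original genome-scale discovery stack (repeat masking +
megablast) with desk-scale equivalents while keeping the published
decision rules exactly:

- Links: global BLOSUM62 protein alignment (biopython PairwiseAligner,
  open −11 / extend −1), back-projected to nucleotides; link if nucleotide
  identity ≥ 75% over > 20% of the average length. Single-linkage
  clustering = connected components (networkx).
- Multiple alignment: center-star on protein translations, back-projected
  to codons. Adequate for recently duplicated, colinear CDS; not a
  general MSA. Equal-length inputs (the simulator's) pass through
  unaligned.
- QC: after removing gap columns, families are kept when the fraction of
  *unanimous* nucleotide columns lies in [0.25, 0.98] (unanimity chosen as
  the column-identity convention; partial agreement is not defined by the
  rule), genes with mean pairwise divergence > 80% are removed most
  divergent first with recomputation after each removal (removal order is
  a stated convention), and ≥ 3 members must remain.

## Triplets and individual rates

Sister: dS-minimizing family member within [0.01, 3]; neighbours with
dS < 0.01 are skipped (recursively — taking the in-window minimum skips
arbitrarily many). Cousin: dS(i,k) > dS(i,j) and dS(j,k) > dS(i,j), both
cousin distances ≤ 3 and unsaturated, minimizing dS(i,k). All selection
ties break toward the lexicographically smaller id (determinism; the rules
themselves are silent on ties). Interval endpoints are inclusive
throughout.

dX_I = (dX(i,j) + dX(i,k) − dX(j,k))/2. Noise can make the triangle
non-additive and dX_I negative; such triplets are kept but flagged, and
the individual-rate window 0.005 ≤ dS_I ≤ 0.6 (inclusive) removes them
from trend analyses. The additivity identity
dX_I(i) + dX_I(j) = dX(i,j) for mutual sisters sharing a cousin is exact
algebra and asserted to 1e-12.

## Asymmetry screen

Bidirectional best pairs (mutual sisters) with the cousin minimizing
dS(a,c) + dS(b,c) under the outgroup inequalities. Assignment rule per
divergent column: copy disagreeing with the outgroup acquired the change;
all-three-distinct columns excluded (counted separately from gap
exclusions). Channels:

- `aa`: translated columns — non-synonymous asymmetry.
- `syn`: nucleotide columns restricted to codons whose amino acid is
  identical across the triplet, so assigned changes are synonymous by
  construction. This channel definition is this package's stated
  convention (clean separation, no double counting); codons not
  amino-acid-conserved across the triplet are excluded from it.

Per-pair test: exact Binomial(Y, ½) with the two-sided p-value defined as
twice the smaller tail, capped at 1 (p = 1 when Y = 0). All 26 published
count pairs are significant under this two-sided choice, so the
reproduction does not hinge on sidedness; one-sided is available behind a
flag. No per-pair multiplicity correction — the meta-test,
P(X ≥ n_asym | n_pairs, 0.05) by direct log-space summation (verified
against scipy's exact survival function to 10 significant digits), is the
screen's answer to multiplicity.

## Trends

OLS of ω_I on dS_I (statsmodels), 95% slope CI from the t distribution;
an all-equal-dS input yields a flagged degenerate fit. Family ω is the
*ratio of averages* mean(dN)/mean(dS) (the family dN and dS are defined as
pair averages; mean-of-ratios is available as an explicit alternative).
The ≥ 100-substitution floor (inclusive) on gene-to-sister nucleotide
differences guards the regression against discrete-count artifacts.
Exon-count stratification is supported only through user-supplied labels,
never inferred.

## Simulator

A stated world for validation, not a fitted model:

- **Clock and calibration.** Branch lengths are expected synonymous
  substitutions per NG86 synonymous site. Candidate single-nucleotide
  changes are uniform over positions and alternative bases (no ts/tv
  bias — a documented extension point). The candidate rate is set from
  the current sequence's synonymous-change count and recalibrated every
  0.05 substitution units, so composition drift along a branch stays
  second-order. Truth-level check: realized synonymous substitutions per
  entry synonymous site match the branch length within 3 SE (measured
  ratio 0.9985 ± 0.0022 over 240 branches).
- **Selection.** Synonymous candidates are always accepted; non-synonymous
  accepted with probability ω (× accel on the designated branch). For
  ω_eff > 1 the candidate rate is boosted by M = ω_eff and synonymous
  acceptances thinned by 1/M, keeping the synonymous clock calibrated
  while dN/dS exceeds 1 (verified for ω = 2).
- **Stop codons.** Candidates creating stops are rejected without
  consuming branch length; sequences stay valid CDS throughout. The root
  is uniform over the 61 sense codons unless given explicitly.
- **Truth.** Every accepted change increments its branch's
  (syn, nonsyn) counter; entry synonymous-site counts are recorded so
  per-branch realized rates are reconstructable. One seeded stream per
  family; identical config ⇒ bit-identical output.
- `duplication_scenario(pair_depth, outgroup_depth, ω, accel, n, seed)`
  builds the canonical 3-leaf family ((i, j), k) with the acceleration on
  i's post-duplication branch.

**What the simulator does not emulate:** indels and alignment error,
gene conversion, recombination, ts/tv and codon-usage bias, site-to-site
rate heterogeneity, alternative genetic codes, and the ascertainment
quirks of real transcript catalogues. Green calibration tests establish
that the *statistics* behave as designed under a clean neutral/selected
codon process — not that real families satisfy these assumptions.

## Validation design (stated before measurement)

- Type-I: 400 symmetric pairs (ω = 0.3, depths 0.05/0.5, 1000 codons);
  rejection rate at α = 0.05 must lie inside the exact binomial 99% band
  around 0.05. The exact test is conservative (discreteness), so rates
  near 0.03–0.04 are expected and within band.
- Power: accel ∈ {1, 2, 5, 10}, 100 replicates each; power saturates at 1
  by accel ≈ 5, so monotonicity is asserted as non-decreasing within a
  2·√(0.25/R) Monte-Carlo tolerance plus a strict overall increase.
- Recovery: 200 replicates at pair depth 0.05; mean dS_I within 3 SE.
- Trend: 100 replicates of 12 families on a 0.05–0.5 depth grid with
  ω(d) = 0.5 − 0.6·d (ω stays in [0.2, 0.47], inside the regime where
  ratio noise is mild); the 95% CI must cover −0.6 in ≥ 90 replicates.
  Regression noise here is heteroskedastic (ω_I noise scales with
  1/dS_I), which OLS tolerates at this coverage threshold.

## Known limitations

- The published genome-wide numbers (families, gene counts, the −1.37
  slope) depend on a historical transcript catalogue and external tools
  and are out of scope; correctness is established on synthetic data and
  on the published substitution-count table.
- Center-star alignment degrades on families with domain shuffling or
  long indels; supply pre-aligned FASTA in that case.
- NG86/JC differs from ML codon models at moderate divergence; use the
  import adapter when codeml-compatible numbers are required.
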