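# Methods

This note records the models behind each pipeline stage, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions adopted where the underlying procedure leaves
room for interpretation.

## Comprehensive tolerance score (D)

The score treats cold tolerance as a latent quantitative trait observed
through five physiological indicators. Indicators are first standardized with
the membership function U(X) = (X − X_min)/(X_max − X_min), computed per
indicator across cultivars; a constant indicator makes U undefined and is
rejected with an error naming the variable. PCA is run on the covariance
matrix of the standardized columns (not z-scores — the membership function is
the standardization), components are sorted by eigenvalue, and the shortest
prefix whose cumulative contribution rate strictly exceeds the retention
threshold (default 0.85) is kept, always at least one.

Three places needed a decision the procedure itself does not fix:

- **Aggregation over time.** Measurements arrive per cultivar × indicator ×
  timepoint × replicate, but the PCA needs one value per cultivar per
  indicator. Default: mean over stress timepoints (day > 0) of replicate
  means, which uses the whole stress response; `single_day` and
  `stress_ratio` (stress mean / day-0 mean) are exposed as alternatives.
- **Component orientation.** Eigenvector signs are arbitrary but D is not
  invariant to them. Each component is oriented so its direction-weighted
  loading sum (benefit indicators +1; MDA, a damage marker, −1) is
  non-negative; exact zeros fall back to making the first non-zero loading
  positive. This makes larger D consistently mean more tolerant without
  pre-inverting the MDA column — inverting inputs before a min–max rescale
  would change U values, whereas orientation only fixes the sign convention.
- **Membership target.** U in the final sum is applied to the retained
  components' score columns (min/max over cultivars), not to the raw
  indicators; the weighted sum of per-component memberships is then
  guaranteed to lie in [0, 1], and the cultivar attaining every per-component
  maximum scores exactly 1.

Class thresholds strong/moderate/weak use half-open intervals [0.70, 1],
[0.40, 0.70), [0, 0.40): nominal class limits quoted as 0–0.39 / 0.4–0.69 /
0.7–1 leave (0.39, 0.40) and (0.69, 0.70) unassigned, and the half-open
convention closes those gaps deterministically. Clustering of D values uses
Ward linkage on Euclidean distance, cut at k = 3 groups labelled by
descending mean D; with identical D values the cut may return fewer groups,
which is reported as-is.

## Tissue specificity and the cold screen

τ is computed on linear (not log) abundances with replicates collapsed to
per-tissue means; it is undefined (NaN, category `not_expressed`) for
all-zero genes. The specific/ubiquitous thresholds 0.8/0.2 are strict
inequalities, so τ = 0.8 exactly is `intermediate`. A gene counts as
"expressed" when any per-tissue mean exceeds 0; the cutoff is a parameter
because presence calls depend on the quantifier's noise floor.

The induction screen tests the first stress timepoint against baseline on
log2(x + 1) replicate values. With the three biological replicates typical of
these designs, per-gene variance estimates carry only ~4 degrees of freedom,
and a plain Welch test loses borderline true positives after multiple-testing
adjustment (measured sensitivity 0.86 at effect log2FC = 2, CV 0.1, n = 3).
The default test therefore moderates each gene's pooled variance toward a
common prior fitted across all genes by empirical Bayes — the limma approach,
implemented here directly: the marginal distribution of log pooled variances
is matched to a scaled F distribution via digamma/trigamma moment equations,
giving prior degrees of freedom d0 and prior variance s0²; the moderated
statistic uses (d0·s0² + d·s²)/(d0 + d) and d + d0 degrees of freedom. When
the observed spread of variances is no larger than sampling noise alone, d0
is infinite and the test collapses to a z-test with the common variance.
Under the null this preserves type-I control (measured flagged fraction 0 at
the screen's joint effect-size + FDR criterion); `test="welch"` restores the
unmoderated test. FDR is Benjamini–Hochberg (via statsmodels). Genes whose
replicates are identical across groups get p = 1 rather than NaN.

## qPCR

ΔCt = Ct_target − Ct_reference per biological replicate after technical
replicates are averaged on the Ct scale (arithmetic mean of cycles, i.e. a
geometric mean of abundances — the conventional order). The calibrator is the
earliest timepoint of the same cultivar and gene unless given explicitly;
ΔΔCt subtracts the calibrator's *mean* ΔCt, so the calibrator's mean fold is
1 by construction while its individual replicates scatter around 1.
Amplification efficiency is fixed at 2. Cross-cultivar ratios default to the
ratio of mean folds (`mean_of_folds`); `fold_of_means` (difference of mean
ΔΔCt, exponentiated) is exposed because the two differ under replicate noise.

The Kruskal–Wallis omnibus p-value is exact for total n ≤ 9: all distinct
assignments of the pooled ranks to the group sizes are enumerated
(multinomial, e.g. 1680 for 3+3+3) and p = P(H ≥ H_obs) with tie-corrected H.
Beyond that the chi-square approximation is used. Dunn's pairwise z uses the
tie-corrected pooled rank variance and Bonferroni multiplication by the
number of pairs. The compact letter display assigns one letter per maximal
window of consecutive rank-ordered groups containing no significant pair —
with all observations identical the omnibus p is 1 and all groups share a
single letter.

## Promoter scanning

Patterns are IUPAC-degenerate strings matched exhaustively: every occurrence
on either strand counts, overlaps included, with minus-strand hits found by
matching the reverse-complemented pattern on the forward sequence and
reported at forward-strand 0-based positions. A palindromic pattern therefore
counts once per strand at the same position — a deliberate, oracle-checkable
convention. `N` in a sequence never matches. The shipped dictionary contains
canonical consensus strings for 30 common plant cis-elements in five
functional classes; motif-database definitions are versioned and differ
between releases, so reproducing any published count depends on supplying the
dictionary that study used (`--dictionary`). The joint statistic defaults to
promoters containing at least one hormone, one stress *and* one light element
("all"); the union reading is available as `joint_mode="any"`.

## Ka/Ks and duplication classes

The estimator is classical Nei–Gojobori (1986) counting: per-position
synonymous site fractions with mutations to stop codons excluded from the
denominator (site counts always sum to 3 per codon); differences between
codons averaged over all minimal mutational pathways whose intermediates are
sense codons, unweighted — when every pathway crosses a stop (rare), all
minimal pathways are used with stop-crossing steps counted nonsynonymous;
Jukes–Cantor correction d = −3/4·ln(1 − 4p/3). The ratio is undefined when
Ks = 0 or either proportion is saturated (p ≥ 3/4), with the reason recorded.
NG86 was chosen over ML codon models because every ingredient is checkable
against brute-force enumeration, which the tests do.

Collinear blocks come from a greedy monotone-chain extractor: per chromosome
pair, anchors sorted by the first chromosome's order; the longest strictly
monotone chain (parallel or antiparallel) with successive order gaps ≤ 25 on
both chromosomes is extracted and removed, repeating while chains reach the
5-anchor minimum. Ties break toward parallel orientation and earliest
predecessors, making the output deterministic. This is a simplification of
MCScanX-style chaining (no scoring, no e-value weighting), adequate for
planted-structure recovery but not a re-implementation of it. Classification
precedence: block membership → tandem (same chromosome, order gap ≤ 10, a
configurable criterion since no standard threshold exists) → dispersed.

## Synthetic-data generators

All generators take an explicit integer seed (numpy `default_rng`; no global
state) and record planted truth in a `TruthBundle`.

- **Physiology:** five indicators driven by a latent tolerance θ per cultivar
  (default: evenly spaced on [0, 1], chosen over random draws so recovery
  experiments see a fixed, well-spread design; explicit θ can be passed).
  Indicator mean = baseline × (1 + amplitude × stress(t) × logistic(θ)), with
  the logistic flipped for MDA; stress(t) ramps linearly from 0 at day 0.
  Baselines/amplitudes sit on enzyme-activity and metabolite scales (SOD 150
  U·g⁻¹, POD 300 U·g⁻¹, sugar 12 mg·g⁻¹, protein 8 mg·g⁻¹, MDA 18 nmol·g⁻¹).
  Replicate noise is multiplicative log-normal with unit mean at the stated
  CV — assay error is scale-proportional. These distributional choices are
  stated assumptions; the design (14 cultivars, days 0/1/3/5/7, five
  replicates) mirrors the motivating experiment.
- **Atlas:** tissue-specific genes expressed at a log-normal level in one
  tissue with fractional leakage (default 0.02 → true τ = 0.98) elsewhere;
  silent genes exactly zero; background genes log-normal with per-gene
  tissue-factor spread so τ spans low values.
- **Time course:** transient induction — peak 2^lfc at the second timepoint,
  2^(lfc/2) afterwards; the generator signature gained a `noise_cv` keyword
  (default 0.1) since recovery experiments need the replicate noise level as
  an explicit condition.
- **qPCR:** target Ct = reference Ct + calibrator ΔCt − log2(fold) plus
  Gaussian cycle noise; the reference gene's Ct is condition-independent.
- **Promoters:** i.i.d. background at the stated GC; planted motifs are
  concretized from their IUPAC patterns, reverse-complemented for
  minus-strand plants, placed without overlap; optional rejection resampling
  scrubs background dictionary matches so planted counts are exact.
- **CDS pairs:** per-codon Gillespie simulation of a continuous-time process
  with equal base exchangeabilities, nonsynonymous rates scaled by ω and stop
  codons excluded, calibrated so the expected substitutions per codon equal
  t at the ancestral composition — the nonsynonymous/synonymous *rate* ratio
  is exactly ω, which is what NG86 should recover.
- **Gene maps:** tandem arrays (consecutive genes, all C(size,2) pairs),
  collinear blocks (order-aligned anchors across two chromosomes) and
  dispersed decoys placed on chromosome pairs free of blocks.

What the generators do **not** emulate: read-level RNA-seq and its
quantification noise structure, tetraploid allele dosage and homoeolog
expression, genomic base composition and repeat structure in promoters,
rate heterogeneity and transition/transversion bias in codon evolution, and
block erosion or inversions-within-blocks in gene maps. Passing recovery
tests therefore demonstrates correctness of the computations under the
stated models, not robustness to every property of real data.

## Problem sizes and runtimes

The test suite and acceptance script use the motivating study's design
scales where they are small (14 cultivars × 5 indicators × 5 timepoints × 5
replicates; 191 genes × 6 tissues; 191 genes × 3 timepoints × 3 replicates;
2000 bp promoters with a 30-entry dictionary) and simulation sizes chosen to
make Monte-Carlo error comfortably smaller than the tolerance being checked:
200 seeds for D-score recovery, 100 seeds for screen sensitivity, 200 pairs ×
1000 codons per ω for Ka/Ks recovery, exhaustive oracles up to 9 observations
(Kruskal–Wallis) and 12 anchors (chaining). The full suite runs in ~15 s and
the acceptance script in ~10 s on one CPU.

## Known limitations

- The D score inherits PCA's linearity; indicators responding non-monotonely
  to tolerance would need transformation first.
- The moderated test assumes exchangeable per-gene variances on the log
  scale; strong mean–variance trends would call for a trended prior.
- The exact Kruskal–Wallis branch grows multinomially; it is capped at n ≤ 9
  by default.
- NG86 underestimates divergence at high saturation and ignores codon-usage
  and ts/tv bias; for deep divergences an ML estimator should be preferred.
- The chainer does not merge chains across max-gap breaks and extracts
  greedily, so heavily eroded blocks may be split.
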