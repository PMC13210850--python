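# coldkit

Tools for the statistical backbone of plant cold-tolerance gene-family
studies: screening cultivars for cold tolerance from physiological panels,
profiling a transcription-factor family's expression across tissues and under
low-temperature stress, quantifying qPCR validation experiments, scanning
promoters for cis-acting elements, and classifying gene-duplication history
with Ka/Ks selection-pressure estimates.

It is aimed at researchers who run these analyses across cultivar panels and
gene families (the motivating system is the bZIP family in tetraploid potato)
and want each step as a tested, scriptable unit rather than a chain of GUI
tools. Every stage has a matching synthetic-data generator that plants known
ground truth, so the whole pipeline can be exercised and validated without
any external download.

## What it computes

**Comprehensive cold-tolerance score (D).** Each physiological indicator
X_j (SOD, POD, soluble sugar, soluble protein, MDA) is rescaled with the
membership function

    U(X_j) = (X_j − X_min) / (X_max − X_min)

PCA of the standardized cultivar × indicator matrix yields composite
indicators; components are retained until their cumulative contribution rate
p_j exceeds 85%, each retained component gets weight W_j = p_j / Σ p_j, and

    D = Σ_j U(X_j) · W_j  ∈ [0, 1]

Cultivars are classed strong (D ≥ 0.70), moderate (0.40 ≤ D < 0.70) or weak
(D < 0.40), and optionally grouped by Ward clustering on D.

**Tissue specificity (τ).** For per-tissue abundances x_i with
x̂_i = x_i / max x_i, τ = Σ(1 − x̂_i)/(n − 1); τ > 0.8 marks tissue-specific
genes (assigned to their maximal tissue), τ < 0.2 ubiquitous ones.

**Cold-induction screen.** Per gene, log2FC of the 12 h stress timepoint over
baseline (pseudocount 1), a variance-moderated t test on log2 replicate
values, Benjamini–Hochberg FDR across genes; induced = log2FC ≥ 1 and
FDR < 0.05, strongly induced additionally log2FC ≥ 2.

**qPCR quantification.** 2^−ΔΔCt with technical replicates averaged on the Ct
scale, a reference gene per sample and the 0 h condition as calibrator;
cross-cultivar fold ratios; Kruskal–Wallis (exact permutation p for total
n ≤ 9) with Dunn's Bonferroni-corrected post hoc and compact letter display.

**Promoter scanning.** Overlap-complete IUPAC matching of a configurable
cis-element dictionary on both strands of 2000 bp promoters, five-class
functional summary (hormone / stress / light / development / other) and the
fraction of promoters jointly carrying hormone, stress and light elements.

**Ka/Ks and duplication classes.** Nei–Gojobori (1986) counting with
Jukes–Cantor correction on gapless codon alignments; homolog pairs are
classified as WGD/segmental (inside a collinear block found by a greedy
monotone-chain extractor), tandem (same chromosome, ≤ 10 intervening genes)
or dispersed, with per-class selection summaries.

## Worked example

Score a simulated 14-cultivar panel (five indicators, 0/1/3/5/7 d, five
replicates, 10% replicate noise) and compare the D ranking to the latent
tolerance the generator planted:

```python
import coldkit as ck
from scipy.stats import spearmanr

table, truth = ck.gen_physiology(14, (0, 1, 3, 5, 7), 5, noise_cv=0.1, seed=42)
scores, res = ck.score_cultivars(ck.aggregate_indicators(table))
print("contribution rates:", res.contribution_rates.round(4))
for s in sorted(scores, key=lambda s: -s.d_value)[:3]:
    print(f"{s.cultivar}  D={s.d_value:.3f}  {s.tolerance_class}")
rho = spearmanr([s.d_value for s in scores],
                [c.theta for c in truth.latent_cultivars]).statistic
print(f"Spearman(D, theta) = {rho:.3f}")
```

Output:

```
contribution rates: [0.9649 0.014  0.0103 0.0081 0.0028]
cv14  D=1.000  strong
cv12  D=0.974  strong
cv13  D=0.968  strong
Spearman(D, theta) = 0.996
```

The first principal component carries 96% of the variance (all five
indicators respond to the same latent tolerance), so only it is retained and
D is essentially the membership value of its score; the D ranking recovers
the planted tolerance order almost perfectly (ρ = 0.996).

The same operations are available from the shell, e.g.

```bash
coldkit simulate physio --n-cultivars 14 --seed 42 --out-dir sim/
coldkit score-tolerance --indicators sim/physiology.tsv --out scores.tsv
coldkit scan-promoters --fasta promoters.fasta --out hits.tsv
coldkit kaks --pairs cds_pairs.fasta --out kaks.tsv
```

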