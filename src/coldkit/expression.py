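"""Tissue-specificity (tau) indexing and the cold-induction expression screen.

tau = sum_i (1 - x_i / max_i x_i) / (n - 1) over n tissues: 0 for uniform
expression, 1 for single-tissue expression, undefined for an all-zero gene.
Genes with tau > 0.8 are tissue specific (assigned to their argmax tissue),
tau < 0.2 ubiquitous.

The cold screen compares stress-timepoint replicates to baseline replicates
gene by gene: effect size log2((mean_12h + c) / (mean_0h + c)) with
pseudocount c, a two-sided test on log2(x + c) replicate values, and
Benjamini-Hochberg adjustment across genes. Induced: log2FC >= 1 and
FDR < 0.05; strongly induced additionally log2FC >= 2.

With the few replicates typical of such designs, per-gene variance estimates
are too unstable for a plain Welch test to have useful power, so the default
test moderates each gene's pooled variance toward a common prior fitted
across all genes by empirical Bayes (the limma approach: the prior is a
scaled inverse chi-square whose degrees of freedom are estimated from the
spread of the observed log-variances); the moderated t statistic is referred
to a t distribution with residual + prior degrees of freedom. A plain Welch
test remains available via ``test="welch"``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tau_index",
    "tau_table",
    "classify_specificity",
    "expressed_fraction",
    "log2_fold_change",
    "bh_fdr",
    "cold_screen",
]


def tau_index(expression_row) -> float:
    """Tissue-specificity index of one gene's per-tissue abundances.

    Returns NaN (undefined) when the gene is not expressed in any tissue.
    """
    x = np.asarray(expression_row, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D row over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def tau_table(matrix: pd.DataFrame) -> pd.Series:
    """tau per gene for a genes x tissues matrix (replicates pre-collapsed)."""
    return matrix.apply(tau_index, axis=1, raw=True).rename("tau")


def classify_specificity(
    matrix: pd.DataFrame,
    threshold_specific: float = 0.8,
    threshold_ubiquitous: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene tau categories plus per-tissue specific-gene counts.

    Categories: ``specific`` (tau strictly > threshold, assigned to the argmax
    tissue), ``ubiquitous`` (tau strictly < threshold), ``not_expressed``
    (all-zero) or ``intermediate``.
    """
    taus = tau_table(matrix)
    categories, spec_tissue = [], []
    for gene, tau in taus.items():
        if np.isnan(tau):
            categories.append("not_expressed")
            spec_tissue.append(None)
        elif tau > threshold_specific:
            categories.append("specific")
            spec_tissue.append(matrix.loc[gene].idxmax())
        elif tau < threshold_ubiquitous:
            categories.append("ubiquitous")
            spec_tissue.append(None)
        else:
            categories.append("intermediate")
            spec_tissue.append(None)
    result = pd.DataFrame(
        {"tau": taus, "category": categories, "specific_tissue": spec_tissue}
    )
    counts = (
        result.loc[result["category"] == "specific", "specific_tissue"]
        .value_counts()
        .reindex(matrix.columns, fill_value=0)
        .rename("n_specific")
    )
    return result, counts


def expressed_fraction(
    matrix: pd.DataFrame, min_abundance: float = 0.0
) -> tuple[int, int, float]:
    """(n_expressed, n_total, percentage) of genes with any abundance above
    ``min_abundance`` in at least one condition."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    expressed = (matrix > min_abundance).any(axis=1)
    n, total = int(expressed.sum()), matrix.shape[0]
    return n, total, 100.0 * n / total


def log2_fold_change(treated, baseline, pseudocount: float = 1.0) -> float:
    """log2((mean treated + c) / (mean baseline + c)) with pseudocount c > 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    t = np.asarray(treated, dtype=float)
    b = np.asarray(baseline, dtype=float)
    if (t < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    return float(np.log2((t.mean() + pseudocount) / (b.mean() + pseudocount)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Empirical-Bayes fit of the variance prior (d0, s0^2).

    Matches the marginal distribution of log pooled variances to a scaled
    F distribution (Smyth's fitFDist): solves
    trigamma(d0/2) = var(log s^2) - trigamma(df/2) for the prior degrees of
    freedom d0, then recovers s0^2 from the mean log variance. Returns
    (inf, mean variance) when the observed spread is no larger than sampling
    noise alone (fully pooled variance).
    """
    from scipy import optimize, special

    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    target = float(np.var(e, ddof=1)) - float(special.polygamma(1, df_resid / 2.0))
    if target <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    f = lambda x: special.polygamma(1, x / 2.0) - target
    # trigamma is decreasing: bracket the root
    lo, hi = 1e-6, 1e6
    if f(lo) < 0:  # target larger than trigamma can reach -> tiny d0
        return 2e-6, float(np.exp(np.mean(e)))
    if f(hi) > 0:
        return math.inf, float(np.exp(np.mean(e)))
    d0 = optimize.brentq(f, lo, hi)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_sq


def _moderated_t(x_treat: np.ndarray, x_base: np.ndarray) -> np.ndarray:
    """Two-sided p-values from an EB variance-moderated two-sample t test.

    Rows are genes; columns replicates (log scale). Pooled within-group
    variance per gene is shrunk toward the fitted prior; the t statistic uses
    df_resid + d0 degrees of freedom.
    """
    n1, n2 = x_treat.shape[1], x_base.shape[1]
    df_resid = n1 + n2 - 2
    s2 = (
        x_treat.var(axis=1, ddof=1) * (n1 - 1) + x_base.var(axis=1, ddof=1) * (n2 - 1)
    ) / df_resid
    d0, s0_sq = _fit_variance_prior(s2, df_resid)
    if math.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    diff = x_treat.mean(axis=1) - x_base.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / denom
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return np.where(np.isnan(p), 1.0, p)


def _timepoint_columns(matrix: pd.DataFrame, sample_sheet: pd.DataFrame) -> dict[float, list[str]]:
    groups: dict[float, list[str]] = {}
    for row in sample_sheet.itertuples():
        groups.setdefault(float(row.timepoint), []).append(row.sample)
    for t, cols in groups.items():
        missing = set(cols) - set(matrix.columns)
        if missing:
            raise ValueError(f"samples {sorted(missing)} absent from matrix")
    return groups


def cold_screen(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame | None = None,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    strong_threshold: float = 2.0,
    pseudocount: float = 1.0,
    test: str = "moderated",
) -> pd.DataFrame:
    """Screen a 0/12/24 h replicate time course for cold-induced genes.

    ``sample_sheet`` needs columns (sample, timepoint, replicate); if omitted
    it is parsed from ``t{timepoint}_r{replicate}`` column names. ``test`` is
    ``"moderated"`` (EB variance moderation, default) or ``"welch"``. Genes
    are returned sorted by FDR then descending \\|log2FC\\|, with ``induced``
    and ``strongly_induced`` flags. Genes whose replicates are identical
    across groups get p = 1 (no evidence against the null).
    """
    if sample_sheet is None:
        from .simulate import sample_sheet_from_columns

        sample_sheet = sample_sheet_from_columns(matrix)
    groups = _timepoint_columns(matrix, sample_sheet)
    times = sorted(groups)
    if len(times) < 2:
        raise ValueError("need a baseline and at least one stress timepoint")
    t0, t12 = times[0], times[1]
    x0 = matrix[groups[t0]].to_numpy(dtype=float)
    x12 = matrix[groups[t12]].to_numpy(dtype=float)
    if x0.shape[1] < 2 or x12.shape[1] < 2:
        raise ValueError("need >= 2 replicates per timepoint for the per-gene test")
    lfc12 = np.log2((x12.mean(axis=1) + pseudocount) / (x0.mean(axis=1) + pseudocount))
    if len(times) > 2:
        x24 = matrix[groups[times[2]]].to_numpy(dtype=float)
        lfc24 = np.log2((x24.mean(axis=1) + pseudocount) / (x0.mean(axis=1) + pseudocount))
    else:
        lfc24 = np.full(len(lfc12), np.nan)
    l12, l0 = np.log2(x12 + pseudocount), np.log2(x0 + pseudocount)
    if test == "moderated":
        p = _moderated_t(l12, l0)
    elif test == "welch":
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(l12, l0, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError(f"unknown test {test!r}")
    fdr = bh_fdr(p)
    out = pd.DataFrame(
        {
            "log2fc_12h": lfc12,
            "log2fc_24h": lfc24,
            "p_value": p,
            "fdr": fdr,
        },
        index=matrix.index,
    )
    out["induced"] = (out["log2fc_12h"] >= lfc_threshold) & (out["fdr"] < fdr_threshold)
    out["strongly_induced"] = out["induced"] & (out["log2fc_12h"] >= strong_threshold)
    return out.sort_values(
        ["fdr", "log2fc_12h"], ascending=[True, False],
        key=lambda s: s.abs() if s.name == "log2fc_12h" else s,
        kind="stable",
    )
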