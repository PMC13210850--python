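"""2^-ddCt relative quantification and rank-based group comparison.

Technical replicates are averaged on the Ct scale; per biological replicate
dCt = Ct_target - Ct_reference, ddCt subtracts the mean dCt of the calibrator
condition of the same cultivar and gene (by default the first timepoint), and
fold = 2^-ddCt, so the calibrator's mean fold is 1 by construction.
Amplification efficiency is fixed at 2 (no efficiency correction).

Group differences in fold values are assessed with a Kruskal-Wallis omnibus
test (exact permutation enumeration for small samples, chi-square otherwise)
followed by Dunn's z post hoc with Bonferroni correction and a compact letter
display: groups sharing a letter are not significantly different.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "collapse_technical",
    "relative_expression",
    "cultivar_fold_ratio",
    "kruskal_dunn",
    "KruskalDunnResult",
    "FoldRatio",
]

_CT_COLUMNS = ["cultivar", "timepoint", "gene", "role", "bio_rep", "tech_rep", "ct"]


def _validate_ct(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    bad = set(table["role"]) - {"target", "reference"}
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}")
    return table


def collapse_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates (arithmetic mean on the Ct scale)."""
    _validate_ct(table)
    keys = ["cultivar", "timepoint", "gene", "role", "bio_rep"]
    return table.groupby(keys, sort=False, as_index=False)["ct"].mean()


def relative_expression(
    table: pd.DataFrame,
    calibrator: float | None = None,
) -> pd.DataFrame:
    """2^-ddCt per biological replicate for every target gene.

    ``calibrator`` is the calibrator timepoint (default: the smallest one
    present per cultivar/gene, conventionally 0 h). Requires a same-sample
    reference measurement for every target measurement.
    """
    collapsed = collapse_technical(table)
    ref = collapsed[collapsed["role"] == "reference"]
    targets = collapsed[collapsed["role"] == "target"]
    if targets.empty:
        raise ValueError("no target measurements")
    if ref.empty:
        raise ValueError("no reference-gene measurements")
    ref_ct = ref.set_index(["cultivar", "timepoint", "bio_rep"])["ct"]
    if ref_ct.index.duplicated().any():
        ref_ct = ref_ct.groupby(level=[0, 1, 2]).mean()
    rows = []
    for row in targets.itertuples():
        key = (row.cultivar, row.timepoint, row.bio_rep)
        if key not in ref_ct.index:
            raise ValueError(f"missing reference measurement for {key}")
        rows.append((row.cultivar, row.timepoint, row.gene, row.bio_rep,
                     row.ct - ref_ct[key]))
    dct = pd.DataFrame(rows, columns=["cultivar", "timepoint", "gene", "bio_rep", "delta_ct"])
    out = []
    for (cv, gene), grp in dct.groupby(["cultivar", "gene"], sort=False):
        cal_t = calibrator if calibrator is not None else grp["timepoint"].min()
        cal = grp[grp["timepoint"] == cal_t]
        if cal.empty:
            raise ValueError(f"calibrator timepoint {cal_t} absent for {cv}/{gene}")
        cal_mean = cal["delta_ct"].mean()
        g = grp.copy()
        g["ddct"] = g["delta_ct"] - cal_mean
        g["fold"] = 2.0 ** (-g["ddct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


@dataclass
class FoldRatio:
    ratio: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def cultivar_fold_ratio(
    rel: pd.DataFrame,
    gene: str,
    timepoint: float,
    cultivar_a: str,
    cultivar_b: str,
    mode: str = "mean_of_folds",
) -> FoldRatio:
    """Ratio of cultivar_a's expression to cultivar_b's at one timepoint.

    ``mean_of_folds`` (default) divides the mean biological-replicate folds;
    ``fold_of_means`` computes 2^-(mean ddCt_a - mean ddCt_b).
    """
    def _grab(cv):
        sub = rel[(rel["gene"] == gene) & (rel["timepoint"] == timepoint)
                  & (rel["cultivar"] == cv)]
        if sub.empty:
            raise ValueError(f"no measurements for {cv}/{gene} at {timepoint}")
        return sub

    a, b = _grab(cultivar_a), _grab(cultivar_b)
    if mode == "mean_of_folds":
        ma, mb = a["fold"].mean(), b["fold"].mean()
        if mb == 0:
            raise ZeroDivisionError("denominator cultivar has zero mean fold")
        ratio = ma / mb
    elif mode == "fold_of_means":
        ratio = 2.0 ** (-(a["ddct"].mean() - b["ddct"].mean()))
        ma, mb = a["fold"].mean(), b["fold"].mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return FoldRatio(
        ratio=float(ratio),
        mean_a=float(ma), mean_b=float(mb),
        sd_a=float(a["fold"].std(ddof=1)) if len(a) > 1 else 0.0,
        sd_b=float(b["fold"].std(ddof=1)) if len(b) > 1 else 0.0,
        n_a=len(a), n_b=len(b),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + compact letter display
# ---------------------------------------------------------------------------

def _kw_h(ranks: np.ndarray, labels: np.ndarray, sizes: np.ndarray, tie_term: float) -> float:
    """Kruskal-Wallis H with tie correction for one assignment of labels."""
    N = len(ranks)
    h = 0.0
    for g, n_g in enumerate(sizes):
        r = ranks[labels == g].sum()
        h += r * r / n_g
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _distinct_assignments(sizes: list[int]):
    """All distinct ways to split indices 0..N-1 into groups of the given sizes."""
    N = sum(sizes)
    def rec(avail: tuple[int, ...], k: int):
        if k == len(sizes) - 1:
            yield (avail,)
            return
        for combo in itertools.combinations(avail, sizes[k]):
            rest = tuple(i for i in avail if i not in combo)
            for tail in rec(rest, k + 1):
                yield (combo,) + tail
    yield from rec(tuple(range(N)), 0)


@dataclass
class KruskalDunnResult:
    h: float
    p_omnibus: float
    method: str                      # "exact" or "asymptotic"
    pairwise: pd.DataFrame           # group_a, group_b, z, p_raw, p_adj
    letters: dict[str, str]
    mean_ranks: pd.Series


def kruskal_dunn(
    groups: dict[str, np.ndarray] | dict[str, list[float]],
    alpha: float = 0.05,
    exact_max_n: int = 9,
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's Bonferroni post hoc and letters.

    With total sample size <= ``exact_max_n`` the omnibus p-value is computed
    by exact enumeration of all distinct group-label assignments of the pooled
    ranks (P(H >= H_obs) under the permutation null); otherwise the chi-square
    approximation with tie correction is used. Dunn's pairwise z statistics
    compare mean ranks with the tie-corrected pooled variance; p-values are
    multiplied by the number of pairs (Bonferroni, capped at 1). Letters are
    assigned over groups sorted by descending mean rank so that groups sharing
    a letter are not significantly different at ``alpha``.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(x) < 2 for x in data):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(data)
    N = len(pooled)
    sizes = np.array([len(x) for x in data])
    labels = np.concatenate([np.full(len(x), g) for g, x in enumerate(data)])
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    tie_term = 1.0 - tie_sum / (N**3 - N)

    all_identical = len(np.unique(pooled)) == 1
    h_obs = 0.0 if all_identical else _kw_h(ranks, labels, sizes, tie_term)

    if all_identical:
        p_omni, method = 1.0, "degenerate"
    elif N <= exact_max_n:
        ge = total = 0
        for assign in _distinct_assignments(list(sizes)):
            lab = np.empty(N, dtype=int)
            for g, idxs in enumerate(assign):
                lab[list(idxs)] = g
            total += 1
            if _kw_h(ranks, lab, sizes, tie_term) >= h_obs - 1e-12:
                ge += 1
        p_omni, method = ge / total, "exact"
    else:
        p_omni = float(stats.chi2.sf(h_obs, df=len(data) - 1))
        method = "asymptotic"

    # Dunn's pairwise z on mean ranks
    mean_ranks = pd.Series(
        [ranks[labels == g].mean() for g in range(len(data))], index=names
    )
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    n_pairs = len(data) * (len(data) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(data)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks.iloc[i] - mean_ranks.iloc[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], z, p_raw, min(1.0, p_raw * n_pairs)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])

    letters = _compact_letters(names, mean_ranks, pairwise, alpha)
    return KruskalDunnResult(
        h=float(h_obs), p_omnibus=float(p_omni), method=method,
        pairwise=pairwise, letters=letters, mean_ranks=mean_ranks,
    )


def _compact_letters(
    names: list[str], mean_ranks: pd.Series, pairwise: pd.DataFrame, alpha: float
) -> dict[str, str]:
    """Letter display by maximal non-significant windows over rank-ordered groups."""
    sig = {
        frozenset((r.group_a, r.group_b)): r.p_adj < alpha for r in pairwise.itertuples()
    }
    ordered = list(mean_ranks.sort_values(ascending=False).index)
    k = len(ordered)
    windows = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            sig[frozenset((ordered[a], ordered[b]))]
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        if not windows or windows[-1][1] < j:
            windows.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in names}
    for w, (i, j) in enumerate(windows):
        for name in ordered[i : j + 1]:
            letters[name] += alphabet[w % len(alphabet)]
    return letters
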