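"""Comprehensive cold-tolerance evaluation (membership function + PCA).

The procedure scores each cultivar from a panel of physiological indicators
measured under cold stress:

1. each indicator column X_j is rescaled to [0, 1] with the membership
   function U(X) = (X - X_min) / (X_max - X_min);
2. principal component analysis of the standardized matrix yields composite
   indicators; components are retained until their cumulative contribution
   rate (eigenvalue fraction) exceeds a threshold (default 85%);
3. each retained component receives weight W_j = p_j / sum(p_j) from its
   contribution rate p_j;
4. the membership function is applied to each retained component's score
   column and the comprehensive tolerance value is D = sum_j U_j * W_j,
   a number in [0, 1] — larger D, stronger cold tolerance;
5. cultivars are classed strong (D >= 0.70), moderate (0.40 <= D < 0.70) or
   weak (D < 0.40), and optionally grouped by Ward clustering on D.

Eigenvector signs are intrinsically arbitrary; each component is oriented so
that its direction-weighted loading sum (benefit indicators +, cost indicators
such as MDA -) is non-negative, which makes larger D consistently mean more
tolerant without pre-inverting any input column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .simulate import INDICATOR_DIRECTIONS

__all__ = [
    "CompositeResult",
    "ToleranceScore",
    "membership",
    "aggregate_indicators",
    "standardize_table",
    "pca_composites",
    "select_components",
    "component_weights",
    "d_value",
    "classify_tolerance",
    "cluster_cultivars",
    "score_cultivars",
]

STRONG_THRESHOLD = 0.70
MODERATE_THRESHOLD = 0.40


def membership(x: float, x_min: float, x_max: float) -> float:
    """Membership function U(X) = (X - X_min) / (X_max - X_min) on [0, 1]."""
    if x_max <= x_min:
        raise ValueError(f"degenerate range: x_max ({x_max}) must exceed x_min ({x_min})")
    if not x_min <= x <= x_max:
        raise ValueError(f"x={x} outside [{x_min}, {x_max}]")
    return (x - x_min) / (x_max - x_min)


def aggregate_indicators(
    long_table: pd.DataFrame,
    method: str = "stress_mean",
    timepoint: float | None = None,
) -> pd.DataFrame:
    """Collapse a (cultivar, variable, timepoint, replicate, value) table to a
    cultivar x variable matrix.

    ``stress_mean`` (default) averages replicate means over all stress
    timepoints (timepoint > 0); ``single_day`` uses one ``timepoint``;
    ``stress_ratio`` divides the stress mean by the day-0 (control) mean.
    """
    required = {"cultivar", "variable", "timepoint", "replicate", "value"}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    means = (
        long_table.groupby(["cultivar", "variable", "timepoint"])["value"]
        .mean()
        .reset_index()
    )
    if method == "stress_mean":
        sel = means[means["timepoint"] > 0]
        agg = sel.groupby(["cultivar", "variable"])["value"].mean()
    elif method == "single_day":
        if timepoint is None:
            raise ValueError("single_day aggregation requires a timepoint")
        sel = means[means["timepoint"] == timepoint]
        if sel.empty:
            raise ValueError(f"timepoint {timepoint} absent from table")
        agg = sel.set_index(["cultivar", "variable"])["value"]
    elif method == "stress_ratio":
        stress = means[means["timepoint"] > 0].groupby(["cultivar", "variable"])["value"].mean()
        control = means[means["timepoint"] == 0].set_index(["cultivar", "variable"])["value"]
        agg = stress / control
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    wide = agg.unstack("variable")
    if wide.isna().any().any():
        raise ValueError("missing cells after aggregation")
    # keep first-appearance variable order rather than alphabetical
    order = long_table["variable"].drop_duplicates().tolist()
    return wide[order]


def standardize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the membership function to every variable column across cultivars."""
    if table.shape[0] < 2:
        raise ValueError("need at least two cultivars to standardize")
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise ValueError(f"variable {col!r} has a degenerate (constant) range")
        out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


@dataclass
class CompositeResult:
    """PCA composite indicators of a standardized indicator table."""

    loadings: pd.DataFrame           # variable x component
    scores: pd.DataFrame             # cultivar x component
    eigenvalues: np.ndarray
    contribution_rates: np.ndarray   # p_j, summing to 1
    retained: list[int] = field(default_factory=list)
    weights: np.ndarray | None = None  # W_j over retained components


def pca_composites(
    standardized: pd.DataFrame,
    directions: dict[str, int] | None = None,
) -> CompositeResult:
    """Covariance PCA of the membership-standardized indicator matrix.

    Components are ordered by eigenvalue, descending. ``directions`` maps each
    variable to +1 (benefit) or -1 (cost) for the deterministic sign
    orientation; unknown variables default to +1.
    """
    if standardized.shape[0] < 2:
        raise ValueError("need at least two cultivars")
    if standardized.shape[1] < 2:
        raise ValueError("need at least two variables")
    directions = {**INDICATOR_DIRECTIONS, **(directions or {})}
    X = standardized.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    dvec = np.array([directions.get(v, 1) for v in standardized.columns], dtype=float)
    for j in range(eigvec.shape[1]):
        s = float(dvec @ eigvec[:, j])
        if s < 0 or (s == 0 and _first_nonzero_sign(eigvec[:, j]) < 0):
            eigvec[:, j] = -eigvec[:, j]
    scores = Xc @ eigvec
    comp_names = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    total = eigval.sum()
    if total == 0:
        raise ValueError("standardized matrix has zero total variance")
    return CompositeResult(
        loadings=pd.DataFrame(eigvec, index=standardized.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        eigenvalues=eigval,
        contribution_rates=eigval / total,
    )


def _first_nonzero_sign(v: np.ndarray) -> float:
    nz = v[np.abs(v) > 1e-12]
    return float(np.sign(nz[0])) if len(nz) else 1.0


def select_components(result: CompositeResult, threshold: float = 0.85) -> CompositeResult:
    """Retain the shortest prefix of components whose cumulative contribution
    rate strictly exceeds ``threshold``; at least one component is retained."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    cum = np.cumsum(result.contribution_rates)
    k = int(np.searchsorted(cum, threshold, side="right")) + 1
    k = min(max(k, 1), len(cum))
    result.retained = list(range(k))
    return result


def component_weights(result: CompositeResult) -> np.ndarray:
    """W_j = p_j / sum over retained p_j; stored on the result and returned."""
    if not result.retained:
        raise ValueError("no components retained; call select_components first")
    p = result.contribution_rates[result.retained]
    result.weights = p / p.sum()
    return result.weights


@dataclass
class ToleranceScore:
    cultivar: str
    memberships: np.ndarray     # U of each retained component score
    d_value: float
    tolerance_class: str


def d_value(result: CompositeResult) -> list[ToleranceScore]:
    """Comprehensive tolerance value D per cultivar.

    The membership function is applied to each retained component's score
    column (min/max over cultivars) and combined with the contribution-rate
    weights: D = sum_j U_j * W_j. The cultivar attaining every per-component
    maximum scores D = 1.
    """
    if result.weights is None:
        component_weights(result)
    U = np.empty((result.scores.shape[0], len(result.retained)))
    for k, j in enumerate(result.retained):
        col = result.scores.iloc[:, j].to_numpy()
        lo, hi = col.min(), col.max()
        if hi <= lo:
            raise ValueError(f"component {j + 1} has a degenerate score range")
        U[:, k] = (col - lo) / (hi - lo)
    d = U @ result.weights
    d = np.clip(d, 0.0, 1.0)  # guard float round-off at the boundaries
    return [
        ToleranceScore(str(cv), U[i], float(d[i]), classify_tolerance(float(d[i])))
        for i, cv in enumerate(result.scores.index)
    ]


def classify_tolerance(d: float) -> str:
    """strong (D >= 0.70), moderate (0.40 <= D < 0.70) or weak (D < 0.40).

    Half-open intervals close the unassigned gaps between the nominal class
    limits 0.39/0.40 and 0.69/0.70.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"D must be in [0,1], got {d}")
    if d >= STRONG_THRESHOLD:
        return "strong"
    if d >= MODERATE_THRESHOLD:
        return "moderate"
    return "weak"


def cluster_cultivars(scores: list[ToleranceScore], k: int = 3) -> pd.DataFrame:
    """Ward/Euclidean agglomerative clustering of the D values cut at k groups.

    Groups are labelled strong/moderate/weak (k = 3) or group1..k by
    descending mean D. With fewer distinct merge levels than k (e.g. identical
    D values) the cut yields fewer groups; the assignment is deterministic.
    """
    n = len(scores)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of cultivars ({n})")
    d = np.array([s.d_value for s in scores]).reshape(-1, 1)
    if k == 1 or n == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(d, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    df = pd.DataFrame(
        {"cultivar": [s.cultivar for s in scores], "d_value": d.ravel(), "cluster": labels}
    )
    mean_d = df.groupby("cluster")["d_value"].mean().sort_values(ascending=False)
    if k == 3:
        names = ["strong", "moderate", "weak"]
    else:
        names = [f"group{i + 1}" for i in range(len(mean_d))]
    rename = {cl: names[i] if i < len(names) else f"group{i + 1}"
              for i, cl in enumerate(mean_d.index)}
    df["group"] = df["cluster"].map(rename)
    return df.drop(columns="cluster")


def score_cultivars(
    table: pd.DataFrame,
    directions: dict[str, int] | None = None,
    threshold: float = 0.85,
) -> tuple[list[ToleranceScore], CompositeResult]:
    """Full pipeline: standardize -> PCA -> retain -> weight -> D + class."""
    std = standardize_table(table)
    result = pca_composites(std, directions)
    select_components(result, threshold)
    component_weights(result)
    return d_value(result), result
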