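"""Statistics over spheroid records: CV summaries, min-max scaling, PCA,
average-linkage clustering, group tests, and bioenergetic OCR-vs-ECAR maps.

All conventions are deterministic (PCA sign fixing, clustering tie-breaks)
so repeated runs of the same data are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .errors import ValidationError

DEFAULT_PCA_COMPONENTS = 2


def coefficient_of_variation(values) -> float:
    """CV as a percentage: 100 * sample SD (n-1 denominator) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def cv_from_moments(mean: float, sd: float) -> float:
    """CV from a reported mean and SD (the tabular summary path)."""
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return 100.0 * sd / mean


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Min-max scaled spheroids x parameters matrix with stored bounds."""

    data: pd.DataFrame  # values in [0, 1]
    column_min: pd.Series
    column_max: pd.Series

    def inverse(self) -> pd.DataFrame:
        span = self.column_max - self.column_min
        return self.data * span + self.column_min


def minmax_scale(matrix: pd.DataFrame) -> PhenotypeMatrix:
    """Rescale each column into [0, 1]; constant columns map to 0."""
    if len(matrix) < 2:
        raise ValidationError("min-max scaling needs >= 2 rows")
    col_min = matrix.min(axis=0)
    col_max = matrix.max(axis=0)
    span = col_max - col_min
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"constant columns scaled to 0: {list(matrix.columns[constant])}",
            stacklevel=2,
        )
    safe_span = span.replace(0, 1.0)
    scaled = (matrix - col_min) / safe_span
    scaled.loc[:, constant] = 0.0
    return PhenotypeMatrix(data=scaled, column_min=col_min, column_max=col_max)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame       # rows x components
    loadings: pd.DataFrame     # columns x components
    explained_proportion: np.ndarray  # over ALL components (sums to 1)
    n_components: int


def run_pca(pm: PhenotypeMatrix, n_components: int = DEFAULT_PCA_COMPONENTS) -> PCAResult:
    """Covariance PCA of the column-centred scaled matrix.

    The data are already range-equalized by min-max scaling, so the
    covariance (not correlation) matrix is decomposed. Component signs are
    fixed so the largest-magnitude loading of each component is positive.
    """
    X = pm.data.to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    total_var = np.sum(Xc**2)
    if total_var == 0:
        raise ValidationError("zero total variance; PCA degenerate")
    n_components = min(n_components, p, n)

    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    explained = s**2 / np.sum(s**2)

    # deterministic sign: largest |loading| per component made positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        (u[:, :n_components] * s[:n_components]), index=pm.data.index, columns=comp_names
    )
    loadings = pd.DataFrame(
        vt[:n_components].T, index=pm.data.columns, columns=comp_names
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_proportion=explained,
        n_components=n_components,
    )


@dataclass(frozen=True)
class ClusterResult:
    merge_tree: np.ndarray  # scipy linkage matrix, n-1 rows
    labels: np.ndarray      # flat labels (1..k) at the requested cut
    k: int
    linkage_method: str = "average"
    metric: str = "euclidean"
    ids: tuple[str, ...] = ()

    def to_newick(self) -> str:
        """Dendrogram serialized as a Newick string with merge heights."""
        tree = to_tree(self.merge_tree)
        names = self.ids or tuple(str(i) for i in range(len(self.labels)))

        def render(node) -> str:
            if node.is_leaf():
                return names[node.id]
            l, r = node.get_left(), node.get_right()
            dl = node.dist - l.dist
            dr = node.dist - r.dist
            return f"({render(l)}:{dl:.6g},{render(r)}:{dr:.6g})"

        return render(tree) + ";"


def run_hclust(pm: PhenotypeMatrix, k: int) -> ClusterResult:
    """Unweighted average-linkage (UPGMA) clustering on Euclidean distances."""
    X = pm.data.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise ValidationError("clustering needs >= 2 rows")
    if k > n:
        raise ValidationError(f"cannot cut {n} items into {k} clusters")
    Z = linkage(X, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        merge_tree=Z,
        labels=labels,
        k=k,
        ids=tuple(str(i) for i in pm.data.index),
    )


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, equal_var: bool = False) -> GroupComparison:
    """Two-sided unpaired t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return GroupComparison(0.0, 1.0, "ns", a.size, b.size)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(float(t), float(p), significance_stars(float(p)), a.size, b.size)


def bioenergetic_map(records: pd.DataFrame, group_cols=("group", "size_class")) -> pd.DataFrame:
    """Group-level mean +/- SD OCR/ECAR operating points, basal and stressed.

    ``records`` must carry per-record ``last_basal_ocr``, ``last_basal_ecar``,
    ``stressed_ocr`` and ``stressed_ecar`` columns (normalized upstream).
    Empty groups are simply absent from the output.
    """
    needed = {"last_basal_ocr", "last_basal_ecar", "stressed_ocr", "stressed_ecar"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns {sorted(missing)}")
    group_cols = [c for c in group_cols if c in records.columns]
    if not group_cols:
        raise ValidationError("no grouping columns present")

    rows = []
    for key, sub in records.groupby(list(group_cols), sort=True, dropna=False):
        if len(sub) == 0:
            continue
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_cols, key))
        row["n"] = len(sub)
        for col in sorted(needed):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def cv_summary(records: pd.DataFrame, value_cols, group_cols=("group",)) -> pd.DataFrame:
    """Per-group mean, SD and CV% for the requested value columns."""
    group_cols = [c for c in group_cols if c in records.columns]
    rows = []
    for key, sub in records.groupby(list(group_cols), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        for col in value_cols:
            vals = sub[col].dropna()
            if len(vals) < 2:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            row = dict(zip(group_cols, key))
            row.update(
                parameter=col, n=len(vals), mean=mean, sd=sd,
                cv_pct=float("nan") if mean == 0 else 100.0 * sd / mean,
            )
            rows.append(row)
    return pd.DataFrame(rows)
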