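"""Filtered rank-correlation screens, Bonferroni thresholds, binary-group
t-tests, generation trends, and PCA + k-means embedding.

The Spearman coefficient is computed from midranks (tie-corrected) as the
Pearson correlation of the rank vectors.  Its p-value uses the exact
permutation distribution for n <= 9 and the t approximation
``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2 degrees of freedom above
that, so reported numbers are reproducible independent of any library
default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .lineage import LineageForest
from .measure import FeatureTable

EXACT_PERMUTATION_MAX_N = 9


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation and two-sided p-value.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs are required.  Returns (nan, nan) when either variable is
    constant after filtering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        p = _t_approximation_p(r, n)
    return r, p


def _t_approximation_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """P(|rho| >= |rho_obs|) over all permutations of one rank vector."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    ry_c = perms - perms.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = math.sqrt(float(rx_c @ rx_c)) * np.sqrt((ry_c * ry_c).sum(axis=1))
    rho = num / den
    return float(np.mean(np.abs(rho) >= abs(r_obs) - 1e-12))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


@dataclass
class CorrelationReport:
    """All pairwise rank correlations of a feature table.

    ``pairs`` has one row per property pair with r_s, p, the number of
    complete valid observations used, and a highlight class: 'pass_both'
    (p below the Bonferroni threshold, and |r_s| above the critical value
    when one is supplied), 'p_only' (p < alpha but not pass_both), or
    'none'.
    """

    pairs: pd.DataFrame
    alpha: float
    m: int
    bonferroni_p: float
    r_critical: float | None = None

    def matrix(self, value: str = "r_s") -> pd.DataFrame:
        """Symmetric property x property matrix of r_s (or p / n_used)."""
        props = sorted(
            set(self.pairs["property_a"]) | set(self.pairs["property_b"])
        )
        mat = pd.DataFrame(np.nan, index=props, columns=props)
        for _, row in self.pairs.iterrows():
            mat.loc[row["property_a"], row["property_b"]] = row[value]
            mat.loc[row["property_b"], row["property_a"]] = row[value]
        if value == "r_s":
            np.fill_diagonal(mat.values, 1.0)
        return mat


def correlation_matrix(
    table: FeatureTable,
    properties: Sequence[str] | None = None,
    alpha: float = 0.05,
    r_critical: float | None = None,
) -> CorrelationReport:
    """Rank-correlation screen over all property pairs with validity filters.

    For every pair, rows are kept only where both properties are valid under
    the table's per-column masks (e.g. cells without a documented lifetime
    are dropped from every lifetime pairing).  The Bonferroni threshold is
    alpha divided by the number of pairs evaluated.
    """
    if properties is None:
        properties = [
            c
            for c in table.data.columns
            if pd.api.types.is_numeric_dtype(table.data[c])
        ]
    pairs = list(itertools.combinations(properties, 2))
    m = len(pairs)
    bonf = bonferroni_threshold(alpha, m)
    rows = []
    for a, b in pairs:
        keep = (
            table.mask[a]
            & table.mask[b]
            & table.data[a].notna()
            & table.data[b].notna()
        )
        n_used = int(keep.sum())
        if n_used >= 3:
            r, p = spearman(table.data.loc[keep, a], table.data.loc[keep, b])
        else:
            r, p = np.nan, np.nan
        if np.isfinite(p) and p < bonf and (
            r_critical is None or abs(r) >= r_critical
        ):
            highlight = "pass_both"
        elif np.isfinite(p) and p < alpha:
            highlight = "p_only"
        else:
            highlight = "none"
        rows.append(
            {
                "property_a": a,
                "property_b": b,
                "r_s": r,
                "p_value": p,
                "n_used": n_used,
                "highlight": highlight,
            }
        )
    return CorrelationReport(
        pairs=pd.DataFrame(rows), alpha=alpha, m=m, bonferroni_p=bonf,
        r_critical=r_critical,
    )


def binary_ttests(
    table: FeatureTable,
    grouping: pd.Series,
    properties: Sequence[str] | None = None,
    filters: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch (unequal-variance) t-tests of every property across a binary label.

    ``grouping`` is a boolean series over cells.  ``filters`` maps each
    property to a filter id; the per-property significance threshold is
    alpha divided by the number of properties sharing that filter (all
    properties form one filter when omitted).  Rows invalid under the
    table's mask are excluded per property.
    """
    if properties is None:
        properties = [
            c
            for c in table.data.columns
            if pd.api.types.is_numeric_dtype(table.data[c])
        ]
    filters = dict(filters or {p: "all" for p in properties})
    filter_sizes = pd.Series(list(filters.values())).value_counts()
    grouping = grouping.reindex(table.data.index)
    rows = []
    for prop in properties:
        keep = table.mask[prop] & table.data[prop].notna() & grouping.notna()
        vals = table.data.loc[keep, prop]
        grp = grouping[keep].astype(bool)
        a, b = vals[grp], vals[~grp]
        if len(a) >= 2 and len(b) >= 2:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        else:
            t, p = np.nan, np.nan
        fid = filters[prop]
        threshold = bonferroni_threshold(alpha, int(filter_sizes[fid]))
        rows.append(
            {
                "property": prop,
                "filter_id": fid,
                "n_group_true": len(a),
                "n_group_false": len(b),
                "mean_true": a.mean() if len(a) else np.nan,
                "mean_false": b.mean() if len(b) else np.nan,
                "t": float(t),
                "p_value": float(p),
                "threshold": threshold,
                "significant": bool(np.isfinite(p) and p < threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrendResult:
    founder_id: str
    r_s: float
    p_value: float
    n_cells: int
    degenerate: bool = False


def generation_area_trend(
    table: FeatureTable, area_column: str = "avg_area_first_0.83d_um2"
) -> list[TrendResult]:
    """Per-progeny Spearman correlation of generation vs early-lifetime area.

    The early-lifetime average (first 0.83 d of each cell's record) keeps
    large, long-lived low-generation cells from dominating the trend.
    Progenies with fewer than three cells, or with no variation in either
    variable, are reported as degenerate with r_s = 0 and p = 1.
    """
    out = []
    for founder, grp in table.data.groupby("colony_id", sort=True):
        keep = table.mask.loc[grp.index, area_column] & grp[area_column].notna()
        g = grp.loc[keep]
        n = len(g)
        if n < 3 or g["generation"].nunique() < 2 or g[area_column].nunique() < 2:
            out.append(
                TrendResult(founder_id=str(founder), r_s=0.0, p_value=1.0,
                            n_cells=n, degenerate=True)
            )
            continue
        r, p = spearman(g["generation"], g[area_column])
        out.append(
            TrendResult(founder_id=str(founder), r_s=r, p_value=p, n_cells=n)
        )
    return out


def generation_dispersion(
    f: LineageForest, frame: int, membership: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Per-colony sample SD of the generations of cells living at ``frame``.

    ``membership`` maps founder ids to colony ids (default: each founder is
    its own colony).  Colonies with a single living cell report 0.0; empty
    colonies are omitted.
    """
    gens: dict[str, list[int]] = {}
    for cid in f.alive_at(frame):
        root = f.root_of(cid)
        colony = membership[root] if membership else root
        gens.setdefault(colony, []).append(f.records[cid].generation)
    return {
        colony: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        for colony, v in sorted(gens.items())
    }


def auto_k(n: int) -> int:
    """Default k-means cluster count: round(sqrt(n / 2))."""
    return max(1, round(math.sqrt(n / 2.0)))


@dataclass
class EmbeddingResult:
    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # properties x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    cluster_labels: pd.Series
    k: int


def pca_embed(
    table: FeatureTable | pd.DataFrame,
    columns: Sequence[str] | None = None,
    k: int | None = None,
    random_state: int = 0,
) -> EmbeddingResult:
    """PCA of the z-scored feature table, with k-means cluster labels.

    Rows with any masked or missing value among the selected columns are
    dropped (documented subset analysis).  Columns are z-scored with the
    sample standard deviation, so the explained variances of all components
    sum to the number of retained columns.  ``k`` defaults to
    round(sqrt(N / 2)) for N retained rows; k-means runs 10 restarts from a
    fixed seed and keeps the best inertia.
    """
    if isinstance(table, FeatureTable):
        data, mask = table.data, table.mask
    else:
        data, mask = table, pd.DataFrame(True, index=table.index,
                                         columns=table.columns)
    if columns is None:
        columns = [
            c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])
        ]
    sub = data[list(columns)]
    valid = mask[list(columns)].all(axis=1) & sub.notna().all(axis=1)
    sub = sub.loc[valid]
    # constant columns carry no information and break the z-score
    keep_cols = [c for c in columns if sub[c].nunique() > 1]
    sub = sub[keep_cols]
    if len(sub) < 3 or not keep_cols:
        raise ValueError("not enough complete rows/varying columns for PCA")
    z = (sub - sub.mean()) / sub.std(ddof=1)
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    n_comp = scores.shape[1]
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    if k is None:
        k = auto_k(len(sub))
    k = min(k, len(sub))
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(scores)
    return EmbeddingResult(
        scores=pd.DataFrame(scores, index=sub.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=keep_cols, columns=comp_names
        ),
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        cluster_labels=pd.Series(labels, index=sub.index, name="cluster"),
        k=k,
    )
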