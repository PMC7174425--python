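"""Association analyses among pangenome features, habitats and function.

Covers the descriptive layer of the analysis: the Spearman correlation
matrix over features (with point-biserial correlations against binary
habitat indicators), BH adjustment over unique pairs, hierarchical
clustering of features on 1 - |rho|, correlations of COG-category relative
frequencies with species ubiquity, and two-group Kruskal-Wallis habitat
contrasts of individual features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance
import scipy.stats

from .habitat_ubiquity import bh_adjust


@dataclass
class AssociationMatrix:
    """Symmetric correlation matrix with p and BH-adjusted q matrices.

    ``method`` marks each pair as ``spearman`` or ``point_biserial``; q is
    computed once over the unique (upper-triangle) pairs.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    method: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.rho.index)


def spearman_matrix(
    features: pd.DataFrame,
    binary: pd.DataFrame | None = None,
    min_pairs: int = 5,
    pool_bh: bool = True,
) -> AssociationMatrix:
    """Pairwise-complete Spearman matrix, optionally with binary columns.

    Continuous feature pairs use Spearman's rank correlation with mid-rank
    ties; pairs of a binary indicator with a continuous feature use the
    point-biserial correlation. Pairs with fewer than ``min_pairs`` complete
    observations, constant columns, or binary-binary pairs are left NaN with
    a warning. BH runs over the upper triangle — over all tested cells when
    ``pool_bh`` (default), else separately per method family.
    """
    cont = list(features.columns)
    bin_cols = [] if binary is None else list(binary.columns)
    all_cols = cont + bin_cols
    data = features.copy()
    if binary is not None:
        data = pd.concat([data, binary.astype(float)], axis=1)
    k = len(all_cols)
    rho = pd.DataFrame(np.full((k, k), np.nan), index=all_cols, columns=all_cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=all_cols, columns=all_cols)
    method = pd.DataFrame("", index=all_cols, columns=all_cols)
    is_binary = {c: (c in bin_cols) for c in all_cols}
    import logging

    log = logging.getLogger(__name__)
    entries = []  # (i, j, p) of testable pairs, per method
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = all_cols[i], all_cols[j]
            if is_binary[ci] and is_binary[cj]:
                continue
            pair = data[[ci, cj]].dropna()
            if len(pair) < min_pairs:
                log.warning("pair (%s, %s): only %d complete rows", ci, cj, len(pair))
                continue
            x, y = pair[ci].to_numpy(), pair[cj].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                log.warning("pair (%s, %s): constant column, correlation undefined", ci, cj)
                continue
            if is_binary[ci] or is_binary[cj]:
                b, v = (x, y) if is_binary[ci] else (y, x)
                r, pv = point_biserial(b, v)
                m = "point_biserial"
            else:
                r, pv = scipy.stats.spearmanr(x, y)
                m = "spearman"
            rho.iloc[i, j] = rho.iloc[j, i] = r
            p.iloc[i, j] = p.iloc[j, i] = pv
            method.iloc[i, j] = method.iloc[j, i] = m
            entries.append((i, j, pv, m))
    q = pd.DataFrame(np.full((k, k), np.nan), index=all_cols, columns=all_cols)
    if entries:
        if pool_bh:
            groups = [entries]
        else:
            fams = sorted({m for *_, m in entries})
            groups = [[e for e in entries if e[3] == f] for f in fams]
        for group in groups:
            qs = bh_adjust([pv for _, _, pv, _ in group])
            for (i, j, _, _), qv in zip(group, qs):
                q.iloc[i, j] = q.iloc[j, i] = qv
    for i in range(k):
        rho.iloc[i, i] = 1.0
    return AssociationMatrix(rho=rho, p=p, q=q, method=method)


def point_biserial(binary, y) -> tuple[float, float]:
    """Point-biserial correlation of a 0/1 indicator with a numeric feature.

    Identical to the Pearson correlation on the encoded data; p from the
    t-distribution with n-2 degrees of freedom.
    """
    b = np.asarray(binary, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.unique(b)
    if not np.isin(groups, (0.0, 1.0)).all():
        raise ValueError("binary vector must contain only 0/1")
    if len(groups) < 2:
        raise ValueError("both binary classes must be present")
    res = scipy.stats.pointbiserialr(b, y)
    return float(res.correlation), float(res.pvalue)


def cluster_features(
    a: AssociationMatrix | pd.DataFrame,
    linkage: str = "average",
    n_groups: int = 2,
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchical clustering of features on distance 1 - |rho|.

    Returns the scipy linkage matrix and a flat ``n_groups``-cut label
    Series (default two groups: the size-like vs diversity-like split).
    Labels are processed in sorted order so the result does not depend on
    input column order; NaN correlations are rejected.
    """
    rho = a.rho if isinstance(a, AssociationMatrix) else a
    order = sorted(rho.index)
    rho = rho.loc[order, order]
    if rho.isna().to_numpy().any():
        raise ValueError("rho matrix has NaN entries; impute or subset before clustering")
    D = 1.0 - rho.abs().to_numpy()
    np.fill_diagonal(D, 0.0)
    condensed = scipy.spatial.distance.squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    flat = sch.fcluster(Z, t=n_groups, criterion="maxclust")
    return Z, pd.Series(flat, index=order, name="group")


def cog_ubiquity_correlation(
    freqs: pd.DataFrame, ubiquity: pd.Series, tol: float = 1e-6
) -> pd.DataFrame:
    """Spearman correlation of ubiquity with COG-category relative frequencies.

    ``freqs`` holds per-species relative frequencies of functional categories
    within one pangenome partition (core or accessory); rows must sum to 1.
    Returns a frame with one row per category (rho, p, q); categories absent
    everywhere give NaN and are excluded from the BH family.
    """
    sums = freqs.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        bad = list(sums.index[~np.isclose(sums, 1.0, atol=tol)])[:5]
        raise ValueError(f"per-species category frequencies must sum to 1; offending rows: {bad}")
    u = ubiquity.reindex(freqs.index).astype(float)
    rows = []
    for cat in freqs.columns:
        f = freqs[cat]
        if (f == 0).all() or f.std() == 0:
            rows.append((cat, np.nan, np.nan))
            continue
        rho, p = scipy.stats.spearmanr(u, f)
        rows.append((cat, rho, p))
    out = pd.DataFrame(rows, columns=["category", "rho", "p"]).set_index("category")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def habitat_contrast(feature, flag) -> tuple[float, float]:
    """Two-group Kruskal-Wallis contrast of a feature between habitat classes.

    Returns the tie-corrected chi-squared statistic (1 df) and p-value.
    """
    f = np.asarray(feature, dtype=float)
    g = np.asarray(flag)
    classes = np.unique(g)
    if len(classes) != 2:
        raise ValueError("flag must define exactly two groups")
    a, b = f[g == classes[0]], f[g == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two observations")
    res = scipy.stats.kruskal(a, b)
    return float(res.statistic), float(res.pvalue)
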