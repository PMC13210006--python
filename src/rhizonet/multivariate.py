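"""Diversity, ordination, and permutation / partitioning statistics.

Covers the community-level statistics a tillage x straw factorial study
leans on: Shannon and Chao1 alpha diversity, Bray-Curtis dissimilarity,
principal coordinate analysis, two-factor PERMANOVA with sequential
(Type-I) sums of squares, the Mantel test, and variation partitioning
(VPA) of a multivariate response among explanatory variable sets via
redundancy-analysis R^2 with the Ezekiel adjustment.

PERMANOVA follows the McArdle-Anderson formulation: the Gower-centred
matrix of squared distances is partitioned by projection (hat) matrices of
a sequential design, pseudo-F per term, and free row/column permutation of
the distance matrix for p-values (add-one formula).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha

from .core_io import FeatureTable, SampleMetadata

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "mantel",
    "variation_partition",
    "PermanovaResult",
    "VpaResult",
]


# ---------------------------------------------------------------------------
# diversity


def alpha_diversity(t: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon (natural log) and Chao1.

    Chao1 = S_obs + F1(F1-1)/(2(F2+1)) needs integer counts (singletons and
    doubletons); in relative mode Chao1 is reported as NaN.
    """
    rows = {}
    for sid in t.sample_ids:
        vec = t.data.loc[sid].to_numpy(dtype=float)
        if vec.sum() <= 0:
            raise ValueError(f"empty sample {sid!r}")
        p = vec / vec.sum()
        nz = p[p > 0]
        shannon = float(-(nz * np.log(nz)).sum())
        if t.mode == "counts":
            chao1 = float(skbio_alpha.chao1(vec.astype(int), bias_corrected=True))
        else:
            chao1 = np.nan
        rows[sid] = {"shannon": shannon, "chao1": chao1}
    return pd.DataFrame(rows).T


def bray_curtis(t: FeatureTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix: d = sum|u-v| / sum(u+v)."""
    vals = t.data.to_numpy(dtype=float)
    zero = vals.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(vals, metric="braycurtis"))
    return pd.DataFrame(d, index=t.sample_ids, columns=t.sample_ids)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    return m


# ---------------------------------------------------------------------------
# ordination


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(d: pd.DataFrame, eps: float = 1e-10):
    """Classical metric scaling of a distance matrix.

    Returns (coordinates, eigenvalues, proportion_explained). All
    eigenvalues of the Gower-centred matrix are reported (negative ones
    included); coordinate axes are restricted to positive eigenvalues and
    scaled by sqrt(eigenvalue).
    """
    m = _check_distance(d)
    g = _gower_center(m ** 2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > eps * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    coords_df = pd.DataFrame(coords, index=d.index, columns=axes)
    return coords_df, pd.Series(eigvals, name="eigenvalue"), pd.Series(prop, index=axes)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms + Residual + Total; df, SS, R2, F, p
    n_perm: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_perm={self.n_perm})\n{self.table}"


def _dummy(series: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(series))
    return np.column_stack([(series == lv).to_numpy(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(series), 0))


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        parts = term.split(":")
        mats = [_dummy(meta[p]) for p in parts]
        cols = []
        for i in range(mats[0].shape[1]):
            for j in range(mats[1].shape[1]):
                cols.append(mats[0][:, i] * mats[1][:, j])
        return np.column_stack(cols) if cols else np.empty((len(meta), 0))
    return _dummy(meta[term])


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T


def permanova(d: pd.DataFrame, meta, terms=("tillage", "straw", "tillage:straw"),
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Sequential (Type-I) multi-factor PERMANOVA on a distance matrix.

    *meta* is a :class:`SampleMetadata` or DataFrame aligned to ``d``;
    *terms* are metadata columns, with ``A:B`` denoting an interaction.
    p-values use free row permutation and the add-one formula, so the
    smallest attainable p is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mtab = meta.table if isinstance(meta, SampleMetadata) else meta
    mtab = mtab.loc[d.index]
    m = _check_distance(d)
    n = m.shape[0]
    g = _gower_center(m ** 2)
    ss_total = float(np.trace(g))

    intercept = np.ones((n, 1))
    hats, dfs = [], []
    x = intercept
    for term in terms:
        x = np.hstack([x, _design_columns(mtab, term)])
        hats.append(_hat(x))
        dfs.append(int(round(np.trace(hats[-1]))) - 1
                   - (int(round(np.trace(hats[-2]))) - 1 if len(hats) > 1 else 0))
    h_full = hats[-1]
    df_res = n - int(round(np.trace(h_full)))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gmat):
        prev = _hat(intercept)
        ss, fs = [], []
        ss_res = float(np.trace((np.eye(n) - h_full) @ gmat))
        for hk, dfk in zip(hats, dfs):
            ssk = float(np.trace((hk - prev) @ gmat))
            ss.append(ssk)
            fs.append((ssk / dfk) / (ss_res / df_res) if dfk > 0 else np.nan)
            prev = hk
        return np.array(ss), np.array(fs), ss_res

    ss_obs, f_obs, ss_res = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_perm, _ = term_stats(gp)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for term, dfk, ssk, fk, pk in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append({"term": term, "df": dfk, "SS": ssk, "R2": ssk / ss_total,
                     "F": fk, "p": pk})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


# ---------------------------------------------------------------------------
# Mantel


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 999,
           seed: int = 0) -> dict:
    """Mantel test: Pearson correlation of upper-triangle distances.

    The permutation p shuffles rows/columns of ``d2`` simultaneously
    (two-sided on |r|, add-one formula).
    """
    if list(d1.index) != list(d2.index):
        d2 = d2.loc[d1.index, d1.index]
    m1 = _check_distance(d1)
    m2 = _check_distance(d2)
    iu = np.triu_indices(m1.shape[0], k=1)
    v1 = m1[iu]
    r_obs = float(np.corrcoef(v1, m2[iu])[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(m1.shape[0])
        r_p = np.corrcoef(v1, m2[np.ix_(perm, perm)][iu])[0, 1]
        if abs(r_p) >= abs(r_obs) - 1e-15:
            exceed += 1
    return {"r": r_obs, "p": (1.0 + exceed) / (1.0 + n_perm), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# variation partitioning


@dataclass
class VpaResult:
    """Adjusted-R^2 fractions of a 2- or 3-set variation partitioning."""

    fractions: dict  # e.g. {"X1": unique, "X2": unique, "X1&X2": shared, ...}
    residual: float
    total_adj_r2: float
    negative_fractions: list

    def as_series(self) -> pd.Series:
        s = dict(self.fractions)
        s["residual"] = self.residual
        return pd.Series(s)


def _rda_r2(y: np.ndarray, x: np.ndarray) -> tuple:
    """Redundancy-analysis R^2 of multivariate y on x (centred), and rank."""
    n = y.shape[0]
    xc = np.hstack([np.ones((n, 1)), x])
    q, r = np.linalg.qr(xc)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    h = q[:, :rank] @ q[:, :rank].T
    yc = y - y.mean(axis=0)
    total = float(np.sum(yc ** 2))
    fitted = float(np.sum((h @ yc) ** 2))
    return (fitted / total if total > 0 else 0.0), rank - 1


def _adj(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if p == 0:
        return 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variation_partition(y: pd.DataFrame, x_sets: dict) -> VpaResult:
    """Partition the RDA-explained variance of *y* among 2-3 predictor sets.

    Unique and shared fractions come from inclusion-exclusion over
    adjusted R^2 of every subset union; negative adjusted fractions are
    reported as computed (flagged, not clipped), as is conventional for
    variation partitioning.
    """
    names = list(x_sets)
    if not 1 <= len(names) <= 3:
        raise ValueError("variation_partition supports 1-3 explanatory sets")
    yv = y.to_numpy(dtype=float)
    n = yv.shape[0]
    mats = {}
    for name in names:
        x = x_sets[name].loc[y.index].to_numpy(dtype=float)
        # drop collinear columns within the set (rank-revealing QR)
        q, r = np.linalg.qr(np.hstack([np.ones((n, 1)), x]))
        diag = np.abs(np.diag(r))
        keep = [j - 1 for j in range(1, len(diag)) if diag[j] > 1e-10 * max(1.0, diag.max())]
        if len(keep) < x.shape[1]:
            warnings.warn(f"dropping collinear predictors in set {name!r}")
            x = x[:, keep]
        mats[name] = x
    total_p = sum(m.shape[1] for m in mats.values())
    if n <= total_p + 1:
        raise ValueError("need n > total predictors + 1")

    from itertools import combinations

    adj_r2 = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            x = np.hstack([mats[c] for c in combo])
            r2, rank = _rda_r2(yv, x)
            adj_r2[frozenset(combo)] = _adj(r2, n, rank)

    full = frozenset(names)
    total = adj_r2[full]
    fractions: dict = {}
    if len(names) == 1:
        fractions[names[0]] = total
    elif len(names) == 2:
        a, b = names
        fractions[a] = total - adj_r2[frozenset([b])]
        fractions[b] = total - adj_r2[frozenset([a])]
        fractions[f"{a}&{b}"] = adj_r2[frozenset([a])] + adj_r2[frozenset([b])] - total
    else:
        a, b, c = names
        ra, rb, rc = (adj_r2[frozenset([x])] for x in names)
        rab = adj_r2[frozenset([a, b])]
        rac = adj_r2[frozenset([a, c])]
        rbc = adj_r2[frozenset([b, c])]
        fractions[a] = total - rbc
        fractions[b] = total - rac
        fractions[c] = total - rab
        # seven Venn fractions; g is the triple intersection
        g = ra + rb + rc - rab - rac - rbc + total
        fractions[f"{a}&{b}"] = ra + rb - rab - g
        fractions[f"{a}&{c}"] = ra + rc - rac - g
        fractions[f"{b}&{c}"] = rb + rc - rbc - g
        fractions[f"{a}&{b}&{c}"] = g
    negative = [k for k, v in fractions.items() if v < -1e-12]
    return VpaResult(fractions=fractions, residual=1.0 - total,
                     total_adj_r2=total, negative_fractions=negative)
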