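"""Core nutrient-cycle-driving taxa via random-forest permutation importance.

For each module, a regression forest predicts a nutrient from the module's
member-taxon relative abundances. Importance is %IncMSE: the percent
increase in out-of-bag mean squared error when a taxon's values are
permuted. Significance comes from a response-permutation null — the whole
importance computation is repeated on permuted nutrient vectors, and a
taxon is "core" if its observed importance beats the null for at least one
nutrient (add-one permutation p-value below alpha).

The forest is a bagged ensemble of CART regression trees
(sklearn ``DecisionTreeRegressor``) with explicit bootstrap bookkeeping so
the out-of-bag sets, and therefore the importances, are exactly
reproducible from the seed. Defaults follow common regression-forest
practice: 500 trees, mtry = ceil(p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .core_io import FeatureTable, NutrientTable
from .community import ModulePartition

__all__ = [
    "ForestConfig",
    "ImportanceRecord",
    "CoreTaxaSet",
    "importance_scores",
    "select_core_taxa",
]


@dataclass
class ForestConfig:
    n_trees: int = 500
    mtry: int | None = None  # default ceil(p / 3)
    min_samples_leaf: int = 5
    seed: int = 0


@dataclass
class ImportanceRecord:
    taxon: str
    nutrient: str
    importance: float  # %IncMSE
    p_value: float | None
    n_trees: int
    seed: int


@dataclass
class CoreTaxaSet:
    """module id -> core taxa, with the supporting importance records."""

    core: dict  # module id -> sorted list of taxa
    records: list  # all ImportanceRecord entries

    def all_taxa(self) -> set:
        return {t for taxa in self.core.values() for t in taxa}


def _oob_incmse(X: np.ndarray, y: np.ndarray, cfg: ForestConfig,
                rng: np.random.Generator) -> np.ndarray:
    """%IncMSE per column from a bagged CART ensemble.

    OOB predictions are aggregated forest-level (mean over trees for which
    the sample was out of bag), once for the intact matrix and once per
    permuted column; %IncMSE = 100 * (MSE_perm - MSE_oob) / MSE_oob.
    """
    n, p = X.shape
    mtry = cfg.mtry if cfg.mtry is not None else max(1, math.ceil(p / 3))
    # float32 C-order lets fit/predict skip input validation (check_input)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    base_pred = np.zeros(n)
    base_cnt = np.zeros(n)
    perm_pred = np.zeros((p, n))
    perm_cnt = np.zeros((p, n))
    for _ in range(cfg.n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X32[boot], y[boot], check_input=False)
        oob_X = X32[oob]
        # one batched predict for OOB rows plus all p permuted-column variants
        stack = np.tile(oob_X, (p + 1, 1, 1))
        for j in range(p):
            stack[j + 1, :, j] = oob_X[rng.permutation(oob.size), j]
        preds = tree.predict(
            np.ascontiguousarray(stack.reshape((p + 1) * oob.size, p)),
            check_input=False,
        ).reshape(p + 1, oob.size)
        base_pred[oob] += preds[0]
        base_cnt[oob] += 1
        perm_pred[:, oob] += preds[1:]
        perm_cnt[:, oob] += 1
    seen = base_cnt > 0
    mse0 = float(np.mean((y[seen] - base_pred[seen] / base_cnt[seen]) ** 2))
    out = np.zeros(p)
    for j in range(p):
        sj = perm_cnt[j] > 0
        msej = float(np.mean((y[sj] - perm_pred[j, sj] / perm_cnt[j, sj]) ** 2))
        out[j] = 100.0 * (msej - mse0) / mse0 if mse0 > 0 else 0.0
    return out


def importance_scores(t: FeatureTable, y: pd.Series,
                      cfg: ForestConfig | None = None,
                      nutrient: str = "") -> list:
    """%IncMSE for each taxon column of *t* predicting nutrient *y*.

    Deterministic given ``cfg.seed``. Raises on a constant response.
    """
    cfg = cfg or ForestConfig()
    X = t.data.loc[y.index].to_numpy(dtype=float)
    yy = y.to_numpy(dtype=float)
    if X.shape[0] < 6:
        raise ValueError("need at least 6 samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictor taxa")
    if np.var(yy) == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(cfg.seed)
    imp = _oob_incmse(X, yy, cfg, rng)
    return [
        ImportanceRecord(taxon, nutrient, float(v), None, cfg.n_trees, cfg.seed)
        for taxon, v in zip(t.taxon_ids, imp)
    ]


def select_core_taxa(t: FeatureTable, partition: ModulePartition,
                     nutrients: NutrientTable, alpha: float = 0.05,
                     n_perm: int = 100, cfg: ForestConfig | None = None,
                     modules=None) -> CoreTaxaSet:
    """Screen every module x nutrient with a response-permutation null.

    For each taxon, p = (1 + #{permuted-response importances >= observed})
    / (1 + n_perm); a taxon is core if p < alpha for at least one nutrient
    within its module. Permuting the response preserves the predictor
    correlation structure, so the null is calibrated per module.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives too coarse a p-value resolution")
    cfg = cfg or ForestConfig()
    module_ids = list(modules) if modules is not None else list(partition.members)
    core: dict = {}
    records: list = []
    for k, mid in enumerate(module_ids):
        taxa = [tx for tx in partition.members[mid] if tx in t.data.columns]
        if len(taxa) < 2:
            core[mid] = []
            continue
        sub = FeatureTable(t.data[taxa], mode=t.mode)
        X = sub.data.to_numpy(dtype=float)
        hits: set = set()
        for v, var in enumerate(nutrients.variables):
            seed = cfg.seed + 1000 * k + v
            run_cfg = ForestConfig(cfg.n_trees, cfg.mtry, cfg.min_samples_leaf, seed)
            y = nutrients.data[var].loc[sub.data.index]
            yy = y.to_numpy(dtype=float)
            if np.var(yy) == 0:
                continue
            rng = np.random.default_rng(seed)
            obs = _oob_incmse(X, yy, run_cfg, rng)
            exceed = np.zeros(len(taxa))
            for _ in range(n_perm):
                y_perm = rng.permutation(yy)
                null_imp = _oob_incmse(X, y_perm, run_cfg, rng)
                exceed += null_imp >= obs
            pvals = (1.0 + exceed) / (1.0 + n_perm)
            for taxon, imp, p in zip(taxa, obs, pvals):
                records.append(ImportanceRecord(taxon, var, float(imp),
                                                float(p), cfg.n_trees, seed))
                if p < alpha:
                    hits.add(taxon)
        core[mid] = sorted(hits)
    return CoreTaxaSet(core=core, records=records)


def core_taxa_frame(cs: CoreTaxaSet) -> pd.DataFrame:
    """Tidy export: module, taxon, best nutrient, importance, p."""
    by_taxon: dict = {}
    for rec in cs.records:
        cur = by_taxon.get(rec.taxon)
        if cur is None or (rec.p_value is not None and rec.p_value < cur.p_value):
            by_taxon[rec.taxon] = rec
    rows = []
    for mid, taxa in cs.core.items():
        for taxon in taxa:
            rec = by_taxon[taxon]
            rows.append({"module": mid, "taxon": taxon, "best_nutrient": rec.nutrient,
                         "importance": rec.importance, "p_value": rec.p_value})
    return pd.DataFrame(rows, columns=["module", "taxon", "best_nutrient",
                                       "importance", "p_value"])
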