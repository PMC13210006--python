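"""Partial least squares path modeling (PLS-PM) with bootstrap validation.

Latent blocks (e.g. tillage, straw amount, bacterial community, fungal
community, C/N/P nutrient pools) are measured reflectively (Mode A) by
their manifest variables and connected by an acyclic inner path model.
Estimation is the Lohmoller alternating algorithm with the path weighting
scheme: standardize manifests, initialise outer weights equally, then
iterate inner estimation (regression weights toward predecessors,
correlations toward successors) and Mode A outer estimation until the
outer weights stabilise. Path coefficients are OLS regressions of each
endogenous latent on its predecessors; the global goodness of fit is
GoF = sqrt(mean communality x mean R^2).

Bootstrap resampling of samples (refit per draw, percentile intervals)
quantifies path-coefficient stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import SampleMetadata

__all__ = [
    "PathModelSpec",
    "PLSPMResult",
    "encode_design",
    "fit",
    "bootstrap",
    "goodness_of_fit",
]

STRAW_CODE = {"NS": 0.0, "HS": 0.5, "TS": 1.0}
TILLAGE_CODE = {"NT": 0.0, "MT": 1.0}


def encode_design(meta: SampleMetadata) -> pd.DataFrame:
    """Numeric design columns: tillage NT=0 / MT=1; straw NS=0 / HS=0.5 / TS=1."""
    t = meta.table
    try:
        till = t["tillage"].map(TILLAGE_CODE).astype(float)
        straw = t["straw"].map(STRAW_CODE).astype(float)
    except KeyError as exc:  # pragma: no cover
        raise ValueError(f"metadata missing design column: {exc}") from exc
    if till.isna().any() or straw.isna().any():
        raise ValueError("unknown tillage/straw level in metadata")
    return pd.DataFrame({"tillage": till, "straw": straw}, index=t.index)


@dataclass
class PathModelSpec:
    """Latent blocks and the inner (structural) path model.

    ``blocks`` maps block name -> list of manifest column names (reflective
    measurement). ``paths`` maps an endogenous block -> list of its
    predecessor blocks; the implied adjacency must be acyclic, which holds
    whenever every predecessor appears earlier in ``blocks`` order.
    """

    blocks: dict
    paths: dict
    n_boot: int = 1000
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        order = {b: i for i, b in enumerate(self.blocks)}
        for endo, preds in self.paths.items():
            if endo not in order:
                raise ValueError(f"unknown endogenous block {endo!r}")
            for p in preds:
                if p not in order:
                    raise ValueError(f"unknown predecessor block {p!r}")
                if order[p] >= order[endo]:
                    raise ValueError(
                        f"path {p} -> {endo} violates the acyclic block order"
                    )
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @property
    def endogenous(self) -> list:
        return [b for b in self.blocks if self.paths.get(b)]


@dataclass
class PLSPMResult:
    weights: dict  # block -> pd.Series outer weights
    loadings: dict  # block -> pd.Series manifest loadings
    scores: pd.DataFrame  # samples x blocks, standardized latents
    path_coefficients: pd.DataFrame  # rows (endogenous, predecessor), column "estimate"
    r_squared: dict  # endogenous block -> R^2
    gof: float
    n_iter: int
    communalities: dict = field(default_factory=dict)  # manifest -> loading^2


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant manifest variable")
    return (x - mu) / sd


def fit(spec: PathModelSpec, data: pd.DataFrame) -> PLSPMResult:
    """Fit the PLS path model on an assembled manifest table."""
    block_names = list(spec.blocks)
    n = len(data)
    largest = max(len(m) for m in spec.blocks.values())
    if n <= largest:
        raise ValueError("need more samples than the largest block's manifests")
    X = {b: _standardize(data[list(m)].to_numpy(dtype=float))
         for b, m in spec.blocks.items()}
    if any(np.isnan(X[b]).any() for b in block_names):
        raise ValueError("missing values in manifest data")

    preds = {b: list(spec.paths.get(b, [])) for b in block_names}
    succs = {b: [e for e in block_names if b in preds[e]] for b in block_names}

    def make_scores(w):
        cols = {}
        for b in block_names:
            y = X[b] @ w[b]
            sd = y.std(ddof=1)
            y = y / sd if sd > 0 else y
            # deterministic orientation: first manifest loads positively
            if np.corrcoef(y, X[b][:, 0])[0, 1] < 0:
                y = -y
                w[b] = -w[b]
            cols[b] = y
        return cols

    w = {b: np.ones(X[b].shape[1]) / np.sqrt(X[b].shape[1]) for b in block_names}
    scores = make_scores(w)
    n_iter = 0
    for n_iter in range(1, spec.max_iter + 1):
        # inner estimation, path weighting scheme
        z = {}
        for b in block_names:
            zb = np.zeros(n)
            if preds[b]:
                P = np.column_stack([scores[p] for p in preds[b]])
                beta, *_ = np.linalg.lstsq(P, scores[b], rcond=None)
                zb = zb + P @ beta
            for s in succs[b]:
                zb = zb + np.corrcoef(scores[b], scores[s])[0, 1] * scores[s]
            if not preds[b] and not succs[b]:
                zb = scores[b]
            z[b] = zb
        # outer estimation, Mode A
        w_new = {}
        for b in block_names:
            wb = X[b].T @ z[b] / n
            norm = np.linalg.norm(wb)
            w_new[b] = wb / norm if norm > 0 else w[b]
        delta = max(np.max(np.abs(np.abs(w_new[b]) - np.abs(w[b])))
                    for b in block_names)
        w = w_new
        scores = make_scores(w)
        if delta < spec.tol:
            break
    else:
        raise RuntimeError(
            f"PLS-PM did not converge in {spec.max_iter} iterations (last delta {delta:.3g})"
        )

    score_df = pd.DataFrame(scores, index=data.index)[block_names]
    loadings, weights, communal = {}, {}, {}
    for b in block_names:
        manifests = list(spec.blocks[b])
        lam = np.array([np.corrcoef(X[b][:, j], scores[b])[0, 1]
                        for j in range(len(manifests))])
        loadings[b] = pd.Series(lam, index=manifests)
        weights[b] = pd.Series(w[b], index=manifests)
        for mname, l in zip(manifests, lam):
            communal[mname] = float(l ** 2)

    path_rows = []
    r2 = {}
    for b in spec.endogenous:
        P = np.column_stack([scores[p] for p in preds[b]])
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), P]),
                                   scores[b], rcond=None)
        fitted = np.column_stack([np.ones(n), P]) @ beta
        r2[b] = float(1 - np.sum((scores[b] - fitted) ** 2)
                      / np.sum((scores[b] - scores[b].mean()) ** 2))
        for p, coef in zip(preds[b], beta[1:]):
            path_rows.append({"endogenous": b, "predecessor": p,
                              "estimate": float(coef)})
    path_df = pd.DataFrame(path_rows, columns=["endogenous", "predecessor", "estimate"])

    res = PLSPMResult(weights=weights, loadings=loadings, scores=score_df,
                      path_coefficients=path_df, r_squared=r2, gof=0.0,
                      n_iter=n_iter, communalities=communal)
    res.gof = goodness_of_fit(res)
    return res


def goodness_of_fit(res: PLSPMResult) -> float:
    """GoF = sqrt(mean communality across manifests x mean R^2)."""
    if not res.r_squared:
        return 0.0
    mean_comm = float(np.mean(list(res.communalities.values())))
    mean_r2 = float(np.mean(list(res.r_squared.values())))
    return float(np.sqrt(max(mean_comm, 0.0) * max(mean_r2, 0.0)))


def bootstrap(spec: PathModelSpec, data: pd.DataFrame,
              base: PLSPMResult | None = None) -> pd.DataFrame:
    """Percentile bootstrap of the path coefficients.

    Resamples rows with replacement ``spec.n_boot`` times and refits.
    Returns a table per path with mean, se, 2.5/97.5 percentile CI and the
    sign-stability fraction (share of draws matching the point estimate's
    sign). Draws that fail to converge are dropped; more than 10% dropped
    is an error.
    """
    base = base or fit(spec, data)
    rng = np.random.default_rng(spec.seed)
    n = len(data)
    draws = []
    failed = 0
    for _ in range(spec.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            res = fit(spec, data.iloc[idx])
        except (RuntimeError, ValueError):
            failed += 1
            continue
        draws.append(res.path_coefficients["estimate"].to_numpy())
    if failed > 0.1 * spec.n_boot:
        raise RuntimeError(f"{failed}/{spec.n_boot} bootstrap refits failed")
    arr = np.array(draws)
    out = base.path_coefficients.copy()
    out["boot_mean"] = arr.mean(axis=0)
    out["boot_se"] = arr.std(axis=0, ddof=1)
    out["ci_2.5"] = np.percentile(arr, 2.5, axis=0)
    out["ci_97.5"] = np.percentile(arr, 97.5, axis=0)
    signs = np.sign(out["estimate"].to_numpy())
    out["sign_stability"] = (np.sign(arr) == signs).mean(axis=0)
    out["n_failed"] = failed
    return out
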