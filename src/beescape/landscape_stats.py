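"""Landscape drivers of colony density and foraging distance.

Covariate extraction from polygon-overlap tables plus the statistical
battery relating per-cell habitat metrics (colNe, ln aveMeanFD) to
landscape and demographic variables: pairwise Spearman correlations with
Benjamini-Hochberg FDR control, variance-inflation screening, exhaustive
best-subset multiple linear regression ranked by adjusted R^2 and AIC,
redundancy analysis (RDA) with a permutation test, and three-set variation
partitioning of the RDA's adjusted R^2 by inclusion-exclusion.

RDA here is the classical constrained ordination: principal components of
the fitted values of a multivariate linear regression of the (standardized)
response matrix on the (standardized) predictors. Adjusted R^2 uses
Ezekiel's formula, so partition fractions can be negative and are reported
as computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RdaResult",
    "VarpartResult",
    "RegressionModel",
    "extract_covariates",
    "spearman_fdr",
    "vif_screen",
    "best_subset_regression",
    "select_parsimonious",
    "rda",
    "varpart3",
]


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------


def extract_covariates(
    overlaps: pd.DataFrame,
    attributes: pd.DataFrame | None,
    modes: dict[str, str],
    points: pd.DataFrame | None = None,
    cell_ids=None,
) -> pd.DataFrame:
    """Per-cell covariates from polygon-overlap fractions.

    ``overlaps`` has columns (cell_id, layer, feature_id, fraction) where
    ``fraction`` is the share of the cell's area covered by that feature;
    ``attributes`` has (layer, feature_id, value) for weighted-average
    layers; ``points`` has (cell_id, layer) rows, one per point feature, for
    count layers. ``modes`` maps each output variable (= layer name) to
    "count", "percent", or "wavg":

    - count: number of point features in the cell;
    - percent: 100 x sum of the layer's overlap fractions;
    - wavg: sum(value_i * w_i) / sum(w_i) with w_i the overlap fraction.
    """
    if not ((overlaps["fraction"] >= 0) & (overlaps["fraction"] <= 1)).all():
        raise ValueError("overlap fractions must lie in [0, 1]")
    sums = overlaps.groupby(["cell_id", "layer"])["fraction"].sum()
    if (sums > 1 + 1e-6).any():
        bad = sums[sums > 1 + 1e-6].index[0]
        raise ValueError(f"overlap fractions for cell/layer {bad} sum above 1")

    if cell_ids is None:
        pools = [overlaps["cell_id"]]
        if points is not None:
            pools.append(points["cell_id"])
        cell_ids = np.unique(pd.concat(pools))
    out = pd.DataFrame({"cell_id": cell_ids})

    for var, mode in modes.items():
        if mode == "percent":
            sub = overlaps[overlaps["layer"] == var]
            agg = sub.groupby("cell_id")["fraction"].sum() * 100.0
            out[var] = out["cell_id"].map(agg).fillna(0.0)
        elif mode == "count":
            if points is None:
                raise ValueError(f"count variable {var!r} needs a points table")
            sub = points[points["layer"] == var]
            agg = sub.groupby("cell_id").size()
            out[var] = out["cell_id"].map(agg).fillna(0).astype(int)
        elif mode == "wavg":
            if attributes is None:
                raise ValueError(f"weighted-average variable {var!r} needs attributes")
            sub = overlaps[overlaps["layer"] == var].merge(
                attributes[attributes["layer"] == var], on=["layer", "feature_id"]
            )
            w = sub.groupby("cell_id").apply(
                lambda g: np.average(g["value"], weights=g["fraction"]) if g["fraction"].sum() > 0 else np.nan,
                include_groups=False,
            )
            out[var] = out["cell_id"].map(w)
        else:
            raise ValueError(f"unknown extraction mode {mode!r} for {var!r}")
    return out


# ---------------------------------------------------------------------------
# correlations and collinearity
# ---------------------------------------------------------------------------


def spearman_fdr(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho with BH-FDR-adjusted two-sided p-values.

    Mid-ranks handle ties; the BH step-up adjustment runs over the set of
    distinct variable pairs. Returns (rho, p_adjusted) as symmetric frames
    with unit diagonal / zero-diagonal p.
    """
    cols = list(table.columns)
    k = len(cols)
    rho = np.eye(k)
    praw = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        r, p = stats.spearmanr(table[cols[i]], table[cols[j]])
        rho[i, j] = rho[j, i] = r
        praw[i, j] = praw[j, i] = p
    iu = np.triu_indices(k, 1)
    if iu[0].size:
        _, padj_flat, _, _ = multipletests(praw[iu], method="fdr_bh")
        padj = np.zeros((k, k))
        padj[iu] = padj_flat
        padj = padj + padj.T
    else:
        padj = praw
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(padj, index=cols, columns=cols),
    )


def vif_screen(predictors: pd.DataFrame, threshold: float = 5.0, keep=()) -> pd.DataFrame:
    """Variance inflation factors with an advisory removal recommendation.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on all others (with
    intercept). Perfect collinearity is reported as +inf. Variables above
    ``threshold`` are flagged; ``keep`` lists flagged variables to retain
    anyway (e.g., for biological relevance), so ``recommend_drop`` is
    flagged-and-not-kept.
    """
    X = predictors.to_numpy(dtype=float)
    n, k = X.shape
    rows = []
    for j, name in enumerate(predictors.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append((name, vif, vif > threshold, vif > threshold and name not in keep))
    return pd.DataFrame(rows, columns=["variable", "vif", "flagged", "recommend_drop"])


# ---------------------------------------------------------------------------
# best-subset regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    r2: float
    adj_r2: float
    aic: float
    variance_explained: dict[str, float] = field(default_factory=dict)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float] | None:
    """Least squares with intercept; returns (coefs, R2, RSS) or None if
    rank-deficient."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return None
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, r2, rss


def _adj_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _aic(rss: float, n: int, p: int) -> float:
    # Gaussian log-likelihood convention with the variance counted as a
    # parameter; only differences matter for selection.
    return n * np.log(rss / n) + 2 * (p + 2)


def best_subset_regression(
    response: pd.Series,
    predictors: pd.DataFrame,
    max_size: int = 10,
    top: int = 10,
    beam_width: int = 200,
) -> list[RegressionModel]:
    """Rank predictor subsets by adjusted R^2; report AIC for parsimony.

    Enumerates every subset up to ``max_size`` predictors (falling back to a
    beam search when the enumeration would exceed 2^20 subsets), fits OLS,
    and returns the ``top`` models by adjusted R^2. The most parsimonious
    model is the one with the lowest AIC among those (see
    :func:`select_parsimonious`). Per-predictor variance explained is the
    adjusted-R^2 drop when that predictor is removed from the subset.
    Rank-deficient subsets are skipped.
    """
    names = list(predictors.columns)
    y = response.to_numpy(dtype=float)
    X = predictors.to_numpy(dtype=float)
    n = len(y)
    if n <= max_size + 2:
        raise ValueError("need n > max_size + 2 observations")
    max_size = min(max_size, len(names))

    total = sum(_ncomb(len(names), k) for k in range(1, max_size + 1))
    if total <= 2**20:
        subsets = (c for k in range(1, max_size + 1) for c in combinations(range(len(names)), k))
    else:
        subsets = _beam_subsets(y, X, max_size, beam_width)

    scored: list[tuple[float, tuple[int, ...], tuple]] = []
    for sub in subsets:
        fit = _ols_fit(y, X[:, sub])
        if fit is None:
            continue
        coef, r2, rss = fit
        scored.append((_adj_r2(r2, n, len(sub)), sub, (coef, r2, rss)))
    scored.sort(key=lambda t: -t[0])

    adj_cache = {sub: adj for adj, sub, _ in scored}

    def adj_of(sub: tuple[int, ...]) -> float:
        if sub in adj_cache:
            return adj_cache[sub]
        fit = _ols_fit(y, X[:, sub])
        val = _adj_r2(fit[1], n, len(sub)) if fit else float("nan")
        adj_cache[sub] = val
        return val

    models = []
    for adj, sub, (coef, r2, rss) in scored[:top]:
        var_expl = {}
        for drop in sub:
            reduced = tuple(s for s in sub if s != drop)
            base = adj_of(reduced) if reduced else 0.0
            var_expl[names[drop]] = adj - base
        models.append(
            RegressionModel(
                response=str(response.name),
                predictors=tuple(names[i] for i in sub),
                intercept=float(coef[0]),
                coefficients={names[i]: float(c) for i, c in zip(sub, coef[1:])},
                r2=r2,
                adj_r2=adj,
                aic=float(_aic(rss, n, len(sub))),
                variance_explained=var_expl,
            )
        )
    return models


def select_parsimonious(models: list[RegressionModel]) -> RegressionModel:
    """Lowest-AIC model among a ranked candidate list."""
    if not models:
        raise ValueError("no candidate models")
    return min(models, key=lambda m: m.aic)


def _ncomb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def _beam_subsets(y, X, max_size, beam_width):
    """Greedy beam enumeration for large predictor pools."""
    n = len(y)
    frontier: list[tuple[int, ...]] = [()]
    seen: set[tuple[int, ...]] = set()
    for size in range(1, max_size + 1):
        candidates = {}
        for base in frontier:
            for j in range(X.shape[1]):
                if j in base:
                    continue
                sub = tuple(sorted(base + (j,)))
                if sub in candidates or sub in seen:
                    continue
                fit = _ols_fit(y, X[:, sub])
                if fit is None:
                    continue
                candidates[sub] = _adj_r2(fit[1], n, size)
        ranked = sorted(candidates, key=candidates.get, reverse=True)[:beam_width]
        for sub in ranked:
            seen.add(sub)
            yield sub
        frontier = ranked


# ---------------------------------------------------------------------------
# redundancy analysis
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    eigenvalues: np.ndarray
    proportion_of_model: np.ndarray
    proportion_of_total: np.ndarray
    r2: float
    adj_r2: float
    perm_p: float
    pseudo_f: float
    response_scores: pd.DataFrame      # responses x axes (correlations with site scores)
    predictor_scores: pd.DataFrame     # predictors x axes (correlations with site scores)
    site_scores: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R2 out of [0, 1]")


def _standardize(df: pd.DataFrame) -> np.ndarray:
    a = df.to_numpy(dtype=float)
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    return (a - mean) / sd


def rda(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaResult:
    """Redundancy analysis of standardized responses on standardized
    predictors, with a row-permutation test of the global model.

    R^2 = tr(Yhat' Yhat) / tr(Y' Y); canonical eigenvalues come from the
    spectral decomposition of the fitted values' covariance; adjusted R^2 is
    Ezekiel's 1 - (1 - R^2)(n - 1)/(n - p - 1). The permutation p-value is
    (1 + #{pseudo-F_perm >= pseudo-F_obs}) / (n_perm + 1), permuting rows of
    the response matrix.
    """
    Y = _standardize(responses)
    X = _standardize(predictors)
    n, q = Y.shape
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError("need more rows than predictors + 1")

    def fit_stats(Ymat):
        B, _, _, _ = np.linalg.lstsq(X, Ymat, rcond=None)
        Yhat = X @ B
        ss_fit = float(np.sum(Yhat**2))
        ss_tot = float(np.sum(Ymat**2))
        ss_res = ss_tot - ss_fit
        f = (ss_fit / p) / (ss_res / (n - p - 1)) if ss_res > 0 else np.inf
        return Yhat, ss_fit, ss_tot, f

    Yhat, ss_fit, ss_tot, f_obs = fit_stats(Y)
    r2 = ss_fit / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    cov = Yhat.T @ Yhat / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    n_axes = min(q, p)
    evals = evals[:n_axes]
    evecs = evecs[:, :n_axes]
    total_var = ss_tot / (n - 1)

    site = Yhat @ evecs
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    resp_scores = pd.DataFrame(_safe_corr(Y, site), index=responses.columns, columns=axes)
    pred_scores = pd.DataFrame(_safe_corr(X, site), index=predictors.columns, columns=axes)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        _, _, _, f_perm = fit_stats(Yp)
        if f_perm >= f_obs:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)

    esum = evals.sum()
    return RdaResult(
        eigenvalues=evals,
        proportion_of_model=evals / esum if esum > 0 else np.zeros_like(evals),
        proportion_of_total=evals / total_var,
        r2=r2,
        adj_r2=adj,
        perm_p=perm_p,
        pseudo_f=f_obs,
        response_scores=resp_scores,
        predictor_scores=pred_scores,
        site_scores=site,
    )


def _safe_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise correlations corr(A_i, B_j); zero where either is constant."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt(np.sum(A**2, axis=0))
    sb = np.sqrt(np.sum(B**2, axis=0))
    out = A.T @ B
    with np.errstate(divide="ignore", invalid="ignore"):
        out = out / np.outer(sa, sb)
    return np.nan_to_num(out)


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------


@dataclass
class VarpartResult:
    """Adjusted-R^2 fractions for three predictor sets.

    unique: per-set fractions a, b, c; pair_shared: fractions shared by
    exactly two sets; triple_shared: shared by all three; residual completes
    the sum to 1. Fractions are on the adjusted scale and may be negative.
    """

    unique: dict[str, float]
    pair_shared: dict[tuple[str, str], float]
    triple_shared: float
    full_adj_r2: float
    residual: float

    def total_explained(self) -> float:
        return sum(self.unique.values()) + sum(self.pair_shared.values()) + self.triple_shared


def _rda_adj_r2(responses: pd.DataFrame, predictors: pd.DataFrame) -> float:
    Y = _standardize(responses)
    X = _standardize(predictors)
    n, p = X.shape
    B, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    r2 = float(np.sum((X @ B) ** 2)) / float(np.sum(Y**2))
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart3(
    responses: pd.DataFrame,
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    set3: pd.DataFrame,
    names: tuple[str, str, str] = ("set1", "set2", "set3"),
) -> VarpartResult:
    """Partition RDA adjusted R^2 among three predictor sets.

    Fits the seven set unions and solves the unique and shared fractions by
    inclusion-exclusion; by construction the seven fractions sum to the
    full-model adjusted R^2 exactly.
    """
    r1 = _rda_adj_r2(responses, set1)
    r2_ = _rda_adj_r2(responses, set2)
    r3 = _rda_adj_r2(responses, set3)
    r12 = _rda_adj_r2(responses, pd.concat([set1, set2], axis=1))
    r13 = _rda_adj_r2(responses, pd.concat([set1, set3], axis=1))
    r23 = _rda_adj_r2(responses, pd.concat([set2, set3], axis=1))
    r123 = _rda_adj_r2(responses, pd.concat([set1, set2, set3], axis=1))

    a = r123 - r23
    b = r123 - r13
    c = r123 - r12
    d = r13 + r23 - r3 - r123           # shared by 1 and 2 only
    e = r12 + r13 - r1 - r123           # shared by 2 and 3 only
    f = r12 + r23 - r2_ - r123          # shared by 1 and 3 only
    g = r123 - a - b - c - d - e - f    # shared by all three

    n1, n2, n3 = names
    return VarpartResult(
        unique={n1: a, n2: b, n3: c},
        pair_shared={(n1, n2): d, (n2, n3): e, (n1, n3): f},
        triple_shared=g,
        full_adj_r2=r123,
        residual=1.0 - r123,
    )
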