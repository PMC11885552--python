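"""Multivariate phylogenetic signal (Kmult with optional λ scaling) and
phylogenetic Procrustes ANOVA / PGLS with residual-randomization permutation
(RRPP).

Kmult generalizes Blomberg's K to multivariate data: the ratio of observed to
Brownian-motion-expected scaled sums of squares,

    K = [tr(YᶜᵀYᶜ) / tr(Yᶜᵀ C⁻¹ Yᶜ)] ÷ [(tr C − n/(1ᵀC⁻¹1)) / (n − 1)],

with Yᶜ the GLS-centered data; K ≈ 1 under BM on the given tree.  Its
significance comes from permuting tip rows, and the effect size Z is the
standardized position of the observed statistic in the log-permutation
distribution.  When λ scaling is requested, λ̂ maximizes the multivariate GLS
likelihood on [0, 1]; λ̂ = 0 means a star phylogeny carries the data best (no
phylogenetic signal) and the remaining quantities are reported as undefined
sentinels (NaN).
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import StrategyTable
from .tree import PhyloTree, lambda_transform

__all__ = ["SignalResult", "PglsTable", "kmult", "pgls_anova", "compare_hypotheses_pgls"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SignalResult:
    kmult: float
    p_value: float
    z: float
    scaling_lambda: float
    loglik_lambda: float
    n_permutations: int
    seed: int | None

    def summary_row(self) -> dict:
        return {
            "scaling_lambda": self.scaling_lambda,
            "loglik": self.loglik_lambda,
            "Z": self.z,
            "Kmult": self.kmult,
            "p_value": self.p_value,
        }


def _align_rows(Y, tree: PhyloTree) -> np.ndarray:
    if isinstance(Y, pd.DataFrame):
        missing = [t for t in tree.tip_labels if t not in Y.index]
        if missing:
            raise ValueError(f"trait rows missing for tips: {missing}")
        return Y.loc[tree.tip_labels].to_numpy(dtype=float)
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError("trait rows do not match tree tips")
    return arr


def _k_statistic(Y: np.ndarray, C: np.ndarray) -> float:
    n = Y.shape[0]
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    w = Cinv @ ones
    a = (w @ Y) / float(ones @ w)
    Yc = Y - a
    num = float(np.trace(Yc.T @ Yc)) / float(np.trace(Yc.T @ Cinv @ Yc))
    denom = (float(np.trace(C)) - n / float(ones @ w)) / (n - 1)
    return num / denom


def _gls_loglik_profiled(Y: np.ndarray, C: np.ndarray) -> float:
    """ML multivariate GLS log-likelihood with the trait covariance profiled."""
    n, m = Y.shape
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    w = Cinv @ ones
    a = (w @ Y) / float(ones @ w)
    Yc = Y - a
    R = (Yc.T @ Cinv @ Yc) / n
    signR, logdetR = np.linalg.slogdet(R)
    if signR <= 0:
        return -np.inf
    return float(-0.5 * (n * m * _LOG2PI + m * logdetC + n * logdetR + n * m))


def kmult(
    Y,
    tree: PhyloTree,
    n_perm: int = 999,
    seed: int | None = None,
    optimize_lambda: bool = False,
    lambda_zero_tol: float = 1e-3,
) -> SignalResult:
    """Multivariate phylogenetic signal with permutation test.

    With ``optimize_lambda`` the tree covariance is rescaled by the
    ML λ̂ ∈ [0, 1] before K is computed; λ̂ ≈ 0 triggers the sentinel output
    (star phylogeny: K, p, Z and logL undefined).
    """
    Ymat = _align_rows(Y, tree)
    n, m = Ymat.shape
    if m >= n:
        warnings.warn(
            f"{m} variables for {n} tips; consider ordination scores instead"
        )
    C = tree.vcv().matrix
    lam = 1.0
    if optimize_lambda:
        def nll(l):
            return -_gls_loglik_profiled(Ymat, lambda_transform(C, float(l)))

        res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(res.x)
        # the bounded optimizer cannot sit exactly on a boundary: check both
        for cand in (0.0, 1.0):
            if nll(cand) <= res.fun:
                lam = cand
        if lam < lambda_zero_tol:
            return SignalResult(
                np.nan, np.nan, np.nan, 0.0, np.nan, n_perm, seed
            )
    Cl = lambda_transform(C, lam)
    ll = _gls_loglik_profiled(Ymat, Cl)
    k_obs = _k_statistic(Ymat, Cl)
    rng = np.random.default_rng(seed)
    k_perm = np.empty(n_perm)
    for b in range(n_perm):
        k_perm[b] = _k_statistic(Ymat[rng.permutation(n)], Cl)
    p = (1 + np.sum(k_perm >= k_obs)) / (n_perm + 1)
    logs = np.log(k_perm)
    sd = logs.std(ddof=1)
    z = (np.log(k_obs) - logs.mean()) / sd if sd > 0 else np.nan
    return SignalResult(float(k_obs), float(p), float(z), lam, ll, n_perm, seed)


# ----------------------------------------------------------------- PGLS

@dataclass
class PglsTable:
    """Sequential (type-I) phylogenetic ANOVA table with RRPP inference."""

    table: pd.DataFrame  # term rows + Residuals/Total: SS, df, R2, F, Z, p
    formula: str
    n_permutations: int
    seed: int | None

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def _factor_column(tps_factor, tree: PhyloTree) -> np.ndarray:
    if isinstance(tps_factor, StrategyTable):
        mapping = tps_factor.mapping
    elif isinstance(tps_factor, pd.Series):
        mapping = {str(k): str(v) for k, v in tps_factor.items()}
    else:
        mapping = {str(k): str(v) for k, v in dict(tps_factor).items()}
    levels = sorted(set(mapping.values()))
    if len(levels) != 2:
        raise ValueError(f"predation-strategy factor must have 2 levels, got {levels}")
    try:
        return np.array([levels.index(mapping[t]) for t in tree.tip_labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"tip without factor level: {exc}") from exc


def _numeric_column(values, tree: PhyloTree) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.loc[tree.tip_labels].to_numpy(dtype=float)
    d = dict(values)
    return np.array([float(d[t]) for t in tree.tip_labels])


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() <= 0:
        raise ValueError("phylogenetic covariance is not positive definite")
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def _hat_apply(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ (Q.T @ Y)


def pgls_anova(
    Y,
    tree: PhyloTree,
    tps_factor,
    centroid_size,
    n_perm: int = 999,
    seed: int | None = None,
    log_size: bool = True,
    lam: float | None = None,
) -> PglsTable:
    """Phylogenetic Procrustes ANOVA: shape ~ strategy * size, RRPP inference.

    The response and design are whitened by C^{−1/2}; sums of squares are
    sequential (type I) with the strategy factor entered first; p-values and
    effect sizes come from randomizing reduced-model residuals (RRPP) with a
    shared, seeded permutation schedule.
    """
    Ymat = _align_rows(Y, tree)
    n = Ymat.shape[0]
    g = _factor_column(tps_factor, tree)
    size = _numeric_column(centroid_size, tree)
    if log_size:
        if (size <= 0).any():
            raise ValueError("centroid sizes must be positive for log transform")
        size = np.log(size)
    size = size - size.mean()
    C = tree.vcv().matrix
    if lam is not None:
        C = lambda_transform(C, lam)
    P = _inv_sqrt(C)
    Yt = P @ Ymat
    cols = {
        "(Intercept)": np.ones(n),
        "TPS": g,
        "log(Csize)" if log_size else "Csize": size,
        "TPS:size": g * size,
    }
    names = list(cols)
    X_full = P @ np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient design; aliased terms among {names[1:]}"
        )
    term_names = names[1:]
    designs = [
        P @ np.column_stack([cols[c] for c in names[: k + 1]])
        for k in range(len(names))
    ]  # designs[0]=intercept-only … designs[3]=full

    def rss(Xk, Yk):
        r = Yk - _hat_apply(Xk, Yk)
        return float((r**2).sum()), r

    rss_models = []
    for Xk in designs:
        rss_models.append(rss(Xk, Yt)[0])
    ss_total = rss_models[0]
    ss_terms = [rss_models[k] - rss_models[k + 1] for k in range(len(term_names))]
    df_terms = [1, 1, 1]
    df_res = n - designs[-1].shape[1]
    ss_res = rss_models[-1]
    ms_res = ss_res / df_res
    f_obs = [ss / df / ms_res for ss, df in zip(ss_terms, df_terms)]

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    f_perm = np.empty((len(term_names), n_perm))
    for k in range(len(term_names)):
        X_red, X_fullk = designs[k], designs[k + 1]
        fitted = _hat_apply(X_red, Yt)
        resid = Yt - fitted
        for b, pidx in enumerate(perms):
            Ystar = fitted + resid[pidx]
            rss_red = float(((Ystar - _hat_apply(X_red, Ystar)) ** 2).sum())
            r_full = Ystar - _hat_apply(designs[-1], Ystar)
            rss_star_full_chain = float(
                ((Ystar - _hat_apply(X_fullk, Ystar)) ** 2).sum()
            )
            ss_k = rss_red - rss_star_full_chain
            ms_res_star = float((r_full**2).sum()) / df_res
            f_perm[k, b] = max(ss_k, 1e-300) / df_terms[k] / ms_res_star
    rows = []
    for k, name in enumerate(term_names):
        fp = f_perm[k]
        p = (1 + np.sum(fp >= f_obs[k])) / (n_perm + 1)
        logs = np.log(fp)
        sd = logs.std(ddof=1)
        z = (np.log(f_obs[k]) - logs.mean()) / sd if sd > 0 else np.nan
        rows.append(
            {
                "term": name,
                "df": df_terms[k],
                "SS": ss_terms[k],
                "R2": ss_terms[k] / ss_total,
                "F": f_obs[k],
                "Z": z,
                "p": p,
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": df_res,
            "SS": ss_res,
            "R2": ss_res / ss_total,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    formula = "shape ~ TPS * " + ("log(Csize)" if log_size else "Csize")
    return PglsTable(pd.DataFrame(rows), formula, n_perm, seed)


def compare_hypotheses_pgls(
    Y,
    tree: PhyloTree,
    prior_table,
    posterior_table,
    centroid_size,
    n_perm: int = 999,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Fit the PGLS under both strategy hypotheses with an identical
    permutation schedule and report the TPS-term differences (Posterior −
    Prior) in effect size Z and R²."""
    prior = pgls_anova(Y, tree, prior_table, centroid_size, n_perm, seed, **kwargs)
    post = pgls_anova(Y, tree, posterior_table, centroid_size, n_perm, seed, **kwargs)
    tp, tq = prior.term("TPS"), post.term("TPS")
    return {
        "prior": prior,
        "posterior": post,
        "delta_z": float(tq["Z"] - tp["Z"]),
        "delta_r2": float(tq["R2"] - tp["R2"]),
    }
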