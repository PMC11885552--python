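"""Multivariate evolutionary models on (possibly non-ultrametric) trees.

Implements maximum-likelihood fitting of multivariate Brownian motion (BM),
multi-rate Brownian motion over a regime painting (BMM), single- and
multi-optimum Ornstein–Uhlenbeck processes (OU1 / OUM), and the early-burst
model (EB), plus Akaike-weight model comparison, a SURFACE-style stepwise
forward search for regime shifts, exact Gaussian simulation from fitted
models, and a parametric-bootstrap model-adequacy check.

All likelihoods are evaluated through the exact joint Gaussian of the tip
data: for n tips and m traits the nm-vector of observations is multivariate
normal with a covariance assembled from shared-path times (BM/BMM/EB) or the
fixed-root OU covariance, and a mean that is linear in the root state /
regime optima and therefore profiled out by GLS.  Rate matrices are kept
positive-definite through a triangular-factor (log-diagonal Cholesky)
parameterization.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .tree import PhyloTree, RegimePainting

__all__ = [
    "EvoModelFit",
    "SurfaceResult",
    "AdequacyResult",
    "fit_evo_model",
    "aic_weights",
    "simulate_from_model",
    "surface_forward",
    "adequacy_bootstrap",
    "MODEL_TYPES",
]

MODEL_TYPES = ("BM", "BMM", "OU1", "OUM", "EB")

_LOG2PI = np.log(2.0 * np.pi)


class ModelError(RuntimeError):
    pass


# ------------------------------------------------------------- utilities

def _tri(m: int) -> int:
    return m * (m + 1) // 2


def _chol_unpack(params: np.ndarray, m: int) -> np.ndarray:
    """Packed vector (m log-diagonals, then row-wise off-diagonals) → PD matrix."""
    L = np.zeros((m, m))
    L[np.diag_indices(m)] = np.exp(np.clip(params[:m], -40, 40))
    if m > 1:
        L[np.tril_indices(m, -1)] = params[m:]
    return L @ L.T


def _chol_pack(R: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(R)
    m = R.shape[0]
    out = np.empty(_tri(m))
    out[:m] = np.log(np.diag(L))
    if m > 1:
        out[m:] = L[np.tril_indices(m, -1)]
    return out


def _data_hash(Y: np.ndarray, taxa) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(Y, dtype=float).tobytes())
    h.update(";".join(taxa).encode())
    return h.hexdigest()


def _align_data(tree: PhyloTree, Y) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, pd.DataFrame):
        missing = [t for t in tree.tip_labels if t not in Y.index]
        if missing:
            raise ModelError(f"trait data missing for tips: {missing}")
        arr = Y.loc[tree.tip_labels].to_numpy(dtype=float)
    else:
        arr = np.asarray(Y, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != tree.n_tips:
            raise ModelError("trait rows do not match tree tips")
    return arr, list(tree.tip_labels)


def _gaussian_profile_loglik(V: np.ndarray, D: np.ndarray, y: np.ndarray):
    """Profile the mean (β̂ by GLS) out of a zero-mean-free Gaussian likelihood."""
    N = len(y)
    jitter = 0.0
    for _ in range(4):
        try:
            c = cho_factor(V + jitter * np.eye(N), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * float(np.mean(np.diag(V))))
    else:
        raise ModelError("covariance matrix not positive definite")
    Vi_D = cho_solve(c, D)
    A = D.T @ Vi_D
    b = Vi_D.T @ y
    beta = np.linalg.solve(A, b)
    r = y - D @ beta
    Vi_r = cho_solve(c, r)
    logdet = 2.0 * np.log(np.diag(c[0])).sum()
    ll = -0.5 * (N * _LOG2PI + logdet + float(r @ Vi_r))
    return ll, beta, c


# ------------------------------------------------- covariance construction

def _kron_cov(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    return np.kron(C, R)


def _eb_time_transform(S: np.ndarray, b: float) -> np.ndarray:
    """∫₀ˢ e^{bt} dt elementwise; reduces to S at b = 0."""
    if abs(b) < 1e-12:
        return S.copy()
    return np.expm1(b * S) / b


def _ou_cov_diag(S: np.ndarray, T: np.ndarray, R: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fixed-root OU covariance with diagonal pull matrix.

    Cov_ab(i,j) = R_ab · e^{−αa(Ti−s) − αb(Tj−s)} · (1 − e^{−(αa+αb)s}) / (αa+αb)
    with s the root→MRCA depth; the BM limit S·R_ab is recovered as α → 0.
    """
    n = S.shape[0]
    m = R.shape[0]
    V4 = np.empty((n, m, n, m))
    Ti = T[:, None]
    Tj = T[None, :]
    for a in range(m):
        for b in range(m):
            asum = alpha[a] + alpha[b]
            if asum < 1e-12:
                M = R[a, b] * S
            else:
                M = (
                    R[a, b]
                    * np.exp(-alpha[a] * (Ti - S) - alpha[b] * (Tj - S))
                    * (-np.expm1(-asum * S))
                    / asum
                )
            V4[:, a, :, b] = M
    return V4.reshape(n * m, n * m)


def _ou_mean_weights(tree: PhyloTree, painting: RegimePainting, alpha: np.ndarray,
                     regimes: tuple[str, ...]) -> np.ndarray:
    """w[i, k, a]: weight of optimum θ_{k,a} in E[X_a(tip i)] (fixed root at the
    root-regime optimum); weights over regimes sum to 1 per (tip, trait)."""
    n = tree.n_tips
    m = len(alpha)
    T = tree.tip_depths()
    paths = tree.path_segments(painting)
    w = np.zeros((n, len(regimes), m))
    ridx = {r: k for k, r in enumerate(regimes)}
    for i, segs in enumerate(paths):
        for a in range(m):
            w[i, ridx[painting.root_regime], a] += np.exp(-alpha[a] * T[i])
        for (u0, u1, reg) in segs:
            k = ridx[reg]
            for a in range(m):
                w[i, k, a] += np.exp(-alpha[a] * (T[i] - u1)) - np.exp(
                    -alpha[a] * (T[i] - u0)
                )
    return w


def _ou_design(w: np.ndarray) -> np.ndarray:
    """(n, K, m) weights → (nm, Km) block design for vec-by-tip-major data."""
    n, K, m = w.shape
    D = np.zeros((n * m, K * m))
    for i in range(n):
        for k in range(K):
            for a in range(m):
                D[i * m + a, k * m + a] = w[i, k, a]
    return D


def _mean_design_constant(n: int, m: int) -> np.ndarray:
    return np.kron(np.ones((n, 1)), np.eye(m))


def model_mean_cov(
    model: str,
    tree: PhyloTree,
    params: dict,
    painting: RegimePainting | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact tip mean vector and (nm × nm) covariance implied by a model.

    ``params`` uses the same field names as :class:`EvoModelFit` (``rates``,
    ``root_state``, ``alpha``, ``theta``, ``eb_rate``).
    """
    S = tree.vcv().matrix
    n = tree.n_tips
    model = model.upper()
    if model == "BM":
        R = np.atleast_2d(params["rates"]["all"] if "all" in params["rates"] else list(params["rates"].values())[0])
        m = R.shape[0]
        V = _kron_cov(S, R)
        mean = np.tile(np.asarray(params["root_state"], float), n)
    elif model == "EB":
        R = np.atleast_2d(list(params["rates"].values())[0])
        m = R.shape[0]
        V = _kron_cov(_eb_time_transform(S, params["eb_rate"]), R)
        mean = np.tile(np.asarray(params["root_state"], float), n)
    elif model == "BMM":
        if painting is None:
            raise ModelError("BMM requires a regime painting")
        shared = tree.regime_shared_times(painting)
        regs = painting.regime_levels
        R0 = np.atleast_2d(params["rates"][regs[0]])
        m = R0.shape[0]
        V = np.zeros((n * m, n * m))
        for r in regs:
            V += _kron_cov(shared[r], np.atleast_2d(params["rates"][r]))
        mean = np.tile(np.asarray(params["root_state"], float), n)
    elif model in {"OU1", "OUM"}:
        if painting is None:
            painting = RegimePainting.uniform(tree, "all")
        R = np.atleast_2d(list(params["rates"].values())[0])
        m = R.shape[0]
        alpha = np.asarray(params["alpha"], float) * np.ones(m)
        V = _ou_cov_diag(S, tree.tip_depths(), R, alpha)
        regs = painting.regime_levels
        w = _ou_mean_weights(tree, painting, alpha, regs)
        theta = np.stack([np.asarray(params["theta"][r], float) for r in regs])
        mean = np.einsum("ika,ka->ia", w, theta).reshape(-1)
    else:
        raise ModelError(f"unknown model type {model!r}")
    return mean, V


# ------------------------------------------------------------- fit result

@dataclass
class EvoModelFit:
    """A fitted multivariate evolutionary model."""

    model: str
    taxa: list[str]
    rates: dict[str, np.ndarray]
    root_state: np.ndarray | None
    alpha: np.ndarray | None
    theta: dict[str, np.ndarray] | None
    eb_rate: float | None
    loglik: float
    n_params: int
    n_obs: int
    painting: RegimePainting | None = None
    aicw: float | None = None
    converged: bool = True
    details: dict = field(default_factory=dict)
    data_hash: str = ""
    seed: int | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def aicc(self) -> float:
        k, N = self.n_params, self.n_obs
        if N - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (N - k - 1)

    @property
    def n_traits(self) -> int:
        return next(iter(self.rates.values())).shape[0]

    def params_dict(self) -> dict:
        return {
            "rates": self.rates,
            "root_state": self.root_state,
            "alpha": self.alpha,
            "theta": self.theta,
            "eb_rate": self.eb_rate,
        }

    def diagonal_parameters(self) -> dict[str, float]:
        """Named diagonal entries of each rate matrix (plus α / EB exponent)."""
        out: dict[str, float] = {}
        for reg, R in self.rates.items():
            for a in range(R.shape[0]):
                out[f"sigma2[{reg}][{a + 1}]"] = float(R[a, a])
        if self.alpha is not None:
            for a, v in enumerate(np.atleast_1d(self.alpha)):
                out[f"alpha[{a + 1}]"] = float(v)
        if self.eb_rate is not None:
            out["eb_rate"] = float(self.eb_rate)
        return out

    def summary_row(self) -> dict:
        return {
            "model": self.model,
            "logL": self.loglik,
            "n_params": self.n_params,
            "AIC": self.aic,
            "AICc": self.aicc,
            "AICw": self.aicw,
        }


# ------------------------------------------------------------- BM closed form

def _closed_form_kron(Ct: np.ndarray, Y: np.ndarray):
    """ML fit of vec(Y) ~ N(1⊗μ, Ct⊗R): GLS mean, profiled R, exact logL."""
    n, m = Y.shape
    c = cho_factor(Ct, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(c, ones)
    denom = float(ones @ Ci1)
    mu = (Ci1 @ Y) / denom
    res = Y - mu
    CiRes = cho_solve(c, res)
    R = (res.T @ CiRes) / n
    logdetC = 2.0 * np.log(np.diag(c[0])).sum()
    sign, logdetR = np.linalg.slogdet(R)
    if sign <= 0:
        raise ModelError("profiled rate matrix is singular")
    ll = -0.5 * (n * m * _LOG2PI + m * logdetC + n * logdetR + n * m)
    return mu, R, float(ll)


# ------------------------------------------------------------------- fitting

def fit_evo_model(
    model: str,
    tree: PhyloTree,
    Y,
    painting: RegimePainting | list[RegimePainting] | None = None,
    *,
    alpha_structure: str = "diagonal",
    n_starts: int = 3,
    seed: int | None = None,
    init_params: dict | None = None,
    optimizer_tol: float = 1e-11,
) -> EvoModelFit:
    """Maximum-likelihood fit of a multivariate evolutionary model.

    ``Y`` is an (n × m) trait matrix (DataFrame indexed by taxon, or an array
    in the tree's tip order) — typically retained phylogenetic PC scores.
    BMM/OUM require a regime ``painting``; passing a *list* of paintings
    (stochastic maps) fits each and returns the median-log-likelihood fit
    with the dispersion recorded in ``details``.
    """
    model = model.upper()
    if model not in MODEL_TYPES:
        raise ModelError(f"unknown model {model!r}; choose from {MODEL_TYPES}")
    if isinstance(painting, (list, tuple)):
        fits = [
            fit_evo_model(
                model, tree, Y, p, alpha_structure=alpha_structure,
                n_starts=n_starts, seed=seed, init_params=init_params,
                optimizer_tol=optimizer_tol,
            )
            for p in painting
        ]
        lls = np.array([f.loglik for f in fits])
        med = int(np.argsort(lls)[len(lls) // 2])
        chosen = fits[med]
        chosen.details["simmap_loglik_spread"] = float(lls.max() - lls.min())
        chosen.details["simmap_logliks"] = lls.tolist()
        return chosen

    Ymat, taxa = _align_data(tree, Y)
    n, m = Ymat.shape
    dh = _data_hash(Ymat, taxa)
    S = tree.vcv().matrix
    rng = np.random.default_rng(seed)

    if model in {"BMM", "OUM"} and painting is None:
        raise ModelError(f"{model} requires a regime painting")
    if model in {"BM", "EB"}:
        painting = None
    if model == "OU1":
        painting = RegimePainting.uniform(tree, "all")

    # ---- moment initialisation from the closed-form BM fit
    mu_bm, R_bm, ll_bm = _closed_form_kron(S, Ymat)
    height = tree.height

    if model == "BM":
        return EvoModelFit(
            "BM", taxa, {"all": R_bm}, mu_bm, None, None, None, ll_bm,
            m + _tri(m), n * m, None, details={"closed_form": True},
            data_hash=dh, seed=seed,
        )

    if model == "EB":
        b_lo = np.log(1e-6) / height

        def nll_eb(b: float) -> float:
            try:
                return -_closed_form_kron(_eb_time_transform(S, b), Ymat)[2]
            except (np.linalg.LinAlgError, ModelError):
                return np.inf

        res = minimize_scalar(nll_eb, bounds=(b_lo, 0.0), method="bounded",
                              options={"xatol": 1e-10})
        b_hat = float(min(res.x, 0.0))
        mu, R, ll = _closed_form_kron(_eb_time_transform(S, b_hat), Ymat)
        if nll_eb(0.0) <= res.fun:  # boundary (BM) at least as good
            b_hat, (mu, R, ll) = 0.0, _closed_form_kron(S, Ymat)
        return EvoModelFit(
            "EB", taxa, {"all": R}, mu, None, None, b_hat, float(ll),
            m + _tri(m) + 1, n * m, None, data_hash=dh, seed=seed,
        )

    y = Ymat.reshape(-1)  # tip-major: (tip 1 traits, tip 2 traits, ...)

    if model == "BMM":
        regs = painting.regime_levels
        shared = {r: M for r, M in tree.regime_shared_times(painting).items()}
        D = _mean_design_constant(n, m)
        nt = _tri(m)

        def unpack(p):
            return {r: _chol_unpack(p[i * nt:(i + 1) * nt], m) for i, r in enumerate(regs)}

        def nll(p):
            try:
                V = np.zeros((n * m, n * m))
                for r in regs:
                    V += _kron_cov(shared[r], _chol_unpack_cached(p, r))
                ll, _, _ = _gaussian_profile_loglik(V, D, y)
                return -ll
            except (np.linalg.LinAlgError, ModelError):
                return np.inf

        def _chol_unpack_cached(p, r):
            i = regs.index(r)
            return _chol_unpack(p[i * nt:(i + 1) * nt], m)

        if init_params is not None:
            base = np.concatenate([_chol_pack(np.atleast_2d(init_params["rates"][r])) for r in regs])
        else:
            base = np.tile(_chol_pack(R_bm + 1e-10 * np.eye(m)), len(regs))
        best = None
        for s in range(max(1, n_starts)):
            x0 = base if s == 0 else base + rng.normal(0, 0.3, size=base.size)
            res = minimize(nll, x0, method="L-BFGS-B",
                           options={"ftol": optimizer_tol, "eps": 1e-5, "maxiter": 1000})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise ModelError("BMM optimization failed to find a finite likelihood")
        rates = unpack(best.x)
        V = np.zeros((n * m, n * m))
        for r in regs:
            V += _kron_cov(shared[r], rates[r])
        ll, beta, _ = _gaussian_profile_loglik(V, D, y)
        return EvoModelFit(
            "BMM", taxa, rates, np.asarray(beta), None, None, None, float(ll),
            m + len(regs) * _tri(m), n * m, painting,
            converged=bool(best.success),
            details={"optimizer_nit": int(best.get("nit", -1)), "optimizer_fun": float(best.fun)},
            data_hash=dh, seed=seed,
        )

    # ---- OU1 / OUM
    regs = painting.regime_levels
    K = len(regs)
    T = tree.tip_depths()
    alpha0 = np.log(2.0) / (0.5 * height)

    def ou_theta_count(structure):
        return (1 if structure == "scalar" else m) + _tri(m) + K * m

    if alpha_structure == "scalar":
        # scalar α gives a separable covariance G(α) ⊗ R: profile R and θ
        def fit_at_alpha(a):
            asum = 2 * a
            if asum < 1e-12:
                G = S.copy()
            else:
                G = (
                    np.exp(-a * (T[:, None] - S) - a * (T[None, :] - S))
                    * (-np.expm1(-asum * S))
                    / asum
                )
            w = _ou_mean_weights(tree, painting, np.array([a]), regs)[:, :, 0]  # (n, K)
            c = cho_factor(G + 1e-12 * np.eye(n), lower=True)
            GiW = cho_solve(c, w)
            A = w.T @ GiW
            theta = np.linalg.solve(A, GiW.T @ Ymat)  # (K, m)
            res = Ymat - w @ theta
            GiRes = cho_solve(c, res)
            R = (res.T @ GiRes) / n
            logdetG = 2.0 * np.log(np.diag(c[0])).sum()
            sign, logdetR = np.linalg.slogdet(R)
            if sign <= 0:
                raise ModelError("profiled OU rate matrix singular")
            ll = -0.5 * (n * m * _LOG2PI + m * logdetG + n * logdetR + n * m)
            return ll, R, theta

        def nll_a(loga):
            try:
                return -fit_at_alpha(float(np.exp(loga)))[0]
            except (np.linalg.LinAlgError, ModelError):
                return np.inf

        lo, hi = np.log(1e-4 / height), np.log(200.0 / height)
        res = minimize_scalar(nll_a, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        a_hat = float(np.exp(res.x))
        ll, R, theta = fit_at_alpha(a_hat)
        alpha = np.full(m, a_hat)
        theta_d = {r: theta[k] for k, r in enumerate(regs)}
        n_par = ou_theta_count("scalar")
        root = theta_d[painting.root_regime]
        return EvoModelFit(
            model, taxa, {"all": R}, np.asarray(root), alpha, theta_d, None,
            float(ll), n_par, n * m, painting, data_hash=dh, seed=seed,
            details={"alpha_structure": "scalar"},
        )

    if alpha_structure != "diagonal":
        raise ModelError("alpha_structure must be 'diagonal' or 'scalar'")

    nt = _tri(m)

    def unpack_ou(p):
        alpha = np.exp(np.clip(p[:m], -40, 40))
        R = _chol_unpack(p[m:m + nt], m)
        return alpha, R

    def nll_ou(p):
        try:
            alpha, R = unpack_ou(p)
            V = _ou_cov_diag(S, T, R, alpha)
            w = _ou_mean_weights(tree, painting, alpha, regs)
            D = _ou_design(w)
            ll, _, _ = _gaussian_profile_loglik(V, D, y)
            return -ll
        except (np.linalg.LinAlgError, ModelError):
            return np.inf

    scale = 2 * alpha0 / max(-np.expm1(-2 * alpha0 * height), 1e-12)
    if init_params is not None:
        a_init = np.atleast_1d(np.asarray(init_params["alpha"], float)) * np.ones(m)
        base = np.concatenate(
            [np.log(np.maximum(a_init, 1e-8)),
             _chol_pack(np.atleast_2d(list(init_params["rates"].values())[0]))]
        )
    else:
        base = np.concatenate(
            [np.full(m, np.log(alpha0)), _chol_pack(R_bm * scale + 1e-10 * np.eye(m))]
        )
    best = None
    for s in range(max(1, n_starts)):
        x0 = base if s == 0 else base + rng.normal(0, 0.4, size=base.size)
        res = minimize(nll_ou, x0, method="L-BFGS-B",
                       options={"ftol": optimizer_tol, "eps": 1e-5, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ModelError(f"{model} optimization failed to find a finite likelihood")
    alpha, R = unpack_ou(best.x)
    V = _ou_cov_diag(S, T, R, alpha)
    w = _ou_mean_weights(tree, painting, alpha, regs)
    D = _ou_design(w)
    ll, beta, _ = _gaussian_profile_loglik(V, D, y)
    theta_d = {r: np.asarray(beta[k * m:(k + 1) * m]) for k, r in enumerate(regs)}
    return EvoModelFit(
        model, taxa, {"all": R}, theta_d[painting.root_regime], alpha, theta_d,
        None, float(ll), ou_theta_count("diagonal"), n * m, painting,
        converged=bool(best.success), data_hash=dh, seed=seed,
        details={"alpha_structure": "diagonal"},
    )


def loglik_evo_model(model: str, tree: PhyloTree, Y, params: dict,
                     painting: RegimePainting | None = None) -> float:
    """Exact log-likelihood at fixed parameters (used by tests and adequacy)."""
    Ymat, _ = _align_data(tree, Y)
    mean, V = model_mean_cov(model, tree, params, painting)
    y = Ymat.reshape(-1) - mean
    c = cho_factor(V + 1e-12 * np.eye(len(y)) * np.mean(np.diag(V)), lower=True)
    logdet = 2.0 * np.log(np.diag(c[0])).sum()
    return float(-0.5 * (len(y) * _LOG2PI + logdet + y @ cho_solve(c, y)))


# --------------------------------------------------------------- AIC weights

def aic_weights(fits: list[EvoModelFit], criterion: str = "aic") -> list[EvoModelFit]:
    """Attach Akaike weights within a comparison set (identical data required)."""
    if len(fits) < 2:
        raise ModelError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ModelError("fits were not computed on identical data")
    vals = np.array([getattr(f, criterion) for f in fits])
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    for f, wi in zip(fits, w):
        f.aicw = float(wi)
    return fits


# ---------------------------------------------------------------- simulation

def simulate_from_model(
    fit_or_params,
    tree: PhyloTree,
    painting: RegimePainting | None = None,
    n_datasets: int = 1,
    seed: int | None = None,
) -> np.ndarray:
    """Exact Gaussian draws of tip traits from a (fitted) evolutionary model.

    Returns an array of shape (n_datasets, n_tips, m); no time discretization
    is involved — tips are drawn from the model-implied joint normal.
    """
    if isinstance(fit_or_params, EvoModelFit):
        model = fit_or_params.model
        params = fit_or_params.params_dict()
        painting = painting or fit_or_params.painting
    else:
        params = dict(fit_or_params)
        model = params.pop("model")
    mean, V = model_mean_cov(model, tree, params, painting)
    rng = np.random.default_rng(seed)
    N = len(mean)
    diag_mean = float(np.mean(np.diag(V)))
    if diag_mean <= 0:  # degenerate zero-rate model
        L = np.zeros_like(V)
    else:
        try:
            L = np.linalg.cholesky(V + 1e-12 * diag_mean * np.eye(N))
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"model covariance not positive definite: {exc}") from exc
    z = rng.standard_normal((n_datasets, N))
    draws = mean[None, :] + z @ L.T
    m = np.atleast_2d(list(params["rates"].values())[0]).shape[0]
    return draws.reshape(n_datasets, tree.n_tips, m)


# ------------------------------------------------------------------- SURFACE

@dataclass
class SurfaceResult:
    """Forward-phase stepwise regime-shift search result."""

    steps: list[dict]
    painting: RegimePainting
    aicc: float
    shift_nodes: list[int]

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _painting_from_shifts(tree: PhyloTree, shifts: dict[int, str],
                          base: str = "reg0") -> RegimePainting:
    levels = tuple([base] + sorted(set(shifts.values())))
    regime_at: dict[int, str] = {tree.root.index: base}
    segments: dict[int, tuple[tuple[float, str], ...]] = {}
    for node in tree.nodes:
        if node.parent is None:
            continue
        reg = shifts.get(node.index, regime_at[node.parent.index])
        regime_at[node.index] = reg
        segments[node.index] = ((node.length, reg),)
    return RegimePainting(tree, segments, base, levels)


def _hansen_univariate(tree: PhyloTree, S, T, y: np.ndarray,
                       painting: RegimePainting, height: float):
    """Univariate fixed-root Hansen (OU) fit: α optimized, σ² and θ profiled.

    Returns (logL, k, α̂, σ̂², θ̂ dict).
    """
    n = len(y)
    regs = painting.regime_levels

    def fit_at(a: float):
        asum = 2 * a
        if asum < 1e-12:
            G = S.copy()
        else:
            G = (
                np.exp(-a * (T[:, None] - S) - a * (T[None, :] - S))
                * (-np.expm1(-asum * S)) / asum
            )
        w = _ou_mean_weights(tree, painting, np.array([a]), regs)[:, :, 0]
        c = cho_factor(G + 1e-12 * np.eye(n), lower=True)
        GiW = cho_solve(c, w)
        A = w.T @ GiW + 1e-12 * np.eye(len(regs))
        theta = np.linalg.solve(A, GiW.T @ y)
        r = y - w @ theta
        Gir = cho_solve(c, r)
        s2 = float(r @ Gir) / n
        if s2 <= 0:
            raise ModelError("degenerate residual variance")
        logdetG = 2.0 * np.log(np.diag(c[0])).sum()
        ll = -0.5 * (n * _LOG2PI + logdetG + n * np.log(s2) + n)
        return ll, s2, theta

    def nll(loga):
        try:
            return -fit_at(float(np.exp(loga)))[0]
        except (np.linalg.LinAlgError, ModelError):
            return np.inf

    res = minimize_scalar(nll, bounds=(np.log(1e-4 / height), np.log(200.0 / height)),
                          method="bounded", options={"xatol": 1e-9})
    a_hat = float(np.exp(res.x))
    ll, s2, theta = fit_at(a_hat)
    k = 2 + len(regs)
    return ll, k, a_hat, s2, {r: float(t) for r, t in zip(regs, theta)}


def _surface_aicc(tree, S, T, Y: np.ndarray, painting, height) -> float:
    """Summed per-trait AICc of independent Hansen fits (the stepwise search
    criterion).

    Each accepted shift's branch placement is itself an estimated quantity
    chosen among all branches, so it is counted as one extra parameter per
    trait; without this the maximization over candidate branches makes
    spurious shifts on small trees almost certain.
    """
    n = Y.shape[0]
    n_shifts = len(painting.regime_levels) - 1
    total = 0.0
    for a in range(Y.shape[1]):
        ll, k, *_ = _hansen_univariate(tree, S, T, Y[:, a], painting, height)
        k = k + n_shifts
        if n - k - 1 <= 0:
            return np.inf
        total += 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)
    return total


def surface_forward(
    tree: PhyloTree,
    Y,
    *,
    aicc_threshold: float = 2.0,
    max_shifts: int | None = None,
    seed: int | None = None,
) -> SurfaceResult:
    """SURFACE-style forward search for regime shifts.

    Starting from a single-regime Hansen (OU) model, repeatedly proposes a new
    regime originating on every branch, keeps the proposal with the best
    summed per-trait AICc, and stops when the improvement drops to
    ``aicc_threshold`` or below.  The default threshold of 2 (the classic
    "substantial support" ΔAIC rule) together with counting shift placements
    as parameters keeps the false-positive rate of the search low on small
    trees.  Traits are treated as independent univariate
    OU processes sharing one painting (the convention of the original method);
    the search is deterministic — ``seed`` is accepted for interface
    uniformity only.
    """
    Ymat, _ = _align_data(tree, Y)
    S = tree.vcv().matrix
    T = tree.tip_depths()
    height = tree.height
    shifts: dict[int, str] = {}
    cur_paint = _painting_from_shifts(tree, shifts)
    cur_aicc = _surface_aicc(tree, S, T, Ymat, cur_paint, height)
    steps = [{"step": 0, "shift_node": None, "shift_clade": None, "aicc": cur_aicc}]
    if max_shifts is None:
        max_shifts = tree.n_tips
    while len(shifts) < max_shifts:
        best_node, best_aicc = None, np.inf
        for node in tree.nodes:
            if node.parent is None or node.index in shifts:
                continue
            trial = dict(shifts)
            trial[node.index] = f"reg{len(shifts) + 1}"
            try:
                aicc = _surface_aicc(
                    tree, S, T, Ymat, _painting_from_shifts(tree, trial), height
                )
            except ModelError:
                continue
            if aicc < best_aicc:
                best_node, best_aicc = node, aicc
        if best_node is None or cur_aicc - best_aicc <= aicc_threshold:
            break
        shifts[best_node.index] = f"reg{len(shifts) + 1}"
        cur_aicc = best_aicc
        steps.append(
            {
                "step": len(shifts),
                "shift_node": best_node.index,
                "shift_clade": ";".join(sorted(tree.clade_tips(best_node))),
                "aicc": cur_aicc,
            }
        )
        cur_paint = _painting_from_shifts(tree, shifts)
    return SurfaceResult(steps, cur_paint, cur_aicc, sorted(shifts))


# ------------------------------------------------------------------ adequacy

@dataclass
class AdequacyResult:
    """Parametric-bootstrap adequacy of a fitted model.

    Simulates from the fitted model, refits, and checks whether each observed
    diagonal parameter lies inside the 95% percentile interval of the
    bootstrap refits.
    """

    n_sim: int
    table: pd.DataFrame  # parameter, observed, ci_lo, ci_hi, inside
    n_failed: int
    seed: int | None

    @property
    def adequate(self) -> bool:
        return bool(self.table["inside"].all())


def adequacy_bootstrap(
    fit: EvoModelFit,
    tree: PhyloTree,
    n_sim: int = 500,
    seed: int | None = None,
    ci: float = 0.95,
    n_starts: int = 1,
) -> AdequacyResult:
    import warnings

    rng = np.random.default_rng(seed)
    sims = simulate_from_model(fit, tree, n_datasets=n_sim, seed=int(rng.integers(2**31)))
    observed = fit.diagonal_parameters()
    collected: dict[str, list[float]] = {k: [] for k in observed}
    n_failed = 0
    for b in range(n_sim):
        try:
            refit = fit_evo_model(
                fit.model, tree, sims[b], fit.painting,
                alpha_structure=fit.details.get("alpha_structure", "diagonal"),
                n_starts=n_starts, seed=int(rng.integers(2**31)),
                init_params=fit.params_dict(),
            )
        except (ModelError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for k, v in refit.diagonal_parameters().items():
            collected[k].append(v)
    if n_sim and n_failed > 0.1 * n_sim:
        warnings.warn(f"adequacy bootstrap: {n_failed}/{n_sim} refits failed")
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for k, obs in observed.items():
        vals = np.asarray(collected[k])
        lo, hi = np.quantile(vals, [lo_q, hi_q]) if len(vals) else (np.nan, np.nan)
        rows.append(
            {
                "parameter": k,
                "observed": obs,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "inside": bool(lo <= obs <= hi) if np.isfinite(lo) else False,
            }
        )
    return AdequacyResult(n_sim, pd.DataFrame(rows), n_failed, seed)
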