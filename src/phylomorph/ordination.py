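"""Ordinary, phylogenetic, and phylogenetically-aligned component analyses,
axis-retention rules, and disparity through time with Brownian-motion
simulation envelopes.

Phylo-PCA eigendecomposes the GLS (evolutionary) trait covariance
R = (Y − 1a)ᵀ C⁻¹ (Y − 1a)/(n − 1), with a the GLS mean under the
phylogenetic covariance C; its early axes are decorrelated from phylogenetic
structure.  PACA instead rotates onto the eigenvectors of Yᶜᵀ C Yᶜ so the
leading axes concentrate phylogenetic signal; axis importance is reported as
the proportion of tip-score dispersion.  Both reduce exactly to ordinary PCA
on a star phylogeny (C = I).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import evomodels
from .tree import PhyloCov, PhyloTree

__all__ = [
    "Ordination",
    "DttResult",
    "pca",
    "phylo_pca",
    "paca",
    "select_axes",
    "dtt",
    "PhyloPCA",
    "PACA",
]


@dataclass
class Ordination:
    """Scores, rotation, eigenvalues and importance proportions of one ordination."""

    kind: str  # PCA | PhyloPCA | PACA
    specimen_ids: list[str]
    scores: np.ndarray  # (n, m)
    rotation: np.ndarray  # (p, m), orthonormal columns
    eigenvalues: np.ndarray  # (m,)
    proportion_variance: np.ndarray  # (m,)
    proportion_tip_dispersion: np.ndarray  # (m,)
    center: np.ndarray  # (p,) mean used for centering (GLS mean a for phylo kinds)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"{self.kind}_{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.specimen_ids, columns=cols)

    def reconstruct(self) -> np.ndarray:
        """Centered data back from scores: scores × rotationᵀ."""
        return self.scores @ self.rotation.T


def _sign_convention(rotation: np.ndarray, scores: np.ndarray):
    """Largest-magnitude loading of each column made positive (determinism)."""
    for j in range(rotation.shape[1]):
        i = int(np.argmax(np.abs(rotation[:, j])))
        if rotation[i, j] < 0:
            rotation[:, j] *= -1
            scores[:, j] *= -1
    return rotation, scores


def _as_matrix(Y, ids=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), [str(i) for i in Y.index]
    arr = np.asarray(Y, dtype=float)
    if ids is None:
        ids = [f"s{i + 1}" for i in range(arr.shape[0])]
    return arr, list(ids)


def _gls_mean(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    ones = np.ones(Y.shape[0])
    w = Cinv @ ones
    return (w @ Y) / float(ones @ w)


def _cov_and_tree(Y, tree_or_cov, ids=None):
    Ymat, ids = _as_matrix(Y, ids)
    if isinstance(tree_or_cov, PhyloTree):
        C = tree_or_cov.vcv().reorder(ids).matrix
    elif isinstance(tree_or_cov, PhyloCov):
        C = tree_or_cov.reorder(ids).matrix
    else:
        C = np.asarray(tree_or_cov, dtype=float)
    if C.shape != (len(ids), len(ids)):
        raise ValueError("phylogenetic covariance does not match specimens")
    return Ymat, ids, C


def _finish(kind, ids, Yc, rotation, eigenvalues, center) -> Ordination:
    # keep axes with non-negligible eigenvalues (rank of the centered data)
    tol = max(eigenvalues.max(), 0) * 1e-10 if eigenvalues.size else 0
    keep = eigenvalues > tol
    rotation = rotation[:, keep]
    eigenvalues = eigenvalues[keep]
    scores = Yc @ rotation
    rotation, scores = _sign_convention(rotation, scores)
    pv = eigenvalues / eigenvalues.sum()
    tip = scores.var(axis=0, ddof=1)
    ptd = tip / tip.sum()
    return Ordination(kind, ids, scores, rotation, eigenvalues, pv, ptd, center)


def pca(Y, ids=None) -> Ordination:
    """Ordinary principal component analysis of (flattened) shape data."""
    Ymat, ids = _as_matrix(Y, ids)
    center = Ymat.mean(axis=0)
    Yc = Ymat - center
    cov = (Yc.T @ Yc) / (len(ids) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return _finish("PCA", ids, Yc, vecs[:, order], np.maximum(vals[order], 0), center)


def phylo_pca(Y, tree, ids=None) -> Ordination:
    """Phylogenetic PCA: eigenvectors of the GLS evolutionary covariance.

    Scores are projections of the GLS-centered data; the variance
    proportions come from the eigenvalues of the evolutionary rate matrix
    (the tip-dispersion proportions of the same axes are also reported).
    """
    Ymat, ids, C = _cov_and_tree(Y, tree, ids)
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance: {exc}") from exc
    a = _gls_mean(Ymat, Cinv)
    Yc = Ymat - a
    R = (Yc.T @ Cinv @ Yc) / (len(ids) - 1)
    vals, vecs = np.linalg.eigh((R + R.T) / 2)
    order = np.argsort(vals)[::-1]
    return _finish("PhyloPCA", ids, Yc, vecs[:, order], np.maximum(vals[order], 0), a)


def paca(Y, tree, ids=None) -> Ordination:
    """Phylogenetically-aligned component analysis.

    Axes are eigenvectors of Yᶜᵀ C Yᶜ, so the first component maximizes the
    alignment of tip scores with phylogenetic covariance; importance per axis
    is the proportion of tip-score dispersion.
    """
    Ymat, ids, C = _cov_and_tree(Y, tree, ids)
    Cinv = np.linalg.inv(C)
    a = _gls_mean(Ymat, Cinv)
    Yc = Ymat - a
    M = Yc.T @ C @ Yc
    vals, vecs = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(vals)[::-1]
    return _finish("PACA", ids, Yc, vecs[:, order], np.maximum(vals[order], 0), a)


def select_axes(ordination: Ordination, threshold: float = 0.90,
                basis: str = "variance") -> list[int]:
    """Smallest prefix of axes whose cumulative importance reaches ``threshold``.

    ``basis='variance'`` uses eigenvalue proportions (the Phylo-PCA
    convention); ``'tip_dispersion'`` uses tip-score dispersion (the PACA
    convention).  Returns 0-based axis indices.
    """
    if basis == "variance":
        props = ordination.proportion_variance
    elif basis == "tip_dispersion":
        props = ordination.proportion_tip_dispersion
    else:
        raise ValueError("basis must be 'variance' or 'tip_dispersion'")
    cum = np.cumsum(props)
    stop = int(np.searchsorted(cum, threshold - 1e-12)) + 1
    return list(range(min(stop, len(props))))


# --------------------------------------------------------- sklearn wrappers

class PhyloPCA(BaseEstimator, TransformerMixin):
    """Estimator-style wrapper around :func:`phylo_pca`.

    fit(Y) expects a DataFrame indexed by taxon (or an array in the order of
    ``tree.tip_labels``); fitted attributes mirror :class:`Ordination`.
    """

    _kind = "PhyloPCA"

    def __init__(self, tree: PhyloTree):
        self.tree = tree

    def _run(self, Y):
        Ymat, ids = _as_matrix(Y, self.tree.tip_labels)
        return phylo_pca(Ymat, self.tree, ids)

    def fit(self, Y, y=None):
        ord_ = self._run(Y)
        self.ordination_ = ord_
        self.scores_ = ord_.scores
        self.components_ = ord_.rotation.T
        self.eigenvalues_ = ord_.eigenvalues
        self.explained_variance_ratio_ = ord_.proportion_variance
        self.tip_dispersion_ratio_ = ord_.proportion_tip_dispersion
        self.mean_ = ord_.center
        return self

    def transform(self, Y):
        Ymat, _ = _as_matrix(Y)
        return (Ymat - self.mean_) @ self.ordination_.rotation

    def fit_transform(self, Y, y=None):
        return self.fit(Y).scores_


class PACA(PhyloPCA):
    """Estimator-style wrapper around :func:`paca`."""

    _kind = "PACA"

    def _run(self, Y):
        Ymat, ids = _as_matrix(Y, self.tree.tip_labels)
        return paca(Ymat, self.tree, ids)


# ----------------------------------------------------------------------- dtt

@dataclass
class DttResult:
    """Observed mean relative subclade disparity against node heights, with a
    pointwise BM simulation envelope."""

    times: np.ndarray  # relative node heights in [0, 1)
    observed: np.ndarray
    sim_mean: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    n_sim: int
    seed: int | None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "relative_time": self.times,
                "observed": self.observed,
                "sim_mean": self.sim_mean,
                "lo95": self.envelope_lo,
                "hi95": self.envelope_hi,
            }
        )


def _avg_sq_disparity(X: np.ndarray) -> float:
    """Average squared pairwise Euclidean distance (0 for fewer than 2 rows)."""
    n = X.shape[0]
    if n < 2:
        return 0.0
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    return float(d2.sum() / (n * (n - 1)))


def _dtt_curve(tree: PhyloTree, Ymat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean relative subclade disparity at each internal-node height.

    At each divergence time (in root-to-tip order) the lineages crossing that
    time are found; each contributes the relative disparity of the clade it
    subtends (tips contribute 0); the curve value is their average.  The root
    entry equals 1 by construction.
    """
    heights = tree.node_heights()
    total = _avg_sq_disparity(Ymat)
    if total <= 0:
        total = 1.0
    tip_pos = {t.label: i for i, t in enumerate(tree.tips)}
    rel_disp: dict[int, float] = {}
    for node in tree.nodes:
        idx = [tip_pos[l] for l in tree.clade_tips(node)]
        rel_disp[node.index] = _avg_sq_disparity(Ymat[idx]) / total
    internal = sorted(
        (n for n in tree.nodes if not n.is_leaf), key=lambda n: heights[n.index]
    )
    times = np.array([heights[n.index] for n in internal])
    # first value: the whole clade, relative disparity 1 by construction;
    # afterwards, the average over internal subclades whose stem branch
    # crosses the divergence time (tips contribute nothing; none crossing → 0)
    values = [rel_disp[tree.root.index]]
    for t in times[1:]:
        contrib = [
            rel_disp[node.index]
            for node in tree.nodes
            if node.parent is not None
            and not node.is_leaf
            and heights[node.parent.index] <= t < heights[node.index]
        ]
        values.append(float(np.mean(contrib)) if contrib else 0.0)
    depth = tree.height
    return times / depth, np.array(values)


def dtt(tree: PhyloTree, scores, n_sim: int = 1000, seed: int | None = None) -> DttResult:
    """Disparity through time with a multivariate-BM envelope.

    The BM rate matrix of the simulations is the GLS evolutionary covariance
    estimated from the data; the envelope is the pointwise 2.5/97.5 percentile
    band over ``n_sim`` simulated curves.
    """
    Ymat, ids = _as_matrix(scores, tree.tip_labels)
    order = [ids.index(t) for t in tree.tip_labels]
    Ymat = Ymat[order]
    if tree.n_tips < 4:
        raise ValueError("dtt needs at least 4 tips")
    times, observed = _dtt_curve(tree, Ymat)
    C = tree.vcv().matrix
    Cinv = np.linalg.inv(C)
    a = _gls_mean(Ymat, Cinv)
    Yc = Ymat - a
    R = (Yc.T @ Cinv @ Yc) / (len(ids) - 1)
    R = (R + R.T) / 2 + 1e-12 * np.eye(R.shape[0]) * max(np.trace(R), 1e-30)
    sims = evomodels.simulate_from_model(
        {"model": "BM", "rates": {"all": R}, "root_state": a},
        tree,
        n_datasets=n_sim,
        seed=seed,
    )
    curves = np.stack([_dtt_curve(tree, sims[b])[1] for b in range(n_sim)])
    return DttResult(
        times,
        observed,
        curves.mean(axis=0),
        np.quantile(curves, 0.025, axis=0),
        np.quantile(curves, 0.975, axis=0),
        n_sim,
        seed,
    )
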