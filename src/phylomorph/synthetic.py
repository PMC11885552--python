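"""Synthetic data generators with the statistical structure the analysis
assumes: birth–death fossil trees, landmark configurations evolving under
(multi-regime) BM or OU in the tangent space of a mean configuration, binary
regime traits under an equal-rates Markov model, and a deterministic
study-scale fixture (17 taxa, 6 fixed + 13 sliding landmarks, Late
Cretaceous specialist clade) used by the integration tests.

All generators are pure functions of their parameters and seed.
"""
from __future__ import annotations

import random
from dataclasses import dataclass

import numpy as np
from dendropy.model import birthdeath

from . import evomodels
from .geometry import unflatten_shapes
from .io import LandmarkSet, StrategyTable
from .tree import PhyloTree, RegimePainting

__all__ = [
    "SyntheticScenario",
    "sim_tree",
    "sim_mk_trait",
    "sim_landmarks",
    "default_mean_config",
    "paper_fixture",
    "fixture_strategy_prior",
    "fixture_strategy_posterior",
    "FIXTURE_SPECIALISTS_PRIOR",
    "FIXTURE_SPECIALISTS_POSTERIOR",
]


def sim_tree(
    n_tips: int,
    birth: float = 0.06,
    death: float = 0.02,
    fossil_fraction: float = 0.5,
    seed: int | None = None,
    max_retries: int = 20,
) -> PhyloTree:
    """Birth–death tree with a fraction of tips truncated before the present.

    Truncated pendant edges emulate fossil sampling: the resulting tree is
    non-ultrametric, as in real paleontological phylogenies.  Branch lengths
    are in the same time unit as 1/birth (Myr in the intended use).
    """
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = np.random.default_rng(seed)
    last_exc: Exception | None = None
    for attempt in range(max_retries):
        try:
            dtree = birthdeath.birth_death_tree(
                birth_rate=birth,
                death_rate=death,
                num_extant_tips=n_tips,
                rng=random.Random(int(rng.integers(2**31))),
                repeat_until_success=False,
            )
            break
        except Exception as exc:  # total extinction
            last_exc = exc
    else:
        raise RuntimeError(f"birth-death simulation failed {max_retries} times: {last_exc}")
    tns = dtree.taxon_namespace
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tns.new_taxon(f"t{i + 1}")
        else:
            leaf.taxon.label = f"t{i + 1}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True,
                             suppress_internal_node_labels=True)
    tree = PhyloTree.from_newick(newick)
    for node in tree.nodes:
        if node.parent is not None and node.length <= 0:
            node.length = 1e-6
    tree = PhyloTree(tree.root)
    if fossil_fraction > 0:
        n_fossil = int(round(fossil_fraction * n_tips))
        idx = rng.choice(tree.n_tips, size=n_fossil, replace=False)
        for i in idx:
            tip = tree.tips[i]
            tip.length = max(tip.length * float(rng.uniform(0.1, 0.9)), 1e-6)
        tree = PhyloTree(tree.root)
    return tree


def sim_mk_trait(tree: PhyloTree, q: float, levels=("0", "1"),
                 seed: int | None = None) -> dict[str, str]:
    """Forward-simulate a binary equal-rates Markov trait; returns tip states."""
    rng = np.random.default_rng(seed)
    state = {tree.root.index: int(rng.integers(2))}
    for node in tree.nodes:
        if node.parent is None:
            continue
        s = state[node.parent.index]
        p_same = 0.5 * (1 + np.exp(-2 * q * node.length))
        state[node.index] = s if rng.uniform() < p_same else 1 - s
    return {t.label: levels[state[t.index]] for t in tree.tips}


def default_mean_config() -> tuple[np.ndarray, tuple[tuple[int, ...], ...]]:
    """A maxilla-like mean configuration: 6 fixed landmarks and 13
    semilandmarks on three curves (ventral margin; posterodorsal and
    anterodorsal outline of the ascending ramus).

    Landmarks 0–5 are fixed; curve tuples include their fixed endpoints.
    Units are arbitrary image units (≈ cm for a mid-sized theropod maxilla).
    """
    fixed = np.array(
        [
            [0.0, 0.0],    # 0 anteroventral tip
            [10.0, 0.4],   # 1 posteroventral end of the jugal ramus
            [10.4, 1.5],   # 2 posterodorsal corner of the jugal ramus
            [3.0, 4.4],    # 3 apex of the ascending ramus
            [0.3, 2.2],    # 4 anterodorsal (premaxillary) contact
            [3.4, 1.6],    # 5 anterior corner of the antorbital fenestra
        ]
    )
    xs = 10.0 * np.arange(1, 8) / 8.0
    ventral = np.column_stack([xs, -0.25 * np.sin(np.pi * xs / 10.0) + 0.04 * xs])
    posterodorsal = np.array([[8.6, 2.6], [6.7, 3.4], [4.8, 4.0]])
    anterodorsal = np.array([[2.2, 4.0], [1.4, 3.4], [0.7, 2.8]])
    coords = np.vstack([fixed, ventral, posterodorsal, anterodorsal])
    curves = (
        (0, 6, 7, 8, 9, 10, 11, 12, 1),
        (2, 13, 14, 15, 3),
        (3, 16, 17, 18, 4),
    )
    return coords, curves


def sim_landmarks(
    tree: PhyloTree,
    mean_config: np.ndarray | None = None,
    curves: tuple[tuple[int, ...], ...] | None = None,
    model_params: dict | None = None,
    painting: RegimePainting | None = None,
    noise_sd: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int | None = None,
    randomize_frame: bool = True,
    clade_jump: tuple[list[str], np.ndarray] | None = None,
) -> LandmarkSet:
    """Landmark configurations evolving along a tree.

    Trait deviations are drawn exactly from the requested evolutionary model
    (default: isotropic BM, rate 2e-4 per coordinate per Myr) in the tangent
    space of ``mean_config``, added to the mean, optionally perturbed by
    i.i.d. digitization noise, optionally placed in random specimen-specific
    image frames (similarity transforms), and optionally masked.  An optional
    ``clade_jump`` (tip list, deviation vector) displaces a clade's tips —
    a stem-branch saltation creating a distinct phenotypic cluster.
    """
    rng = np.random.default_rng(seed)
    if mean_config is None:
        mean_config, default_curves = default_mean_config()
        if curves is None:
            curves = default_curves
    mean_config = np.asarray(mean_config, dtype=float)
    k = mean_config.shape[0]
    d = 2 * k
    if model_params is None:
        model_params = {"model": "BM", "rates": {"all": 2e-4 * np.eye(d)},
                        "root_state": np.zeros(d)}
    dev = evomodels.simulate_from_model(
        model_params, tree, painting, n_datasets=1,
        seed=int(rng.integers(2**31)),
    )[0]
    if clade_jump is not None:
        taxa, delta = clade_jump
        for t in taxa:
            dev[tree.tip_index(t)] += np.asarray(delta, float)
    configs = mean_config[None, :, :] + unflatten_shapes(dev)
    if noise_sd > 0:
        configs = configs + rng.normal(0, noise_sd, size=configs.shape)
    n = tree.n_tips
    if randomize_frame:
        for i in range(n):
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            s = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            tvec = rng.uniform(-5, 5, size=2)
            configs[i] = s * configs[i] @ R.T + tvec
    missing = np.zeros((n, k), dtype=bool)
    if missing_fraction > 0:
        for i in range(1, n):  # specimen 0 always stays complete
            mask = rng.uniform(size=k) < missing_fraction
            if mask.sum() > k - 3:
                mask[np.argsort(rng.uniform(size=k))[: k - 3]] = False
            missing[i] = mask
        configs[missing] = np.nan
    return LandmarkSet(
        [t for t in tree.tip_labels], configs, curves or (), missing, None
    )


# ------------------------------------------------------------------ fixture

FIXTURE_NEWICK = (
    "(Herrerasaurus:5,(Syntarsus:30,(Dilophosaurus:27,(Allosaurus:55,"
    "(Ceratosaurus:40,((Elaphrosaurus:8,(Noasaurus:45,Masiakasaurus:47):45):15,"
    "(Spectrovenator:25,((Majungasaurus:52,Rugops:25):15,((Abelisaurus:30,"
    "(Aucasaurus:15,Carnotaurus:25):15):13,(Llukalkan:27,(Skorpiovenator:10,"
    "Ekrixinatosaurus:10):8):10):12):15):25):15):15):12):8):10);"
)

FIXTURE_SPECIALISTS_PRIOR = (
    "Majungasaurus", "Rugops", "Abelisaurus", "Aucasaurus", "Carnotaurus",
    "Llukalkan", "Skorpiovenator", "Ekrixinatosaurus",
)
FIXTURE_SPECIALISTS_POSTERIOR = FIXTURE_SPECIALISTS_PRIOR + ("Spectrovenator",)
FIXTURE_ESTIMATED_TAXA = ("Llukalkan", "Abelisaurus")

_FIXTURE_SEED = 20251
_FIXTURE_RATE = 2e-4          # mean generalist per-coordinate BM rate (units² / Myr)
_FIXTURE_RATE_RATIO = 4.0     # specialist / generalist rate ratio
_FIXTURE_JUMP_NORM = 5.0      # stem saltation of the specialist clade: ~4.5× the
                              # BM shape dispersion, giving the non-overlapping
                              # clade clusters seen in real maxilla morphospaces
_FIXTURE_NOISE_SD = 0.02      # digitization noise
_FIXTURE_SPECTRUM_DECAY = 0.5 # eigenvalue ratio between successive shape directions


def _fixture_rate_matrix(d: int, total_rate: float, seed: int) -> np.ndarray:
    """Anisotropic shape rate matrix with a geometric eigenvalue spectrum.

    Real landmark data concentrates its variation in a few shape directions
    (a steep ordination scree); a geometric spectrum over random orthogonal
    directions reproduces that structure while keeping the total rate fixed.
    """
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    lams = _FIXTURE_SPECTRUM_DECAY ** np.arange(d)
    lams *= total_rate * d / lams.sum()
    return (Q * lams) @ Q.T


def fixture_tree() -> PhyloTree:
    return PhyloTree.from_newick(FIXTURE_NEWICK)


def _strategy(specialists) -> StrategyTable:
    tree = fixture_tree()
    return StrategyTable(
        {
            t: ("specialist" if t in specialists else "generalist")
            for t in tree.tip_labels
        }
    )


def fixture_strategy_prior() -> StrategyTable:
    return _strategy(set(FIXTURE_SPECIALISTS_PRIOR))


def fixture_strategy_posterior() -> StrategyTable:
    return _strategy(set(FIXTURE_SPECIALISTS_POSTERIOR))


def paper_fixture() -> tuple[LandmarkSet, PhyloTree, StrategyTable]:
    """Deterministic study-scale fixture.

    17 taxa (9 abelisaurids including the Early Cretaceous Spectrovenator,
    8 outgroups) on a non-ultrametric tree spanning ~235 Myr; 19-landmark
    maxilla configurations simulated under a two-regime Brownian motion whose
    specialist clade (Spectrovenator + Late Cretaceous abelisaurids) carries
    a faster rate and a stem displacement; the strategy table returned is the
    Prior hypothesis (specialists = Late Cretaceous abelisaurids only,
    8 specialist / 9 generalist labels).  Identical across runs.
    """
    from .markov import paint_from_hypothesis

    tree = fixture_tree()
    mean, curves = default_mean_config()
    d = 2 * mean.shape[0]
    posterior = fixture_strategy_posterior()
    painting = paint_from_hypothesis(tree, posterior, derived_level="specialist")
    R_base = _fixture_rate_matrix(d, _FIXTURE_RATE, _FIXTURE_SEED + 7)
    rates = {
        "generalist": R_base,
        "specialist": _FIXTURE_RATE_RATIO * R_base,
    }
    rng = np.random.default_rng(_FIXTURE_SEED)
    delta = rng.standard_normal(d)
    delta *= _FIXTURE_JUMP_NORM / np.linalg.norm(delta)
    landmarks = sim_landmarks(
        tree,
        mean_config=mean,
        curves=curves,
        model_params={"model": "BMM", "rates": rates, "root_state": np.zeros(d)},
        painting=painting,
        noise_sd=_FIXTURE_NOISE_SD,
        missing_fraction=0.0,
        seed=_FIXTURE_SEED + 1,
        randomize_frame=True,
        clade_jump=(list(FIXTURE_SPECIALISTS_POSTERIOR), delta),
    )
    # the two estimated taxa of the study design lack part of the jugal ramus
    coords = landmarks.coords.copy()
    missing = landmarks.missing.copy()
    for taxon in FIXTURE_ESTIMATED_TAXA:
        i = landmarks.specimen_ids.index(taxon)
        for j in (1, 2, 12):
            missing[i, j] = True
            coords[i, j] = np.nan
    landmarks = LandmarkSet(
        landmarks.specimen_ids, coords, landmarks.curves, missing, None
    )
    return landmarks, tree, fixture_strategy_prior()


@dataclass
class SyntheticScenario:
    """A reproducible bundle of generator settings.

    ``generate(seed)`` yields (landmarks, tree, strategy): the tree from the
    birth–death settings, a binary strategy trait from the equal-rates Markov
    rate ``mk_q``, and landmarks from the shape model (BM by default; a
    two-regime model when ``rate_ratio`` ≠ 1, painted on the strategy's
    derived clade when it is monophyletic, else on a stochastic map).
    """

    n_tips: int = 17
    birth: float = 0.06
    death: float = 0.02
    fossil_fraction: float = 0.5
    base_rate: float = 2e-4
    rate_ratio: float = 1.0
    mk_q: float = 0.01
    noise_sd: float = 0.02
    missing_fraction: float = 0.0
    seed: int = 0

    def generate(self, seed: int | None = None):
        from .markov import simmap_sample

        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        tree = sim_tree(
            self.n_tips, self.birth, self.death, self.fossil_fraction,
            seed=int(rng.integers(2**31)),
        )
        states = sim_mk_trait(
            tree, self.mk_q, ("generalist", "specialist"),
            seed=int(rng.integers(2**31)),
        )
        strategy = StrategyTable(states)
        mean, curves = default_mean_config()
        d = 2 * mean.shape[0]
        painting = None
        params = {"model": "BM", "rates": {"all": self.base_rate * np.eye(d)},
                  "root_state": np.zeros(d)}
        if self.rate_ratio != 1.0 and len(set(states.values())) == 2:
            maps = simmap_sample(
                tree, states, max(self.mk_q, 1e-6), n_maps=1,
                seed=int(rng.integers(2**31)),
            )
            painting = maps[0]
            params = {
                "model": "BMM",
                "rates": {
                    "generalist": self.base_rate * np.eye(d),
                    "specialist": self.base_rate * self.rate_ratio * np.eye(d),
                },
                "root_state": np.zeros(d),
            }
        landmarks = sim_landmarks(
            tree, mean, curves, params, painting,
            noise_sd=self.noise_sd, missing_fraction=self.missing_fraction,
            seed=int(rng.integers(2**31)),
        )
        return landmarks, tree, strategy
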