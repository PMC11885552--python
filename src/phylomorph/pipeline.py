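"""End-to-end orchestration of the maxilla-shape macroevolutionary analysis.

The full workflow mirrors the study design: mirror/estimate missing landmarks
→ GPA with sliding semilandmarks → ordinations (PCA, Phylo-PCA, PACA) with
90% axis retention → phylogenetic signal (Kmult with λ scaling) → PGLS under
the Prior and Posterior strategy hypotheses → disparity through time →
SURFACE forward search (which defines the Posterior hypothesis) → the
seven-model comparison {OU1, OUM, BM, BMM, EB, BMMS, OUMS} with Akaike
weights → optional estimated-taxa-removal rerun → parametric-bootstrap
adequacy of the best model.  Every stage writes self-describing CSV/JSON
artifacts; the master seed deterministically spawns per-stage seeds so the
whole run is bit-reproducible.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evomodels import adequacy_bootstrap, aic_weights, fit_evo_model, surface_forward
from .geometry import estimate_missing_tps, gpa_align
from .io import (
    LandmarkSet,
    StrategyTable,
    check_taxon_join,
    read_newick,
    read_strategy_table,
    read_tps,
    write_tps,
)
from .markov import paint_from_hypothesis
from .ordination import dtt, paca, pca, phylo_pca, select_axes
from .signal import compare_hypotheses_pgls, kmult
from .tree import PhyloTree

__all__ = ["RunConfig", "run_full", "run_taxa_removal", "stage_seed"]


@dataclass
class RunConfig:
    """Configuration of one analysis cell (clade variant × removal setting)."""

    tps_path: str | None = None
    tree_path: str | None = None
    strategy_path: str | None = None
    out_dir: str = "phylomorph_out"
    clade_variant: str = "all_taxa"  # or "dilophosaurus_clade"
    clade_drop_taxa: tuple[str, ...] = ("Herrerasaurus", "Syntarsus")
    estimated_taxa_removal: bool = False
    estimated_taxa: tuple[str, ...] = ()  # default: specimens with missing landmarks
    axis_threshold: float = 0.90
    slide_semilandmarks: bool = True
    slide_criterion: str = "bending_energy"
    n_perm: int = 999
    n_sim_dtt: int = 1000
    n_sim_adequacy: int = 500
    simmap_draws: int = 10
    alpha_structure: str = "diagonal"
    zero_branch_epsilon: float = 0.1
    derived_level: str = "specialist"
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["clade_drop_taxa"] = list(self.clade_drop_taxa)
        data["estimated_taxa"] = list(self.estimated_taxa)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _load_inputs(config: RunConfig, inputs=None):
    if inputs is not None:
        landmarks, tree, strategy = inputs
    else:
        if not (config.tps_path and config.tree_path and config.strategy_path):
            raise ValueError("config must provide tps/tree/strategy paths (or pass inputs)")
        landmarks = read_tps(config.tps_path)
        tree = read_newick(config.tree_path)
        strategy = read_strategy_table(config.strategy_path, tree)
    tree = tree.fix_zero_branches(config.zero_branch_epsilon)
    check_taxon_join(landmarks, tree, strategy)
    return landmarks, tree, strategy


def _posterior_from_surface(tree: PhyloTree, surface_res, prior: StrategyTable,
                            derived_level: str) -> StrategyTable:
    """Tips whose painted regime differs from the root regime form the derived group."""
    tip_states = surface_res.painting.tip_states()
    root = surface_res.painting.root_regime
    levels = prior.levels
    ancestral_level = next(l for l in levels if l != derived_level)
    return StrategyTable(
        {
            t: (derived_level if tip_states[t] != root else ancestral_level)
            for t in tree.tip_labels
        }
    )


def _painting_or_simmap(tree, strategy, derived_level, draws, seed):
    """Deterministic clade painting when the derived taxa are monophyletic,
    otherwise a set of stochastic maps (flagged in the returned info)."""
    from .markov import fit_mk_er, simmap_sample
    from .tree import TreeError

    try:
        return paint_from_hypothesis(tree, strategy, derived_level=derived_level), False
    except TreeError:
        q, _ = fit_mk_er(tree, strategy)
        maps = simmap_sample(tree, strategy, max(q, 1e-8), n_maps=draws, seed=seed)
        return maps, True


def run_full(config: RunConfig, inputs=None) -> dict:
    """Run the complete analysis for one configuration cell.

    ``inputs`` may supply (LandmarkSet, PhyloTree, StrategyTable) directly
    (e.g. the synthetic fixture); otherwise the configured paths are read.
    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    landmarks, tree, prior = _load_inputs(config, inputs)

    stage = "input"
    try:
        # ---------------- alignment -------------------------------------
        stage = "align"
        estimated = tuple(config.estimated_taxa) or tuple(
            sid
            for sid, row in zip(landmarks.specimen_ids, landmarks.missing)
            if row.any()
        )
        completed = estimate_missing_tps(landmarks)
        if config.clade_variant == "dilophosaurus_clade":
            keep = [t for t in tree.tip_labels if t not in set(config.clade_drop_taxa)]
            tree = tree.prune(keep)
        if config.estimated_taxa_removal and estimated:
            keep = [t for t in tree.tip_labels if t not in set(estimated)]
            ingroup = [t for t in keep]
            if len(ingroup) < 4:
                raise ValueError("taxa removal leaves fewer than 4 tips")
            tree = tree.prune(keep)
        completed = completed.subset(tree.tip_labels)
        shapes = gpa_align(
            completed,
            slide_semilandmarks=config.slide_semilandmarks,
            slide_criterion=config.slide_criterion,
        )
        write_tps(
            LandmarkSet(shapes.specimen_ids, shapes.aligned, completed.curves),
            out / "aligned_shapes.tps",
        )
        pd.DataFrame(
            {"taxon": shapes.specimen_ids, "centroid_size": shapes.centroid_sizes}
        ).to_csv(out / "centroid_sizes.csv", index=False)

        # ---------------- ordinations -----------------------------------
        stage = "ordinate"
        flat = pd.DataFrame(shapes.flat(), index=shapes.specimen_ids)
        ord_pca = pca(flat)
        ord_phy = phylo_pca(flat, tree)
        ord_paca = paca(flat, tree)
        phy_axes = select_axes(ord_phy, config.axis_threshold, "variance")
        paca_axes = select_axes(ord_paca, config.axis_threshold, "tip_dispersion")
        for o in (ord_pca, ord_phy, ord_paca):
            o.scores_frame().to_csv(out / f"scores_{o.kind}.csv")
        phy_scores = ord_phy.scores_frame().iloc[:, phy_axes]
        paca_scores = ord_paca.scores_frame().iloc[:, paca_axes]

        # ---------------- phylogenetic signal ---------------------------
        stage = "signal"
        csizes = pd.Series(shapes.centroid_sizes, index=shapes.specimen_ids)
        signal_rows = []
        for label, data in (
            ("Procrustes_coordinates", flat),
            (f"PhyloPCA_1-{len(phy_axes)}", phy_scores),
            (f"PACA_1-{len(paca_axes)}", paca_scores),
        ):
            res = kmult(
                data, tree, n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"kmult:{label}"),
                optimize_lambda=True,
            )
            signal_rows.append({"data": label, **res.summary_row()})
        signal_table = pd.DataFrame(signal_rows)
        signal_table.to_csv(out / "phylogenetic_signal.csv", index=False)

        # ---------------- SURFACE → posterior hypothesis ----------------
        stage = "surface"
        surf = surface_forward(tree, phy_scores)
        surf.step_table().to_csv(out / "surface_steps.csv", index=False)
        surf.painting.to_table().to_csv(out / "surface_painting.csv", index=False)
        posterior = _posterior_from_surface(tree, surf, prior, config.derived_level)
        if set(posterior.taxa_with(config.derived_level)) == set():
            posterior = prior  # no shift found: posterior collapses onto prior

        # ---------------- PGLS (prior vs posterior) ---------------------
        stage = "pgls"
        pgls_results = {}
        for label, data in (
            ("PC", flat),
            ("PhyloPCA", phy_scores),
            ("PACA", paca_scores),
        ):
            cmp = compare_hypotheses_pgls(
                data, tree, prior, posterior, csizes,
                n_perm=config.n_perm, seed=stage_seed(config.seed, f"pgls:{label}"),
            )
            cmp["prior"].table.to_csv(out / f"pgls_{label}_prior.csv", index=False)
            cmp["posterior"].table.to_csv(out / f"pgls_{label}_posterior.csv", index=False)
            pgls_results[label] = cmp

        # ---------------- disparity through time ------------------------
        stage = "dtt"
        dtt_res = dtt(
            tree, phy_scores, n_sim=config.n_sim_dtt,
            seed=stage_seed(config.seed, "dtt"),
        )
        dtt_res.frame().to_csv(out / "dtt.csv", index=False)
        try:
            from .plotting import plot_dtt, plot_morphospace

            plot_dtt(dtt_res, out / "dtt.png")
            plot_morphospace(
                ord_phy,
                {t: prior[t] for t in tree.tip_labels},
                out / "morphospace_phylopca.png",
            )
        except Exception:
            pass  # figures are conveniences; never fail the run over them

        # ---------------- evolutionary models ---------------------------
        stage = "models"
        prior_paint, prior_stochastic = _painting_or_simmap(
            tree, prior, config.derived_level, config.simmap_draws,
            stage_seed(config.seed, "simmap:prior"),
        )
        post_paint, post_stochastic = _painting_or_simmap(
            tree, posterior, config.derived_level, config.simmap_draws,
            stage_seed(config.seed, "simmap:posterior"),
        )
        model_specs = [
            ("OU1", "OU1", None),
            ("OUM", "OUM", prior_paint),
            ("BM", "BM", None),
            ("BMM", "BMM", prior_paint),
            ("EB", "EB", None),
            ("BMMS", "BMM", post_paint),
            ("OUMS", "OUM", post_paint),
        ]
        fits = {}
        for name, kind, paint in model_specs:
            fits[name] = fit_evo_model(
                kind, tree, phy_scores, paint,
                alpha_structure=config.alpha_structure,
                seed=stage_seed(config.seed, f"fit:{name}"),
            )
        flist = [fits[n] for n, _, _ in model_specs]
        aic_weights(flist)
        model_table = pd.DataFrame(
            [{"model": name, **fits[name].summary_row()} for name, _, _ in model_specs]
        ).drop(columns=["model"], errors="ignore")
        model_table.insert(0, "model", [n for n, _, _ in model_specs])
        model_table.to_csv(out / "model_comparison.csv", index=False)
        best_name = max(fits, key=lambda n: fits[n].aicw)
        best_aic = min(f.aic for f in flist)
        best_set = [n for n, _, _ in model_specs if fits[n].aic - best_aic < 2.0]

        # ---------------- adequacy of the best model --------------------
        stage = "adequacy"
        adequacy = adequacy_bootstrap(
            fits[best_name], tree, n_sim=config.n_sim_adequacy,
            seed=stage_seed(config.seed, "adequacy"),
        )
        adequacy.table.to_csv(out / "adequacy.csv", index=False)

        # ---------------- summary ---------------------------------------
        stage = "summary"
        summary = {
            "package_version": __version__,
            "seed": config.seed,
            "clade_variant": config.clade_variant,
            "estimated_taxa_removal": config.estimated_taxa_removal,
            "n_taxa": tree.n_tips,
            "estimated_taxa": list(estimated),
            "phylo_pca_axes_retained": len(phy_axes),
            "paca_axes_retained": len(paca_axes),
            "phylo_pc12_variance": float(ord_phy.proportion_variance[:2].sum()),
            "surface_n_shifts": len(surf.shift_nodes),
            "surface_shift_clades": [
                s["shift_clade"] for s in surf.steps if s["shift_node"] is not None
            ],
            "posterior_specialists": posterior.taxa_with(config.derived_level),
            "prior_painting_stochastic": prior_stochastic,
            "posterior_painting_stochastic": post_stochastic,
            "pgls_delta_z": {k: v["delta_z"] for k, v in pgls_results.items()},
            "pgls_delta_r2": {k: v["delta_r2"] for k, v in pgls_results.items()},
            "pgls_tps_r2_posterior": {
                k: float(v["posterior"].term("TPS")["R2"]) for k, v in pgls_results.items()
            },
            "signal": signal_rows,
            "best_model": best_name,
            "best_model_set": best_set,
            "model_aicw": {n: fits[n].aicw for n, _, _ in model_specs},
            "adequacy_all_inside": adequacy.adequate,
            "adequacy_fraction_inside": float(adequacy.table["inside"].mean()),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def run_taxa_removal(config: RunConfig, inputs=None) -> dict:
    """The estimated-taxa-removal rerun: prune → re-GPA → re-ordinate → refit."""
    cfg = RunConfig(**{**asdict(config), "estimated_taxa_removal": True,
                       "out_dir": str(Path(config.out_dir))})
    return run_full(cfg, inputs=inputs)
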