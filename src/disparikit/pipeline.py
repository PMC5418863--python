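"""End-to-end study workflow: from five input tables (or a synthetic study)
to the full set of analysis stage outputs.

Stages, in order: size correction and femur ratio; phylogenetic PCA of
locomotory traits; Procrustes alignment of head landmarks, species mean
shapes, tangent PCA, allometry check; phylogenetic signal (Pagel's lambda)
per focal variable; substrate phylogenetic ANOVAs (all taxa and a taxon
subset) and PGLS of each variable on ecological specialization (PDI);
disparity-through-time with MDI; node-height tests; and the four-model
comparison (BM/EB/OU1/OUMV over stochastic regime maps) per variable.

Every stage writes a TSV and/or JSON file into the output directory and all
randomness flows from one root seed through named child streams, so reruns
with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparative import pagel_lambda, pdi, pgls, phylo_anova, phylo_pca
from .disparity import dtt, node_height_test, phylomorphospace
from .models import compare_models
from .morpho import (
    LandmarkSet,
    femur_ratio,
    gpa,
    allometry_test,
    read_landmarks,
    size_correct,
    species_mean_shapes,
    tangent_pca,
)
from .simulate import make_study, stream
from .tree import Phylogeny, load_newick, prune_to_subset, write_newick

log = logging.getLogger("disparikit")

__all__ = ["PipelineConfig", "run_pipeline", "prune_to_subset", "load_inputs"]


@dataclass
class PipelineConfig:
    """Study configuration: either five input paths or a synthetic block."""

    seed: int = 0
    output_dir: str = "disparikit_out"
    inputs: dict | None = None  # keys: tree, traits, landmarks, guilds, habitats
    synthetic: dict | None = None  # kwargs for simulate.make_study
    n_sim_anova: int = 10000
    n_sim_dtt: int = 1000
    n_maps: int = 500
    taxon_subset: list | str | None = None  # labels, or "auto" (largest ~half clade)
    filled_defaults: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "filled_defaults"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.filled_defaults = sorted(known - set(d))
        if (cfg.inputs is None) == (cfg.synthetic is None):
            raise ValueError("config needs exactly one of 'inputs' or 'synthetic'")
        for name in ("n_sim_anova", "n_sim_dtt", "n_maps"):
            if getattr(cfg, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_inputs(paths: dict):
    """Read the five input files and reconcile their species sets.

    Species present in some inputs but not all are dropped with a logged
    warning (intersection semantics).
    """
    tree = load_newick(paths["tree"])
    traits = pd.read_csv(paths["traits"], sep="\t", index_col=0)
    landmarks = read_landmarks(paths["landmarks"])
    guilds = pd.read_csv(paths["guilds"], sep="\t", index_col=0).iloc[:, 0]
    habitats = pd.read_csv(paths["habitats"], sep="\t", index_col=0)
    bad = ~habitats.isin(range(4)).all(axis=None)
    if bad:
        raise ValueError("habitat matrix entries must be integers 0-3")
    common = (set(tree.tip_labels) & set(traits.index) & set(guilds.index)
              & set(habitats.index) & set(landmarks.species))
    dropped = set(tree.tip_labels) - common
    if dropped:
        log.warning("dropping %d species absent from some inputs: %s",
                    len(dropped), sorted(dropped))
        tree = prune_to_subset(tree, sorted(common))
    keep = sorted(common)
    traits = traits.loc[keep]
    guilds = guilds.loc[keep]
    habitats = habitats.loc[keep]
    mask = [sp in common for sp in landmarks.species]
    landmarks = LandmarkSet(
        [i for i, m in zip(landmarks.specimen_ids, mask) if m],
        [s for s, m in zip(landmarks.species, mask) if m],
        landmarks.coords[np.asarray(mask)],
        None if landmarks.scale is None else landmarks.scale[np.asarray(mask)],
    )
    return tree, traits, landmarks, guilds, habitats


def _auto_subset(tree: Phylogeny) -> list[str]:
    """Largest proper clade closest to half the tips (a stand-in subfamily)."""
    target = tree.n_tips / 2
    best, best_score = None, np.inf
    for node in range(tree.n_tips, tree.n_nodes):
        if node == tree.root:
            continue
        tips = tree.clade_tips[node]
        score = abs(len(tips) - target)
        if 3 <= len(tips) < tree.n_tips and score < best_score:
            best, best_score = tips, score
    return [tree.tip_labels[i] for i in best]


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", float_format="%.10g")


def _write_json(obj, path: Path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns a dict of in-memory stage results.

    Stage outputs are written incrementally, so a failing stage leaves the
    completed ones on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}

    def stage(name):
        log.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # ---------------------------------------------------------------- inputs
    with stage("load"):
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", seed)
            study = make_study(**syn)
            tree, traits, landmarks = study.tree, study.traits, study.landmarks
            guilds, habitats = study.guilds, study.habitats
            (out / "synthetic_tree.nwk").write_text(write_newick(tree) + "\n")
        else:
            tree, traits, landmarks, guilds, habitats = load_inputs(config.inputs)
        results["tree"] = tree

    # ------------------------------------------------- linear-trait pipeline
    with stage("size_correction"):
        body = traits["body_length"]
        rel = pd.DataFrame({
            "rel_tibia": size_correct(traits["tibia_length"], body),
            "femur_ratio": femur_ratio(traits["femur_width"],
                                       traits["femur_length"]),
            "rel_tegmina": size_correct(traits["tegmina_length"], body),
            "rel_antenna": size_correct(traits["antenna_length"], body),
        })
        rel.index.name = "species"
        _write_tsv(rel, out / "traits_relative.tsv")
        results["relative_traits"] = rel

    with stage("ppca_locomotory"):
        loco = rel[["rel_tibia", "femur_ratio", "rel_tegmina"]]
        pp = phylo_pca(tree, loco)
        ppc_lm = pp.scores["pPC1"].rename("pPClm")
        _write_tsv(pp.scores.join(ppc_lm), out / "ppca_locomotory.tsv")
        # ordinary (non-phylogenetic) PCA cross-check of the first axis
        plain = tangent_pca(loco.loc[tree.tip_labels])
        corr = float(np.corrcoef(ppc_lm.loc[tree.tip_labels],
                                 plain.scores["PC1"])[0, 1])
        _write_json({
            "var_prop": list(pp.var_prop),
            "loadings": pp.loadings.to_dict(),
            "pc1_var_pct": 100.0 * pp.var_prop[0],
            "corr_ppca_vs_pca": corr,
        }, out / "ppca_locomotory.json")
        results["ppca"] = pp
        results["pPClm"] = ppc_lm

    # -------------------------------------------------------- head shape GPA
    with stage("head_shape"):
        aligned = gpa(landmarks)
        means, mean_cs = species_mean_shapes(aligned)
        _write_tsv(means, out / "head_mean_shapes.tsv")
        spca = tangent_pca(means)
        _write_tsv(spca.scores, out / "head_pca.tsv")
        _write_json({
            "var_prop": list(spca.var_prop),
            "pc12_var_pct": 100.0 * float(spca.var_prop[:2].sum()),
        }, out / "head_pca.json")
        allo = allometry_test(means, mean_cs, n_perm=999,
                              rng=stream(seed, "allometry"))
        _write_json(allo, out / "allometry.json")
        results["head_pca"] = spca
        results["PChs"] = spca.scores["PC1"].rename("PChs")
        results["PChs2"] = spca.scores["PC2"].rename("PChs2")
        results["allometry"] = allo

    focal = {
        "rel_antenna": rel["rel_antenna"],
        "pPClm": results["pPClm"],
        "PChs": results["PChs"],
        "PChs2": results["PChs2"],
    }

    # ----------------------------------------------------- phylogenetic signal
    with stage("phylo_signal"):
        rows = []
        for name, var in focal.items():
            r = pagel_lambda(tree, var)
            rows.append({"variable": name, "lambda": r.lambda_hat,
                         "loglik": r.loglik, "p_value": r.p_value})
        signal = pd.DataFrame(rows).set_index("variable")
        _write_tsv(signal, out / "phylo_signal.tsv")
        results["phylo_signal"] = signal

    # -------------------------------------------------------------- subset
    with stage("subset"):
        if config.taxon_subset == "auto" or (
                config.taxon_subset is None and config.synthetic is not None):
            subset_labels = _auto_subset(tree)
        elif config.taxon_subset:
            subset_labels = list(config.taxon_subset)
        else:
            subset_labels = None
        if subset_labels is not None:
            subtree = prune_to_subset(tree, subset_labels)
            (out / "subset_tree.nwk").write_text(write_newick(subtree) + "\n")
        else:
            subtree = None
        results["subset_labels"] = subset_labels

    # ------------------------------------------------------ ecology associations
    with stage("substrate_anova"):
        anova_vars = ["rel_antenna", "pPClm", "PChs"]
        rows = []
        for name in anova_vars:
            var = focal[name]
            r = phylo_anova(tree, var, guilds, n_sim=config.n_sim_anova,
                            rng=stream(seed, f"anova_{name}"))
            rows.append({"variable": name, "scope": "all", "F": r.f_observed,
                         "p_standard": r.p_standard, "phylo_p": r.p_phylo,
                         "n_sim": r.n_sim})
            if subtree is not None:
                sub_groups = guilds.loc[subtree.tip_labels]
                if sub_groups.nunique() > 1 and sub_groups.value_counts().min() >= 2:
                    rs = phylo_anova(subtree, var.loc[subtree.tip_labels],
                                     sub_groups, n_sim=config.n_sim_anova,
                                     rng=stream(seed, f"anova_sub_{name}"))
                    rows.append({"variable": name, "scope": "subset",
                                 "F": rs.f_observed,
                                 "p_standard": rs.p_standard,
                                 "phylo_p": rs.p_phylo, "n_sim": rs.n_sim})
        anova = pd.DataFrame(rows).set_index(["variable", "scope"])
        _write_tsv(anova, out / "substrate_anova.tsv")
        results["substrate_anova"] = anova

    with stage("pgls_pdi"):
        spec_index = pdi(habitats)
        rows = []
        for name in ["rel_antenna", "pPClm", "PChs"]:
            r = pgls(tree, focal[name], spec_index.to_frame("pdi"))
            rows.append({
                "variable": name,
                "slope": r.coefficients["pdi"],
                "se": r.std_errors["pdi"],
                "t": r.t_values["pdi"],
                "p_value": r.p_values["pdi"],
                "lambda": r.lambda_hat,
            })
        pgls_tab = pd.DataFrame(rows).set_index("variable")
        _write_tsv(pgls_tab, out / "pgls_pdi.tsv")
        results["pdi"] = spec_index
        results["pgls_pdi"] = pgls_tab

    # ------------------------------------------------------------- disparity
    with stage("dtt"):
        mdi_summary = {}
        for name in ["rel_antenna", "pPClm", "PChs"]:
            var = focal[name]
            r = dtt(tree, var, n_sim=config.n_sim_dtt,
                    rng=stream(seed, f"dtt_{name}"))
            _write_tsv(r.to_frame().set_index("relative_time"),
                       out / f"dtt_{name}.tsv")
            mdi_summary[name] = {"mdi": r.mdi, "p": r.p_mdi, "n_sim": r.n_sim}
            if subtree is not None:
                rs = dtt(subtree, var.loc[subtree.tip_labels],
                         n_sim=config.n_sim_dtt,
                         rng=stream(seed, f"dtt_sub_{name}"))
                _write_tsv(rs.to_frame().set_index("relative_time"),
                           out / f"dtt_{name}_subset.tsv")
                mdi_summary[f"{name}_subset"] = {
                    "mdi": rs.mdi, "p": rs.p_mdi, "n_sim": rs.n_sim}
        _write_json(mdi_summary, out / "mdi.json")
        results["mdi"] = mdi_summary

    with stage("node_height"):
        rows = []
        for name, var in focal.items():
            r = node_height_test(tree, var)
            rows.append({"variable": name, "slope": r.slope, "se": r.std_error,
                         "t": r.t_value, "p_value": r.p_value,
                         "n_contrasts": r.n_contrasts})
        nh = pd.DataFrame(rows).set_index("variable")
        _write_tsv(nh, out / "node_height.tsv")
        results["node_height"] = nh

    with stage("phylomorphospace"):
        pms = phylomorphospace(
            tree, pd.DataFrame({"PChs": focal["PChs"], "pPClm": focal["pPClm"]}))
        _write_tsv(pms["nodes"].set_index("node"),
                   out / "phylomorphospace_nodes.tsv")
        _write_tsv(pms["edges"].set_index("child"),
                   out / "phylomorphospace_edges.tsv")
        results["phylomorphospace"] = pms

    # ---------------------------------------------------------- model fitting
    with stage("model_comparison"):
        comp_summary = {}
        for name in ["rel_antenna", "pPClm", "PChs"]:
            comp = compare_models(tree, focal[name], guilds,
                                  n_maps=config.n_maps,
                                  rng=stream(seed, f"models_{name}"))
            _write_tsv(comp.table, out / f"model_comparison_{name}.tsv")
            comp_summary[name] = {
                "best_model": comp.best_model,
                "aicc": comp.table["AICc"].to_dict(),
                "daicc": comp.table["dAICc"].to_dict(),
                "n_maps": comp.n_maps,
            }
            results[f"models_{name}"] = comp
        _write_json(comp_summary, out / "model_comparison.json")
        results["model_comparison"] = comp_summary

    # --------------------------------------------------------------- manifest
    with stage("manifest"):
        cfg_dict = asdict(config)
        cfg_hash = hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        _write_json({
            "seed": seed,
            "config": cfg_dict,
            "config_hash": cfg_hash,
            "filled_defaults": config.filled_defaults,
            "package_version": __version__,
            "node_height_convention": "time since root (root=0, tips=height)",
            "n_species": tree.n_tips,
        }, out / "manifest.json")

    return results
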