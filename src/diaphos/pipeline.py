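"""End-to-end orchestration: simulate/load → normalize → differential →
clustering → motifs → kinase activity → PPI modules, with a run manifest.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  The
input block either names the five input files (protein matrix, phospho
matrix, site table, kinase GMT, PPI edge list, plus a design table) or
requests a simulation with a seed, in which case the synthetic generator
provides all of them.  Outputs land in a fixed directory layout under
``outdir`` together with ``manifest.json`` recording parameter values,
seeds and input checksums, so a finished run can be audited and replayed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .errors import ConfigError, DiaphosError
from .io import (
    FeatureSetCollection,
    QuantMatrix,
    read_design,
    read_edge_list,
    read_gmt,
    read_quant_table,
    read_site_table,
    write_design,
    write_edge_list,
    write_gmt,
    write_quant_table,
    write_site_table,
)
from .normalization import protein_normalize, total_normalize
from .differential import Thresholds, all_contrasts, compare_groups
from .clustering import assign_clusters, fuzzy_cmeans, prepare_profiles
from .motifs import extract_windows, motif_x
from .kinase import activities_frame, build_ks_network, build_site_ranks, kinase_activity_scores
from .network import build_subnetwork, mcode_modules, modules_frame
from .synthetic import SimulationConfig, generate_dataset, generate_kinase_substrate_map, generate_ppi

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "qc_summary"]


class PipelineError(DiaphosError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str = "diaphos_run"
    # either a simulation block ...
    simulate: dict | None = None  # kwargs for SimulationConfig
    # ... or explicit input paths
    protein_path: str | None = None
    phospho_path: str | None = None
    site_path: str | None = None
    design_path: str | None = None
    kinase_gmt_path: str | None = None
    ppi_path: str | None = None
    # stage parameters
    up_threshold: float = 1.3
    down_threshold: float = 0.77
    alpha: float = 0.05
    extreme_fold: float = 5.0
    cluster_c: int = 6
    cluster_m: float = 2.0
    cluster_min_sd: float = 0.4
    cluster_seed: int = 0
    motif_p_cutoff: float = 1e-6
    motif_min_occurrences: int = 20
    ksea_n_perm: int = 1000
    ksea_seed: int = 0
    ksea_min_set_size: int = 3
    ppi_min_confidence: float = 0.7
    mcode_vwp: float = 0.2
    mcode_min_size: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            required = {
                "protein matrix": self.protein_path,
                "phospho matrix": self.phospho_path,
                "site table": self.site_path,
                "design table": self.design_path,
            }
            missing = [name for name, path in required.items() if path is None]
            if missing:
                raise ConfigError(f"missing input(s): {', '.join(missing)} (no simulation block)")
            for name, path in required.items():
                if not Path(path).exists():
                    raise ConfigError(f"{name} file not found: {path}")
            for name, path in (("kinase GMT", self.kinase_gmt_path), ("PPI edges", self.ppi_path)):
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{name} file not found: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _slug(contrast: str) -> str:
    return contrast.replace("/", "_over_")


def qc_summary(protein: QuantMatrix, phospho: QuantMatrix, sites=None) -> dict:
    """Sample-level quality control of the two matrices.

    Returns, per matrix, the sample–sample Pearson correlation matrix of
    log2 values and the first two principal-component coordinates of the
    samples, plus the count of proteins quantified in both matrices (the
    phosphoprotein/proteome overlap).
    """
    out: dict = {}
    for name, matrix in (("protein", protein), ("phospho", phospho)):
        log = matrix.log2().values
        corr = log.corr(method="pearson")
        centered = log.T - log.T.mean(axis=0)
        coords = PCA(n_components=2, svd_solver="full").fit_transform(centered)
        out[name] = {
            "correlation": corr,
            "pca": pd.DataFrame(coords, index=log.columns, columns=["PC1", "PC2"]),
        }
    if sites is not None:
        phospho_proteins = {s.protein_id for s in sites if s.site_id in set(phospho.feature_ids)}
        out["overlap"] = len(phospho_proteins & set(protein.feature_ids))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the artifact bundle under ``outdir``.

    Returns a dictionary of in-memory results keyed by stage.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "parameters": asdict(config), "inputs": {}, "counts": {}}
    results: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc

        return wrap

    # ---- inputs -----------------------------------------------------------
    def load_inputs():
        if config.simulate is not None:
            sim = SimulationConfig(**config.simulate)
            data = generate_dataset(sim)
            kinase_sets = (
                generate_kinase_substrate_map(sim, data.sites, data.truth)
                if data.truth.kinase_truth
                else None
            )
            edges, modules = generate_ppi(sim, data.protein.feature_ids)
            data.truth.ppi_modules = modules
            simdir = outdir / "simulated"
            simdir.mkdir(exist_ok=True)
            write_quant_table(data.protein, simdir / "protein.tsv")
            write_quant_table(data.phospho, simdir / "phospho.tsv")
            write_site_table(data.sites, simdir / "sites.tsv")
            write_design(data.protein.design, simdir / "design.tsv")
            write_edge_list(edges, simdir / "ppi.tsv")
            if kinase_sets is not None:
                write_gmt(kinase_sets, simdir / "kinases.gmt")
            data.truth.to_json(simdir / "ground_truth.json")
            manifest["inputs"]["simulation_seed"] = sim.seed
            return data.protein, data.phospho, data.sites, kinase_sets, edges, data.truth
        design = read_design(config.design_path)
        protein = read_quant_table(config.protein_path, design)
        phospho = read_quant_table(config.phospho_path, design)
        sites = read_site_table(config.site_path)
        kinase_sets = read_gmt(config.kinase_gmt_path) if config.kinase_gmt_path else None
        edges = read_edge_list(config.ppi_path) if config.ppi_path else None
        for key, path in (
            ("protein", config.protein_path),
            ("phospho", config.phospho_path),
            ("sites", config.site_path),
            ("design", config.design_path),
            ("kinase_gmt", config.kinase_gmt_path),
            ("ppi", config.ppi_path),
        ):
            if path:
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(Path(path))}
        return protein, phospho, sites, kinase_sets, edges, None

    protein, phospho, sites, kinase_sets, edges, truth = stage("inputs")(load_inputs)
    results["truth"] = truth

    # ---- normalization ----------------------------------------------------
    def normalize():
        normdir = outdir / "normalized"
        normdir.mkdir(exist_ok=True)
        protein_n, pf = total_normalize(protein)
        phospho_n, ff = total_normalize(phospho)
        phospho_adj, report = protein_normalize(phospho_n, protein_n, sites)
        write_quant_table(protein_n, normdir / "protein.tsv")
        write_quant_table(phospho_adj, normdir / "phospho_protein_normalized.tsv")
        with open(normdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "protein_scale_factors": pf.to_dict(),
                    "phospho_scale_factors": ff.to_dict(),
                    "sites_adjusted": report.n_adjusted,
                    "sites_unadjusted": report.n_unadjusted,
                },
                fh,
                indent=1,
            )
        manifest["counts"]["sites_protein_adjusted"] = report.n_adjusted
        return protein_n, phospho_adj

    protein_n, phospho_adj = stage("normalization")(normalize)
    results["normalized"] = {"protein": protein_n, "phospho": phospho_adj}

    thresholds = Thresholds(
        up_threshold=config.up_threshold,
        down_threshold=config.down_threshold,
        alpha=config.alpha,
        extreme_fold=config.extreme_fold,
    )
    contrasts = all_contrasts(protein_n.stages)

    # ---- differential -----------------------------------------------------
    def differential_stage():
        diffdir = outdir / "differential"
        diffdir.mkdir(exist_ok=True)
        out = {"protein": {}, "phospho": {}}
        for kind, matrix in (("protein", protein_n), ("phospho", phospho_adj)):
            for pair in contrasts:
                records = compare_groups(matrix, pair, thresholds)
                label = records["contrast"].iloc[0]
                out[kind][label] = records
                records.to_csv(diffdir / f"{kind}_{_slug(label)}.tsv", sep="\t")
                manifest["counts"][f"{kind}_{_slug(label)}_up"] = int((records["class"] == "up").sum())
                manifest["counts"][f"{kind}_{_slug(label)}_down"] = int(
                    (records["class"] == "down").sum()
                )
        return out

    diff = stage("differential")(differential_stage)
    results["differential"] = diff

    # ---- clustering -------------------------------------------------------
    def clustering_stage():
        clustdir = outdir / "clusters"
        clustdir.mkdir(exist_ok=True)
        out = {}
        for kind, matrix in (("protein", protein_n), ("phospho", phospho_adj)):
            profiles = prepare_profiles(matrix, min_sd=config.cluster_min_sd)
            model = fuzzy_cmeans(
                profiles, c=config.cluster_c, m=config.cluster_m, seed=config.cluster_seed
            )
            assignments = assign_clusters(model)
            model.memberships.to_csv(clustdir / f"{kind}_memberships.tsv", sep="\t")
            model.centers.to_csv(clustdir / f"{kind}_centers.tsv", sep="\t")
            assignments.to_csv(clustdir / f"{kind}_assignments.tsv", sep="\t")
            manifest["counts"][f"{kind}_profiles_clustered"] = len(profiles.profiles)
            out[kind] = {"profiles": profiles, "model": model, "assignments": assignments}
        return out

    results["clusters"] = stage("clustering")(clustering_stage)

    # ---- motifs -----------------------------------------------------------
    def motif_stage():
        motifdir = outdir / "motifs"
        motifdir.mkdir(exist_ok=True)
        out = {}
        for label, records in diff["phospho"].items():
            for direction in ("up", "down"):
                regulated = set(records.index[records["class"] == direction])
                if not regulated:
                    continue
                pairs = extract_windows(sites, regulated)
                found = []
                for central, (fg, bg) in pairs.items():
                    found.extend(
                        motif_x(
                            fg,
                            bg,
                            central=central if len(central) == 1 else "S",
                            p_cutoff=config.motif_p_cutoff,
                            min_occurrences=config.motif_min_occurrences,
                        )
                    )
                out[(label, direction)] = found
                rows = [
                    {
                        "pattern": m.pattern.render(),
                        "motif_score": m.motif_score,
                        "fold_change": m.fold_change,
                        "fg_matches": m.fg_matches,
                        "bg_matches": m.bg_matches,
                        "step_p_values": ";".join(f"{p:.3e}" for p in m.step_p_values),
                    }
                    for m in found
                ]
                pd.DataFrame(
                    rows,
                    columns=[
                        "pattern",
                        "motif_score",
                        "fold_change",
                        "fg_matches",
                        "bg_matches",
                        "step_p_values",
                    ],
                ).to_csv(motifdir / f"{_slug(label)}_{direction}.tsv", sep="\t", index=False)
        return out

    results["motifs"] = stage("motifs")(motif_stage)

    # ---- kinase activity --------------------------------------------------
    def ksea_stage():
        if kinase_sets is None:
            return {}
        kseadir = outdir / "ksea"
        kseadir.mkdir(exist_ok=True)
        out = {}
        for label, records in diff["phospho"].items():
            ranking = build_site_ranks(records)
            activities = kinase_activity_scores(
                ranking,
                kinase_sets,
                n_perm=config.ksea_n_perm,
                seed=config.ksea_seed,
                min_set_size=config.ksea_min_set_size,
            )
            frame = activities_frame(activities)
            frame.to_csv(kseadir / f"{_slug(label)}.tsv", sep="\t")
            graph = build_ks_network(activities, records, alpha=config.alpha)
            payload = {
                "nodes": [{"id": n, **graph.nodes[n]} for n in graph.nodes],
                "edges": [{"source": a, "target": b, **graph.edges[a, b]} for a, b in graph.edges],
            }
            with open(kseadir / f"{_slug(label)}_network.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)
            out[label] = {"activities": activities, "network": graph}
        return out

    results["ksea"] = stage("kinase_activity")(ksea_stage)

    # ---- PPI modules ------------------------------------------------------
    def network_stage():
        if edges is None:
            return {}
        netdir = outdir / "network"
        netdir.mkdir(exist_ok=True)
        out = {}
        for label, records in diff["protein"].items():
            selected = set(records.index[records["class"].isin(["up", "down"])])
            graph = build_subnetwork(edges, selected, min_confidence=config.ppi_min_confidence)
            modules = mcode_modules(
                graph,
                vwp=config.mcode_vwp,
                min_size=config.mcode_min_size,
            )
            modules_frame(modules).to_csv(
                netdir / f"{_slug(label)}_modules.tsv", sep="\t", index=False
            )
            manifest["counts"][f"network_{_slug(label)}_modules"] = len(modules)
            out[label] = {"graph": graph, "modules": modules}
        return out

    results["network"] = stage("ppi_modules")(network_stage)

    # ---- QC and manifest --------------------------------------------------
    def qc_stage():
        summary = qc_summary(protein_n, phospho_adj, sites)
        payload = {
            kind: {
                "correlation": summary[kind]["correlation"].round(6).to_dict(),
                "pca": summary[kind]["pca"].round(6).to_dict(),
            }
            for kind in ("protein", "phospho")
        }
        payload["overlap"] = summary.get("overlap")
        with open(outdir / "qc.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return summary

    results["qc"] = stage("qc")(qc_stage)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
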