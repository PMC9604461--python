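"""Synthetic proteome/phosphoproteome datasets with recorded ground truth.

The generator emulates a stage-resolved TMT experiment: three developmental
stages (diapause D, postdiapause PD, founder postdiapause FPD) with three
biological replicates each.  Protein log2 abundance is a feature baseline
drawn from Normal(20, 2) plus a per-stage trajectory offset plus replicate
noise; matrices are linearized by 2^x so all values are positive.
Trajectories come from six archetypes (single-step and two-step rises and
falls across the three stages); a configurable fraction of features gets a
non-flat archetype, the rest stay flat.

Phosphosites are tethered to their parent protein: a site's per-sample log2
value is the parent's value in that sample plus a constant site offset, a
site-level stage effect and the site's own replicate noise — so dividing by
the parent abundance isolates the site-level signal.  Kinase regulons are
disjoint groups of sites that receive a common log2 shift from the kinase's
activation stage onward, with the kinase's activity sign recorded; regulon
windows additionally carry a planted sequence motif.  PPI graphs consist of
planted high-confidence cliques over a sparse random background.

Everything is driven by a single seed; identical configuration gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import FeatureSetCollection, PhosphoSite, QuantMatrix

__all__ = [
    "TRAJECTORY_TEMPLATES",
    "BACKGROUND_AA_FREQ",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_dataset",
    "generate_kinase_substrate_map",
    "generate_ppi",
]

# Six trajectory archetypes over (D, PD, FPD), as log2 offsets from baseline:
# an early rise that plateaus, a sustained rise, an early fall, a late fall,
# a late rise, and a sustained fall.
TRAJECTORY_TEMPLATES: dict[str, tuple[float, ...]] = {
    "up_early": (0.0, 1.0, 1.0),
    "up_both": (0.0, 1.0, 2.0),
    "down_early": (0.0, -1.0, -1.0),
    "down_late": (0.0, 0.0, -1.0),
    "up_late": (0.0, 0.0, 1.0),
    "down_both": (0.0, -1.0, -2.0),
}
FLAT = "flat"

# Background amino-acid frequencies (SwissProt-like composition).
BACKGROUND_AA_FREQ: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}

DEFAULT_STAGES = ("D", "PD", "FPD")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    The defaults mirror the emulated study design: 3 stages × 3 biological
    replicates, log-normal abundance with replicate noise on the log2 scale,
    unit-log2 trajectory effects, and kinase regulons whose substrate sites
    co-shift by ``kinase_shift`` from the kinase's activation stage onward.
    """

    n_proteins: int = 400
    sites_per_protein: float = 2.5  # Poisson mean per protein
    n_stages: int = 3
    n_replicates: int = 3
    replicate_sd: float = 0.25  # log2 replicate noise
    de_fraction: float = 0.3  # fraction of features with a non-flat template
    n_kinases: int = 8
    regulon_size: int = 10  # substrates per kinase
    kinase_shift: float = 1.0  # log2 shift applied to substrate sites
    motif_spec: tuple[tuple[int, str], ...] = ((1, "D"), (3, "E"))
    # optional fixed activation patterns, cycled over kinases; None → random
    kinase_stages: tuple[int, ...] | None = None  # stage index ≥ 1 where the shift starts
    kinase_signs: tuple[int, ...] | None = None  # +1 activation, −1 inhibition
    ppi_module_sizes: tuple[int, ...] = (6, 5, 4)
    background_edge_prob: float = 0.01
    seed: int = 0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    site_offset_sd: float = 1.0
    protein_length: int = 300
    stage_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.sites_per_protein <= 0:
            raise ConfigError("n_proteins and sites_per_protein must be positive")
        if self.n_stages < 2 or self.n_replicates < 1:
            raise ConfigError("need n_stages ≥ 2 and n_replicates ≥ 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigError("background_edge_prob must be in [0, 1]")
        if self.replicate_sd < 0:
            raise ConfigError("replicate_sd must be non-negative")
        if self.n_kinases < 0 or self.regulon_size <= 0:
            raise ConfigError("n_kinases must be ≥ 0 and regulon_size positive")
        if self.stage_labels is not None and len(self.stage_labels) != self.n_stages:
            raise ConfigError("stage_labels length must equal n_stages")

    @property
    def stages(self) -> tuple[str, ...]:
        if self.stage_labels is not None:
            return tuple(self.stage_labels)
        if self.n_stages == len(DEFAULT_STAGES):
            return DEFAULT_STAGES
        return tuple(f"S{i + 1}" for i in range(self.n_stages))

    def templates(self) -> dict[str, tuple[float, ...]]:
        """Trajectory templates truncated/extended to n_stages."""
        if self.n_stages == 3:
            return dict(TRAJECTORY_TEMPLATES)
        out = {}
        for name, offs in TRAJECTORY_TEMPLATES.items():
            padded = list(offs[: self.n_stages])
            while len(padded) < self.n_stages:
                padded.append(padded[-1])
            out[name] = tuple(padded)
        return out


@dataclass
class GroundTruth:
    """Everything planted by the generator, for downstream verification."""

    stages: tuple[str, ...]
    protein_templates: dict[str, str]  # protein id → template name (or "flat")
    protein_stage_means: dict[str, list[float]]  # true log2 means per stage
    site_templates: dict[str, str]
    site_effects: dict[str, list[float]]  # per-stage site-level log2 effect
    kinase_truth: dict[str, dict]  # kinase → stage_index/sign/contrast/substrates
    motif_spec: tuple[tuple[int, str], ...]
    ppi_modules: list[list[str]] = field(default_factory=list)

    def site_contrast_effect(self, site_id: str, stage_a: int, stage_b: int) -> float:
        """True site-level log2 change from stage index a to b."""
        eff = self.site_effects[site_id]
        return eff[stage_b] - eff[stage_a]

    def to_json(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["motif_spec"] = [list(c) for c in self.motif_spec]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data["stages"] = tuple(data["stages"])
        data["motif_spec"] = tuple((int(o), r) for o, r in data["motif_spec"])
        return cls(**data)


@dataclass
class SimulatedDataset:
    protein: QuantMatrix
    phospho: QuantMatrix
    sites: list[PhosphoSite]
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------


def _design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        (f"{stage}_{r + 1}", stage, r + 1)
        for stage in config.stages
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows, columns=["sample", "stage", "replicate"]).set_index("sample")


def _draw_window(rng: np.random.Generator, central: str, position: int, length: int) -> str:
    aa = np.array(list(BACKGROUND_AA_FREQ))
    probs = np.array(list(BACKGROUND_AA_FREQ.values()))
    probs = probs / probs.sum()
    left_n = min(6, position - 1)
    right_n = min(6, length - position)
    flanks = rng.choice(aa, size=left_n + right_n, p=probs)
    left = "".join(flanks[:left_n])
    right = "".join(flanks[left_n:])
    return "_" * (6 - left_n) + left + central + right + "_" * (6 - right_n)


def _plant_motif(window: str, spec: Sequence[tuple[int, str]]) -> str:
    cells = list(window)
    cells[6] = "S"  # planted motifs are serine-centred
    for offset, residue in spec:
        cells[offset + 6] = residue
    return "".join(cells)


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate protein and phosphosite matrices plus their ground truth.

    Returns a bundle with two linear-scale :class:`QuantMatrix` objects
    (proteins, phosphosites), the phosphosite annotation table and a
    :class:`GroundTruth` recording every planted template, kinase regulon
    and motif.  Identical configuration (including seed) reproduces the
    output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    stages = config.stages
    design = _design(config)
    samples = list(design.index)
    stage_of = design["stage"].to_numpy()
    templates = config.templates()
    template_names = list(templates)

    # --- proteins ----------------------------------------------------------
    protein_ids = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    is_de = rng.random(config.n_proteins) < config.de_fraction
    chosen = rng.integers(0, len(template_names), config.n_proteins)
    protein_templates = {
        pid: (template_names[chosen[i]] if is_de[i] else FLAT)
        for i, pid in enumerate(protein_ids)
    }
    offsets = np.array(
        [templates.get(protein_templates[pid], (0.0,) * config.n_stages) for pid in protein_ids]
    )
    stage_index = {s: i for i, s in enumerate(stages)}
    protein_true = baselines[:, None] + offsets  # proteins × stages, log2
    col_stage = np.array([stage_index[s] for s in stage_of])
    protein_log2 = protein_true[:, col_stage] + rng.normal(
        0.0, config.replicate_sd, (config.n_proteins, len(samples))
    ) if config.replicate_sd > 0 else protein_true[:, col_stage]
    protein_values = pd.DataFrame(2.0**protein_log2, index=protein_ids, columns=samples)

    # --- phosphosites ------------------------------------------------------
    site_counts = rng.poisson(config.sites_per_protein, config.n_proteins)
    np.minimum(site_counts, config.protein_length, out=site_counts)
    site_rows: list[tuple[int, int]] = []  # (parent protein row, 1-based position)
    for i in range(config.n_proteins):
        positions = np.sort(
            rng.choice(config.protein_length, size=site_counts[i], replace=False) + 1
        )
        site_rows.extend((i, int(pos)) for pos in positions)
    n_sites = len(site_rows)
    if n_sites == 0:
        raise ConfigError("no phosphosites generated; increase sites_per_protein")

    site_parent_row = np.array([r[0] for r in site_rows])
    site_is_de = rng.random(n_sites) < config.de_fraction
    site_chosen = rng.integers(0, len(template_names), n_sites)
    site_template_list = [
        template_names[site_chosen[i]] if site_is_de[i] else FLAT for i in range(n_sites)
    ]
    site_effects = np.array(
        [templates.get(t, (0.0,) * config.n_stages) for t in site_template_list]
    )

    # --- kinase regulons (drawn from template-flat sites, disjoint) --------
    flat_site_idx = [i for i in range(n_sites) if site_template_list[i] == FLAT]
    regulon_member = np.full(n_sites, False)
    regulon_assignment: dict[int, int] = {}  # site row → kinase index
    kinase_info: list[tuple[int, int, list[int]]] = []  # (active stage, sign, member rows)
    if config.n_kinases > 0:
        needed = config.n_kinases * config.regulon_size
        if needed > len(flat_site_idx):
            raise ConfigError(
                f"regulons need {needed} template-flat sites but only "
                f"{len(flat_site_idx)} are available"
            )
        pool = rng.permutation(flat_site_idx)
        for k in range(config.n_kinases):
            members = [int(m) for m in pool[k * config.regulon_size : (k + 1) * config.regulon_size]]
            if config.kinase_stages is not None:
                active_stage = int(config.kinase_stages[k % len(config.kinase_stages)])
            else:
                active_stage = int(rng.integers(1, config.n_stages))
            if config.kinase_signs is not None:
                sign = int(config.kinase_signs[k % len(config.kinase_signs)])
            else:
                sign = int(rng.choice([-1, 1]))
            if not 1 <= active_stage < config.n_stages:
                raise ConfigError("kinase stage index must be in [1, n_stages)")
            for idx in members:
                site_effects[idx, active_stage:] += sign * config.kinase_shift
                regulon_member[idx] = True
                regulon_assignment[idx] = k
            kinase_info.append((active_stage, sign, members))

    # --- residues, ids and sequence windows --------------------------------
    aa_central = np.array(["S", "T", "Y"])
    central_probs = np.array([0.80, 0.15, 0.05])
    site_ids: list[str] = []
    sites: list[PhosphoSite] = []
    for i, (prow, pos) in enumerate(site_rows):
        pid = protein_ids[prow]
        # regulon sites are serine-centred so the planted motif is coherent
        residue = "S" if regulon_member[i] else str(rng.choice(aa_central, p=central_probs))
        window = _draw_window(rng, residue, pos, config.protein_length)
        if regulon_member[i]:
            window = _plant_motif(window, config.motif_spec)
        sid = f"{pid}_{residue}{pos}"
        site_ids.append(sid)
        sites.append(PhosphoSite(sid, pid, residue, pos, window))

    site_templates = {sid: site_template_list[i] for i, sid in enumerate(site_ids)}
    kinase_truth: dict[str, dict] = {}
    for k, (active_stage, sign, members) in enumerate(kinase_info):
        kinase_truth[f"K{k + 1:03d}"] = {
            "stage_index": active_stage,
            "sign": sign,
            "contrast": f"{stages[active_stage]}/{stages[active_stage - 1]}",
            "substrates": sorted(site_ids[i] for i in members),
        }

    # --- phospho matrix: tethered to the parent's per-sample value ---------
    site_offsets = rng.normal(0.0, config.site_offset_sd, n_sites)
    parent_log2 = protein_log2[site_parent_row]  # sites × samples
    noise = (
        rng.normal(0.0, config.replicate_sd, (n_sites, len(samples)))
        if config.replicate_sd > 0
        else 0.0
    )
    phospho_log2 = parent_log2 + site_offsets[:, None] + site_effects[:, col_stage] + noise
    phospho_values = pd.DataFrame(2.0**phospho_log2, index=site_ids, columns=samples)

    truth = GroundTruth(
        stages=stages,
        protein_templates=protein_templates,
        protein_stage_means={
            pid: list(map(float, protein_true[i])) for i, pid in enumerate(protein_ids)
        },
        site_templates=site_templates,
        site_effects={sid: list(map(float, site_effects[i])) for i, sid in enumerate(site_ids)},
        kinase_truth=kinase_truth,
        motif_spec=config.motif_spec,
    )
    return SimulatedDataset(
        protein=QuantMatrix(protein_values, design, scale="linear"),
        phospho=QuantMatrix(phospho_values, design, scale="linear"),
        sites=sites,
        truth=truth,
        config=config,
    )


def generate_kinase_substrate_map(
    config: SimulationConfig,
    sites: list[PhosphoSite],
    truth: GroundTruth,
) -> FeatureSetCollection:
    """Materialize the planted regulons as a kinase → substrate-site map."""
    known = {s.site_id for s in sites}
    if not known:
        raise ConfigError("empty site table")
    sets = {}
    for kinase, info in truth.kinase_truth.items():
        members = [s for s in info["substrates"] if s in known]
        if not members:
            raise ConfigError(f"kinase {kinase} has no substrate in the site table")
        sets[kinase] = members
    descriptions = {
        k: f"planted regulon, {info['contrast']} sign {info['sign']:+d}"
        for k, info in truth.kinase_truth.items()
    }
    return FeatureSetCollection(sets, descriptions)


def generate_ppi(
    config: SimulationConfig,
    feature_ids: Sequence[str],
    module_members: Sequence[Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """PPI edge list with planted dense modules over ``feature_ids``.

    Planted modules are cliques with confidence ~ Uniform(0.7, 1.0);
    background edges appear independently with ``background_edge_prob`` and
    confidence ~ Uniform(0.15, 0.95), so the 0.7 high-confidence filter is
    exercised in both directions.  Module memberships are disjoint; passing
    overlapping ``module_members`` explicitly is an error.
    """
    rng = np.random.default_rng([config.seed, 7])  # independent stream per artifact
    feature_ids = list(feature_ids)
    if module_members is None:
        total = sum(config.ppi_module_sizes)
        if total > len(feature_ids):
            raise ConfigError(
                f"module sizes sum to {total} but only {len(feature_ids)} features exist"
            )
        shuffled = list(rng.permutation(feature_ids))
        modules, start = [], 0
        for size in config.ppi_module_sizes:
            modules.append(sorted(shuffled[start : start + size]))
            start += size
    else:
        modules = [sorted(m) for m in module_members]
        seen: set[str] = set()
        for m in modules:
            if seen & set(m):
                raise ConfigError("module memberships overlap")
            if not set(m) <= set(feature_ids):
                raise ConfigError("module member outside feature ids")
            seen |= set(m)

    edges: dict[tuple[str, str], float] = {}
    for module in modules:
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                key = tuple(sorted((module[i], module[j])))
                edges[key] = float(rng.uniform(0.7, 1.0))

    n = len(feature_ids)
    if config.background_edge_prob > 0 and n > 1:
        draw = rng.random((n, n))
        conf = rng.uniform(0.15, 0.95, (n, n))
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((feature_ids[i], feature_ids[j])))
                if key in edges:
                    continue
                if draw[i, j] < config.background_edge_prob:
                    edges[key] = float(conf[i, j])

    frame = pd.DataFrame(
        [(a, b, c) for (a, b), c in sorted(edges.items())],
        columns=["node_a", "node_b", "confidence"],
    )
    return frame, modules
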