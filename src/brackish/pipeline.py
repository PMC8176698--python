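"""End-to-end analysis pipeline and its configuration.

Stage order mirrors the study workflow: load (or simulate) an OTU table and
metadata → rare-OTU filtering → rarefaction → core/satellite occupancy
classes → salinity-level grouping → diversity and permutation statistics →
per-level assembly diagnostics (NCM, niche breadth, C-score SES) →
per-level co-occurrence networks with topology, roles, βw, and robustness.

All configuration defaults equal the study's stated constants; scaled runs
override them explicitly. Randomness flows from a single root seed expanded
per stage by a stable hash, so one stage's draws never perturb another's.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, network as netmod
from .otu_table import (
    OtuTable,
    SampleMetadata,
    assign_salinity_levels,
    classify_occupancy,
    filter_rare_otus,
    occupancy_partition,
    rarefy,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    subset,
)
from .synthetic import (
    NeutralSimConfig,
    SelectionConfig,
    make_source_pool,
    simulate_metadata,
    simulate_selection_series,
    stable_stage_seed,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SyntheticConfig", "AnalysisReport", "run_pipeline"]


@dataclass
class SyntheticConfig:
    """In-run synthetic data bundle (used when no input table is given)."""

    S: int = 300
    N: int = 5000
    m: float = 0.1
    n_samples: int = 116
    lognormal_sigma: float = 1.5
    selection_strength: float = 2.0
    selection_sigma: float = 1.0
    salinity_profile: str = "seasonal"
    salinity_range: tuple[float, float] = (0.0, 6.1)
    cadence_days: float = 3.5


@dataclass
class PipelineConfig:
    """Every tunable of the analysis; defaults are the study's constants."""

    # inputs (None -> synthetic bundle)
    input_table: str | None = None
    input_metadata: str | None = None
    input_taxonomy: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    # filtering / rarefaction
    filter_min_samples: int = 5
    filter_min_total_reads: int = 10
    filter_mode: str = "conjunctive"
    rarefaction_depth: int = 146973
    rarefy_to_min: bool = False  # use the minimum sample total instead

    # occupancy and salinity partitioning
    core_threshold: float = 0.75
    satellite_threshold: float = 0.50
    salinity_breaks: tuple[float, float] = (0.2, 2.0)

    # permutation statistics
    n_permutations: int = 999

    # null model
    n_swap_samples: int = 30000
    swap_thin: int = 1

    # networks
    network_min_samples: int = 20
    network_min_total_reads: int = 200
    sparcc_inner_iter: int = 20
    sparcc_exclusion_rounds: int = 10
    sparcc_exclusion_threshold: float = 0.8
    sparcc_n_boot: int = 100
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    n_random_graphs: int = 1000
    robustness_fractions: tuple[float, ...] = netmod.DEFAULT_REMOVAL_FRACTIONS
    robustness_reps: int = 100
    network_subsets: tuple[str, ...] = ("all", "core", "satellite")

    # stage toggles (heavy stages can be switched off for partial runs)
    do_assembly: bool = True
    do_networks: bool = True
    do_random_graphs: bool = False

    seed: int = 0

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn:
            cfg.synthetic = SyntheticConfig(**syn)
        for name in ("salinity_breaks", "robustness_fractions", "network_subsets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.synthetic.salinity_range = tuple(cfg.synthetic.salinity_range)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Machine-readable pipeline output: a JSON-able summary plus tables."""

    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame]
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True, default=_jsonable)
        manifest = ["summary.json"]
        for name, frame in self.tables.items():
            fname = f"{name}.tsv"
            frame.to_csv(out / fname, sep="\t")
            manifest.append(fname)
        with open(out / "MANIFEST.txt", "w") as fh:
            fh.write("\n".join(manifest) + "\n")

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.summary, sort_keys=True, default=_jsonable).encode())
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv().encode())
        return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_inputs(cfg: PipelineConfig) -> tuple[OtuTable, list[SampleMetadata]]:
    if cfg.input_table is not None:
        table = read_otu_table(cfg.input_table)
        if cfg.input_taxonomy:
            table = OtuTable(table.sample_ids, table.otu_ids, table.counts,
                             read_taxonomy(cfg.input_taxonomy))
        if cfg.input_metadata is None:
            raise PipelineError("load", "input_table given without input_metadata")
        metadata = read_metadata(cfg.input_metadata)
    else:
        syn = cfg.synthetic
        seed = stable_stage_seed(cfg.seed, "synthetic")
        metadata = simulate_metadata(
            syn.n_samples, cadence=syn.cadence_days,
            salinity_profile=syn.salinity_profile,
            salinity_range=syn.salinity_range, seed=seed,
        )
        pool = make_source_pool(syn.S, syn.lognormal_sigma, seed=seed + 1)
        sim_cfg = NeutralSimConfig(S=syn.S, N=syn.N, m=syn.m,
                                   n_samples=syn.n_samples, seed=seed + 2)
        rng = np.random.default_rng(seed + 3)
        lo, hi = syn.salinity_range
        optima = rng.uniform(lo, hi, size=syn.S)
        sel = SelectionConfig(optima=optima, sigma=syn.selection_sigma,
                              strength=syn.selection_strength)
        sal = np.array([m.salinity for m in metadata])
        table = simulate_selection_series(pool, sim_cfg, sel, sal)
    tids = set(table.sample_ids)
    mids = {m.sample_id for m in metadata}
    if tids != mids:
        diff = sorted(tids ^ mids)
        raise PipelineError(
            "load", f"sample ids differ between table and metadata: {diff[:10]}"
        )
    order = {m.sample_id: m for m in metadata}
    return table, [order[s] for s in table.sample_ids]


def run_pipeline(cfg: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis; see module docstring for stage order."""
    warnings_log: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {
        "provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed},
    }

    table, metadata = _load_inputs(cfg)
    summary["input"] = {"n_samples": table.n_samples, "n_otus": table.n_otus}

    # --- filter + rarefy ---------------------------------------------
    try:
        table = filter_rare_otus(table, cfg.filter_min_samples,
                                 cfg.filter_min_total_reads, cfg.filter_mode)
        depth = (int(table.sample_totals.min()) if cfg.rarefy_to_min
                 else cfg.rarefaction_depth)
        if depth > table.sample_totals.max():
            warnings_log.append(
                f"rarefaction depth {depth} exceeds every sample total; skipped"
            )
        else:
            table = rarefy(table, depth, stable_stage_seed(cfg.seed, "rarefy"))
        present = table.occupancy() > 0
        if not present.all():
            table = subset(table, otu_ids=[o for o, k in zip(table.otu_ids, present) if k])
        metadata = [m for m in metadata if m.sample_id in set(table.sample_ids)]
    except (ValueError, KeyError) as exc:
        raise PipelineError("filter_rarefy", str(exc)) from exc
    summary["filtered"] = {"n_samples": table.n_samples, "n_otus": table.n_otus}

    # --- occupancy + salinity partitions -----------------------------
    occ = classify_occupancy(table, cfg.core_threshold, cfg.satellite_threshold)
    occ_groups = occupancy_partition(occ)
    levels = assign_salinity_levels(metadata, cfg.salinity_breaks)
    level_of = {lv.sample_id: lv.level for lv in levels}
    level_samples = {
        name: [s for s in table.sample_ids if level_of[s] == name]
        for name in ("low", "medium", "high")
    }
    summary["occupancy"] = {k: len(v) for k, v in occ_groups.items()}
    summary["salinity_levels"] = {k: len(v) for k, v in level_samples.items()}
    tables["occupancy"] = pd.DataFrame(
        [(c.otu_id, c.occupancy_fraction, c.category.value) for c in occ],
        columns=["otu_id", "occupancy_fraction", "category"],
    ).set_index("otu_id")

    # --- diversity ----------------------------------------------------
    try:
        tables["alpha_diversity"] = diversity.alpha_diversity_frame(table)
        bc = diversity.bray_curtis(table)
        groups = [level_of[s] for s in table.sample_ids]
        div_summary: dict[str, Any] = {}
        usable = {g for g in set(groups) if groups.count(g) >= 2}
        if len(usable) >= 2:
            keep = [s for s, g in zip(table.sample_ids, groups) if g in usable]
            bc_keep = diversity.bray_curtis(subset(table, sample_ids=keep))
            res = diversity.anosim(
                bc_keep, [level_of[s] for s in keep], cfg.n_permutations,
                stable_stage_seed(cfg.seed, "anosim"),
            )
            div_summary["anosim_salinity"] = {"R": res.statistic, "p": res.p_value}
        sal = np.array([m.salinity for m in metadata])
        d_sal = diversity.DistanceMatrix(
            table.sample_ids, np.abs(sal[:, None] - sal[None, :]))
        res = diversity.mantel(bc, d_sal, "pearson", cfg.n_permutations,
                               stable_stage_seed(cfg.seed, "mantel_salinity"))
        div_summary["mantel_salinity"] = {"r": res.statistic, "p": res.p_value}
        dates = [m.date for m in metadata]
        if all(d is not None for d in dates):
            t = np.array([d.toordinal() for d in dates], dtype=float)
            d_time = diversity.DistanceMatrix(
                table.sample_ids, np.abs(t[:, None] - t[None, :]))
            res = diversity.mantel(bc, d_time, "pearson", cfg.n_permutations,
                                   stable_stage_seed(cfg.seed, "mantel_time"))
            div_summary["mantel_time"] = {"r": res.statistic, "p": res.p_value}
            res = diversity.partial_mantel(
                bc, d_sal, d_time, "pearson", cfg.n_permutations,
                stable_stage_seed(cfg.seed, "partial_mantel"))
            div_summary["partial_mantel_salinity_given_time"] = {
                "r": res.statistic, "p": res.p_value}
            _, rho_abs = diversity.time_lag_analysis(bc, dates, "absolute")
            _, rho_ann = diversity.time_lag_analysis(bc, dates, "annual")
            div_summary["time_lag_spearman"] = {"absolute": rho_abs, "annual": rho_ann}
        summary["diversity"] = div_summary
    except (ValueError, KeyError) as exc:
        raise PipelineError("diversity", str(exc)) from exc

    # --- assembly per salinity level ---------------------------------
    if cfg.do_assembly:
        try:
            assembly_summary = {}
            for name, samples in level_samples.items():
                if len(samples) < 5:
                    warnings_log.append(f"assembly: level {name!r} has < 5 samples; skipped")
                    continue
                sub = subset(table, sample_ids=samples)
                keep = sub.occupancy() > 0
                sub = subset(sub, otu_ids=[o for o, k in zip(sub.otu_ids, keep) if k])
                entry: dict[str, Any] = {"n_samples": sub.n_samples, "n_otus": sub.n_otus}
                try:
                    fit = assembly.fit_ncm(sub)
                    entry["ncm"] = fit.summary()
                except (ValueError, RuntimeError) as exc:
                    warnings_log.append(f"assembly: NCM fit failed for {name!r}: {exc}")
                nb = assembly.levins_niche_breadth(sub)
                entry["mean_niche_breadth"] = nb.mean_b
                entry["mean_bcom"] = float(nb.bcom.mean())
                try:
                    ses = assembly.ses_c_score(
                        sub, n_sim=cfg.n_swap_samples, thin=cfg.swap_thin,
                        seed=stable_stage_seed(cfg.seed, f"cscore_{name}"),
                    )
                    entry["c_score"] = {
                        "c_obs": ses.c_obs, "null_mean": ses.null_mean,
                        "null_sd": ses.null_sd, "ses": ses.ses,
                        "verdict": ses.verdict,
                    }
                except ValueError as exc:
                    warnings_log.append(f"assembly: C-score failed for {name!r}: {exc}")
                assembly_summary[name] = entry
            summary["assembly"] = assembly_summary
        except (ValueError, KeyError) as exc:
            raise PipelineError("assembly", str(exc)) from exc

    # --- networks -----------------------------------------------------
    if cfg.do_networks:
        try:
            networks: dict[tuple[str, str], netmod.CorrelationNetwork] = {}
            net_summary: dict[str, Any] = {}
            for level_name, samples in level_samples.items():
                if len(samples) < 10:
                    warnings_log.append(
                        f"network: level {level_name!r} has < 10 samples; skipped")
                    continue
                for subset_name in cfg.network_subsets:
                    otus = None if subset_name == "all" else occ_groups[subset_name]
                    if otus is not None and not otus:
                        continue
                    sub = subset(table, sample_ids=samples, otu_ids=otus)
                    sub = netmod.filter_for_network(
                        sub, cfg.network_min_samples, cfg.network_min_total_reads,
                        cfg.filter_mode)
                    if sub.n_otus < 10:
                        warnings_log.append(
                            f"network: {level_name}/{subset_name} has < 10 OTUs; skipped")
                        continue
                    sd = stable_stage_seed(cfg.seed, f"sparcc_{level_name}_{subset_name}")
                    r = netmod.sparcc(
                        sub, cfg.sparcc_inner_iter, cfg.sparcc_exclusion_rounds,
                        cfg.sparcc_exclusion_threshold, sd)
                    p = netmod.sparcc_pvalues(sub, r, cfg.sparcc_n_boot, sd + 1)
                    net = netmod.build_network(r, p, cfg.r_threshold, cfg.p_threshold)
                    key = f"{level_name}_{subset_name}"
                    entry = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
                    if net.n_nodes >= 3 and net.n_edges >= 1:
                        partition = netmod.detect_modules(net)
                        topo = netmod.topology(net, partition)
                        entry["topology"] = {
                            "avg_degree": topo.avg_degree,
                            "avg_clustering": topo.avg_clustering,
                            "avg_path_length": topo.avg_path_length,
                            "modularity": topo.modularity,
                            "degree_verdict": topo.degree_fit.get("verdict"),
                        }
                        roles = netmod.zi_pi(net, partition,
                                             cfg.zi_threshold, cfg.pi_threshold)
                        entry["n_keystone"] = len(netmod.keystone_nodes(roles))
                        curve = netmod.robustness_curve(
                            net, cfg.robustness_fractions, cfg.robustness_reps,
                            seed=stable_stage_seed(cfg.seed, f"robust_{key}"))
                        tables[f"robustness_{key}"] = curve.to_frame()
                        if cfg.do_random_graphs:
                            ens = netmod.erdos_renyi_ensemble(
                                net.n_nodes, net.n_edges, cfg.n_random_graphs,
                                stable_stage_seed(cfg.seed, f"er_{key}"))
                            entry["er_null"] = {
                                "clustering_mean": float(ens.metrics["avg_clustering"].mean()),
                                "modularity_mean": float(ens.metrics["modularity"].mean()),
                            }
                        networks[(level_name, subset_name)] = net
                    net_summary[key] = entry
            # βw between salinity levels within each subset
            betaw: dict[str, float] = {}
            for subset_name in cfg.network_subsets:
                levels_present = [lv for lv in ("low", "medium", "high")
                                  if (lv, subset_name) in networks]
                for i, la in enumerate(levels_present):
                    for lb in levels_present[i + 1:]:
                        try:
                            betaw[f"{subset_name}:{la}-{lb}"] = netmod.network_dissimilarity(
                                networks[(la, subset_name)], networks[(lb, subset_name)])
                        except ValueError:
                            pass
            summary["networks"] = net_summary
            summary["network_dissimilarity"] = betaw
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            raise PipelineError("network", str(exc)) from exc

    summary["warnings"] = warnings_log
    return AnalysisReport(summary=summary, tables=tables, warnings=warnings_log)
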