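"""Config-driven orchestration of the full synthetic-data pipeline.

Stages (each writes its artifacts plus a JSON manifest with input checksums,
parameters and seeds, so deterministic stages reproduce byte-identical
output):

    simulate    -> network edge list, per-stratum expression matrices +
                   metadata, ground-truth labels, genomic intervals,
                   methylation windows, cohort tables, gene sets
    fit         -> per-stratum longitudinal fit tables
    propagate   -> per-drug diffusion subnetworks (needs fit)
    consensus   -> >=2-drug consensus network (needs propagate)
    enrich      -> hypergeometric over-representation of the consensus nodes
    methprofile -> 75-bin metagene methylation profiles + TFBS/DMR odds ratio
    mito        -> exposure series, local and macroscopic sensitivities
    clinical    -> LVEF correlations, discordance ranking, network coverage
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    clinical,
    longitudinal,
    methylation_profile,
    mitochondrial_model as mito,
    propagation,
    set_statistics,
    synthetic_data as synth,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "fit", "propagate", "consensus",
    "enrich", "methprofile", "mito", "clinical",
)

STAGE_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "fit": ("simulate",),
    "propagate": ("fit",),
    "consensus": ("propagate",),
    "enrich": ("consensus",),
    "methprofile": ("simulate",),
    "mito": ("consensus",),
    "clinical": ("consensus",),
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline parameters (defaults match the study design)."""

    outdir: str = "actnet_out"
    seed: int = 0
    # design
    times: tuple[float, ...] = synth.DEFAULT_TIMES_H
    n_reps: int = 3
    drugs: tuple[str, ...] = synth.DEFAULT_DRUGS
    doses: tuple[str, ...] = ("therapeutic",)
    layers: tuple[str, ...] = synth.LAYERS
    # synthetic network / effects
    n_nodes: int = 300
    mean_degree: float = 4.0
    n_modules: int = 1
    module_size: int = 15
    intra_module_edge_prob: float = 0.6
    affected_drugs: tuple[str, ...] = ("DOX", "EPI", "IDA")
    terminal_log2fc: float = 2.0
    noise_sd: float = 0.25
    missing_rate: float = 0.1
    # thresholds
    q_thresh: float = 0.05
    r2_thresh: float = 0.7
    min_obs: int = 10
    # propagation
    restart_prob: float = 0.4
    delta_quantiles: tuple[float, ...] = propagation.DEFAULT_DELTA_QUANTILES
    min_component_size: int = 3
    min_occurrence: int = 2
    # enrichment: background is a mandatory explicit choice
    enrichment_background: str = "network"  # "network" or "measured"
    # intervals / methylation
    n_genes: int = 60
    n_tfbs: int = 2000
    n_dmrs: int = 150
    target_odds_ratio: float = 1.0
    # mito
    mito_terminal_log2fc: dict[str, float] = field(
        default_factory=lambda: {"R1": -1.0, "R2": -0.8, "R3": -0.6, "R5": -0.5}
    )
    # clinical
    n_tox: int = 7
    n_ctrl: int = 8
    concordant_corr: float = 0.8
    discordant_corr: float = -0.3


_RANGE_CHECKS = {
    "q_thresh": (0.0, 1.0),
    "r2_thresh": (0.0, 1.0),
    "restart_prob": (0.0, 1.0),
    "missing_rate": (0.0, 1.0),
    "intra_module_edge_prob": (0.0, 1.0),
}


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected with a
    suggestion, out-of-range thresholds raise ConfigError."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)

    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    for key, (lo, hi) in _RANGE_CHECKS.items():
        if key in raw and not lo <= float(raw[key]) <= hi:
            raise ConfigError(f"{key} = {raw[key]} outside [{lo}, {hi}]")
    for key in ("times", "drugs", "doses", "layers", "delta_quantiles", "affected_drugs"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    outdir: Path, stage: str, outputs: list[Path], params: dict, seed: int,
    inputs: list[Path] | None = None,
) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in (inputs or []) if p.exists()},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _require(outdir: Path, stage: str, *files: str) -> None:
    missing = [f for f in files if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifacts {missing}; "
            f"run {STAGE_DEPENDENCIES[stage]} first"
        )


def _stratum_tag(drug: str, dose: str, layer: str) -> str:
    return f"{drug}_{dose}_{layer}"


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    rng = np.random.default_rng(cfg.seed)
    network = synth.generate_network(
        cfg.n_nodes, cfg.mean_degree, cfg.n_modules, cfg.module_size,
        cfg.intra_module_edge_prob, seed=int(rng.integers(2**31)),
    )
    synth.write_edge_list(network, outdir / "network_edges.tsv")
    truth = synth.plant_module_effects(
        network,
        affected={d: list(range(cfg.n_modules)) for d in cfg.affected_drugs},
        doses=cfg.doses,
        layers=cfg.layers,
        terminal_log2fc=cfg.terminal_log2fc,
        noise_sd=cfg.noise_sd,
        missing_rate=cfg.missing_rate,
        seed=int(rng.integers(2**31)),
        horizon_h=cfg.times[-1],
    )
    truth.to_json(outdir / "ground_truth.json")
    (outdir / "planted_modules.json").write_text(
        json.dumps({f"module_{i}": m for i, m in enumerate(network.planted_modules)})
    )
    outputs = [outdir / "network_edges.tsv", outdir / "ground_truth.json"]
    for drug in cfg.drugs:
        for dose in cfg.doses:
            for layer in cfg.layers:
                tc = synth.generate_timecourse(
                    network, truth, drug, dose, layer,
                    times=cfg.times, n_reps=cfg.n_reps,
                    seed=int(rng.integers(2**31)),
                )
                tag = _stratum_tag(drug, dose, layer)
                tc.write_tsv(outdir / f"values_{tag}.tsv", outdir / f"meta_{tag}.tsv")
                outputs += [outdir / f"values_{tag}.tsv", outdir / f"meta_{tag}.tsv"]

    intervals = synth.generate_intervals(
        cfg.n_genes, n_tfbs=cfg.n_tfbs, n_dmrs=cfg.n_dmrs,
        target_odds_ratio=cfg.target_odds_ratio, seed=int(rng.integers(2**31)),
    )
    synth.write_gene_bed12(intervals.genes, outdir / "genes.bed")
    synth.write_bed6(intervals.tfbs, outdir / "tfbs.bed")
    synth.write_bed6(intervals.dmrs, outdir / "dmrs.bed")
    (outdir / "chrom_length.json").write_text(
        json.dumps({"chrom": intervals.chrom, "length": intervals.chrom_length})
    )
    gene_expr = pd.Series(
        rng.lognormal(2.0, 1.0, size=cfg.n_genes), index=intervals.genes.gene_id
    )
    gene_expr.rename("median_abundance").to_csv(outdir / "gene_expression.tsv", sep="\t")
    classes = methylation_profile.expression_classes(gene_expr)
    meth = synth.generate_methylation_windows(
        intervals, classes, seed=int(rng.integers(2**31))
    )
    meth.to_csv(outdir / "methylation_windows.tsv", sep="\t", index=False)

    # gene sets over the network universe: each planted module plus random sets
    universe = set(network.nodes)
    sets = {
        f"planted_module_{i}": set(m) for i, m in enumerate(network.planted_modules)
    }
    set_rng = np.random.default_rng(cfg.seed + 17)
    node_list = sorted(universe)
    for i in range(10):
        size = int(set_rng.integers(10, 40))
        sets[f"random_set_{i}"] = set(set_rng.choice(node_list, size=size, replace=False))
    set_statistics.write_gmt(sets, outdir / "gene_sets.gmt")

    cohort = synth.generate_cohort(
        cfg.n_tox, cfg.n_ctrl,
        proteins=sorted(universe)[: max(50, cfg.module_size * 3)],
        concordant_corr=cfg.concordant_corr,
        discordant_corr=cfg.discordant_corr,
        seed=int(rng.integers(2**31)),
    )
    synth.write_cohort_tsv(cohort, outdir / "cohort_expression.tsv", outdir / "cohort_meta.tsv")
    (outdir / "cohort_signal_proteins.json").write_text(json.dumps(cohort.signal_proteins))

    outputs += [
        outdir / "genes.bed", outdir / "tfbs.bed", outdir / "dmrs.bed",
        outdir / "methylation_windows.tsv", outdir / "gene_sets.gmt",
        outdir / "cohort_expression.tsv", outdir / "cohort_meta.tsv",
    ]
    _write_manifest(outdir, "simulate", outputs, _public_params(cfg), cfg.seed)


def _stage_fit(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "fit", "network_edges.tsv")
    outputs = []
    for drug in cfg.drugs:
        for dose in cfg.doses:
            for layer in cfg.layers:
                tag = _stratum_tag(drug, dose, layer)
                _require(outdir, "fit", f"values_{tag}.tsv", f"meta_{tag}.tsv")
                tc = synth.OmicsTimeCourse.read_tsv(
                    outdir / f"values_{tag}.tsv", outdir / f"meta_{tag}.tsv", layer
                )
                fits = longitudinal.fit_timecourse(tc)
                longitudinal.call_dynamic_features(
                    fits, cfg.q_thresh, cfg.r2_thresh, cfg.min_obs
                )
                longitudinal.write_fit_table(fits, outdir / f"fits_{tag}.tsv")
                outputs.append(outdir / f"fits_{tag}.tsv")
    _write_manifest(outdir, "fit", outputs, _public_params(cfg), cfg.seed)


def _stage_propagate(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "propagate", "network_edges.tsv")
    graph = synth.read_edge_list(outdir / "network_edges.tsv")
    W, nodes = propagation.build_transition(graph)
    prop_cfg = propagation.PropagationConfig(
        restart_prob=cfg.restart_prob,
        delta_quantiles=cfg.delta_quantiles,
        min_component_size=cfg.min_component_size,
    )
    outputs = []
    for drug in cfg.drugs:
        for dose in cfg.doses:
            layer_scores = []
            for layer in cfg.layers:
                tag = _stratum_tag(drug, dose, layer)
                _require(outdir, "propagate", f"fits_{tag}.tsv")
                fits = longitudinal.read_fit_table(outdir / f"fits_{tag}.tsv")
                layer_scores.append(
                    propagation.score_nodes(fits, (drug, dose, layer))
                )
            scores = layer_scores[0]
            for other in layer_scores[1:]:
                scores = propagation.integrate_scores(scores, other)
            E = propagation.diffuse(W, nodes, scores, cfg.restart_prob)
            sub = propagation.extract_subnetworks(E, nodes, prop_cfg, drug, dose)
            edge_df = pd.DataFrame(sorted(sub.edges), columns=["source", "target"])
            edge_df.to_csv(outdir / f"subnetwork_{drug}_{dose}.tsv", sep="\t", index=False)
            summary = {
                "drug": drug, "dose": dose,
                "chosen_delta": sub.chosen_delta,
                "delta_candidates": list(sub.delta_candidates),
                "nodes_per_delta": {str(k): v for k, v in sub.nodes_per_delta.items()},
                "nodes": sorted(sub.nodes),
                "restart_prob": cfg.restart_prob,
                "seed": cfg.seed,
                "top_ranked": sub.node_ranking.head(25).to_dict(),
            }
            (outdir / f"subnetwork_{drug}_{dose}.json").write_text(
                json.dumps(summary, indent=1)
            )
            outputs += [
                outdir / f"subnetwork_{drug}_{dose}.tsv",
                outdir / f"subnetwork_{drug}_{dose}.json",
            ]
    _write_manifest(outdir, "propagate", outputs, _public_params(cfg), cfg.seed)


def _stage_consensus(cfg: PipelineConfig, outdir: Path) -> None:
    for dose in cfg.doses:
        subs = []
        for drug in cfg.drugs:
            _require(outdir, "consensus", f"subnetwork_{drug}_{dose}.json")
            payload = json.loads((outdir / f"subnetwork_{drug}_{dose}.json").read_text())
            edges = pd.read_csv(outdir / f"subnetwork_{drug}_{dose}.tsv", sep="\t")
            subs.append(
                propagation.DrugSubnetwork(
                    drug=drug, dose=dose,
                    nodes=set(payload["nodes"]),
                    edges=set(map(tuple, edges.to_numpy())),
                    chosen_delta=payload["chosen_delta"],
                    delta_candidates=tuple(payload["delta_candidates"]),
                )
            )
        consensus = propagation.build_consensus(subs, cfg.min_occurrence)
        node_df, edge_df = propagation.consensus_to_frames(consensus)
        node_df.to_csv(outdir / f"consensus_nodes_{dose}.tsv", sep="\t", index=False)
        edge_df.to_csv(outdir / f"consensus_edges_{dose}.tsv", sep="\t", index=False)
    _write_manifest(
        outdir, "consensus",
        [outdir / f"consensus_nodes_{d}.tsv" for d in cfg.doses]
        + [outdir / f"consensus_edges_{d}.tsv" for d in cfg.doses],
        _public_params(cfg), cfg.seed,
    )


def _consensus_nodes(cfg: PipelineConfig, outdir: Path, stage: str) -> set[str]:
    dose = cfg.doses[0]
    _require(outdir, stage, f"consensus_nodes_{dose}.tsv")
    df = pd.read_csv(outdir / f"consensus_nodes_{dose}.tsv", sep="\t")
    return set(df["node"]) if len(df) else set()


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "enrich", "gene_sets.gmt", "network_edges.tsv")
    hits = _consensus_nodes(cfg, outdir, "enrich")
    graph = synth.read_edge_list(outdir / "network_edges.tsv")
    if cfg.enrichment_background == "network":
        universe = set(graph.nodes)
    elif cfg.enrichment_background == "measured":
        dose, layer = cfg.doses[0], cfg.layers[0]
        tag = _stratum_tag(cfg.drugs[0], dose, layer)
        values = pd.read_csv(outdir / f"values_{tag}.tsv", sep="\t", index_col="feature")
        universe = set(graph.nodes) & set(values.index)
    else:
        raise ConfigError(
            f"enrichment_background must be 'network' or 'measured', "
            f"got {cfg.enrichment_background!r}"
        )
    collection = set_statistics.GeneSetCollection.from_gmt(
        outdir / "gene_sets.gmt", universe
    )
    result = set_statistics.hypergeom_ora(hits & universe, collection)
    result.to_csv(outdir / "enrichment.tsv", sep="\t")
    _write_manifest(outdir, "enrich", [outdir / "enrichment.tsv"], _public_params(cfg), cfg.seed)


def _stage_methprofile(cfg: PipelineConfig, outdir: Path) -> None:
    _require(
        outdir, "methprofile",
        "genes.bed", "tfbs.bed", "dmrs.bed", "methylation_windows.tsv",
        "gene_expression.tsv", "chrom_length.json",
    )
    genes = synth.read_gene_bed12(outdir / "genes.bed")
    expr = pd.read_csv(outdir / "gene_expression.tsv", sep="\t", index_col=0)[
        "median_abundance"
    ]
    classes = methylation_profile.expression_classes(expr)
    meth = pd.read_csv(outdir / "methylation_windows.tsv", sep="\t")
    profile = methylation_profile.metagene_profile(genes, classes, meth)
    profile.to_csv(outdir / "metagene_profile.tsv", sep="\t")

    chrom = json.loads((outdir / "chrom_length.json").read_text())
    universe = pd.DataFrame({"chrom": [chrom["chrom"]], "start": [0], "end": [chrom["length"]]})
    ratio, p = methylation_profile.tfbs_dmr_odds_ratio(
        synth.read_bed6(outdir / "dmrs.bed"),
        synth.read_bed6(outdir / "tfbs.bed"),
        universe,
        seed=cfg.seed + 23,
    )
    (outdir / "tfbs_dmr_enrichment.json").write_text(
        json.dumps({"odds_ratio": ratio, "permutation_p": p})
    )
    _write_manifest(
        outdir, "methprofile",
        [outdir / "metagene_profile.tsv", outdir / "tfbs_dmr_enrichment.json"],
        _public_params(cfg), cfg.seed,
    )


def _stage_mito(cfg: PipelineConfig, outdir: Path) -> None:
    model = mito.MitoModel()
    days = [0.0, 3.5, 7.0, 10.5, 14.0]
    results = {}
    for dose, amplitude in (("therapeutic", 0.5), ("toxic", 1.0)):
        effects = {r: fc * amplitude for r, fc in cfg.mito_terminal_log2fc.items()}
        traj = synth.generate_mito_foldchanges(
            list(mito.REACTIONS), days, effects, seed=cfg.seed
        )
        series = mito.simulate_exposure_series(model, traj, mapping={})
        series.to_csv(outdir / f"mito_series_{dose}.tsv", sep="\t", index=False)
        day7 = {r: float(traj.loc[r, 7.0]) for r in traj.index}
        macro = mito.sensitivity_macro(model, day7, mapping={})
        macro.to_csv(outdir / f"mito_macro_sensitivity_{dose}.tsv", sep="\t")
        results[dose] = {
            "atp_day14": float(series.atp_norm.iloc[-1]),
            "psi_day14": float(series.psi_norm.iloc[-1]),
        }
    local = mito.sensitivity_local(model)
    local.to_csv(outdir / "mito_local_sensitivity.tsv", sep="\t")
    (outdir / "mito_summary.json").write_text(json.dumps(results, indent=1))
    _write_manifest(
        outdir, "mito",
        [outdir / "mito_summary.json", outdir / "mito_local_sensitivity.tsv"],
        _public_params(cfg), cfg.seed,
    )


def _stage_clinical(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "clinical", "cohort_expression.tsv", "cohort_meta.tsv")
    cohort = synth.read_cohort_tsv(
        outdir / "cohort_expression.tsv", outdir / "cohort_meta.tsv"
    )
    c_tox = clinical.lvef_correlation(cohort, clinical.CARDIOTOXIC)
    c_ctrl = clinical.lvef_correlation(cohort, clinical.CONTROL)
    table = clinical.discordance(c_tox["corr"].dropna(), c_ctrl["corr"].dropna())
    table.to_csv(outdir / "lvef_discordance.tsv", sep="\t", index_label="protein")

    consensus_nodes = _consensus_nodes(cfg, outdir, "clinical")
    detected = set(cohort.expression.dropna(how="all").index)
    if consensus_nodes:
        n_cov, frac = clinical.network_coverage(consensus_nodes, detected)
    else:
        n_cov, frac = 0, float("nan")
    (outdir / "clinical_summary.json").write_text(
        json.dumps({"n_consensus": len(consensus_nodes), "n_covered": n_cov,
                    "coverage_fraction": frac})
    )
    _write_manifest(
        outdir, "clinical",
        [outdir / "lvef_discordance.tsv", outdir / "clinical_summary.json"],
        _public_params(cfg), cfg.seed,
    )


def _public_params(cfg: PipelineConfig) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "propagate": _stage_propagate,
    "consensus": _stage_consensus,
    "enrich": _stage_enrich,
    "methprofile": _stage_methprofile,
    "mito": _stage_mito,
    "clinical": _stage_clinical,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in order) and return outdir."""
    stages = list(STAGES) if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:  # canonical order regardless of request order
        if stage not in stages:
            continue
        t0 = time.time()
        _STAGE_FUNCS[stage](cfg, outdir)
        logger.info("stage %-12s done in %.1fs", stage, time.time() - t0)
    return outdir
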