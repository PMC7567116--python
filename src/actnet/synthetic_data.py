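"""Synthetic inputs with planted ground truth for the whole pipeline.

Every generator emulates one input of the drug-response network study design:

* a protein interaction network with densified "planted" response modules,
* two-layer (proteome / transcriptome) expression time courses over
  7 time points (2, 8, 24, 72, 168, 240, 336 h) x 3 replicates, treated vs
  time-matched control, with polynomial treatment effects confined to the
  planted module and missing-at-random values in the proteome layer,
* genomic intervals (gene models with 5 kb promoters, TFBS sites, DMRs) on a
  single linear synthetic chromosome with a controllable TFBS-in-DMR odds
  ratio,
* a biopsy patient cohort with planted expression-LVEF correlations, and
* smooth fold-change trajectories driving the mitochondrial model.

All generators take an explicit integer seed and are bit-reproducible; no
global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .clinical import CARDIOTOXIC, CONTROL, PatientCohort

DEFAULT_TIMES_H: tuple[float, ...] = (2.0, 8.0, 24.0, 72.0, 168.0, 240.0, 336.0)
DEFAULT_N_REPS = 3
PROTEOME = "proteome"
TRANSCRIPTOME = "transcriptome"
LAYERS = (PROTEOME, TRANSCRIPTOME)
DEFAULT_DRUGS = ("DOX", "EPI", "IDA", "DAU")


# ---------------------------------------------------------------------------
# network with planted modules
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNetwork:
    """Undirected PPI stand-in with designated true response modules."""

    graph: nx.Graph
    planted_modules: list[list[str]]
    seed: int

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def module_nodes(self, index: int = 0) -> set[str]:
        return set(self.planted_modules[index])


def generate_network(
    n_nodes: int,
    mean_degree: float,
    n_modules: int,
    module_size: int,
    intra_module_edge_prob: float,
    seed: int,
) -> SyntheticNetwork:
    """Preferential-attachment backbone plus densified planted modules.

    Module members are wired into a random cycle (guaranteeing connectivity)
    and every within-module pair is additionally linked with probability
    ``intra_module_edge_prob`` (prob 1 -> clique).
    """
    if n_modules * module_size > n_nodes:
        raise ValueError(
            f"infeasible sizes: {n_modules} modules x {module_size} > {n_nodes} nodes"
        )
    if not 0 < intra_module_edge_prob <= 1:
        raise ValueError("intra_module_edge_prob must be in (0, 1]")
    if module_size < 2 and n_modules > 0:
        raise ValueError("module_size must be >= 2")

    rng = np.random.default_rng(seed)
    m = max(1, int(round(mean_degree / 2)))
    backbone = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    mapping = {i: f"P{i:05d}" for i in backbone.nodes}
    graph = nx.relabel_nodes(backbone, mapping)

    pool = rng.permutation(n_nodes)
    modules: list[list[str]] = []
    for k in range(n_modules):
        idx = pool[k * module_size : (k + 1) * module_size]
        members = sorted(mapping[i] for i in idx)
        cycle_order = list(rng.permutation(members))
        for a, b in zip(cycle_order, cycle_order[1:] + cycle_order[:1]):
            if a != b:
                graph.add_edge(a, b)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rng.random() < intra_module_edge_prob:
                    graph.add_edge(a, b)
        modules.append(members)

    graph.remove_edges_from(nx.selfloop_edges(graph))
    return SyntheticNetwork(graph=graph, planted_modules=modules, seed=seed)


# ---------------------------------------------------------------------------
# ground truth and expression time courses
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted treatment effects: who responds, how, and how noisily.

    ``dynamic_features`` maps a (drug, dose, layer) stratum to the feature ids
    given a true treatment-vs-control effect; ``effect_coefficients`` holds the
    true (constant, linear, quadratic) terms of that effect polynomial in raw
    hours.
    """

    dynamic_features: dict[tuple[str, str, str], set[str]]
    effect_coefficients: dict[str, tuple[float, float, float]]
    noise_sd: float
    missing_rate: float

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dynamic_features": {
                "|".join(k): sorted(v) for k, v in self.dynamic_features.items()
            },
            "effect_coefficients": {
                k: list(v) for k, v in self.effect_coefficients.items()
            },
            "noise_sd": self.noise_sd,
            "missing_rate": self.missing_rate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            dynamic_features={
                tuple(k.split("|")): set(v)
                for k, v in payload["dynamic_features"].items()
            },
            effect_coefficients={
                k: tuple(v) for k, v in payload["effect_coefficients"].items()
            },
            noise_sd=payload["noise_sd"],
            missing_rate=payload["missing_rate"],
        )


def plant_module_effects(
    network: SyntheticNetwork,
    affected: dict[str, list[int]],
    doses: tuple[str, ...] = ("therapeutic",),
    layers: tuple[str, ...] = LAYERS,
    terminal_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    missing_rate: float = 0.1,
    seed: int = 0,
    horizon_h: float = DEFAULT_TIMES_H[-1],
) -> GroundTruth:
    """Build a GroundTruth giving each listed drug an effect on whole modules.

    ``affected`` maps drug -> indices of planted modules it perturbs. Effects
    are linear ramps in time reaching ``terminal_log2fc`` (sign alternating
    per feature) at the last time point, i.e. coefficients
    (0, +/-terminal_log2fc / horizon_h, 0).
    """
    rng = np.random.default_rng(seed)
    dynamic: dict[tuple[str, str, str], set[str]] = {}
    coefs: dict[str, tuple[float, float, float]] = {}
    all_members = sorted({n for mod in network.planted_modules for n in mod})
    signs = {n: (1.0 if rng.random() < 0.5 else -1.0) for n in all_members}
    for node in all_members:
        coefs[node] = (0.0, signs[node] * terminal_log2fc / horizon_h, 0.0)
    for drug, module_indices in affected.items():
        members: set[str] = set()
        for k in module_indices:
            members |= network.module_nodes(k)
        for dose in doses:
            for layer in layers:
                dynamic[(drug, dose, layer)] = set(members)
    return GroundTruth(
        dynamic_features=dynamic,
        effect_coefficients=coefs,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
    )


@dataclass
class OmicsTimeCourse:
    """One layer's feature x sample matrix with per-sample design metadata."""

    values: pd.DataFrame  # features x samples, log2 scale, NaN = missing
    sample_meta: pd.DataFrame  # sample_id, condition, time_h, replicate, drug, dose
    layer: str

    def __post_init__(self) -> None:
        meta = self.sample_meta
        required = {"condition", "time_h", "replicate"}
        if not required <= set(meta.columns):
            raise ValueError(f"sample_meta must have columns {sorted(required)}")
        if list(self.values.columns) != list(meta.index):
            raise ValueError("values columns and sample_meta index must align")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, val in conditions.items():
            mask &= self.sample_meta[col] == val
        return list(self.sample_meta.index[mask])

    def write_tsv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="feature")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(
        cls, values_path: str | Path, meta_path: str | Path, layer: str
    ) -> "OmicsTimeCourse":
        values = pd.read_csv(values_path, sep="\t", index_col="feature")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(values=values, sample_meta=meta, layer=layer)


def generate_timecourse(
    network: SyntheticNetwork,
    truth: GroundTruth,
    drug: str,
    dose: str,
    layer: str,
    times: tuple[float, ...] = DEFAULT_TIMES_H,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    baseline_mean: float = 10.0,
    baseline_drift_sd: float = 0.3,
) -> OmicsTimeCourse:
    """Simulate one (drug, dose, layer) stratum: control + treated samples.

    Control samples follow a per-feature smooth baseline quadratic (intercept
    ~ N(baseline_mean, 2), drift terms scaled so the full-course excursion has
    SD ``baseline_drift_sd`` log2 units) plus Gaussian noise. Treated samples
    add the true treatment-vs-control polynomial for the stratum's dynamic
    features. The proteome layer is thinned completely at random at
    ``truth.missing_rate``.
    """
    times = tuple(float(t) for t in times)
    if any(t <= 0 for t in times):
        raise ValueError("times must be positive hours")
    if list(times) != sorted(set(times)):
        raise ValueError("times must be strictly increasing")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")

    rng = np.random.default_rng(seed)
    features = network.nodes
    n_feat = len(features)
    horizon = times[-1]

    # smooth nontrivial baselines: y0 + a*t + b*t^2 in raw hours
    b0 = rng.normal(baseline_mean, 2.0, size=n_feat)
    b1 = rng.normal(0.0, baseline_drift_sd / horizon, size=n_feat)
    b2 = rng.normal(0.0, baseline_drift_sd / horizon**2, size=n_feat)

    dynamic = truth.dynamic_features.get((drug, dose, layer), set())
    e0 = np.zeros(n_feat)
    e1 = np.zeros(n_feat)
    e2 = np.zeros(n_feat)
    for i, f in enumerate(features):
        if f in dynamic:
            c = truth.effect_coefficients[f]
            e0[i], e1[i], e2[i] = c

    sample_ids, conditions, time_col, rep_col = [], [], [], []
    columns = {}
    for condition in ("C", "T"):
        for t in times:
            for r in range(1, n_reps + 1):
                sid = f"{drug}_{dose}_{layer}_{condition}_t{int(t)}_r{r}"
                mean = b0 + b1 * t + b2 * t**2
                if condition == "T":
                    mean = mean + e0 + e1 * t + e2 * t**2
                columns[sid] = mean + rng.normal(0.0, truth.noise_sd, size=n_feat)
                sample_ids.append(sid)
                conditions.append(condition)
                time_col.append(t)
                rep_col.append(r)

    values = pd.DataFrame(columns, index=features)
    if layer == PROTEOME and truth.missing_rate > 0:
        mask = rng.random(values.shape) < truth.missing_rate
        values = values.mask(mask)

    meta = pd.DataFrame(
        {
            "condition": conditions,
            "time_h": time_col,
            "replicate": rep_col,
            "drug": drug,
            "dose": dose,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return OmicsTimeCourse(values=values, sample_meta=meta, layer=layer)


# ---------------------------------------------------------------------------
# genomic intervals on a synthetic chromosome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticIntervals:
    """Gene models, TFBS sites and DMRs on one linear chromosome (0-based,
    half-open, + strand)."""

    genes: pd.DataFrame  # gene_id, chrom, tss, tts
    tfbs: pd.DataFrame  # chrom, start, end, name
    dmrs: pd.DataFrame  # chrom, start, end, name
    chrom_length: int
    chrom: str = "chrS"


def generate_intervals(
    n_genes: int,
    gene_length_range: tuple[int, int] = (5_000, 20_000),
    n_tfbs: int = 1_000,
    n_dmrs: int = 200,
    target_odds_ratio: float = 1.0,
    seed: int = 0,
    dmr_length: int = 500,
    tfbs_length: int = 10,
    intergenic_gap: int = 2_000,
    promoter_length: int = 5_000,
) -> SyntheticIntervals:
    """Place non-overlapping gene bodies, DMRs, and TFBS on one chromosome.

    TFBS midpoints fall inside DMRs with probability ``target_odds_ratio *
    dmr_fraction`` so that the expected observed/expected site-count odds
    ratio equals ``target_odds_ratio`` under the bp-fraction expectation.
    """
    if target_odds_ratio <= 0:
        raise ValueError("target_odds_ratio must be > 0")
    lo, hi = gene_length_range
    if lo < 2_000 or hi < lo:
        raise ValueError("gene_length_range must satisfy 2000 <= lo <= hi")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    genes = []
    cursor = promoter_length  # keep the first promoter on-chromosome
    for g, length in enumerate(lengths):
        tss = cursor
        tts = tss + int(length)
        genes.append((f"G{g:05d}", tss, tts))
        cursor = tts + intergenic_gap + promoter_length
    chrom_length = cursor + 10_000
    genes_df = pd.DataFrame(genes, columns=["gene_id", "tss", "tts"])
    genes_df.insert(1, "chrom", "chrS")

    # non-overlapping DMRs on a regular lattice of candidate slots
    n_slots = chrom_length // (2 * dmr_length)
    if n_dmrs > n_slots:
        raise ValueError("chromosome too small to host the requested DMRs")
    slots = rng.choice(n_slots, size=n_dmrs, replace=False)
    slots.sort()
    dmr_starts = slots * 2 * dmr_length
    dmrs_df = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": dmr_starts,
            "end": dmr_starts + dmr_length,
            "name": [f"DMR{i:05d}" for i in range(n_dmrs)],
        }
    )

    dmr_fraction = n_dmrs * dmr_length / chrom_length
    p_in = target_odds_ratio * dmr_fraction
    if p_in > 1:
        raise ValueError(
            f"target_odds_ratio {target_odds_ratio} infeasible: DMR fraction "
            f"{dmr_fraction:.4f} gives in-DMR probability > 1"
        )
    in_dmr = rng.random(n_tfbs) < p_in
    mids = np.empty(n_tfbs, dtype=np.int64)
    # uniform over DMR bp for the in-DMR sites, uniform over the rest otherwise
    n_in = int(in_dmr.sum())
    if n_in:
        which = rng.integers(0, n_dmrs, size=n_in)
        offset = rng.integers(0, dmr_length, size=n_in)
        mids[in_dmr] = dmr_starts[which] + offset
    n_out = n_tfbs - n_in
    if n_out:
        out_mids = np.empty(n_out, dtype=np.int64)
        filled = 0
        while filled < n_out:
            cand = rng.integers(0, chrom_length, size=2 * (n_out - filled))
            slot = cand // (2 * dmr_length)
            within = cand - slot * 2 * dmr_length
            ok = ~(np.isin(slot, slots) & (within < dmr_length))
            take = cand[ok][: n_out - filled]
            out_mids[filled : filled + len(take)] = take
            filled += len(take)
        mids[~in_dmr] = out_mids
    starts = np.clip(mids - tfbs_length // 2, 0, chrom_length - tfbs_length)
    tfbs_df = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + tfbs_length,
            "name": [f"TFBS{i:06d}" for i in range(n_tfbs)],
        }
    )
    return SyntheticIntervals(
        genes=genes_df, tfbs=tfbs_df, dmrs=dmrs_df, chrom_length=chrom_length
    )


def generate_methylation_windows(
    intervals: SyntheticIntervals,
    classes: pd.Series,
    n_timepoints: int = 7,
    window_size: int = 250,
    base_pct: float = 80.0,
    class_step: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tile the chromosome with %-methylation windows inversely related to
    expression class inside gene bodies (class k body methylation
    ~ base_pct - class_step*k), background at ``base_pct`` elsewhere.

    Returns a DataFrame (chrom, start, end, t1..t{n_timepoints}).
    """
    rng = np.random.default_rng(seed)
    n_windows = intervals.chrom_length // window_size
    starts = np.arange(n_windows) * window_size
    level = np.full(n_windows, base_pct)
    for _, gene in intervals.genes.iterrows():
        k = int(classes[gene.gene_id])
        w0, w1 = gene.tss // window_size, -(-gene.tts // window_size)
        level[w0:w1] = base_pct - class_step * k
    out = pd.DataFrame({"chrom": intervals.chrom, "start": starts, "end": starts + window_size})
    for t in range(1, n_timepoints + 1):
        out[f"t{t}"] = np.clip(level + rng.normal(0, noise_sd, size=n_windows), 0, 100)
    return out


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    n_tox: int = 7,
    n_ctrl: int = 8,
    proteins: list[str] | None = None,
    concordant_corr: float = 0.8,
    discordant_corr: float = -0.3,
    seed: int = 0,
    n_signal: int | None = None,
    lvef_mean: float = 35.0,
    lvef_sd: float = 8.0,
) -> PatientCohort:
    """Biopsy cohort with planted expression-LVEF correlations.

    A designated protein subset (the first ``n_signal`` ids, default one fifth
    of the panel) is drawn jointly bivariate-normal with LVEF at correlation
    ``concordant_corr`` within the cardiotoxic group and ``discordant_corr``
    within the control group. Therapy duration is anti-correlated with LVEF in
    the cardiotoxic group.
    """
    if n_tox < 3 or n_ctrl < 3:
        raise ValueError("need at least 3 patients per group")
    for c in (concordant_corr, discordant_corr):
        if abs(c) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if proteins is None:
        proteins = [f"BP{i:04d}" for i in range(50)]
    if n_signal is None:
        n_signal = max(1, len(proteins) // 5)
    signal = list(proteins[:n_signal])

    rng = np.random.default_rng(seed)
    patients = [f"TOX{i:02d}" for i in range(n_tox)] + [
        f"CTL{i:02d}" for i in range(n_ctrl)
    ]
    group = pd.Series(
        [CARDIOTOXIC] * n_tox + [CONTROL] * n_ctrl, index=patients, name="group"
    )
    lvef_raw = rng.normal(lvef_mean, lvef_sd, size=len(patients))
    lvef = pd.Series(np.clip(lvef_raw, 5.0, 80.0), index=patients, name="lvef")
    # population-standardized LVEF keeps (expression, LVEF) jointly normal
    z = (lvef_raw - lvef_mean) / lvef_sd

    expr = np.empty((len(proteins), len(patients)))
    is_tox = np.array([g == CARDIOTOXIC for g in group])
    for i, protein in enumerate(proteins):
        eps = rng.normal(0.0, 1.0, size=len(patients))
        if protein in signal:
            rho = np.where(is_tox, concordant_corr, discordant_corr)
            expr[i] = rho * z + np.sqrt(1 - rho**2) * eps
        else:
            expr[i] = eps
    expression = pd.DataFrame(10.0 + expr, index=proteins, columns=patients)

    therapy = pd.Series(np.nan, index=patients, name="therapy_days")
    therapy[is_tox] = np.clip(
        400.0 - 150.0 * z[is_tox] + rng.normal(0, 60.0, size=n_tox), 30.0, None
    )
    return PatientCohort(
        expression=expression,
        lvef=lvef,
        group=group,
        therapy_days=therapy,
        signal_proteins=signal,
    )


# ---------------------------------------------------------------------------
# fold-change trajectories for the mitochondrial model
# ---------------------------------------------------------------------------

def generate_mito_foldchanges(
    reactions: list[str],
    times_days: list[float],
    drug_effect: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Smooth monotone fold-change trajectories from 1 at day 0 to
    2**terminal_log2fc at day 14.

    The trajectory is fc_r(t) = 2**(L_r * s(t/14)) with the cubic smoothstep
    s(x) = x^2 (3 - 2x); it is deterministic (the seed parameter is accepted
    for protocol uniformity but unused — the required monotone smooth shape
    leaves no randomness to inject).
    """
    del seed
    times = [float(t) for t in times_days]
    if any(t < 0 or t > 14 for t in times):
        raise ValueError("times must lie within [0, 14] days")
    if times != sorted(times):
        raise ValueError("times must be non-decreasing")
    x = np.array(times) / 14.0
    s = x * x * (3.0 - 2.0 * x)
    data = {}
    for r in reactions:
        log2fc = float(drug_effect.get(r, 0.0))
        traj = np.power(2.0, log2fc * s)
        if np.any(traj <= 0):
            raise ValueError(f"nonpositive fold change for reaction {r}")
        data[r] = traj
    out = pd.DataFrame(data, index=pd.Index(times, name="day")).T
    out.index.name = "reaction"
    return out


# ---------------------------------------------------------------------------
# writers for the on-disk formats the pipeline reads
# ---------------------------------------------------------------------------

def write_edge_list(network: SyntheticNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    graph.add_edges_from(df.itertuples(index=False, name=None))
    return graph


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["chrom", "start", "end", "name"]].copy()
    out["score"] = 0
    out["strand"] = "+"
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )


def write_gene_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Gene models as single-block BED12 (+ strand, thick region = body)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            size = g.tts - g.tss
            fh.write(
                f"{g.chrom}\t{g.tss}\t{g.tts}\t{g.gene_id}\t0\t+\t"
                f"{g.tss}\t{g.tts}\t0\t1\t{size},\t0,\n"
            )


def read_gene_bed12(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None)
    return pd.DataFrame(
        {
            "gene_id": raw[3],
            "chrom": raw[0],
            "tss": raw[1].astype(int),
            "tts": raw[2].astype(int),
        }
    )


def write_cohort_tsv(cohort: PatientCohort, expr_path: str | Path, meta_path: str | Path) -> None:
    cohort.expression.to_csv(expr_path, sep="\t", index_label="protein")
    meta = pd.DataFrame(
        {
            "group": cohort.group,
            "lvef": cohort.lvef,
            "therapy_days": cohort.therapy_days,
        }
    )
    meta.to_csv(meta_path, sep="\t", index_label="patient_id")


def read_cohort_tsv(
    expr_path: str | Path, meta_path: str | Path, signal_proteins: list[str] | None = None
) -> PatientCohort:
    expression = pd.read_csv(expr_path, sep="\t", index_col="protein")
    meta = pd.read_csv(meta_path, sep="\t", index_col="patient_id")
    return PatientCohort(
        expression=expression,
        lvef=meta["lvef"],
        group=meta["group"],
        therapy_days=meta["therapy_days"],
        signal_proteins=signal_proteins or [],
    )
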