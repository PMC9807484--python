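"""Synthetic corpora, interaction ledgers and pathway graphs with planted truth.

The generator emulates the statistical structure the analysis assumes: each
substudy contributes per-microRNA binomial dysregulation events in case and
control arms; for an effect microRNA the case-arm event probability is
shifted on the logit scale by a substudy-specific draw around the planted
logOR (between-substudy SD ``tau_between``), so the population logOR of the
event indicator equals the planted effect.  Sample sizes are log-normal and
truncated; tissue, blood-fraction and platform strata are sampled from
configurable mixes; an optional censoring rule suppresses small-effect
substudies of null microRNAs to induce funnel asymmetry (selective
reporting).  Interaction ledgers plant robust support for effect-microRNA
targets amid decoys that each fail one clause of the robustness rule, and
pathway generation wires the planted targets into a connected signed DAG
with matched null pathways.

Three independent RNG streams are derived from the master seed (corpus,
interaction DB, pathways) so each artefact can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .corpus import MicroRNAName, StudyCorpus, SubStudyRecord
from .impact import PathwayGraph
from .interactions import InteractionRecord

import networkx as nx


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass
class SimulationConfig:
    seed: int  # mandatory master seed
    n_mirnas: int = 50
    n_studies: int = 40
    substudies_per_study: Mapping[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    sample_size_median: float = 50.0
    sample_size_sigma: float = 0.6
    sample_size_bounds: tuple[int, int] = (10, 500)
    baseline_event_prob: float = 0.1
    effect_mirnas: int = 5
    effect_logOR: float = 2.0
    tau_between: float = 0.3
    report_prob: float = 0.35  # probability a substudy reports a given microRNA
    tissue_mix: Mapping[str, float] = field(default_factory=lambda: {
        "blood": 0.75, "muscle": 0.05, "adipose": 0.05, "pancreatic": 0.05,
        "heart": 0.04, "vessel": 0.03, "kidney": 0.03})
    fraction_mix: Mapping[str, float] = field(default_factory=lambda: {
        "serum": 0.32, "plasma": 0.35, "pbmc": 0.12, "whole_blood": 0.21})
    platform_mix: Mapping[str, float] = field(default_factory=lambda: {"pcr": 0.95, "seq": 0.05})
    censor_rule: str = "none"  # none | suppress_small_null
    censor_threshold: float = 1.0
    censor_prob: float = 0.8
    retracted_fraction: float = 0.1
    targets_per_mirna: int = 3
    n_null_pathways: int = 5
    pathway_extra_genes: int = 12
    top_pct: float = 1.4

    def __post_init__(self):
        if self.effect_mirnas > self.n_mirnas:
            raise ValueError("effect_mirnas must not exceed n_mirnas")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ValueError("baseline_event_prob must lie strictly in (0, 1)")
        for mix in (self.substudies_per_study, self.tissue_mix,
                    self.fraction_mix, self.platform_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mix probabilities must sum to 1: {mix}")


@dataclass
class GroundTruth:
    effect_set: set[str]
    true_logOR: dict[str, float]
    true_direction: dict[str, str]
    planted_pathway_id: str
    planted_targets: dict[str, list[str]]
    retracted_pmids: set[str] = field(default_factory=set)


def _stream(cfg: SimulationConfig, index: int) -> np.random.Generator:
    """Per-artefact RNG stream: 0 corpus, 1 interaction DB, 2 pathways."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[index])


def mirna_names(cfg: SimulationConfig) -> list[str]:
    return [f"miR-{1000 + i}-5p" for i in range(cfg.n_mirnas)]


def _make_truth(cfg: SimulationConfig) -> GroundTruth:
    names = mirna_names(cfg)
    effect = names[: cfg.effect_mirnas]
    true_logOR = {m: 0.0 for m in names}
    true_dir = {}
    for i, m in enumerate(effect):
        sign = 1.0 if i % 2 == 0 else -1.0
        true_logOR[m] = sign * cfg.effect_logOR
        true_dir[m] = "up" if sign > 0 else "down"
    targets = {m: [f"PG{i:02d}_{j}" for j in range(cfg.targets_per_mirna)]
               for i, m in enumerate(effect)}
    return GroundTruth(effect_set=set(effect), true_logOR=true_logOR,
                       true_direction=true_dir, planted_pathway_id="pw_planted",
                       planted_targets=targets)


#: raw labels the generator writes, chosen to round-trip through tissue
#: classification when the corpus is written to TSV and read back
_RAW_TISSUE_LABEL = {
    "pancreatic": "pancreatic islets", "muscle": "skeletal muscle",
    "adipose": "adipose tissue", "vessel": "blood vessel",
    "heart": "heart", "kidney": "kidney",
}


def _sample_mix(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=[mix[k] for k in keys])]


def simulate_corpus(cfg: SimulationConfig) -> tuple[StudyCorpus, GroundTruth]:
    """Generate a substudy corpus with planted effect microRNAs.

    Per substudy x reported microRNA: control events ~ Binomial(n_ctrl, p0)
    and case events ~ Binomial(n_case, p1) with logit(p1) = logit(p0) +
    delta, delta ~ Normal(true_logOR, tau_between^2) (mean 0 for null
    microRNAs).  Fully reproducible under the config seed.
    """
    rng = _stream(cfg, 0)
    truth = _make_truth(cfg)
    names = mirna_names(cfg)
    p0 = cfg.baseline_event_prob
    lo, hi = cfg.sample_size_bounds
    records: list[SubStudyRecord] = []

    for s in range(cfg.n_studies):
        study_id = f"study{s:03d}"
        n_sub = int(_sample_mix(rng, {str(k): v for k, v in cfg.substudies_per_study.items()}))
        for c in range(n_sub):
            sid_base = f"{study_id}.{c}"
            tissue = _sample_mix(rng, cfg.tissue_mix)
            fraction = _sample_mix(rng, cfg.fraction_mix) if tissue == "blood" else "none"
            tissue_raw = (fraction.replace("_", " ") if tissue == "blood"
                          else _RAW_TISSUE_LABEL[tissue])
            platform = _sample_mix(rng, cfg.platform_mix)
            n_total = int(np.clip(round(rng.lognormal(math.log(cfg.sample_size_median),
                                                      cfg.sample_size_sigma)), lo, hi))
            n_case = n_total // 2
            n_ctrl = n_total - n_case
            for m_idx, mirna in enumerate(names):
                if rng.random() >= cfg.report_prob:
                    continue
                delta = rng.normal(truth.true_logOR[mirna], cfg.tau_between)
                p1 = _expit(_logit(p0) + delta)
                ev_ctrl = int(rng.binomial(n_ctrl, p0))
                ev_case = int(rng.binomial(n_case, p1))
                a, b = ev_case + 0.5, n_case - ev_case + 0.5
                cc, d = ev_ctrl + 0.5, n_ctrl - ev_ctrl + 0.5
                y_obs = math.log(a * d / (b * cc))
                if (cfg.censor_rule == "suppress_small_null"
                        and mirna not in truth.effect_set
                        and abs(y_obs) < cfg.censor_threshold
                        and rng.random() < cfg.censor_prob):
                    continue
                records.append(SubStudyRecord(
                    substudy_id=f"{sid_base}.m{m_idx:03d}",
                    parent_study_id=study_id,
                    mirna=MicroRNAName(mirna, mirna, "exact"),
                    tissue_raw=tissue_raw, tissue_class=tissue,
                    blood_fraction=fraction, platform=platform,
                    n_case=n_case, n_ctrl=n_ctrl,
                    events_case=ev_case, events_ctrl=ev_ctrl,
                    reported_direction="up" if y_obs > 0 else "down",
                ))
    corpus = StudyCorpus(records, provenance=f"simulated(seed={cfg.seed})")
    return corpus, truth


def simulate_interaction_db(cfg: SimulationConfig, truth: GroundTruth
                            ) -> tuple[list[list[InteractionRecord]], frozenset[str]]:
    """Experimental + predicted ledgers with planted robust pairs and decoys.

    Planted pairs carry three experimental PMIDs and a top-ranked
    prediction.  Decoys each fail one robustness clause: a single
    supporting PMID, or no prediction record, or (via the global retraction
    draw) loss of support.  ``retracted_fraction`` of all assigned PMIDs is
    marked retracted.
    """
    rng = _stream(cfg, 1)
    pmid_counter = [10_000_000]

    def next_pmids(n: int) -> frozenset[str]:
        start = pmid_counter[0]
        pmid_counter[0] += n
        return frozenset(str(p) for p in range(start, start + n))

    exp_a: list[InteractionRecord] = []
    exp_b: list[InteractionRecord] = []
    pred: list[InteractionRecord] = []

    for mirna, genes in truth.planted_targets.items():
        for gene in genes:
            pm = sorted(next_pmids(3))
            exp_a.append(InteractionRecord(mirna, gene, "experimental", "expdb_a",
                                           frozenset(pm[:2])))
            exp_b.append(InteractionRecord(mirna, gene, "experimental", "expdb_b",
                                           frozenset(pm[2:])))
            pred.append(InteractionRecord(mirna, gene, "predicted", "preddb",
                                          prediction_rank_pct=float(rng.uniform(0.05, cfg.top_pct))))

    names = mirna_names(cfg)
    null_names = [m for m in names if m not in truth.effect_set]
    # decoys failing the two-PMID clause
    for i in range(10):
        m = null_names[int(rng.integers(len(null_names)))]
        g = f"OG{i:03d}"
        exp_a.append(InteractionRecord(m, g, "experimental", "expdb_a", next_pmids(1)))
        pred.append(InteractionRecord(m, g, "predicted", "preddb",
                                      prediction_rank_pct=float(rng.uniform(0.05, cfg.top_pct))))
    # decoys failing the prediction clause
    for i in range(10):
        m = null_names[int(rng.integers(len(null_names)))]
        exp_a.append(InteractionRecord(m, f"OG1{i:02d}", "experimental", "expdb_a", next_pmids(2)))
    # qualifying decoys: null microRNAs onto null-pathway genes
    for pw in range(cfg.n_null_pathways):
        for j in range(3):
            m = null_names[(pw * 3 + j) % len(null_names)]
            g = f"NG{pw}_{j:02d}"
            exp_a.append(InteractionRecord(m, g, "experimental", "expdb_a", next_pmids(2)))
            pred.append(InteractionRecord(m, g, "predicted", "preddb",
                                          prediction_rank_pct=float(rng.uniform(0.05, cfg.top_pct))))
    # low-rank predictions that the top-percentile cut must remove
    for i in range(5):
        m = null_names[int(rng.integers(len(null_names)))]
        pred.append(InteractionRecord(m, f"OG2{i:02d}", "predicted", "preddb",
                                      prediction_rank_pct=float(rng.uniform(cfg.top_pct + 0.1, 100.0))))

    all_pmids = sorted({p for rec in exp_a + exp_b for p in rec.pmids})
    n_retract = int(round(cfg.retracted_fraction * len(all_pmids)))
    retracted = frozenset(rng.choice(all_pmids, size=n_retract, replace=False).tolist()) \
        if n_retract else frozenset()
    truth.retracted_pmids = set(retracted)
    return [exp_a, exp_b, pred], retracted


def _random_dag(rng: np.random.Generator, nodes: list[str]) -> nx.DiGraph:
    """Connected signed DAG: each later node wired from 1-2 earlier nodes."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for i in range(1, len(nodes)):
        n_par = 1 + int(rng.random() < 0.4)
        parents = rng.choice(i, size=min(n_par, i), replace=False)
        for p in np.atleast_1d(parents):
            beta = 1.0 if rng.random() < 0.6 else -1.0
            g.add_edge(nodes[int(p)], nodes[i], beta=beta,
                       relation="activation" if beta > 0 else "inhibition")
    return g


def simulate_pathways(cfg: SimulationConfig, truth: GroundTruth) -> list[PathwayGraph]:
    """Planted pathway containing every planted target, plus size-matched
    null pathways over disjoint gene sets."""
    rng = _stream(cfg, 2)
    planted_genes = [g for genes in truth.planted_targets.values() for g in genes]
    extra = [f"PX{i:02d}" for i in range(cfg.pathway_extra_genes)]
    nodes = planted_genes + extra
    order = [nodes[i] for i in rng.permutation(len(nodes))]
    pathways = [PathwayGraph(truth.planted_pathway_id, "planted disease pathway",
                             _random_dag(rng, order))]
    n_nodes = len(nodes)
    for pw in range(cfg.n_null_pathways):
        null_nodes = [f"NG{pw}_{i:02d}" for i in range(n_nodes)]
        order = [null_nodes[i] for i in rng.permutation(n_nodes)]
        pathways.append(PathwayGraph(f"pw_null{pw}", f"null pathway {pw}",
                                     _random_dag(rng, order)))
    return pathways


def endtoend_config(seed: int) -> SimulationConfig:
    """Study conditions for end-to-end recovery studies.

    A circulating-only corpus (every substudy a blood fraction) with a
    strong planted effect and larger samples, so per-microRNA statistical
    power is near one and composite recovery properties isolate the
    evidence-filter / pathway / selection plumbing rather than marginal
    power (which the power suite probes at its own design point).
    """
    return SimulationConfig(seed=seed, tissue_mix={"blood": 1.0},
                            effect_logOR=2.5, sample_size_median=80.0)


def simulate_bundle(cfg: SimulationConfig):
    """Convenience: corpus, truth, ledgers, retractions and pathways in one call."""
    corpus, truth = simulate_corpus(cfg)
    ledgers, retracted = simulate_interaction_db(cfg, truth)
    pathways = simulate_pathways(cfg, truth)
    return corpus, truth, ledgers, retracted, pathways
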