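"""Configuration, orchestration and report bundling for the full run.

The pipeline executes corpus reading/validation, overall + subgroup +
sensitivity meta-analyses, publication-bias testing, interaction-evidence
filtering, pathway augmentation, impact analysis and biomarker selection,
writing one TSV per stage plus a machine-readable manifest (config hash,
seed, input-file content hashes, per-stage counts).  A YAML file is the
single source of truth for a run; every stochastic stage takes its seed
from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import bias as bias_mod
from . import corpus as corpus_mod
from . import impact as impact_mod
from . import interactions as inter_mod
from . import meta as meta_mod
from . import selection as select_mod
from .simulate import SimulationConfig, simulate_bundle

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    corpus_path: str
    ledger_paths: list[str]
    retractions_path: str
    pathways_path: str
    out_dir: str
    alias_table_path: str | None = None
    meta: meta_mod.MetaConfig = field(default_factory=meta_mod.MetaConfig)
    subgroup_axes: list[str] = field(default_factory=lambda: ["tissue", "blood_fraction", "platform"])
    sensitivity_thresholds: list[int] = field(default_factory=lambda: [25, 50])
    bias_targets: list[str] | None = None  # None -> most-reported defaults
    top_pct: float = 1.4
    min_pmids: int = 2
    n_perm: int = 2000
    seed: int | None = None
    adjustment: str = "bh"
    target_pathway_id: str = ""
    selection_alpha: float = 0.05
    apply_bias_gate_to_all: bool = False
    simulate: dict[str, Any] | None = None  # optional SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        try:
            paths = raw["paths"]
            meta_cfg = meta_mod.MetaConfig(**raw.get("meta", {}))
            imp = raw.get("impact", {})
            sel = raw.get("selection", {})
            bias_targets = raw.get("bias_targets")
            if bias_targets in ("auto", None):
                bias_targets = None
            return cls(
                corpus_path=paths["corpus"],
                ledger_paths=list(paths["ledgers"]),
                retractions_path=paths["retractions"],
                pathways_path=paths["pathways"],
                alias_table_path=paths.get("alias_table"),
                out_dir=paths["out_dir"],
                meta=meta_cfg,
                subgroup_axes=list(raw.get("subgroup_axes", ["tissue", "blood_fraction", "platform"])),
                sensitivity_thresholds=list(raw.get("sensitivity_thresholds", [25, 50])),
                bias_targets=bias_targets,
                top_pct=float(raw.get("top_pct", 1.4)),
                min_pmids=int(raw.get("min_pmids", 2)),
                n_perm=int(imp.get("n_perm", 2000)),
                seed=imp.get("seed", raw.get("seed")),
                adjustment=imp.get("adjustment", "bh"),
                target_pathway_id=sel.get("target_pathway_id", ""),
                selection_alpha=float(sel.get("alpha", 0.05)),
                apply_bias_gate_to_all=bool(sel.get("apply_bias_gate_to_all", False)),
                simulate=raw.get("simulate"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is required when the impact stage is enabled")
        if not self.target_pathway_id:
            raise ConfigError("selection.target_pathway_id is required")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["meta"] = dataclasses.asdict(self.meta)
        return d


@dataclass
class PipelineBundle:
    config: RunConfig
    corpus: corpus_mod.StudyCorpus
    analysis_sets: list[meta_mod.AnalysisSet]
    inconsistency_tables: dict[str, pd.DataFrame]
    consistency: dict[str, str]
    bias_reports: list[bias_mod.BiasReport]
    robust: inter_mod.RobustInteractionSet
    augmented: list[impact_mod.AugmentedPathway]
    impact_results: list[impact_mod.ImpactResult]
    profiles: list[select_mod.CandidateProfile]
    ranking: select_mod.BiomarkerRanking
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def overall(self) -> meta_mod.AnalysisSet:
        return self.analysis_sets[0]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def build_perturbation(sets: Sequence[meta_mod.AnalysisSet],
                       consistency: dict[str, str]) -> impact_mod.PerturbationInput:
    """Perturbation inputs for impact analysis from the meta-analyses.

    The measured universe is every microRNA meta-analysed overall; the DE
    set is the significant microRNAs with a consistent direction, each
    carrying its pooled signed logOR (overall REML estimate where present,
    else from the first set in which it is significant).
    """
    overall = sets[0]
    universe = {r.mirna for r in overall.results}
    delta: dict[str, float] = {}
    for m, status in consistency.items():
        if status not in ("consistent_up", "consistent_down"):
            continue
        r = overall.get(m)
        if r is not None and r.significant:
            delta[m] = r.mu_reml
        else:
            for s in sets:
                rr = s.get(m)
                if rr is not None and rr.significant:
                    delta[m] = rr.mu_reml
                    break
    universe |= set(delta)
    return impact_mod.PerturbationInput(delta_e=delta, measured_universe=universe,
                                        de_set=set(delta))


@_stage("corpus")
def _load_corpus(config: RunConfig) -> corpus_mod.StudyCorpus:
    alias = (corpus_mod.load_alias_table(config.alias_table_path)
             if config.alias_table_path else corpus_mod.default_alias_table())
    return corpus_mod.read_corpus(config.corpus_path, alias)


@_stage("interactions")
def _load_robust(config: RunConfig) -> inter_mod.RobustInteractionSet:
    ledgers = [inter_mod.read_ledger(p) for p in config.ledger_paths]
    retracted = inter_mod.read_retractions(config.retractions_path)
    return filter_interactions(config, ledgers, retracted)


def filter_interactions(config: RunConfig,
                        ledgers: Sequence[Sequence[inter_mod.InteractionRecord]],
                        retracted: frozenset[str]) -> inter_mod.RobustInteractionSet:
    """Merge → top-percentile prediction cut → retraction strike → robustness filter."""
    merged = inter_mod.merge_sources(ledgers)
    merged = inter_mod.prediction_top_filter(merged, config.top_pct)
    merged = inter_mod.apply_retractions(merged, retracted)
    return inter_mod.filter_robust(merged, config.min_pmids)


def run_pipeline(config: RunConfig) -> PipelineBundle:
    """Execute the full evidence-synthesis pipeline, reading inputs from disk."""
    config.validate()
    corpus = _load_corpus(config)
    robust = _load_robust(config)
    try:
        pathways = impact_mod.read_pathways_tsv(config.pathways_path)
    except Exception as exc:
        raise StageError(f"stage 'augment' failed: {exc}") from exc
    return run_from_inputs(config, corpus, robust, pathways)


def run_from_inputs(config: RunConfig, corpus: corpus_mod.StudyCorpus,
                    robust: inter_mod.RobustInteractionSet,
                    pathways: Sequence[impact_mod.PathwayGraph]) -> PipelineBundle:
    """Execute the analysis stages on already-loaded inputs."""
    config.validate()
    counts: dict[str, int] = {}
    counts["corpus_records"] = len(corpus.records)

    try:
        overall = meta_mod.run_meta(corpus, config.meta, label="overall")
        sets = [overall]
        inconsistency: dict[str, pd.DataFrame] = {}
        for axis in config.subgroup_axes:
            sub_sets, table = meta_mod.run_subgroups(corpus, config.meta, axis)
            sets.extend(sub_sets)
            inconsistency[axis] = table
        sets.extend(meta_mod.run_sensitivity(corpus, config.meta, config.sensitivity_thresholds))
        consistency = meta_mod.direction_consistency(sets)
    except Exception as exc:
        raise StageError(f"stage 'meta' failed: {exc}") from exc
    counts["mirnas_analysed"] = len(overall.results)
    counts["significant_overall"] = len(overall.significant())

    try:
        reports = bias_mod.bias_summary(overall, corpus, config.bias_targets,
                                        alpha=config.meta.alpha)
    except Exception as exc:
        raise StageError(f"stage 'bias' failed: {exc}") from exc
    counts["bias_targets_tested"] = sum(r.begg_method != "not_testable" for r in reports)

    counts["robust_pairs"] = len(robust.pairs)

    try:
        augmented = [impact_mod.augment_pathway(pw, robust) for pw in pathways]
    except Exception as exc:
        raise StageError(f"stage 'augment' failed: {exc}") from exc
    counts["pathways"] = len(augmented)

    try:
        perturbation = build_perturbation(sets, consistency)
        impact_results = impact_mod.impact_analysis(
            augmented, perturbation, n_perm=config.n_perm,
            seed=config.seed, adjustment=config.adjustment)
    except Exception as exc:
        raise StageError(f"stage 'impact' failed: {exc}") from exc
    counts["pathways_significant"] = sum(r.p_g_adj < config.selection_alpha
                                         for r in impact_results)

    try:
        profiles = select_mod.collect_evidence(
            sets, consistency, impact_results, reports,
            config.target_pathway_id, alpha=config.selection_alpha,
            apply_bias_gate_to_all=config.apply_bias_gate_to_all)
        ranking = select_mod.select_and_rank(profiles)
    except Exception as exc:
        raise StageError(f"stage 'selection' failed: {exc}") from exc
    counts["biomarkers_ranked"] = len(ranking.entries)

    return PipelineBundle(
        config=config, corpus=corpus, analysis_sets=sets,
        inconsistency_tables=inconsistency, consistency=consistency,
        bias_reports=reports, robust=robust, augmented=augmented,
        impact_results=impact_results, profiles=profiles, ranking=ranking,
        stage_counts=counts)


# ---------------------------------------------------------------------------
# report writing

def _slug(label: str) -> str:
    return (label.replace("subgroup:", "subgroup_").replace("sensitivity:n>=", "sensitivity_n")
            .replace(":", "_").replace(">=", "ge"))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True, default=str)
                          .encode()).hexdigest()


def bias_reports_to_frame(reports: Sequence[bias_mod.BiasReport]) -> pd.DataFrame:
    rows = [{
        "mirna": r.mirna, "k": r.k, "n_parent_studies": r.n_parent_studies,
        "kendall_tau": r.kendall_tau, "p_begg": r.p_begg, "begg_method": r.begg_method,
        "egger_intercept": r.egger_intercept, "egger_z": r.egger_z, "p_egger": r.p_egger,
        "k0": r.k0, "mu_adjusted": r.mu_adjusted, "p_adjusted": r.p_adjusted,
        "significant_after_correction": r.significant_after_correction,
    } for r in reports]
    return pd.DataFrame(rows, columns=["mirna", "k", "n_parent_studies", "kendall_tau",
                                       "p_begg", "begg_method", "egger_intercept",
                                       "egger_z", "p_egger", "k0", "mu_adjusted",
                                       "p_adjusted", "significant_after_correction"])


def write_reports(bundle: PipelineBundle, out_dir: str | Path, force: bool = False) -> list[Path]:
    """Write every stage's TSV plus summary.json and manifest.json.

    Refuses to overwrite an existing run (manifest.json present) unless
    ``force``.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists() and not force:
        raise FileExistsError(f"{out} already holds a run manifest; use force to overwrite")
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        p = out / name
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)

    save(corpus_mod.corpus_to_frame(bundle.corpus), "corpus.tsv")
    for s in bundle.analysis_sets:
        save(meta_mod.analysis_to_frame(s), f"meta_{_slug(s.label)}.tsv")
    for axis, table in bundle.inconsistency_tables.items():
        save(table, f"direction_inconsistency_{axis}.tsv")
    cons = pd.DataFrame(sorted(bundle.consistency.items()), columns=["mirna", "consistency"])
    save(cons, "direction_consistency.tsv")
    save(bias_reports_to_frame(bundle.bias_reports), "bias_reports.tsv")
    groups = meta_mod.effects_by_mirna(bundle.corpus)
    for rep in bundle.bias_reports:
        if rep.begg_method != "not_testable" and rep.mirna in groups:
            save(bias_mod.funnel_to_frame(bias_mod.funnel_data(groups[rep.mirna])),
                 f"funnel_{rep.mirna}.tsv")
    save(inter_mod.robust_set_to_frame(bundle.robust), "robust_interactions.tsv")
    save(impact_mod.impact_to_frame(bundle.impact_results), "impact.tsv")
    target = next((r for r in bundle.impact_results
                   if r.pathway_id == bundle.config.target_pathway_id), None)
    if target is not None and target.pf:
        save(impact_mod.node_perturbations_to_frame(target), "node_perturbations_target.tsv")
    save(select_mod.ranking_to_frame(bundle.ranking, bundle.profiles), "ranking.tsv")

    summary = {
        "n_significant_overall": bundle.stage_counts.get("significant_overall", 0),
        "k0_per_tested_mirna": {r.mirna: r.k0 for r in bundle.bias_reports
                                if r.k0 is not None},
        "n_enriched_pathways": bundle.stage_counts.get("pathways_significant", 0),
        "final_ranking": bundle.ranking.mirnas(),
        "stage_counts": bundle.stage_counts,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(out / "summary.json")

    cfg = bundle.config
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stage_counts": bundle.stage_counts,
        "inputs": {p: _sha256(p) for p in
                   [cfg.corpus_path, *cfg.ledger_paths, cfg.retractions_path,
                    cfg.pathways_path] if Path(p).exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(out / "manifest.json")
    return written


def default_run_config(sim_cfg: SimulationConfig, n_perm: int = 2000,
                       out_dir: str = "run_out") -> RunConfig:
    """A RunConfig wired for a synthetic bundle (in-memory paths unused)."""
    return RunConfig(
        corpus_path="corpus.tsv", ledger_paths=["exp_a.tsv", "exp_b.tsv", "pred.tsv"],
        retractions_path="retractions.txt", pathways_path="pathways.tsv",
        out_dir=out_dir, n_perm=n_perm, seed=sim_cfg.seed,
        top_pct=sim_cfg.top_pct, target_pathway_id="pw_planted")


def run_synthetic(sim_cfg: SimulationConfig, config: RunConfig | None = None):
    """Simulate a full input bundle and run every stage in memory.

    Returns ``(bundle, truth)`` — the pipeline outputs next to the planted
    ground truth, for recovery studies.
    """
    config = config or default_run_config(sim_cfg)
    corpus, truth, ledgers, retracted, pathways = simulate_bundle(sim_cfg)
    robust = filter_interactions(config, ledgers, retracted)
    bundle = run_from_inputs(config, corpus, robust, pathways)
    return bundle, truth


def write_simulation_inputs(sim_cfg: SimulationConfig, paths: RunConfig) -> None:
    """Generate a synthetic bundle and write it to the configured input paths."""
    corpus, truth, ledgers, retracted, pathways = simulate_bundle(sim_cfg)
    for p in [paths.corpus_path, *paths.ledger_paths, paths.retractions_path,
              paths.pathways_path]:
        Path(p).parent.mkdir(parents=True, exist_ok=True)
    corpus_mod.write_corpus(corpus, paths.corpus_path)
    for ledger, p in zip(ledgers, paths.ledger_paths):
        inter_mod.write_ledger(ledger, p)
    Path(paths.retractions_path).write_text("\n".join(sorted(retracted)) + ("\n" if retracted else ""))
    impact_mod.write_pathways_tsv(pathways, paths.pathways_path)
    truth_path = Path(paths.corpus_path).with_suffix(".truth.json")
    truth_path.write_text(json.dumps({
        "effect_set": sorted(truth.effect_set),
        "true_logOR": truth.true_logOR,
        "true_direction": truth.true_direction,
        "planted_pathway_id": truth.planted_pathway_id,
        "planted_targets": truth.planted_targets,
        "retracted_pmids": sorted(truth.retracted_pmids),
    }, indent=2, sort_keys=True) + "\n")
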