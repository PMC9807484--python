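"""Biomarker selection: intersect statistical and biological evidence.

A candidate biomarker must be statistically significant with a consistent
direction across the analyses in which it is significant, and biologically
relevant: it must act as a measured perturbation input on the disease
target pathway, and that pathway must itself be significantly impacted.
Candidates are then ranked by a two-key priority — (1) detectable in blood
or a blood fraction, (2) significance across analyses — made total with
documented tie-breaks so the ordering is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .bias import BiasReport
from .impact import ImpactResult
from .meta import AnalysisSet

logger = logging.getLogger(__name__)

BLOOD_LABELS = {"subgroup:blood", "subgroup:serum", "subgroup:plasma",
                "subgroup:pbmc", "subgroup:whole_blood"}


@dataclass
class CandidateProfile:
    mirna: str
    consistent_direction: str  # consistent_up | consistent_down
    n_analyses_significant: int
    min_p_adj: float
    max_abs_logOR: float
    blood_detectable: bool
    on_target_pathway: bool
    survives_bias_correction: bool | None = None  # None when untested


@dataclass
class BiomarkerRanking:
    entries: list[tuple[int, str, int, str]]  # (rank, mirna, tier, evidence summary)

    def mirnas(self) -> list[str]:
        return [e[1] for e in self.entries]


def collect_evidence(sets: Sequence[AnalysisSet],
                     consistency: Mapping[str, str],
                     impact: Sequence[ImpactResult],
                     bias: Sequence[BiasReport],
                     target_pathway_id: str,
                     alpha: float = 0.05,
                     apply_bias_gate_to_all: bool = False) -> list[CandidateProfile]:
    """Assemble candidate profiles from one pipeline run.

    Candidates are microRNAs that are significant somewhere with a
    consistent direction and that enter the target pathway as perturbation
    inputs, provided the target pathway itself is significant (adjusted
    pG < alpha).  MicroRNAs failing the trim-and-fill significance gate
    are excluded; by default the gate applies only where bias tests were
    run, ``apply_bias_gate_to_all`` widens it.
    """
    target = next((r for r in impact if r.pathway_id == target_pathway_id), None)
    if target is None:
        raise ValueError(f"target pathway {target_pathway_id!r} absent from impact results")
    if not target.p_g_adj < alpha:
        logger.info("target pathway %s not significant (adjusted pG=%.3g); no candidates",
                    target_pathway_id, target.p_g_adj)
        return []

    bias_by_mirna = {b.mirna: b for b in bias}
    profiles: list[CandidateProfile] = []
    sig_sets: dict[str, list[tuple[str, float, float]]] = {}
    for s in sets:
        for r in s.significant():
            sig_sets.setdefault(r.mirna, []).append((s.label, r.p_adj_reml, abs(r.mu_reml)))

    for mirna, hits in sorted(sig_sets.items()):
        cons = consistency.get(mirna, "never_significant")
        if cons not in ("consistent_up", "consistent_down"):
            logger.info("%s excluded: direction %s", mirna, cons)
            continue
        on_pathway = mirna in target.de_nodes
        if not on_pathway:
            logger.info("%s excluded: not biologically enriched (no robust target on %s)",
                        mirna, target_pathway_id)
            continue
        rep = bias_by_mirna.get(mirna)
        survives: bool | None = None
        if rep is not None and rep.significant_after_correction is not None:
            survives = rep.significant_after_correction
            if not survives:
                logger.info("%s excluded: effect not significant after trim-and-fill", mirna)
                continue
        elif apply_bias_gate_to_all:
            logger.info("%s excluded: bias correction required for all but not tested", mirna)
            continue
        profiles.append(CandidateProfile(
            mirna=mirna,
            consistent_direction=cons,
            n_analyses_significant=len(hits),
            min_p_adj=min(p for _, p, _ in hits),
            max_abs_logOR=max(a for _, _, a in hits),
            blood_detectable=any(lbl in BLOOD_LABELS for lbl, _, _ in hits),
            on_target_pathway=True,
            survives_bias_correction=survives,
        ))
    return profiles


def select_and_rank(profiles: Sequence[CandidateProfile]) -> BiomarkerRanking:
    """Priority order: blood-detectable first (tier 1), then by number of
    analyses significant (desc), minimum adjusted p (asc), maximum |logOR|
    (desc), and name — a total order with dense ranks."""
    def key(p: CandidateProfile):
        return (0 if p.blood_detectable else 1, -p.n_analyses_significant,
                p.min_p_adj, -p.max_abs_logOR, p.mirna)

    entries = []
    for rank, p in enumerate(sorted(profiles, key=key), start=1):
        tier = 1 if p.blood_detectable else 2
        summary = (f"{p.consistent_direction}; significant in {p.n_analyses_significant} "
                   f"analyses; min adj p={p.min_p_adj:.3g}; max |logOR|={p.max_abs_logOR:.3g}")
        entries.append((rank, p.mirna, tier, summary))
    return BiomarkerRanking(entries=entries)


def ranking_to_frame(ranking: BiomarkerRanking,
                     profiles: Sequence[CandidateProfile]) -> pd.DataFrame:
    by_name = {p.mirna: p for p in profiles}
    rows = []
    for rank, mirna, tier, _ in ranking.entries:
        p = by_name[mirna]
        rows.append({
            "rank": rank, "mirna": mirna, "tier": tier,
            "direction": p.consistent_direction.removeprefix("consistent_"),
            "n_analyses_significant": p.n_analyses_significant,
            "min_p_adj": p.min_p_adj, "max_abs_logOR": p.max_abs_logOR,
            "on_target_pathway": p.on_target_pathway,
            "survives_bias_correction": p.survives_bias_correction,
        })
    return pd.DataFrame(rows, columns=["rank", "mirna", "tier", "direction",
                                       "n_analyses_significant", "min_p_adj",
                                       "max_abs_logOR", "on_target_pathway",
                                       "survives_bias_correction"])
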