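"""Per-microRNA random-effects meta-analysis of event-count log odds ratios.

Each substudy contributes a 2x2 table of dysregulation events; the effect
size is the natural-log odds ratio with the usual large-sample variance
``1/a + 1/b + 1/c + 1/d`` (Haldane–Anscombe +0.5 continuity correction on
all cells when any cell is zero).  Between-substudy heterogeneity ``tau^2``
is estimated twice, by restricted maximum likelihood (REML) and by the
Paule–Mandel fixed point (which coincides with the empirical-Bayes
estimator), and a microRNA is called significant only when *both*
estimators give a Bonferroni-adjusted Wald p below alpha with matching
direction.

Internally every effect is signed; reporting layers present ``|mu|`` plus a
direction column (up for pooled logOR > 0, down for < 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .corpus import StudyCorpus, SubStudyRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    """Signed logOR and within-substudy variance for one substudy."""

    y: float
    v: float
    corrected: bool
    substudy_id: str
    parent_study_id: str

    def __post_init__(self):
        if not (self.v > 0 and math.isfinite(self.y)):
            raise ValueError(f"invalid effect: y={self.y}, v={self.v}")

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


@dataclass
class MetaConfig:
    min_substudies: int = 2
    alpha: float = 0.05
    m_tests: int | None = None  # Bonferroni divisor; defaults to the per-run count
    tau2_tol: float = 1e-8
    tau2_max_iter: int = 200
    ci_level: float = 0.95

    def __post_init__(self):
        if self.min_substudies < 2:
            raise ValueError("min_substudies must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class MetaResult:
    """Pooled signed logOR for one microRNA under both tau^2 estimators."""

    mirna: str
    k: int
    mu_reml: float
    mu_eb: float
    tau2_reml: float
    tau2_eb: float
    se_reml: float
    se_eb: float
    ci_low: float
    ci_high: float
    p_raw_reml: float
    p_raw_eb: float
    p_adj_reml: float
    p_adj_eb: float
    direction: str
    significant: bool


@dataclass
class AnalysisSet:
    """Results of one meta-analysis run (overall, a subgroup, a sensitivity cut)."""

    label: str
    results: list[MetaResult]
    m_tests: int
    excluded: dict[str, int] = field(default_factory=dict)  # mirna -> k below threshold

    def significant(self) -> list[MetaResult]:
        return [r for r in self.results if r.significant]

    def get(self, mirna: str) -> MetaResult | None:
        for r in self.results:
            if r.mirna == mirna:
                return r
        return None


def effect_from_counts(rec: SubStudyRecord) -> EffectSize:
    """2x2 table -> signed logOR and its variance.

    With ``a`` dysregulated cases, ``b = n_case - a``, ``c`` dysregulated
    controls, ``d = n_ctrl - c``: ``y = ln(ad/bc)``, ``v = 1/a+1/b+1/c+1/d``.
    Any zero cell triggers the +0.5 correction on all four cells.
    """
    a = float(rec.events_case)
    b = float(rec.n_case - rec.events_case)
    c = float(rec.events_ctrl)
    d = float(rec.n_ctrl - rec.events_ctrl)
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    y = math.log(a * d / (b * c))
    v = 1 / a + 1 / b + 1 / c + 1 / d
    return EffectSize(y=y, v=v, corrected=corrected,
                      substudy_id=rec.substudy_id, parent_study_id=rec.parent_study_id)


def _check_k(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) < 2:
        raise ValueError("not meta-analysable: fewer than 2 substudies")
    y = np.array([e.y for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def _q_gen(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu) ** 2))


def tau2_eb(effects: Sequence[EffectSize], tol: float = 1e-8, max_iter: int = 200) -> float:
    """Empirical-Bayes / Paule–Mandel tau^2: root of Q_gen(tau^2) = k - 1.

    Q_gen is strictly decreasing in tau^2, so the root is found by
    bisection after bracketing; truncated at 0 when Q_gen(0) <= k - 1.
    """
    y, v = _check_k(effects)
    k = len(y)
    target = k - 1.0
    if _q_gen(0.0, y, v) <= target:
        return 0.0
    hi = max(1.0, float(np.var(y, ddof=1)))
    for _ in range(200):
        if _q_gen(hi, y, v) < target:
            break
        hi *= 2.0
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _q_gen(mid, y, v) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    ll = -0.5 * np.sum(np.log(v + tau2)) - 0.5 * math.log(np.sum(w)) \
        - 0.5 * np.sum(w * (y - mu) ** 2)
    return -float(ll)


def tau2_reml(effects: Sequence[EffectSize], tol: float = 1e-8, max_iter: int = 200) -> float:
    """REML tau^2 by bounded maximisation of the restricted log-likelihood."""
    y, v = _check_k(effects)
    cap = max(10.0, 100.0 * float(np.var(y, ddof=1)))
    res = optimize.minimize_scalar(
        _reml_nll, args=(y, v), bounds=(0.0, cap), method="bounded",
        options={"xatol": tol, "maxiter": max_iter * 10},
    )
    tau2 = float(res.x)
    # the bounded optimiser never lands exactly on the boundary; snap to 0
    # when 0 is at least as good
    if _reml_nll(0.0, y, v) <= res.fun:
        return 0.0
    return tau2


def pool_random_effects(effects: Sequence[EffectSize], tau2: float,
                        ci_level: float = 0.95) -> tuple[float, float, float, float, float]:
    """Inverse-variance pooling at a given tau^2: (mu, se, ci_low, ci_high, p)."""
    y, v = _check_k(effects)
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    p = float(2 * stats.norm.sf(abs(mu) / se))
    return mu, se, mu - z * se, mu + z * se, p


def bonferroni_adjust(p_raw: float, m_tests: int) -> float:
    """min(1, m * p)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return min(1.0, m_tests * p_raw)


def effects_by_mirna(corpus: StudyCorpus) -> dict[str, list[EffectSize]]:
    """Group per-substudy effects by canonical microRNA name."""
    out: dict[str, list[EffectSize]] = {}
    for rec in corpus.records:
        if rec.mirna.resolved_via == "unresolved":
            continue
        out.setdefault(rec.mirna.canonical, []).append(effect_from_counts(rec))
    return out


def meta_analyse_one(mirna: str, effects: Sequence[EffectSize], cfg: MetaConfig,
                     m_tests: int) -> MetaResult:
    t2_reml = tau2_reml(effects, cfg.tau2_tol, cfg.tau2_max_iter)
    t2_eb = tau2_eb(effects, cfg.tau2_tol, cfg.tau2_max_iter)
    mu_r, se_r, lo, hi, p_r = pool_random_effects(effects, t2_reml, cfg.ci_level)
    mu_e, se_e, _, _, p_e = pool_random_effects(effects, t2_eb, cfg.ci_level)
    p_adj_r = bonferroni_adjust(p_r, m_tests)
    p_adj_e = bonferroni_adjust(p_e, m_tests)
    same_sign = np.sign(mu_r) == np.sign(mu_e) and mu_r != 0
    sig = bool(p_adj_r < cfg.alpha and p_adj_e < cfg.alpha and same_sign)
    if p_adj_r < cfg.alpha and p_adj_e < cfg.alpha and not same_sign:
        logger.warning("%s: adjusted p < alpha under both estimators but pooled "
                       "directions disagree; not flagged significant", mirna)
    return MetaResult(
        mirna=mirna, k=len(effects),
        mu_reml=mu_r, mu_eb=mu_e, tau2_reml=t2_reml, tau2_eb=t2_eb,
        se_reml=se_r, se_eb=se_e, ci_low=lo, ci_high=hi,
        p_raw_reml=p_r, p_raw_eb=p_e, p_adj_reml=p_adj_r, p_adj_eb=p_adj_e,
        direction="up" if mu_r > 0 else "down",
        significant=sig,
    )


def run_meta(corpus: StudyCorpus, cfg: MetaConfig | None = None,
             label: str = "overall") -> AnalysisSet:
    """Meta-analyse every microRNA with at least ``min_substudies`` substudies.

    The Bonferroni divisor defaults to the number of microRNAs actually
    meta-analysed in this run (override via ``cfg.m_tests``).
    """
    cfg = cfg or MetaConfig()
    if not corpus.records:
        raise ValueError("empty corpus")
    groups = effects_by_mirna(corpus)
    analysable = {m: eff for m, eff in groups.items() if len(eff) >= cfg.min_substudies}
    excluded = {m: len(eff) for m, eff in groups.items() if len(eff) < cfg.min_substudies}
    for m, k in excluded.items():
        logger.info("[%s] %s excluded: only %d substudy(ies)", label, m, k)
    m_tests = cfg.m_tests if cfg.m_tests is not None else len(analysable)
    results = [meta_analyse_one(m, eff, cfg, m_tests) for m, eff in analysable.items()]
    return AnalysisSet(label=label, results=results, m_tests=max(m_tests, 1), excluded=excluded)


#: strata the subgroup axes analyse; others are skipped with a log entry
SUBGROUP_STRATA = {
    "tissue": None,  # all observed classes
    "blood_fraction": ("serum", "plasma", "pbmc", "whole_blood"),
    "platform": ("pcr", "seq"),
}


def _axis_value(rec: SubStudyRecord, axis: str) -> str:
    if axis == "tissue":
        return rec.tissue_class
    if axis == "blood_fraction":
        return rec.blood_fraction
    if axis == "platform":
        return rec.platform
    raise ValueError(f"unknown subgroup axis {axis!r}")


def run_subgroups(corpus: StudyCorpus, cfg: MetaConfig | None = None,
                  axis: str = "tissue") -> tuple[list[AnalysisSet], pd.DataFrame]:
    """Partition the corpus along one axis and meta-analyse each stratum.

    Returns the per-stratum analysis sets (each with its own Bonferroni
    divisor) and a cross-stratum direction table listing microRNAs that are
    significantly up in one stratum and down in another.
    """
    cfg = cfg or MetaConfig()
    allowed = SUBGROUP_STRATA[axis]
    values = sorted({_axis_value(r, axis) for r in corpus.records})
    sets: list[AnalysisSet] = []
    for val in values:
        if val == "none":
            continue
        if allowed is not None and val not in allowed:
            logger.info("subgroup axis %s: stratum %r skipped (not analysed)", axis, val)
            continue
        sub = corpus.subset(lambda r, v=val: _axis_value(r, axis) == v)
        groups = effects_by_mirna(sub)
        if not any(len(e) >= cfg.min_substudies for e in groups.values()):
            logger.info("subgroup %s=%s: no analysable microRNA, empty set", axis, val)
            sets.append(AnalysisSet(label=f"subgroup:{val}", results=[], m_tests=1))
            continue
        sets.append(run_meta(sub, cfg, label=f"subgroup:{val}"))

    rows = []
    sig_dirs: dict[str, dict[str, str]] = {}
    for s in sets:
        for r in s.significant():
            sig_dirs.setdefault(r.mirna, {})[s.label] = r.direction
    for mirna, dirs in sorted(sig_dirs.items()):
        if len(set(dirs.values())) > 1:
            for lbl, d in dirs.items():
                rows.append({"mirna": mirna, "stratum": lbl, "direction": d})
    inconsistent = pd.DataFrame(rows, columns=["mirna", "stratum", "direction"])
    return sets, inconsistent


def run_sensitivity(corpus: StudyCorpus, cfg: MetaConfig | None = None,
                    thresholds: Sequence[int] = (25, 50)) -> list[AnalysisSet]:
    """Re-run the meta-analysis keeping substudies with total n >= threshold."""
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    cfg = cfg or MetaConfig()
    sets = []
    for t in thresholds:
        sub = corpus.subset(lambda r, t=t: r.n_total >= t)
        label = f"sensitivity:n>={t}"
        if not sub.records:
            logger.info("%s: no substudies remain", label)
            sets.append(AnalysisSet(label=label, results=[], m_tests=1))
            continue
        s = run_meta(sub, cfg, label=label)
        logger.info("%s: %d substudies, %d significant microRNAs",
                    label, len(sub.records), len(s.significant()))
        sets.append(s)
    return sets


def direction_consistency(sets: Sequence[AnalysisSet]) -> dict[str, str]:
    """Classify each microRNA's direction across every set where it is significant.

    ``consistent_up`` / ``consistent_down`` when all significant appearances
    agree; ``inconsistent`` otherwise; ``never_significant`` when the
    microRNA is significant in no set.
    """
    if not sets:
        raise ValueError("at least one analysis set required")
    all_mirnas: set[str] = set()
    sig_dirs: dict[str, set[str]] = {}
    for s in sets:
        for r in s.results:
            all_mirnas.add(r.mirna)
            if r.significant:
                sig_dirs.setdefault(r.mirna, set()).add(r.direction)
    out = {}
    for m in sorted(all_mirnas):
        dirs = sig_dirs.get(m)
        if not dirs:
            out[m] = "never_significant"
        elif dirs == {"up"}:
            out[m] = "consistent_up"
        elif dirs == {"down"}:
            out[m] = "consistent_down"
        else:
            out[m] = "inconsistent"
    return out


def analysis_to_frame(s: AnalysisSet) -> pd.DataFrame:
    """Reporting view: |logOR| plus direction, per the presentation convention."""
    rows = []
    for r in sorted(s.results, key=lambda r: r.p_adj_reml):
        # CI presented on the same absolute scale as |logOR| (mirrored for
        # downregulation); the direction column carries the sign
        lo, hi = ((r.ci_low, r.ci_high) if r.mu_reml >= 0
                  else (-r.ci_high, -r.ci_low))
        rows.append({
            "mirna": r.mirna, "k": r.k,
            "abs_logOR_reml": abs(r.mu_reml), "ci_low": lo, "ci_high": hi,
            "p_raw_reml": r.p_raw_reml, "p_adj_reml": r.p_adj_reml,
            "abs_logOR_eb": abs(r.mu_eb), "p_adj_eb": r.p_adj_eb,
            "tau2_reml": r.tau2_reml, "tau2_eb": r.tau2_eb,
            "direction": r.direction, "significant": r.significant,
        })
    cols = ["mirna", "k", "abs_logOR_reml", "ci_low", "ci_high", "p_raw_reml",
            "p_adj_reml", "abs_logOR_eb", "p_adj_eb", "tau2_reml", "tau2_eb",
            "direction", "significant"]
    return pd.DataFrame(rows, columns=cols)
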