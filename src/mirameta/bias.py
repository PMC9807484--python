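"""Publication-bias diagnostics: funnel data, Begg, Egger, trim-and-fill.

Small-study effects are probed three ways.  Begg's test rank-correlates
standardised effect deviates with their variances (Kendall's tau); at small
k with no ties the two-sided p is exact, obtained from the permutation null
of Kendall's S (enumerated via the Mahonian inversion-count distribution).
Egger's test regresses the standardised effect on precision and asks
whether the intercept departs from zero.  The Duval–Tweedie trim-and-fill
procedure estimates the number of suppressed studies (L0 estimator),
imputes mirrored counterparts and re-pools under REML so that significance
can be re-assessed after correction.

MicroRNAs whose substudies all come from one parent study (or with k < 3)
do not fit these models and are reported ``not_testable``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .corpus import StudyCorpus
from .meta import (AnalysisSet, EffectSize, MetaConfig, effects_by_mirna,
                   pool_random_effects, tau2_reml)

logger = logging.getLogger(__name__)

EXACT_CUTOFF = 8  # largest k for which the exact Begg p is enumerated
_EPS = 1e-12


@dataclass
class FunnelData:
    """Effect/precision scatter for one microRNA, centred at the FE estimate."""

    points: list[tuple[float, float, str]]  # (y, se, substudy_id)
    center: float


@dataclass
class BiasReport:
    mirna: str
    k: int
    n_parent_studies: int
    kendall_tau: float | None = None
    p_begg: float | None = None
    begg_method: str = "not_testable"  # exact | normal_approx | not_testable
    egger_intercept: float | None = None
    egger_z: float | None = None
    p_egger: float | None = None
    egger_perfect_fit: bool = False
    k0: int | None = None
    mu_adjusted: float | None = None
    p_adjusted: float | None = None
    significant_after_correction: bool | None = None


def fixed_effect_center(effects: Sequence[EffectSize]) -> float:
    y = np.array([e.y for e in effects])
    w = 1.0 / np.array([e.v for e in effects])
    return float(np.sum(w * y) / np.sum(w))


def funnel_data(effects: Sequence[EffectSize]) -> FunnelData:
    center = fixed_effect_center(effects)
    pts = [(e.y, e.se, e.substudy_id) for e in effects]
    return FunnelData(points=pts, center=center)


def funnel_to_frame(fd: FunnelData):
    """Funnel scatter as a table (y, se, substudy_id, center) for external plotting."""
    import pandas as pd
    return pd.DataFrame([{"y": y, "se": se, "substudy_id": sid, "center": fd.center}
                         for y, se, sid in fd.points],
                        columns=["y", "se", "substudy_id", "center"])


@lru_cache(maxsize=32)
def _mahonian(k: int) -> tuple[int, ...]:
    """Number of permutations of k items with 0..k(k-1)/2 inversions."""
    counts = [1]
    for n in range(2, k + 1):
        prev = counts
        m = len(prev) + n - 1
        counts = [0] * m
        for inv in range(m):
            lo = max(0, inv - n + 1)
            counts[inv] = sum(prev[lo:inv + 1])
    return tuple(counts)


def kendall_s(x: Sequence[float], y: Sequence[float]) -> int:
    """Kendall S = #concordant - #discordant pairs."""
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign((x[i] - x[j]) * (y[i] - y[j])))
    return s


def begg_exact_p(s_obs: int, k: int) -> float:
    """Two-sided exact p for Kendall S under the permutation null (no ties).

    Under the null all k! orderings are equally likely; the distribution of
    the inversion count is Mahonian, and S = k(k-1)/2 - 2*inversions, so the
    tail is summed directly: p = P(|S| >= |s_obs|).
    """
    counts = _mahonian(k)
    smax = k * (k - 1) // 2
    total = math.factorial(k)
    hits = sum(c for inv, c in enumerate(counts) if abs(smax - 2 * inv) >= abs(s_obs))
    return hits / total


def _standardised_deviates(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    mu_fe = fixed_effect_center(effects)
    v_star = v - 1.0 / np.sum(1.0 / v)
    if np.any(v_star <= 0):
        logger.warning("non-positive conditional variance for %d point(s); clipped to %g",
                       int(np.sum(v_star <= 0)), _EPS)
        v_star = np.maximum(v_star, _EPS)
    return (y - mu_fe) / np.sqrt(v_star), v


def _n_parents(effects: Sequence[EffectSize]) -> int:
    return len({e.parent_study_id for e in effects})


def begg_test(effects: Sequence[EffectSize]) -> tuple[float | None, float | None, str]:
    """Rank correlation between standardised deviates and variances.

    Returns (kendall_tau, p, method).  Exact permutation p when k <= 8 with
    no ties in either ranking; otherwise the tie-corrected normal
    approximation.  Fewer than 3 substudies or fewer than 2 parent studies
    -> not testable.
    """
    k = len(effects)
    if k < 3 or _n_parents(effects) < 2:
        return None, None, "not_testable"
    y_star, v = _standardised_deviates(effects)
    tau = float(stats.kendalltau(y_star, v).statistic)
    no_ties = len(set(y_star)) == k and len(set(v)) == k
    if k <= EXACT_CUTOFF and no_ties:
        p = begg_exact_p(kendall_s(y_star, v), k)
        return tau, p, "exact"
    p = float(stats.kendalltau(y_star, v, method="asymptotic").pvalue)
    return tau, p, "normal_approx"


def egger_test(effects: Sequence[EffectSize]) -> tuple[float, float, float, bool]:
    """Regression of standardised effect on precision; returns
    (intercept, z, p, perfect_fit).

    t_i = y_i/se_i is regressed on x_i = 1/se_i with intercept; z is the
    intercept over its OLS standard error with a two-sided normal p
    (matching the z-statistic convention for this test).
    """
    k = len(effects)
    if k < 3 or _n_parents(effects) < 2:
        raise ValueError("Egger regression needs >= 3 substudies from >= 2 parent studies")
    se = np.array([e.se for e in effects])
    t = np.array([e.y for e in effects]) / se
    x = 1.0 / se
    if np.allclose(x, x[0]):
        raise ValueError("degenerate precision design: all precisions equal")
    fit = sm.OLS(t, sm.add_constant(x)).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    perfect = fit.ssr <= 1e-10 * max(1.0, float(np.sum(t ** 2)))
    if perfect or se_int == 0.0 or not math.isfinite(se_int):
        z = math.inf if intercept > 0 else (-math.inf if intercept < 0 else 0.0)
        logger.warning("Egger regression is a perfect fit; z reported as %s", z)
        return intercept, z, 0.0 if intercept != 0 else 1.0, True
    z = intercept / se_int
    p = float(2 * stats.norm.sf(abs(z)))
    return intercept, z, p, False


def _l0_pass(y: np.ndarray, v: np.ndarray, n_trim: int) -> tuple[float, float]:
    """One trim-and-fill pass: trimmed FE center and the L0 estimate."""
    k = len(y)
    order = np.argsort(y)
    keep = order[: k - n_trim] if n_trim else order
    w = 1.0 / v[keep]
    center = float(np.sum(w * y[keep]) / np.sum(w))
    d = y - center
    ranks = stats.rankdata(np.abs(d))
    t_n = float(np.sum(ranks[d > 0]))
    l0 = (4.0 * t_n - k * (k + 1)) / (2.0 * k - 1.0)
    return center, l0


def trim_and_fill(effects: Sequence[EffectSize], side: str = "auto",
                  max_iter: int = 50) -> tuple[int, list[EffectSize], float, float]:
    """Duval–Tweedie trim-and-fill with the L0 missing-study estimator.

    ``side`` is the side of the funnel with the *excess* (i.e. suppressed
    counterparts are imputed on the opposite side); ``auto`` picks the side
    whose first-pass L0 is larger (ties broken by the Egger intercept's
    sign).  Returns ``(k0, observed+filled effects, mu_adjusted,
    p_adjusted)`` with the adjusted estimate from REML random-effects
    pooling of the filled set.
    """
    if len(effects) < 3:
        raise ValueError("trim-and-fill needs >= 3 substudies")
    y = np.array([e.y for e in effects])
    v = np.array([e.v for e in effects])
    if side == "auto":
        _, l0_right = _l0_pass(y, v, 0)
        _, l0_left = _l0_pass(-y, v, 0)
        if l0_right > l0_left:
            side = "right"
        elif l0_left > l0_right:
            side = "left"
        else:
            try:
                intercept, *_ = egger_test(effects)
            except ValueError:
                intercept = 0.0  # symmetric/degenerate design: side is immaterial
            side = "right" if intercept >= 0 else "left"
    if side not in ("left", "right"):
        raise ValueError(f"side must be auto/left/right, got {side!r}")
    flip = -1.0 if side == "left" else 1.0
    yw = flip * y

    k = len(yw)
    k0 = 0
    trace = []
    for it in range(max_iter):
        center, l0 = _l0_pass(yw, v, k0)
        k0_new = min(max(0, round(l0)), k - 1)
        trace.append((it, k0, center, l0))
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise RuntimeError(f"trim-and-fill did not stabilise in {max_iter} iterations; trace={trace}")

    center, _ = _l0_pass(yw, v, k0)
    filled: list[EffectSize] = list(effects)
    if k0 > 0:
        order = np.argsort(yw)
        for rank, idx in enumerate(order[k - k0:]):
            e = effects[int(idx)]
            filled.append(EffectSize(
                y=flip * (2.0 * center - yw[int(idx)]), v=e.v, corrected=e.corrected,
                substudy_id=f"fill:{e.substudy_id}", parent_study_id=f"fill:{e.parent_study_id}",
            ))
    t2 = tau2_reml(filled)
    mu_adj, se_adj, _, _, p_adj = pool_random_effects(filled, t2)
    return k0, filled, mu_adj, p_adj


def default_bias_targets(analysis: AnalysisSet, n_top: int = 3) -> list[str]:
    """Most-reported microRNAs: top-k overall and per pooled direction."""
    by_k = sorted(analysis.results, key=lambda r: (-r.k, r.mirna))
    targets: list[str] = [r.mirna for r in by_k[:n_top]]
    for direction in ("up", "down"):
        picked = [r.mirna for r in by_k if r.direction == direction][:n_top]
        targets.extend(m for m in picked if m not in targets)
    return targets


def bias_summary(analysis: AnalysisSet, corpus: StudyCorpus,
                 targets: Sequence[str] | None = None,
                 alpha: float = 0.05) -> list[BiasReport]:
    """Begg + Egger + trim-and-fill for each target microRNA.

    Targets default to the most-reported microRNAs overall and per
    direction.  Substudies all sharing one parent study do not fit the
    models and yield ``not_testable`` reports.
    """
    groups = effects_by_mirna(corpus)
    if targets is None:
        targets = default_bias_targets(analysis)
    reports = []
    for mirna in targets:
        if analysis.get(mirna) is None or mirna not in groups:
            logger.info("bias target %s absent from analysis; skipped", mirna)
            continue
        eff = groups[mirna]
        k = len(eff)
        n_par = _n_parents(eff)
        rep = BiasReport(mirna=mirna, k=k, n_parent_studies=n_par)
        if k < 3 or n_par < 2:
            reports.append(rep)
            continue
        rep.kendall_tau, rep.p_begg, rep.begg_method = begg_test(eff)
        rep.egger_intercept, rep.egger_z, rep.p_egger, rep.egger_perfect_fit = egger_test(eff)
        rep.k0, _, rep.mu_adjusted, rep.p_adjusted = trim_and_fill(eff)
        rep.significant_after_correction = bool(rep.p_adjusted < alpha)
        reports.append(rep)
    return reports
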