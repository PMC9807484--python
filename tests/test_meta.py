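import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirameta.corpus import StudyCorpus
from mirameta.meta import (MetaConfig, bonferroni_adjust, direction_consistency,
                           effect_from_counts, pool_random_effects, run_meta,
                           run_sensitivity, run_subgroups, tau2_eb, tau2_reml)

from conftest import make_effects, make_record


class TestEffectFromCounts:
    def test_plain_2x2(self):
        e = effect_from_counts(make_record(events_case=8, events_ctrl=2))
        assert e.y == pytest.approx(math.log(16), abs=1e-10)
        assert e.v == pytest.approx(1.25, abs=1e-10)
        assert not e.corrected

    def test_equal_proportions_give_zero(self):
        e = effect_from_counts(make_record(events_case=3, events_ctrl=3))
        assert e.y == 0.0

    def test_zero_cell_continuity_correction(self):
        e = effect_from_counts(make_record(events_case=5, events_ctrl=0))
        assert e.corrected
        assert e.y == pytest.approx(math.log(21), abs=1e-4)
        assert e.v == pytest.approx(2.4589, abs=1e-3)


class TestTau2:
    def test_balanced_closed_form(self):
        eff = make_effects([0.5, 1.0, 1.5], 0.1)
        # equal-variance case: both estimators equal max(0, S^2_y - v)
        assert tau2_eb(eff) == pytest.approx(0.15, abs=1e-6)
        assert tau2_reml(eff) == pytest.approx(0.15, abs=1e-6)

    def test_no_heterogeneity(self):
        eff = make_effects([0.7, 0.7, 0.7], [0.1, 0.2, 0.3])
        assert tau2_eb(eff) == 0.0
        assert tau2_reml(eff) == 0.0

    def test_two_point_algebra(self):
        assert tau2_eb(make_effects([0.0, 2.0], 1.0)) == pytest.approx(1.0, abs=1e-6)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="not meta-analysable"):
            tau2_eb(make_effects([1.0], 0.5))

    @pytest.mark.parametrize("seed", range(10))
    def test_balanced_designs_agree(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 10))
        y = rng.normal(0, 1.5, size=k)
        v = float(rng.uniform(0.05, 0.5))
        expected = max(0.0, float(np.var(y, ddof=1)) - v)
        assert tau2_eb(make_effects(y, v)) == pytest.approx(expected, abs=1e-5)
        assert tau2_reml(make_effects(y, v)) == pytest.approx(expected, abs=1e-5)

    def test_against_metafor_oracle(self):
        """Frozen oracle: R metafor rma(yi, vi, method=...) on this instance
        gives tau2 REML=0.238149, EB=0.259316, mu REML=0.621704 (se 0.283225)."""
        y = [0.12, 0.95, 1.40, -0.30, 0.78]
        v = [0.10, 0.20, 0.15, 0.30, 0.12]
        eff = make_effects(y, v)
        assert tau2_reml(eff) == pytest.approx(0.238149, abs=1e-4)
        assert tau2_eb(eff) == pytest.approx(0.259316, abs=1e-4)
        mu, se, *_ = pool_random_effects(eff, tau2_reml(eff))
        assert mu == pytest.approx(0.621704, abs=1e-4)
        assert se == pytest.approx(0.283225, abs=1e-4)


class TestPooling:
    def test_balanced_example(self):
        eff = make_effects([0.5, 1.0, 1.5], 0.1)
        mu, se, lo, hi, p = pool_random_effects(eff, 0.15)
        assert mu == pytest.approx(1.0, abs=1e-10)
        assert se == pytest.approx(0.2887, abs=1e-4)
        assert (lo, hi) == (pytest.approx(0.4342, abs=1e-4), pytest.approx(1.5658, abs=1e-4))
        assert p == pytest.approx(5.3e-4, rel=0.02)

    def test_dominant_weight_limit(self):
        mu, *_ = pool_random_effects(make_effects([1.0, 5.0], [0.01, 100.0]), 0.0)
        assert mu == pytest.approx(1.0004, abs=1e-4)

    @given(st.floats(0.001, 1.0), st.integers(1, 500))
    def test_bonferroni(self, p, m):
        adj = bonferroni_adjust(p, m)
        assert adj == min(1.0, m * p)

    def test_bonferroni_examples(self):
        assert bonferroni_adjust(0.001, 205) == pytest.approx(0.205)
        assert bonferroni_adjust(0.5, 5) == 1.0
        assert bonferroni_adjust(0.01, 1) == 0.01


class TestRunMeta:
    def test_single_substudy_mirna_excluded(self):
        corpus = StudyCorpus([make_record()])
        s = run_meta(corpus)
        assert s.results == [] and s.excluded == {"miR-1-3p": 1}

    def test_m_tests_equals_mirnas_analysed(self, two_mirna_corpus):
        s = run_meta(two_mirna_corpus)
        assert s.m_tests == 2
        for r in s.results:
            assert r.p_adj_reml == pytest.approx(min(1.0, 2 * r.p_raw_reml))

    def test_antisymmetry_under_arm_swap(self, two_mirna_corpus):
        s1 = run_meta(two_mirna_corpus)
        swapped = StudyCorpus([
            make_record(substudy_id=r.substudy_id, parent=r.parent_study_id,
                        mirna=r.mirna.canonical, n_case=r.n_ctrl, n_ctrl=r.n_case,
                        events_case=r.events_ctrl, events_ctrl=r.events_case)
            for r in two_mirna_corpus.records])
        s2 = run_meta(swapped)
        for r1 in s1.results:
            r2 = s2.get(r1.mirna)
            assert r2.mu_reml == pytest.approx(-r1.mu_reml, abs=1e-9)
            assert r2.mu_eb == pytest.approx(-r1.mu_eb, abs=1e-9)

    def test_permutation_invariance(self, two_mirna_corpus):
        s1 = run_meta(two_mirna_corpus)
        shuffled = StudyCorpus(list(reversed(two_mirna_corpus.records)))
        s2 = run_meta(shuffled)
        for r1 in s1.results:
            r2 = s2.get(r1.mirna)
            assert r2.mu_reml == pytest.approx(r1.mu_reml, abs=1e-12)
            assert r2.tau2_eb == pytest.approx(r1.tau2_eb, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_meta(StudyCorpus([]))


class TestStrata:
    def _mixed_corpus(self):
        recs = []
        for i in range(3):  # up in serum
            recs.append(make_record(substudy_id=f"se{i}", parent=f"ps{i}",
                                    events_case=9, events_ctrl=1))
        for i in range(3):  # down in plasma, same microRNA
            recs.append(make_record(substudy_id=f"pl{i}", parent=f"pp{i}",
                                    fraction="plasma", events_case=1, events_ctrl=9))
        return StudyCorpus(recs)

    def test_partition_and_inconsistency_table(self):
        sets, table = run_subgroups(self._mixed_corpus(), MetaConfig(), "blood_fraction")
        labels = {s.label for s in sets}
        assert labels == {"subgroup:serum", "subgroup:plasma"}
        assert set(table["mirna"]) == {"miR-1-3p"}
        assert set(table["direction"]) == {"up", "down"}

    def test_nanostring_stratum_skipped(self):
        recs = [make_record(substudy_id=f"n{i}", platform="nanostring") for i in range(3)]
        sets, _ = run_subgroups(StudyCorpus(recs), MetaConfig(), "platform")
        assert sets == []

    def test_sensitivity_inclusive_threshold(self):
        recs = [make_record(substudy_id=f"s{i}", parent=f"p{i}", n_case=12, n_ctrl=13,
                            events_case=9, events_ctrl=2) for i in range(3)]
        recs.append(make_record(substudy_id="small", parent="px", n_case=12, n_ctrl=12,
                                events_case=9, events_ctrl=2))
        sets = run_sensitivity(StudyCorpus(recs), thresholds=[25, 50])
        assert [s.label for s in sets] == ["sensitivity:n>=25", "sensitivity:n>=50"]
        assert sets[0].results[0].k == 3  # n=24 substudy excluded, n=25 kept
        assert sets[1].results == []

    def test_threshold_zero_equals_overall(self, two_mirna_corpus):
        overall = run_meta(two_mirna_corpus)
        s0 = run_sensitivity(two_mirna_corpus, thresholds=[0])[0]
        assert {r.mirna: r.mu_reml for r in s0.results} == \
               {r.mirna: r.mu_reml for r in overall.results}

    def test_planted_effect_and_heterogeneity_recovered(self):
        """Pooled estimates recover the planted logOR and between-study
        variance over 200 replicates, up to the known O(1/cell-count)
        attenuation of the empirical logOR (allowances 0.015 on mu and 0.01
        on tau2 at ~80 expected events per cell)."""
        from mirameta.simulate import SimulationConfig, simulate_corpus
        mus, taus = [], []
        for rep in range(200):
            cfg = SimulationConfig(seed=30000 + rep, n_mirnas=4, n_studies=30,
                                   effect_mirnas=4, report_prob=1.0,
                                   baseline_event_prob=0.4,
                                   sample_size_median=400.0,
                                   sample_size_bounds=(100, 1000),
                                   effect_logOR=1.0, tau_between=0.3)
            corpus, truth = simulate_corpus(cfg)
            for r in run_meta(corpus).results:
                sign = 1.0 if truth.true_direction[r.mirna] == "up" else -1.0
                mus.append(sign * r.mu_reml)
                taus.append(r.tau2_reml)
        mus, taus = np.array(mus), np.array(taus)
        mc_se_mu = mus.std(ddof=1) / np.sqrt(len(mus))
        mc_se_tau = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(mus.mean() - 1.0) < 2 * mc_se_mu + 0.015
        assert abs(taus.mean() - 0.09) < 3 * mc_se_tau + 0.01

    def test_direction_consistency_rules(self):
        sets, _ = run_subgroups(self._mixed_corpus(), MetaConfig(), "blood_fraction")
        cons = direction_consistency(sets)
        assert cons["miR-1-3p"] == "inconsistent"
        null = run_meta(StudyCorpus([
            make_record(substudy_id=f"x{i}", parent=f"q{i}", events_case=5, events_ctrl=5)
            for i in range(3)]))
        assert direction_consistency([null])["miR-1-3p"] == "never_significant"
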