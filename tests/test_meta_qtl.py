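"""Mixture fitting, criterion arithmetic, model selection and MQTL summaries."""

import math

import numpy as np
import pytest

from mqtlkit.consensus_map import ProjectedQTL
from mqtlkit.meta_qtl import (
    CriteriaRow,
    MixtureFit,
    assign_members,
    candidate_ks,
    fit_mixture,
    information_criteria,
    mqtl_summary,
    overview_index,
    run_chromosome,
    select_model,
)

from conftest import make_qtl


def projected(qtl_id, pos, sd, chrom=1):
    half = 1.96 * sd
    return ProjectedQTL(
        qtl=make_qtl(qtl_id=qtl_id, chrom=chrom, peak=pos,
                     ci=(pos - half, pos + half)),
        position_cm=pos, ci_low_cm=pos - half, ci_high_cm=pos + half, sd_cm=sd,
    )


class TestFitMixture:
    def test_k1_equal_sds_is_arithmetic_mean(self):
        fit = fit_mixture([10.0, 20.0], [1.0, 1.0], k=1)
        assert fit.means[0] == pytest.approx(15.0, abs=1e-10)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_k1_is_inverse_variance_weighted_mean(self):
        # (10/1 + 20/4) / (1 + 1/4) = 12
        fit = fit_mixture([10.0, 20.0], [1.0, 2.0], k=1)
        assert fit.means[0] == pytest.approx(12.0, abs=1e-10)

    def test_k2_recovers_two_well_separated_groups(self, rng):
        x = np.concatenate([rng.normal(20, 1, 20), rng.normal(60, 1, 20)])
        s = np.ones(40)
        fit2 = fit_mixture(x, s, k=2, seed=0)
        fit1 = fit_mixture(x, s, k=1, seed=0)
        assert np.abs(fit2.means - [20, 60]).max() < 0.5
        assert fit2.loglik >= fit1.loglik

    def test_loglik_monotone_within_run(self, rng):
        x = rng.uniform(0, 100, 30)
        s = rng.uniform(0.5, 2.0, 30)
        fit = fit_mixture(x, s, k=3, seed=1)
        diffs = np.diff(fit.loglik_path)
        assert np.all(diffs >= -1e-10)

    def test_responsibilities_row_normalized_and_means_sorted(self, rng):
        x = rng.uniform(0, 50, 25)
        fit = fit_mixture(x, np.ones(25), k=3, seed=2)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert np.all(np.diff(fit.means) >= 0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(positions=[1.0], sds=[1.0], k=2),
        dict(positions=[1.0, np.nan], sds=[1.0, 1.0], k=1),
        dict(positions=[1.0, 2.0], sds=[1.0, 0.0], k=1),
        dict(positions=[1.0, 2.0], sds=[1.0, 1.0], k=0),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_mixture(**bad)


class TestInformationCriteria:
    def make_fit(self, loglik, k, n, hard=True):
        resp = np.zeros((n, k))
        resp[:, 0] = 1.0 if hard else 1.0 / k
        if not hard:
            resp[:] = 1.0 / k
        return MixtureFit(k=k, means=np.arange(k, dtype=float),
                          weights=np.full(k, 1 / k), loglik=loglik,
                          responsibilities=resp, converged=True, n_iter=5)

    def test_hand_computed_values(self):
        row = information_criteria(self.make_fit(-10.0, 2, 20))
        assert row.p_free == 3
        assert row.aic == pytest.approx(26.0)
        assert row.aicc == pytest.approx(27.5)
        assert row.aic3 == pytest.approx(29.0)
        assert row.bic == pytest.approx(20 + 3 * math.log(20))
        # hard assignments: completed-data loglik equals the mixture loglik
        assert row.awe == pytest.approx(20 + 6 * (1.5 + math.log(20)))

    def test_k1_awe_has_no_entropy_term(self):
        row = information_criteria(self.make_fit(-10.0, 1, 20))
        assert row.awe == pytest.approx(20 + 2 * (1.5 + math.log(20)))

    def test_soft_assignments_penalize_awe(self):
        hard = information_criteria(self.make_fit(-10.0, 2, 20, hard=True))
        soft = information_criteria(self.make_fit(-10.0, 2, 20, hard=False))
        assert soft.awe > hard.awe  # entropy -sum r ln r > 0 raises AWE

    def test_small_n_gives_infinite_aicc_with_warning(self):
        with pytest.warns(RuntimeWarning):
            row = information_criteria(self.make_fit(-10.0, 2, 4))
        assert math.isinf(row.aicc)

    def test_aicc_at_least_aic(self):
        row = information_criteria(self.make_fit(-3.0, 3, 30))
        assert row.aicc >= row.aic


class TestSelectModel:
    def make_rows(self, values):
        """values: {k: (aic, aicc, aic3, bic, awe)}"""
        return [CriteriaRow(k, 2 * k - 1, 50, *v) for k, v in values.items()]

    def test_unanimous_minimum(self):
        rows = self.make_rows({1: (5, 5, 5, 5, 5), 2: (9, 9, 9, 9, 9),
                               3: (1, 1, 1, 1, 1)})
        assert select_model(rows) == 3

    def test_three_of_five_rule(self):
        rows = self.make_rows({
            1: (9, 9, 9, 1, 1),   # BIC and AWE prefer K=1
            2: (1, 1, 1, 9, 9),   # AIC, AICc, AIC3 prefer K=2
        })
        assert select_model(rows) == 2

    def test_tie_break_most_minima_then_smallest_k(self):
        rows = self.make_rows({
            1: (9, 9, 9, 9, 1),   # AWE
            2: (1, 1, 9, 9, 9),   # AIC, AICc
            3: (9, 9, 1, 1, 9),   # AIC3, BIC
        })
        assert select_model(rows) == 2  # 2-2-1 votes -> smallest among the 2s

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            select_model([])


class TestMqtlSummary:
    def test_single_member_posterior(self):
        peak, lo, hi = mqtl_summary([projected("q", 30.0, 2.0)])
        assert peak == pytest.approx(30.0)
        assert hi - lo == pytest.approx(2 * 1.96 * 2.0)

    def test_two_equal_members_shrink_by_sqrt2(self):
        s = 1.5
        peak, lo, hi = mqtl_summary(
            [projected("a", 10.0, s), projected("b", 14.0, s)])
        assert peak == pytest.approx(12.0)
        assert hi - lo == pytest.approx(3.92 * s / math.sqrt(2))

    def test_five_members_narrower_than_any_member(self):
        members = [projected(f"q{i}", 20.0 + i * 0.1, 2.0) for i in range(5)]
        _, lo, hi = mqtl_summary(members)
        assert hi - lo == pytest.approx(3.92 * 2.0 / math.sqrt(5))
        assert hi - lo < 3.92 * 2.0


class TestAssignMembers:
    def test_membership_above_threshold_and_peak_in_ci(self):
        qtls = [projected("a", 10.0, 1.0), projected("b", 10.2, 1.0)]
        fit = fit_mixture([10.0, 10.2], [1.0, 1.0], k=1)
        mqtls, unassigned = assign_members(fit, qtls)
        assert len(mqtls) == 1 and not unassigned
        assert mqtls[0].mqtl_id == "MQTL1.1"
        assert {q for q, _ in mqtls[0].members} == {"a", "b"}
        assert all(p > 0.60 for _, p in mqtls[0].members)

    def test_split_membership_unassigned(self):
        qtls = [projected("a", 10.0, 1.0)]
        fit = MixtureFit(k=2, means=np.array([9.0, 11.0]),
                         weights=np.array([0.5, 0.5]), loglik=0.0,
                         responsibilities=np.array([[0.5, 0.5]]),
                         converged=True, n_iter=1)
        mqtls, unassigned = assign_members(fit, qtls)
        assert not mqtls and unassigned == ["a"]

    def test_barely_above_threshold_assigned(self):
        qtls = [projected("a", 10.0, 1.0)]
        fit = MixtureFit(k=2, means=np.array([10.0, 30.0]),
                         weights=np.array([0.6, 0.4]), loglik=0.0,
                         responsibilities=np.array([[0.61, 0.39]]),
                         converged=True, n_iter=1)
        mqtls, unassigned = assign_members(fit, qtls)
        assert [q for q, _ in mqtls[0].members] == ["a"] and not unassigned

    def test_peak_outside_component_ci_unassigned(self):
        # many precise members make the combined CI narrow; a distant member
        # with high responsibility still fails the peak-in-CI requirement
        qtls = [projected(f"q{i}", 20.0, 0.2) for i in range(8)]
        qtls.append(projected("far", 22.0, 5.0))
        fit = fit_mixture([q.position_cm for q in qtls],
                          [q.sd_cm for q in qtls], k=1)
        mqtls, unassigned = assign_members(fit, qtls)
        assert "far" in unassigned


class TestRunChromosome:
    def test_single_qtl_degenerates_to_itself(self):
        q = projected("only", 33.0, 1.0)
        result = run_chromosome([q])
        assert result.selected_k == 1
        assert [m for m, _ in result.mqtls[0].members] == ["only"]
        assert result.mqtls[0].peak_cm == pytest.approx(33.0)

    def test_candidate_k_rules(self):
        assert candidate_ks(1) == [1]
        assert candidate_ks(8) == [1, 2, 3, 4]
        assert candidate_ks(60) == list(range(1, 13))
        assert candidate_ks(14) == list(range(1, 8))
        assert candidate_ks(0) == []

    def test_empty_input(self):
        result = run_chromosome([])
        assert result.mqtls == [] and result.fit is None

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            run_chromosome([projected("a", 1.0, 1.0, chrom=1),
                            projected("b", 1.0, 1.0, chrom=2)])


class TestOverviewIndex:
    def test_point_mass_lands_in_one_bin(self):
        q = projected("q", 5.25, 0.01)
        ov = overview_index([q], span=(0.0, 10.0))
        values = {(a, b): v for a, b, v in ov.bins}
        assert values[(5.0, 5.5)] == pytest.approx(1.0, abs=1e-6)
        assert sum(values.values()) == pytest.approx(1.0, abs=1e-6)

    def test_boundary_qtl_splits_between_bins(self):
        q = projected("q", 5.0, 0.05)
        ov = overview_index([q], span=(0.0, 10.0))
        values = {(a, b): v for a, b, v in ov.bins}
        assert values[(4.5, 5.0)] == pytest.approx(0.5, abs=1e-6)
        assert values[(5.0, 5.5)] == pytest.approx(0.5, abs=1e-6)

    def test_matches_quadrature_oracle(self):
        from scipy.integrate import quad
        from scipy.stats import norm as snorm

        qtls = [projected("a", 3.0, 0.8), projected("b", 7.4, 1.5),
                projected("c", 5.1, 0.3)]
        ov = overview_index(qtls, span=(0.0, 10.0))
        for a, b, v in ov.bins:
            expected = np.mean([
                quad(lambda t: snorm.pdf(t, q.position_cm, q.sd_cm), a, b)[0]
                for q in qtls
            ])
            assert v == pytest.approx(expected, abs=1e-6)

    def test_bins_tile_span_and_mass_bounded(self):
        qtls = [projected("a", 2.0, 1.0), projected("b", 9.0, 2.0)]
        ov = overview_index(qtls, span=(0.0, 10.3))
        starts = [a for a, _, _ in ov.bins]
        ends = [b for _, b, _ in ov.bins]
        assert starts[0] == 0.0 and ends[-1] == pytest.approx(10.3)
        assert all(e1 == pytest.approx(s2) for e1, s2 in zip(ends, starts[1:]))
        assert all(v >= 0 for _, _, v in ov.bins)
        # total index mass <= 1 because it is a per-QTL average of masses <= 1
        assert sum(v for _, _, v in ov.bins) <= 1.0 + 1e-9

    def test_empty_input_gives_zero_index(self):
        ov = overview_index([], span=(0.0, 2.0))
        assert all(v == 0.0 for _, _, v in ov.bins)


def test_mqtl_ci_narrower_than_members_on_simulated_chromosome(one_chrom_panel):
    """Pooling member QTLs tightens the consensus interval."""
    _, _, projected_qtls = one_chrom_panel
    result = run_chromosome(projected_qtls, seed=11)
    member_widths = [q.ci_high_cm - q.ci_low_cm for q in projected_qtls]
    mqtl_widths = [m.ci_high_cm - m.ci_low_cm for m in result.mqtls]
    assert np.mean(mqtl_widths) < np.mean(member_widths)
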