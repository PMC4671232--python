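"""Discounting, survival, QALY and cost accounting of the Markov stage."""

import numpy as np
import pytest

from hgscreen.exposure import weighted_tail_probability
from hgscreen.lifecourse import (
    CostSchedule,
    DiscountSchedule,
    LifeTable,
    TableError,
    UtilityNorms,
    discount_factor,
    discounted_life_years,
    education_cost_pv,
    lifetime_qalys,
    screening_cost_per_birth,
    survival_curve,
)
from hgscreen.parameters import Strategy


def _flat_table(n_ages, q=0.0):
    qx = np.full(n_ages + 1, q)
    qx[-1] = 1.0
    return LifeTable(qx)


class TestDiscounting:
    def test_zero_rate_is_one_everywhere(self):
        ds = DiscountSchedule.constant(0.0)
        assert ds.factors(50) == pytest.approx(np.ones(50))

    def test_constant_five_percent(self):
        ds = DiscountSchedule.constant(0.05)
        assert discount_factor(ds, 0) == 1.0
        assert discount_factor(ds, 1) == pytest.approx(1 / 1.05, abs=1e-12)
        assert discount_factor(ds, 10) == pytest.approx(1.05 ** -10, abs=1e-12)

    def test_variable_schedule_hand_product(self):
        # 5% for 10 years, 3% for 5, 1% thereafter
        ds = DiscountSchedule.variable()
        assert discount_factor(ds, 12) == pytest.approx(
            1.05 ** -10 * 1.03 ** -2, abs=1e-12
        )
        assert discount_factor(ds, 12) == pytest.approx(0.5787, abs=1e-4)
        assert discount_factor(ds, 20) == pytest.approx(
            1.05 ** -10 * 1.03 ** -5 * 1.01 ** -5, abs=1e-12
        )

    def test_dict_roundtrip(self):
        for ds in (DiscountSchedule.constant(0.05), DiscountSchedule.variable()):
            assert DiscountSchedule.from_dict(ds.to_dict()) == ds


class TestSurvival:
    def test_no_mortality(self):
        S = survival_curve(_flat_table(10))
        assert S == pytest.approx(np.ones(11))

    def test_constant_hazard_closed_form(self):
        S = survival_curve(_flat_table(5, q=0.5))
        assert S[2] == pytest.approx(0.25, abs=1e-15)

    def test_product_oracle_on_gompertz(self, lt):
        S = survival_curve(lt)
        oracle = [1.0]
        for q in lt.qx[:-1]:
            oracle.append(oracle[-1] * (1 - q))
        assert S == pytest.approx(oracle, abs=1e-12)
        assert np.all(np.diff(S) <= 0)


class TestQalys:
    def test_annuity_with_no_mortality_no_discount(self):
        T = 30
        lt = _flat_table(T)
        un = UtilityNorms(np.ones(T + 1))
        ds = DiscountSchedule.constant(0.0)
        assert lifetime_qalys(lt, un, ds) == pytest.approx(T + 1, abs=1e-9)

    def test_geometric_series_limit(self):
        # u = 1, no deaths, 5%: sum_{t>=0} 1.05^-t -> 1.05/0.05 = 21
        lt = _flat_table(2000)
        un = UtilityNorms(np.ones(2001))
        ds = DiscountSchedule.constant(0.05)
        assert lifetime_qalys(lt, un, ds) == pytest.approx(21.0, abs=1e-6)

    def test_mmr_identity(self, lt, un):
        """QALY(MMR) = QALY - d x discounted life years while u - d >= 0."""
        ds = DiscountSchedule.constant(0.05)
        base = lifetime_qalys(lt, un, ds)
        mmr = lifetime_qalys(lt, un, ds, disutility=0.38, has_mmr=True)
        dly = discounted_life_years(lt, ds)
        assert base - mmr == pytest.approx(0.38 * dly, abs=1e-9)

    def test_monotone_in_rate_and_disutility(self, lt, un):
        q_by_rate = [
            lifetime_qalys(lt, un, DiscountSchedule.constant(r))
            for r in (0.0, 0.03, 0.05)
        ]
        assert q_by_rate[0] > q_by_rate[1] > q_by_rate[2]
        ds = DiscountSchedule.constant(0.05)
        q_by_dis = [
            lifetime_qalys(lt, un, ds, disutility=d, has_mmr=True)
            for d in (0.0, 0.38, 0.76)
        ]
        assert q_by_dis[0] > q_by_dis[1] > q_by_dis[2]


class TestEducationCosts:
    def test_undiscounted_no_mortality_hand_sum(self):
        # 5 years JK-grade 3, 5 years grades 4-8, 4 years grades 9-12
        cs = CostSchedule()
        total = education_cost_pv(cs, _flat_table(20), DiscountSchedule.constant(0.0))
        assert total == pytest.approx(5 * 931.29 + 5 * 715.34 + 4 * 472.92, abs=1e-9)

    def test_discounting_shrinks_value(self, lt):
        cs = CostSchedule()
        v0 = education_cost_pv(cs, lt, DiscountSchedule.constant(0.0))
        v5 = education_cost_pv(cs, lt, DiscountSchedule.constant(0.05))
        assert v5 < v0

    def test_no_survivors_no_cost(self):
        qx = np.zeros(20)
        qx[3] = 1.0
        qx[-1] = 1.0
        total = education_cost_pv(CostSchedule(), LifeTable(qx),
                                  DiscountSchedule.constant(0.0))
        assert total == 0.0


class TestScreeningCost:
    def test_reference_is_free(self, ps):
        assert screening_cost_per_birth(ps, Strategy.reference()) == 0.0

    def test_formula_audit(self, ps):
        p_advice = weighted_tail_probability(ps, 3.4)
        expected = (23.27 + 0.08 * 33.70 + p_advice * 33.70) / 0.9
        got = screening_cost_per_birth(ps, Strategy.screening(3.4))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_visit_for_every_screening_scenario(self, ps):
        p_advice = weighted_tail_probability(ps, 3.4)
        expected = (23.27 + 33.70 + p_advice * 33.70) / 0.9
        got = screening_cost_per_birth(
            ps, Strategy.screening(3.4), visit_per_screening=True
        )
        assert got == pytest.approx(expected, abs=1e-12)


class TestTableIO:
    def test_life_table_roundtrip(self, lt, tmp_path):
        path = tmp_path / "lt.csv"
        lt.to_file(path)
        assert LifeTable.from_file(path).qx == pytest.approx(lt.qx, abs=1e-12)

    def test_utility_roundtrip(self, un, tmp_path):
        path = tmp_path / "un.csv"
        un.to_file(path)
        assert UtilityNorms.from_file(path).utility == pytest.approx(
            un.utility, abs=1e-12
        )

    def test_open_table_rejected(self):
        with pytest.raises(TableError):
            LifeTable(np.array([0.01, 0.02, 0.5]))  # q(max_age) != 1

    def test_out_of_range_utility_rejected(self):
        with pytest.raises(TableError):
            UtilityNorms(np.array([0.9, 1.2]))
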