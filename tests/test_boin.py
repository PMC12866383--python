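"""BOIN boundaries, decisions, elimination and MTD selection."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from boindosim.boin import (
    BoinDesign,
    Decision,
    DlState,
    InvalidDesignError,
    compute_boundaries,
    decide,
    eliminate_check,
    isotonic_estimates,
    select_mtd,
)


class TestBoundaries:
    @pytest.mark.parametrize(
        "phi, phi1, phi2, expect_e, expect_d",
        [
            # frozen from the closed-form expressions evaluated at 30
            # significant digits with mpmath
            (0.25, 0.15, 0.35, 0.1968008706, 0.2983921524),
            (0.30, 0.18, 0.42, 0.2364906852, 0.3585194646),
        ],
    )
    def test_closed_form_values(self, phi, phi1, phi2, expect_e, expect_d):
        le, ld = compute_boundaries(phi, phi1, phi2)
        assert le == pytest.approx(expect_e, abs=1e-9)
        assert ld == pytest.approx(expect_d, abs=1e-9)

    @pytest.mark.parametrize("phi", np.linspace(0.1, 0.4, 13))
    def test_interval_brackets_target(self, phi):
        le, ld = compute_boundaries(phi, 0.6 * phi, 1.4 * phi)
        assert le < phi < ld

    def test_boundaries_increase_with_phi(self):
        grid = np.linspace(0.1, 0.4, 31)
        les, lds = zip(*(compute_boundaries(p, 0.6 * p, 1.4 * p) for p in grid))
        assert all(b > a for a, b in zip(les, les[1:]))
        assert all(b > a for a, b in zip(lds, lds[1:]))

    @pytest.mark.parametrize("triple", [(0.25, 0.25, 0.35), (0.25, 0.3, 0.35),
                                        (0.25, 0.15, 0.25), (0.0, -0.1, 0.5)])
    def test_invalid_ordering_rejected(self, triple):
        with pytest.raises(InvalidDesignError):
            compute_boundaries(*triple)


class TestEliminateCheck:
    def test_three_of_five_dlts_fires(self):
        # Pr(p > 0.25 | Beta(4, 3)) = 0.96240234375 exactly
        assert eliminate_check(5, 3, 0.25, 0.95, 3) is True
        assert stats.beta.sf(0.25, 4, 3) == pytest.approx(0.96240234375, abs=1e-12)

    def test_zero_dlts_posterior_is_closed_form(self):
        # y = 0: Pr(p > phi) = (1 - phi)^(n+1) = 0.75^4
        assert eliminate_check(3, 0, 0.25) is False
        assert stats.beta.sf(0.25, 1, 4) == pytest.approx(0.75**4, abs=1e-12)

    def test_minimum_n_gate(self):
        assert eliminate_check(2, 2, 0.25) is False

    def test_matches_brute_force_integral(self):
        """Posterior tail equals numeric integration of the beta density."""
        for n in range(1, 13):
            for y in range(n + 1):
                a, b = 1 + y, 1 + n - y
                norm = math.gamma(a + b) / (math.gamma(a) * math.gamma(b))
                val, _ = integrate.quad(
                    lambda p: norm * p ** (a - 1) * (1 - p) ** (b - 1), 0.25, 1.0
                )
                assert stats.beta.sf(0.25, a, b) == pytest.approx(val, abs=1e-8)
                assert eliminate_check(n, y, 0.25, 0.95, 1) == (val > 0.95)


class TestDecide:
    def test_no_dlts_escalates(self, design):
        st = DlState(0, n_evaluable=3, n_dlt=0)
        assert decide(st, design, True, False) is Decision.ESCALATE

    def test_three_of_five_deescalates_and_eliminates(self, design):
        st = DlState(2, n_evaluable=5, n_dlt=3)
        assert decide(st, design, False, True) is Decision.DEESCALATE_AND_ELIMINATE

    def test_escalate_into_eliminated_level_degrades_to_stay(self, design):
        st = DlState(1, n_evaluable=9, n_dlt=0)
        assert decide(st, design, False, True) is Decision.STAY

    def test_deescalate_below_lowest_terminates(self, design):
        st = DlState(0, n_evaluable=3, n_dlt=3)
        assert decide(st, design, False, False) is Decision.TERMINATE

    def test_empty_cohort_rejected(self, design):
        with pytest.raises(ValueError):
            decide(DlState(0, 0, 0), design, True, True)

    @pytest.mark.parametrize("n", [3, 5, 6, 9])
    def test_decision_monotone_in_dlt_count(self, design, n):
        """escalate -> stay -> deescalate as y rises, never backwards."""
        order = {
            Decision.ESCALATE: 0,
            Decision.STAY: 1,
            Decision.DEESCALATE: 2,
            Decision.DEESCALATE_AND_ELIMINATE: 2,
        }
        ranks = [
            order[decide(DlState(1, n, y), design, True, True)] for y in range(n + 1)
        ]
        assert ranks == sorted(ranks)


class TestSelectMtd:
    def test_trial_history_selects_midlevel(self, design):
        """3/0 at the step-up rung, 9/0 at 9.25, 3/5 eliminated at 11.1
        must yield the 9.25 GBq level as MTD."""
        states = [
            DlState(0, 3, 0),
            DlState(1, 9, 0),
            DlState(2, 5, 3, eliminated=True),
        ]
        assert select_mtd(states, design) == 1

    def test_single_tried_level(self, design):
        assert select_mtd([DlState(0, 3, 0)], design) == 0

    def test_two_levels_brute_force(self, design):
        # 1/6 vs 3/6: posterior means 1.05/6.1 = 0.172 and 3.05/6.1 = 0.5
        # are already isotonic; 0.172 is closer to phi = 0.25
        assert select_mtd([DlState(0, 6, 1), DlState(1, 6, 3)], design) == 0

    def test_never_selects_eliminated(self, design):
        states = [DlState(0, 3, 2, eliminated=True), DlState(1, 3, 3, eliminated=True)]
        assert select_mtd(states, design) is None

    def test_isotonic_estimates_nondecreasing(self, design):
        rng = np.random.default_rng(7)
        for _ in range(50):
            states = [
                DlState(i, int(n), int(rng.integers(0, n + 1)))
                for i, n in enumerate(rng.integers(1, 10, size=4))
            ]
            iso = isotonic_estimates(states)
            assert all(b >= a - 1e-12 for a, b in zip(iso, iso[1:]))

    def test_pava_matches_sklearn(self):
        """Hand-rolled PAVA agrees with an independent isotonic fit."""
        sklearn_iso = pytest.importorskip("sklearn.isotonic")
        rng = np.random.default_rng(11)
        for _ in range(25):
            k = int(rng.integers(2, 6))
            states = [
                DlState(i, int(n), int(rng.integers(0, n + 1)))
                for i, n in enumerate(rng.integers(1, 12, size=k))
            ]
            means, weights = [], []
            for st in states:
                a, b = st.n_dlt + 0.05, st.n_evaluable - st.n_dlt + 0.05
                means.append(a / (a + b))
                weights.append(((a + b) ** 2 * (a + b + 1)) / (a * b))
            ours = isotonic_estimates(states)
            ref = sklearn_iso.IsotonicRegression().fit(
                np.arange(k), means, sample_weight=weights
            ).predict(np.arange(k))
            np.testing.assert_allclose(ours, ref, atol=1e-10)


def test_design_invariants_validated():
    with pytest.raises(InvalidDesignError):
        BoinDesign(phi=0.25, phi1=0.3)
    with pytest.raises(InvalidDesignError):
        BoinDesign(max_per_dl=2, min_cohort=3)
    with pytest.raises(InvalidDesignError):
        BoinDesign(max_total=5, max_per_dl=9)
    d = BoinDesign(phi=0.25)
    assert d.phi1 == pytest.approx(0.15)
    assert d.phi2 == pytest.approx(0.35)
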