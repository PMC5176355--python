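"""Mass-action sequestration solver: oracles, closed forms, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdtox.equilibrium import (
    DEFAULT_CELL_VOLUME_L,
    EquilibriumSystem,
    Species,
    copies_to_molar,
    molar_to_copies,
    percent,
    solve_competitive,
    solve_pairwise,
    titration_scan,
)


def fixed_point_complex(D, P, K, iters=500):
    """Independent oracle: iterate c <- (D - c)(P - c)/K to convergence."""
    c = 0.0
    for _ in range(iters):
        c = (D - c) * (P - c) / K
    return c


def brute_force_free_hub(totals, kds, H, grid=4000, refine=6):
    """Oracle for the multi-partner system: nested grid search on the free-hub
    conservation equation, independent of the bisection implementation."""
    lo, hi = 0.0, H
    for _ in range(refine):
        hs = np.linspace(lo, hi, grid)
        excess = hs + sum(hs * P / (K + hs) for P, K in zip(totals, kds)) - H
        i = int(np.searchsorted(excess, 0.0))
        i = min(max(i, 1), grid - 1)
        lo, hi = hs[i - 1], hs[i]
    return 0.5 * (lo + hi)


class TestPairwise:
    def test_matches_fixed_point_oracle_at_study_concentrations(self):
        # basal DHFR 5e-8 M vs PurH 2e-7 M at KD 3 uM
        D, P, K = 5e-8, 2e-7, 3e-6
        st_ = solve_pairwise(D, P, K)
        c = st_.complex_conc[("hub", "partner")]
        assert c == pytest.approx(fixed_point_complex(D, P, K), rel=1e-9)
        assert st_.fraction_bound["hub"] == pytest.approx(0.0616, abs=5e-4)
        assert st_.fraction_bound["partner"] == pytest.approx(0.0154, abs=5e-4)

    def test_no_partner_leaves_hub_free(self):
        st_ = solve_pairwise(5e-8, 0.0, 3e-6)
        assert st_.complex_conc[("hub", "partner")] == 0.0
        assert st_.free_conc["hub"] == 5e-8

    def test_weak_binding_limit_leaves_both_free(self):
        st_ = solve_pairwise(1e-6, 1e-6, 1.0)
        assert st_.fraction_bound["hub"] == pytest.approx(0.0, abs=1e-5)
        assert st_.fraction_bound["partner"] == pytest.approx(0.0, abs=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_pairwise(-1e-9, 1e-7, 1e-6)
        with pytest.raises(ValueError):
            solve_pairwise(1e-9, 1e-7, 0.0)

    @given(
        D=st.floats(1e-12, 1e-3),
        P=st.floats(1e-12, 1e-3),
        K=st.floats(1e-9, 1e-2),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_conservation_and_mass_action(self, D, P, K):
        st_ = solve_pairwise(D, P, K)
        c = st_.complex_conc[("hub", "partner")]
        assert 0.0 <= c <= min(D, P)
        assert st_.free_conc["hub"] + c == pytest.approx(D, rel=1e-9)
        assert st_.free_conc["partner"] + c == pytest.approx(P, rel=1e-9)
        # mass action: c = h*p/K
        assert c == pytest.approx(
            st_.free_conc["hub"] * st_.free_conc["partner"] / K, rel=1e-9
        )

    def test_trace_partner_limit_closed_form(self):
        # P << K and P << H: bound fraction of partner -> H/(H+K)
        H, P, K = 1e-5, 1e-10, 3e-6
        st_ = solve_pairwise(H, P, K)
        assert st_.fraction_bound["partner"] == pytest.approx(H / (H + K), rel=1e-2)


class TestCompetitive:
    def _system(self, hub_total, partner_totals, kds):
        return EquilibriumSystem.from_totals("hub", hub_total, partner_totals, kds)

    def test_single_partner_reduces_to_pairwise(self):
        sys_ = self._system(5e-8, {"p": 2e-7}, {"p": 3e-6})
        st_comp = solve_competitive(sys_)
        st_pair = solve_pairwise(5e-8, 2e-7, 3e-6)
        assert st_comp.free_conc["hub"] == pytest.approx(
            st_pair.free_conc["hub"], rel=1e-9
        )
        assert st_comp.complex_conc[("hub", "p")] == pytest.approx(
            st_pair.complex_conc[("hub", "partner")], rel=1e-9
        )

    def test_two_identical_partners_match_grid_oracle(self):
        totals, kds = [2e-7, 2e-7], [3e-6, 3e-6]
        sys_ = self._system(5e-8, dict(zip("ab", totals)), dict(zip("ab", kds)))
        st_ = solve_competitive(sys_)
        h_oracle = brute_force_free_hub(totals, kds, 5e-8)
        assert st_.free_conc["hub"] == pytest.approx(h_oracle, rel=1e-6)

    def test_zero_hub_leaves_partners_free(self):
        sys_ = self._system(0.0, {"a": 1e-7, "b": 2e-7}, {"a": 1e-6, "b": 2e-6})
        st_ = solve_competitive(sys_)
        assert st_.free_conc["a"] == 1e-7
        assert st_.free_conc["b"] == 2e-7
        assert all(v == 0.0 for v in st_.complex_conc.values())

    def test_no_partners_returns_all_free(self):
        sys_ = EquilibriumSystem(Species("hub", 1e-6), (), ())
        st_ = solve_competitive(sys_)
        assert st_.free_conc == {"hub": 1e-6}

    @given(
        H=st.floats(1e-10, 1e-4),
        totals=st.lists(st.floats(1e-10, 1e-4), min_size=1, max_size=3),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_on_random_systems(self, H, totals, data):
        kds = [data.draw(st.floats(1e-8, 1e-3)) for _ in totals]
        names = [f"p{i}" for i in range(len(totals))]
        sys_ = self._system(H, dict(zip(names, totals)), dict(zip(names, kds)))
        st_ = solve_competitive(sys_)
        total_complex = sum(st_.complex_conc.values())
        assert st_.free_conc["hub"] + total_complex == pytest.approx(H, rel=1e-9)
        for n, tot in zip(names, totals):
            c = st_.complex_conc[("hub", n)]
            assert st_.free_conc[n] + c == pytest.approx(tot, rel=1e-9)
            assert c == pytest.approx(
                st_.free_conc["hub"] * st_.free_conc[n] / kds[names.index(n)],
                rel=1e-7,
            )


class TestTitration:
    def test_partner_bound_fraction_monotone_in_fold(self):
        sys_ = EquilibriumSystem.from_totals("hub", 5e-8, {"p": 2e-7}, {"p": 3e-6})
        scan = titration_scan(sys_, np.logspace(0, 4, 25))
        fb = scan["fbound_p"].to_numpy()
        assert np.all(np.diff(fb) >= -1e-12)

    def test_thousandfold_overexpression_saturates_partner(self):
        # hub in vast excess: free partner fraction -> K/(K + hub_free)
        sys_ = EquilibriumSystem.from_totals("hub", 5e-8, {"p": 2e-7}, {"p": 3e-6})
        scan = titration_scan(sys_, [1000.0])
        free_frac = 1.0 - float(scan["fbound_p"].iloc[0])
        assert free_frac == pytest.approx(3e-6 / (3e-6 + 4.98e-5), rel=2e-2)

    def test_fold_one_reproduces_basal_state(self):
        sys_ = EquilibriumSystem.from_totals("hub", 5e-8, {"p": 2e-7}, {"p": 3e-6})
        scan = titration_scan(sys_, [1.0])
        basal = solve_pairwise(5e-8, 2e-7, 3e-6)
        assert float(scan["fbound_p"].iloc[0]) == pytest.approx(
            basal.fraction_bound["partner"], rel=1e-9
        )

    def test_empty_factor_list_gives_empty_table(self):
        sys_ = EquilibriumSystem.from_totals("hub", 5e-8, {"p": 2e-7}, {"p": 3e-6})
        assert len(titration_scan(sys_, [])) == 0

    def test_nonpositive_fold_rejected(self):
        sys_ = EquilibriumSystem.from_totals("hub", 5e-8, {"p": 2e-7}, {"p": 3e-6})
        with pytest.raises(ValueError):
            titration_scan(sys_, [0.0, 1.0])


class TestUnits:
    @pytest.mark.parametrize(
        "copies,expected", [(50, 5.0e-8), (200, 2.0e-7), (0, 0.0)]
    )
    def test_copies_to_molar_default_volume(self, copies, expected):
        assert copies_to_molar(copies) == pytest.approx(expected, rel=1e-2)

    def test_round_trip(self):
        assert molar_to_copies(copies_to_molar(123.0)) == pytest.approx(123.0, rel=1e-12)

    def test_volume_must_be_positive(self):
        with pytest.raises(ValueError):
            copies_to_molar(10, 0.0)

    def test_percent_rounds_half_up(self):
        assert percent(0.015) == 2.0
        assert percent(0.0616) == 6.0
        assert percent(0.125, ndigits=1) == 12.5


class TestSystemValidation:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            EquilibriumSystem.from_totals("x", 1e-7, {"x": 1e-7}, {"x": 1e-6})

    def test_missing_pair_rejected(self):
        from gdtox.equilibrium import BindingPair

        with pytest.raises(ValueError):
            EquilibriumSystem(
                Species("h", 1e-7),
                (Species("a", 1e-7), Species("b", 1e-7)),
                (BindingPair("h", "a", 1e-6),),
            )
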