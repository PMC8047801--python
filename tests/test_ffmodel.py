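"""Pair-potential algebra: LJ/Coulomb evaluation, combination rules, and the
built-in optimized Mg2+ parameter sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgff.errors import DomainError, LookupError_
from mgff.ffmodel import (
    AMBER_PHOSPHATE_OXYGEN,
    TIP3P_OXYGEN,
    IonModel,
    LJParams,
    PairInteraction,
    ScalingFactors,
    available_params,
    builtin_params,
    combine_lb,
    combine_scaled,
    coulomb_energy,
    invert_lb_epsilon,
    lj_energy,
    potential_curve,
)

lj_params = st.builds(
    LJParams,
    sigma=st.floats(0.05, 0.6),
    epsilon=st.floats(0.0, 500.0),
)


class TestLJEnergy:
    @pytest.mark.parametrize(
        "sigma,eps,c4,r,expected",
        [
            (0.3, 1.0, 0.0, 0.3, 0.0),  # V(sigma) = 0 for 12-6
            (0.3, 1.0, 0.0, 0.3 * 2 ** (1 / 6), -1.0),  # well depth -eps at the minimum
            # independent high-precision arithmetic, frozen
            (0.2085, 12.250, 0.0, 0.30, -4.899788177940852),
        ],
    )
    def test_closed_form_values(self, sigma, eps, c4, r, expected):
        pair = PairInteraction(sigma_ij=sigma, epsilon_ij=eps, c4=c4)
        assert lj_energy(pair, r) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_r_rejected(self):
        pair = PairInteraction(0.3, 1.0)
        for bad in (0.0, -0.1, np.array([0.2, -0.3])):
            with pytest.raises(DomainError):
                lj_energy(pair, bad)

    def test_decays_to_zero_at_long_range(self):
        pair = PairInteraction(0.3, 5.0)
        r = np.linspace(15 * pair.sigma_ij, 40 * pair.sigma_ij, 50)
        assert np.all(np.abs(lj_energy(pair, r)) < 1e-6 * pair.epsilon_ij)
        # and strictly decreasing magnitude toward zero
        assert np.all(np.diff(np.abs(lj_energy(pair, r))) < 0)

    def test_r4_term_strictly_lowers_curve(self):
        base = PairInteraction(0.25, 10.0, c4=0.0)
        with_c4 = PairInteraction(0.25, 10.0, c4=5e-4)
        r = np.linspace(0.1, 2.0, 200)
        assert np.all(lj_energy(with_c4, r) < lj_energy(base, r))


class TestCoulomb:
    def test_zero_charge(self):
        assert coulomb_energy(0.0, 3.0, 1.0) == 0.0

    def test_unlike_charges_at_unit_distance(self):
        # -2 * k_e with k_e = 138.935458 kJ nm / (mol e^2)
        assert coulomb_energy(2, -1, 1.0) == pytest.approx(-277.870916, abs=1e-9)

    @given(
        qa=st.floats(-3, 3), qb=st.floats(-3, 3), r=st.floats(0.05, 5.0)
    )
    def test_symmetric_in_charges(self, qa, qb, r):
        assert coulomb_energy(qa, qb, r) == coulomb_energy(qb, qa, r)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            coulomb_energy(1, 1, 0.0)


class TestCombinationRules:
    @pytest.mark.parametrize(
        "name,sigma_io,eps_io",
        [("microMg", 0.2085, 12.250), ("nanoMg", 0.2088, 15.750)],
    )
    def test_ion_water_pairs_reproduce_printed_values(self, name, sigma_io, eps_io):
        """Recombining the ion-ion parameters with TIP3P oxygen reproduces the
        printed ion-water pair values to 4 significant figures."""
        ion, _ = builtin_params(name)
        pair = combine_lb(ion.lj, TIP3P_OXYGEN)
        assert pair.sigma_ij == pytest.approx(sigma_io, abs=5e-5)
        assert pair.epsilon_ij == pytest.approx(eps_io, rel=5e-5)
        assert pair.provenance == "standard-rule"

    @given(a=lj_params, b=lj_params)
    @settings(max_examples=50)
    def test_lb_symmetric(self, a, b):
        pa, pb = combine_lb(a, b), combine_lb(b, a)
        assert pa.sigma_ij == pb.sigma_ij and pa.epsilon_ij == pb.epsilon_ij

    def test_lb_idempotent_on_identical_species(self):
        a = LJParams(0.31, 0.65)
        pair = combine_lb(a, a)
        assert pair.sigma_ij == pytest.approx(a.sigma)
        assert pair.epsilon_ij == pytest.approx(a.epsilon)

    @given(a=lj_params, b=lj_params)
    @settings(max_examples=50)
    def test_unit_scaling_reduces_to_standard(self, a, b):
        s = ScalingFactors(1.0, 1.0, "X")
        scaled, std = combine_scaled(a, b, s), combine_lb(a, b)
        assert scaled.sigma_ij == std.sigma_ij
        assert scaled.epsilon_ij == std.epsilon_ij

    @pytest.mark.parametrize(
        "name,eps_mgop", [("microMg", 4.6061), ("nanoMg", 4.6266)]
    )
    def test_scaled_phosphate_pair(self, name, eps_mgop):
        """Scaled rules against the AMBER nonbridging phosphate oxygen give
        the printed Mg-OP well depths."""
        ion, scalings = builtin_params(name)
        rna = next(s for s in scalings if s.species_tag == "RNA")
        pair = combine_scaled(ion.lj, AMBER_PHOSPHATE_OXYGEN, rna)
        assert pair.epsilon_ij == pytest.approx(eps_mgop, abs=2e-4)
        assert pair.provenance == "scaled-rule"

    def test_chloride_round_trip_consistency(self):
        """Inverting the microMg Mg-Cl well depth for epsilon_Cl and forward
        computing the nanoMg pair closes the loop on the printed table."""
        micro, _ = builtin_params("microMg")
        nano, _ = builtin_params("nanoMg")
        eps_cl = invert_lb_epsilon(0.8181, micro.lj.epsilon, lambda_epsilon=0.1)
        assert eps_cl == pytest.approx(0.283837, abs=1e-5)
        pair = combine_scaled(
            nano.lj, LJParams(0.4401, eps_cl), ScalingFactors(1.8, 0.1, "Cl")
        )
        assert pair.epsilon_ij == pytest.approx(1.0518, abs=2e-4)
        # forward arithmetic gives 0.48834; the published table rounds to
        # 0.4884, so agreement is to 1e-4 only
        assert pair.sigma_ij == pytest.approx(0.4884, abs=1e-4)


class TestRegistry:
    def test_known_sets(self):
        micro, _ = builtin_params("microMg")
        assert (micro.lj.sigma, micro.lj.epsilon) == (0.1019, 235.80)
        assert micro.charge == 2
        nano, scalings = builtin_params("nanoMg")
        rna = next(s for s in scalings if s.species_tag == "RNA")
        assert (rna.lambda_sigma, rna.lambda_epsilon) == (1.1435, 0.2500)

    def test_unknown_set_lists_available(self):
        with pytest.raises(LookupError_, match="microMg"):
            builtin_params("unknown")
        assert available_params() == ["microMg", "nanoMg"]


class TestPotentialCurve:
    def test_single_point_at_sigma_is_zero(self):
        pair = PairInteraction(0.3, 2.0)
        table = potential_curve(pair, np.array([0.3]))
        assert table.shape == (1, 2) and table[0, 1] == pytest.approx(0.0)

    def test_minimum_located_at_rmin(self):
        pair = PairInteraction(0.3, 2.0)
        r = np.linspace(0.25, 1.0, 2001)
        table = potential_curve(pair, r)
        r_at_min = table[np.argmin(table[:, 1]), 0]
        assert r_at_min == pytest.approx(0.3 * 2 ** (1 / 6), abs=r[1] - r[0])

    def test_matches_pointwise_energy(self):
        pair = PairInteraction(0.21, 12.25, c4=1e-4)
        r = np.linspace(0.18, 1.5, 57)
        table = potential_curve(pair, r)
        expected = [lj_energy(pair, float(x)) for x in r]
        np.testing.assert_allclose(table[:, 1], expected, rtol=1e-12)

    def test_invalid_grids(self):
        pair = PairInteraction(0.3, 2.0)
        with pytest.raises(DomainError):
            potential_curve(pair, np.array([0.2, 0.1]))
        with pytest.raises(DomainError):
            potential_curve(pair, np.array([-0.1, 0.2]))


def test_type_invariants():
    with pytest.raises(DomainError):
        LJParams(-0.1, 1.0)
    with pytest.raises(DomainError):
        LJParams(0.1, -1.0)
    with pytest.raises(DomainError):
        IonModel("", 2, LJParams(0.1, 1.0))
    with pytest.raises(DomainError):
        PairInteraction(0.2, 1.0, c4=-1.0)
    with pytest.raises(DomainError):
        ScalingFactors(0.0, 1.0, "Cl")
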