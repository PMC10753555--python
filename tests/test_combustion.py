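"""Bomb-calorimetry reduction: published-record regressions and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoforge.combustion import (
    CombustionExperiment,
    MolecularFormula,
    buoyancy_correct,
    combustion_stoichiometry,
    formation_enthalpy_crystal,
    formation_uncertainty,
    isothermal_bomb_energy,
    massic_combustion_energy,
    molar_combustion,
    molar_mass,
)
from thermoforge.constants import GAS_CONSTANT, T_REFERENCE
from thermoforge.uncertainty import expanded_uncertainty_of_mean


def _experiment(**overrides):
    base = dict(
        sample_mass=0.04,
        fuse_mass=5e-4,
        delta_Tc=0.9,
        calor_equiv=1281.2,
        cont_term=-0.001,
        ignition_energy=0.004,
        standard_state_correction=0.0008,
        fuse_massic_energy=-16.9452,
    )
    base.update(overrides)
    return CombustionExperiment(**base)


class TestIsothermalBombEnergy:
    def test_published_record(self, run1):
        assert round(isothermal_bomb_energy(run1), 5) == -1.13938

    def test_vanishing_temperature_rise(self):
        exp = _experiment(delta_Tc=1e-12, cont_term=0.0, ignition_energy=0.0)
        assert isothermal_bomb_energy(exp) == pytest.approx(0.0, abs=1e-9)

    def test_equals_term_by_term_sum(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            exp = _experiment(
                delta_Tc=float(rng.uniform(0.5, 1.5)),
                calor_equiv=float(rng.uniform(1000, 1500)),
                cont_term=float(rng.uniform(-0.002, 0.0)),
                ignition_energy=float(rng.uniform(0.0, 0.01)),
            )
            oracle = math.fsum(
                [exp.calor_equiv * (-exp.delta_Tc) / 1000.0, exp.cont_term, exp.ignition_energy]
            )
            assert isothermal_bomb_energy(exp) == pytest.approx(oracle, rel=0, abs=1e-15)

    def test_nonpositive_temperature_rise_rejected(self):
        with pytest.raises(ValueError):
            _experiment(delta_Tc=-0.1)


class TestMassicEnergy:
    def test_published_record(self, run1):
        assert round(massic_combustion_energy(run1), 4) == -27.6334

    def test_no_auxiliary_terms(self):
        exp = _experiment(
            sample_mass=0.05, fuse_mass=0.0, standard_state_correction=0.0
        )
        assert massic_combustion_energy(exp, -1.0) == pytest.approx(-20.0)

    def test_cotton_fuse_credit(self):
        # direct product: fuse mass times (negated) massic fuse energy
        assert round(0.0005911 * 16.9452, 5) == 0.01002

    def test_zero_sample_mass_rejected(self):
        with pytest.raises(ValueError):
            _experiment(sample_mass=0.0)


class TestStoichiometry:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C11H10O3", (12.0, 11.0, 5.0, -1.0)),
            ("C", (1.0, 1.0, 0.0, 0.0)),
            ("C7H6O2", (7.5, 7.0, 3.0, -0.5)),
        ],
    )
    def test_known_formulas(self, formula, expected):
        assert tuple(combustion_stoichiometry(MolecularFormula.parse(formula))) == expected

    @given(
        a=st.integers(1, 30), b=st.integers(0, 15).map(lambda k: 2 * k), c=st.integers(0, 10)
    )
    @settings(derandomize=True, max_examples=100)
    def test_element_balance_by_atom_counting(self, a, b, c):
        s = combustion_stoichiometry(MolecularFormula({"C": a, "H": b, "O": c}))
        # brute-force atom balance: reactant atoms == product atoms
        assert a == s.co2_coeff
        assert b == 2 * s.h2o_coeff
        assert c + 2 * s.o2_coeff == 2 * s.co2_coeff + s.h2o_coeff
        assert s.delta_n_gas == s.co2_coeff - s.o2_coeff

    def test_odd_hydrogen_rejected(self):
        with pytest.raises(ValueError, match="odd hydrogen"):
            combustion_stoichiometry(MolecularFormula.parse("C2H5O"))


class TestMolarCombustion:
    def test_molar_mass_iupac_2021(self):
        assert round(molar_mass(MolecularFormula.parse("C11H10O3")), 3) == 190.198

    def test_published_molar_energies(self):
        res = molar_combustion(-27.6912, MolecularFormula.parse("C11H10O3"))
        assert round(res.molar_energy, 1) == -5266.8
        assert round(res.molar_enthalpy, 1) == -5269.3

    def test_zero_gas_mole_change(self):
        # CaHbOc with c/2 == b/4, e.g. C2H4O2
        res = molar_combustion(-10.0, MolecularFormula.parse("C2H4O2"))
        assert res.delta_n_gas == 0
        assert res.molar_enthalpy == res.molar_energy

    @given(
        a=st.integers(1, 20),
        b=st.integers(0, 10).map(lambda k: 2 * k),
        c=st.integers(0, 8),
        massic=st.floats(-40.0, -5.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_enthalpy_energy_identity(self, a, b, c, massic):
        f = MolecularFormula({"C": a, "H": b, "O": c})
        res = molar_combustion(massic, f)
        gap = res.molar_enthalpy - res.molar_energy
        assert gap == pytest.approx(
            res.delta_n_gas * GAS_CONSTANT * T_REFERENCE / 1000.0, rel=1e-12, abs=1e-12
        )

    def test_positive_massic_rejected(self):
        with pytest.raises(ValueError):
            molar_combustion(1.0, MolecularFormula.parse("C6H6"))


class TestFormationEnthalpy:
    def test_published_value(self):
        assert round(formation_enthalpy_crystal(-5269.3, 11, 5), 1) == -488.5

    def test_hess_consistent_zero(self):
        dch = 11 * (-393.51) + 5 * (-285.83)
        assert formation_enthalpy_crystal(dch, 11, 5) == pytest.approx(0.0, abs=1e-12)

    @given(
        co2=st.floats(1, 20),
        h2o=st.floats(0, 10),
        dch=st.floats(-6000, -100),
    )
    @settings(derandomize=True, max_examples=60)
    def test_hess_identity_oracle(self, co2, h2o, dch):
        got = formation_enthalpy_crystal(dch, co2, h2o)
        oracle = math.fsum([co2 * -393.51, h2o * -285.83, -dch])
        assert got == pytest.approx(oracle, rel=1e-12, abs=1e-9)

    def test_uncertainty_propagation_quadrature(self):
        u = formation_uncertainty(6.2, 11, 5)
        assert u == pytest.approx(math.sqrt(6.2**2 + (11 * 0.13) ** 2 + (5 * 0.04) ** 2))
        assert round(u, 1) == 6.4


class TestSupportingPieces:
    def test_expanded_uncertainty_is_twice_sd_of_mean(self):
        rng = np.random.default_rng(7)
        values = rng.normal(-27.7, 0.02, size=6)
        expected = 2 * np.std(values, ddof=1) / np.sqrt(6)
        assert expanded_uncertainty_of_mean(values) == pytest.approx(expected, rel=1e-12)

    def test_buoyancy_correction_direction(self):
        # sample less dense than the weights displaces more air: mass revised up
        corrected = buoyancy_correct(1.0, sample_density=1.195)
        assert corrected > 1.0
        assert corrected == pytest.approx(1.0 * (1 + 1.2e-3 * (1 / 1.195 - 1 / 8.0)))

    def test_formula_parsing_roundtrip(self):
        f = MolecularFormula.parse("C11H10O3")
        assert f.element_counts == {"C": 11, "H": 10, "O": 3}
        with pytest.raises(ValueError):
            MolecularFormula.parse("H2O")  # no carbon
        with pytest.raises(ValueError):
            MolecularFormula.parse("C2N1")  # out-of-scope element
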