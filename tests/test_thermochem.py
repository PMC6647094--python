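"""RRHO thermochemistry, standard-state corrections and reaction energies."""

import math

import numpy as np
import pytest
import scipy.constants as sc
from hypothesis import given, strategies as st

from mitrametab import thermochem as T
from mitrametab.constants import HARTREE_TO_KCAL
from mitrametab.network import ReactionStep
from mitrametab.grammar import MetaboliteCode
from mitrametab.qmio import Atom, SpeciesRecord


def _argon(**kw):
    defaults = dict(
        label="Ar", electronic_energy=0.0, frequencies=(),
        atoms=(Atom("Ar", 39.948, (0.0, 0.0, 0.0)),),
    )
    defaults.update(kw)
    return SpeciesRecord(**defaults)


def _molecule(freqs=(500.0, 1500.0, 3000.0), **kw):
    defaults = dict(
        label="mol", electronic_energy=-100.0, frequencies=tuple(freqs),
        atoms=(
            Atom("O", 15.999, (0.0, 0.0, 0.1173)),
            Atom("H", 1.008, (0.0, 0.7572, -0.4692)),
            Atom("H", 1.008, (0.0, -0.7572, -0.4692)),
        ),
        solvation_energy=-5.0,
    )
    defaults.update(kw)
    return SpeciesRecord(**defaults)


class TestRRHO:
    def test_sackur_tetrode_argon(self):
        """Monoatomic translational entropy against the closed-form
        Sackur-Tetrode expression evaluated independently."""
        res = T.rrho_thermo(_argon(), 298.15)
        m = 39.948 * sc.atomic_mass
        q = (2 * math.pi * m * sc.k * 298.15 / sc.h**2) ** 1.5 * sc.k * 298.15 / sc.atm
        s_oracle = 1.98720 * (math.log(q) + 2.5)  # cal/(mol K)
        assert res.entropy == pytest.approx(s_oracle, abs=1e-6)
        assert res.entropy == pytest.approx(36.98, abs=0.01)

    @given(
        efreq=st.lists(st.floats(50.0, 3900.0), min_size=1, max_size=12),
        temp=st.floats(50.0, 1500.0),
        mult=st.integers(1, 3),
    )
    def test_g_equals_h_minus_ts(self, efreq, temp, mult):
        rec = _molecule(freqs=sorted(efreq), spin_multiplicity=mult)
        res = T.rrho_thermo(rec, temp)
        g = res.enthalpy - temp * res.entropy / 1000.0
        assert g == pytest.approx(res.gibbs_gas_1atm, abs=1e-9)

    def test_low_temperature_limit_is_e_plus_zpe(self):
        """As T -> 0 the Gibbs energy converges to E_elec + ZPE."""
        rec = _molecule()
        prev_gap = None
        for temp in (50.0, 10.0, 1.0):
            res = T.rrho_thermo(rec, temp)
            e_zpe = rec.electronic_energy * HARTREE_TO_KCAL + res.zpe
            gap = abs(res.gibbs_gas_1atm - e_zpe)
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 0.05

    def test_zpe_doubles_with_frequencies(self):
        base = T.rrho_thermo(_molecule())
        doubled = T.rrho_thermo(_molecule(freqs=(1000.0, 3000.0, 6000.0)))
        assert doubled.zpe == pytest.approx(2 * base.zpe, rel=1e-9)

    def test_entropy_and_enthalpy_increase_with_temperature(self):
        rec = _molecule()
        temps = [100.0, 200.0, 298.15, 400.0, 600.0]
        results = [T.rrho_thermo(rec, t) for t in temps]
        entropies = [r.entropy for r in results]
        enthalpies = [r.enthalpy for r in results]
        assert entropies == sorted(entropies)
        assert enthalpies == sorted(enthalpies)

    def test_imaginary_frequency_refused(self):
        rec = _molecule(freqs=(-100.0, 1500.0, 3000.0), is_minimum=False)
        with pytest.raises(T.ThermoError, match="frequency"):
            T.rrho_thermo(rec)

    def test_monoatomic_with_frequencies_refused(self):
        rec = _argon(frequencies=(100.0,))
        with pytest.raises(T.ThermoError, match="monoatomic"):
            T.rrho_thermo(rec)

    def test_linear_molecule_uses_linear_rotor(self):
        o2 = SpeciesRecord(
            label="O2", electronic_energy=-150.0, frequencies=(1580.0,),
            atoms=(Atom("O", 15.999, (0.0, 0.0, 0.0)),
                   Atom("O", 15.999, (0.0, 0.0, 1.2075))),
            spin_multiplicity=3, symmetry_number=2,
        )
        res = T.rrho_thermo(o2, 298.15)
        # gas-phase standard entropy of O2 is ~49.0 cal/(mol K)
        assert res.entropy == pytest.approx(49.0, abs=0.2)


class TestStandardState:
    def test_one_molar_term(self):
        # independent arithmetic oracle: RT ln(24.46...)
        rt = 1.98720e-3 * 298.15
        c_gas = sc.atm / (sc.R * 298.15) / 1000.0
        assert T.standard_state_correction(1.0, 298.15) == pytest.approx(
            rt * math.log(1.0 / c_gas), abs=1e-6
        )
        assert T.standard_state_correction(1.0, 298.15) == pytest.approx(1.89, abs=0.005)

    def test_water_extra_term(self):
        rt = 1.98720e-3 * 298.15
        extra = T.standard_state_correction(55.34, 298.15) - T.standard_state_correction(
            1.0, 298.15
        )
        assert extra == pytest.approx(rt * math.log(55.34), abs=1e-9)
        assert extra == pytest.approx(2.38, abs=0.005)

    def test_identity_concentration_gives_zero(self):
        c_gas = T.ideal_gas_concentration(298.15)
        assert T.standard_state_correction(c_gas, 298.15) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("c,temp", [(0.0, 298.15), (-1.0, 298.15), (1.0, 0.0)])
    def test_nonpositive_arguments_refused(self, c, temp):
        with pytest.raises(T.ThermoError):
            T.standard_state_correction(c, temp)


class TestAqueous:
    def test_zero_solvation_reduces_to_standard_state_term(self):
        rec = _molecule(solvation_energy=0.0)
        res = T.gibbs_aqueous(rec)
        assert res.gibbs_aqueous - res.gibbs_gas_1atm == pytest.approx(
            T.standard_state_correction(1.0), abs=1e-9
        )

    def test_water_gets_both_corrections(self):
        rec = _molecule(label="water", solvation_energy=-6.31,
                        standard_concentration=55.34)
        res = T.gibbs_aqueous(rec)
        expected = res.gibbs_gas_1atm + T.standard_state_correction(55.34) - 6.31
        assert res.gibbs_aqueous == pytest.approx(expected, abs=1e-9)

    def test_electronic_energy_linearity(self):
        a = T.gibbs_aqueous(_molecule())
        b = T.gibbs_aqueous(_molecule(electronic_energy=-99.0))
        assert b.gibbs_aqueous - a.gibbs_aqueous == pytest.approx(
            HARTREE_TO_KCAL, abs=1e-6
        )

    def test_solvation_includes_1m_convention(self):
        rec = _molecule()
        split = T.gibbs_aqueous(rec, solvation_includes_1M=False)
        folded = T.gibbs_aqueous(rec, solvation_includes_1M=True)
        assert split.gibbs_aqueous - folded.gibbs_aqueous == pytest.approx(
            T.standard_state_correction(1.0), abs=1e-9
        )

    def test_missing_solvation_energy_refused(self):
        with pytest.raises(T.ThermoError, match="solvation"):
            T.gibbs_aqueous(_molecule(solvation_energy=None))


def _fake_step(reactants, products, step_id_src="M_mmm", step_id_tgt="M_dmm"):
    return ReactionStep(
        source=MetaboliteCode("M", ("m", "m", "m")),
        target=MetaboliteCode("M", ("d", "m", "m")),
        reaction_type="O_demethylation", position="9", parent="M", step_index=1,
        reactants=reactants, products=products,
    )


class TestReactionEnergy:
    def test_null_reaction_is_zero(self):
        thermo = {"M_mmm": T.gibbs_aqueous(_molecule(label="M_mmm"))}
        step = ReactionStep(
            source=MetaboliteCode("M", ("m", "m", "m")),
            target=MetaboliteCode("M", ("m", "m", "m")),
            reaction_type="O_demethylation", position="9", parent="M", step_index=0,
            reactants={"M_mmm": 1}, products={"M_mmm": 1},
        )
        e = T.reaction_energy(step, thermo)
        assert e.dG_gas == 0.0 and e.dG_aqueous == 0.0

    def test_reversal_negates(self, clean_study, clean_thermo, full_steps):
        step = full_steps[0]
        fwd = T.reaction_energy(step, clean_thermo)
        rev = T.reaction_energy(step.reversed(), clean_thermo)
        assert rev.dG_gas == pytest.approx(-fwd.dG_gas, abs=1e-12)
        assert rev.dG_aqueous == pytest.approx(-fwd.dG_aqueous, abs=1e-12)

    def test_missing_species_listed(self, full_steps):
        with pytest.raises(T.ThermoError, match="missing"):
            T.reaction_energy(full_steps[0], {})

    def test_mixed_temperatures_refused(self):
        a = T.gibbs_aqueous(_molecule(label="A"), 298.15)
        b = T.gibbs_aqueous(_molecule(label="B"), 310.0)
        step = _fake_step({"A": 1}, {"B": 1})
        with pytest.raises(T.ThermoError, match="temperature"):
            T.reaction_energy(step, {"A": a, "B": b})

    def test_synthetic_network_matches_constructed_truth(
        self, clean_study, clean_thermo, full_steps
    ):
        """With zero noise, pipeline reaction energies equal the synthetic
        generator's independently constructed ground truth."""
        truth = dict(zip(clean_study.truth_steps.step_id, clean_study.truth_steps.dG_aq))
        for step in full_steps:
            e = T.reaction_energy(step, clean_thermo)
            assert e.dG_aqueous == pytest.approx(truth[step.step_id], abs=1e-6)

    def test_charged_steps_show_larger_gas_aqueous_gap(
        self, clean_study, clean_thermo, full_steps
    ):
        """Gas-vs-aqueous discrepancies are largest where net charge moves
        between species (sulfation, reduction), as constructed in the
        charge-dependent synthetic solvation."""
        gaps = {}
        for step in full_steps:
            e = T.reaction_energy(step, clean_thermo)
            gaps.setdefault(step.reaction_type, []).append(
                abs(e.dG_gas - e.dG_aqueous)
            )
        mean = {rt: float(np.mean(v)) for rt, v in gaps.items()}
        neutral_max = max(
            mean[rt] for rt in ("O_demethylation", "ester_hydrolysis", "glucuronidation")
        )
        assert mean["sulfation"] > neutral_max
        assert mean["reduction"] > neutral_max
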