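"""Energy-table aggregation: ladders, averages, substitution effects."""

import pandas as pd
import pytest

from mitrametab import analysis as A, synthetic as S, thermochem as T


@pytest.fixture(scope="module")
def clean_table(clean_thermo, full_steps):
    return A.energy_table(full_steps, clean_thermo)


@pytest.fixture(scope="module")
def m_steps(full_steps):
    return [s for s in full_steps if s.parent == "M"]


@pytest.fixture(scope="module")
def m_table(clean_table):
    return clean_table[clean_table.parent == "M"].reset_index(drop=True)


@pytest.fixture(scope="module")
def h_table(clean_table):
    return clean_table[clean_table.parent == "H"].reset_index(drop=True)


class TestLadder:
    def test_parent_maps_to_zero(self, m_steps, m_table):
        ladder = A.relative_ladder(m_steps, m_table, "M")
        assert ladder["M_mmm"] == 0.0
        assert len(ladder) == 60

    def test_ladder_matches_constructed_sums(self, clean_study, m_steps, m_table):
        """Ladder levels equal the generator's group-contribution sums
        (metabolite target minus parent target, corrected for cofactors
        consumed along the way)."""
        ladder = A.relative_ladder(m_steps, m_table, "M")
        # reconstruct expected level by summing truth step energies on a path
        truth = dict(zip(clean_study.truth_steps.step_id, clean_study.truth_steps.dG_aq))
        # path M_mmm -> M_dmm -> M_ddm
        expected = truth["M_mmm->M_dmm"] + truth["M_dmm->M_ddm"]
        assert ladder["M_ddm"] == pytest.approx(expected, abs=1e-9)

    def test_alternative_paths_agree(self, clean_study):
        truth = dict(zip(clean_study.truth_steps.step_id, clean_study.truth_steps.dG_aq))
        via_dmm = truth["M_mmm->M_dmm"] + truth["M_dmm->M_ddm"]
        via_mdm = truth["M_mmm->M_mdm"] + truth["M_mdm->M_ddm"]
        assert via_dmm == pytest.approx(via_mdm, abs=1e-9)

    def test_hess_consistency_exhaustive(self, m_steps, m_table):
        """Every network edge is consistent with the assigned levels, i.e.
        all alternative paths between any two metabolites agree."""
        ladder = A.relative_ladder(m_steps, m_table, "M", tolerance=1e-6)
        dg = dict(zip(m_table.step_id, m_table.dG_aq))
        for s in m_steps:
            dev = ladder[s.target.text] - ladder[s.source.text] - dg[s.step_id]
            assert abs(dev) < 1e-6

    def test_path_dependence_is_hard_error(self, m_steps, m_table):
        corrupted = m_table.copy()
        corrupted.loc[corrupted.step_id == "M_mmm->M_dmm", "dG_aq"] += 0.5
        with pytest.raises(A.AnalysisError, match="path-dependent|deviates"):
            A.relative_ladder(m_steps, corrupted, "M")

    def test_unreachable_metabolite_is_error(self, m_steps, m_table):
        reachable_from_root = [s for s in m_steps if s.source.text != "M_mmm"]
        # drop the three root edges: M_mmm still present as a source of nothing
        table = m_table[m_table.step_id.isin(s.step_id for s in reachable_from_root)]
        with pytest.raises(A.AnalysisError):
            A.relative_ladder(reachable_from_root, table, "M")

    def test_missing_parent_is_error(self, m_steps, m_table):
        with pytest.raises(A.AnalysisError, match="no steps"):
            A.relative_ladder(m_steps, m_table, "X")


class TestAverages:
    def test_single_step_group_mean_is_that_value(self, m_table):
        one = m_table.iloc[[0]]
        avg = A.position_type_averages(one)
        assert len(avg) == 1
        assert avg.mean_dG_aq.item() == pytest.approx(one.dG_aq.item())
        assert avg.n.item() == 1

    def test_row_order_invariance(self, clean_table):
        shuffled = clean_table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = A.position_type_averages(clean_table)
        b = A.position_type_averages(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_pooling_parents_doubles_counts(self, clean_table, m_table, h_table):
        pooled = A.position_type_averages(clean_table)
        only_m = A.position_type_averages(m_table)
        for row in only_m.itertuples():
            match = pooled[
                (pooled.parent == "M")
                & (pooled.reaction_type == row.reaction_type)
                & (pooled.position == row.position)
            ]
            assert match.n.item() == row.n
        # grouping is per parent: pooled table has one row per parent per group
        assert len(pooled) == 2 * len(only_m)

    def test_means_recover_constructed_offsets(self, clean_study, clean_table):
        """Per-(type, position) means equal the generator's construction."""
        truth_means = clean_study.truth_steps.groupby(
            ["parent", "reaction_type", "position"]
        )["dG_aq"].mean()
        avg = A.position_type_averages(clean_table)
        for row in avg.itertuples():
            expected = truth_means[(row.parent, row.reaction_type, row.position)]
            assert row.mean_dG_aq == pytest.approx(expected, abs=1e-9)

    def test_empty_table_is_error(self, clean_table):
        with pytest.raises(A.AnalysisError, match="empty"):
            A.position_type_averages(clean_table.iloc[0:0])


class TestSubstitutionEffect:
    def test_identical_tables_give_zero(self, m_table):
        per_step, per_group, unmatched = A.substitution_effect(m_table, m_table)
        assert unmatched == []
        assert (per_step.ddG_aq.abs() < 1e-12).all()
        assert (per_group.mean_ddG_aq.abs() < 1e-12).all()

    def test_defaults_inject_known_h_modifiers(self, m_table, h_table):
        """The generator's 7-hydroxy modifiers (-3 on d17, -2 on g17, +2 on
        g9) are recovered as ddG group means."""
        _, per_group, unmatched = A.substitution_effect(m_table, h_table)
        assert unmatched == []
        got = {
            (r.reaction_type, r.position): r.mean_ddG_aq for r in per_group.itertuples()
        }
        assert got[("O_demethylation", "17")] == pytest.approx(-3.0, abs=1e-9)
        assert got[("glucuronidation", "17")] == pytest.approx(-2.0, abs=1e-9)
        assert got[("glucuronidation", "9")] == pytest.approx(+2.0, abs=1e-9)
        assert got[("ester_hydrolysis", "16")] == pytest.approx(0.0, abs=1e-9)

    def test_injected_shift_recovered(self, m_table):
        """An extra -2 kcal/mol shift injected on 17-demethylation steps is
        recovered exactly as the group ddG."""
        shifted = m_table.copy()
        mask = (shifted.reaction_type == "O_demethylation") & (shifted.position == "17")
        shifted.loc[mask, "dG_aq"] -= 2.0
        _, per_group, _ = A.substitution_effect(m_table, shifted)
        got = {
            (r.reaction_type, r.position): r.mean_ddG_aq for r in per_group.itertuples()
        }
        assert got[("O_demethylation", "17")] == pytest.approx(-2.0, abs=1e-12)

    def test_uniform_offset_cancels(self, m_table):
        offset = m_table.copy()
        offset["dG_aq"] += 7.5
        offset["dG_gas"] += 7.5
        per_step, _, _ = A.substitution_effect(m_table, offset)
        assert (per_step.ddG_aq - 7.5).abs().max() < 1e-12
        # per-step differences of a *relative* quantity cancel parent offsets:
        ladder_like = m_table.copy()
        per_step2, _, _ = A.substitution_effect(ladder_like, ladder_like)
        assert per_step2.ddG_aq.abs().max() == 0.0

    def test_unmatched_steps_reported_and_excluded(self, m_table, h_table):
        trimmed = h_table[h_table.reaction_type != "sulfation"].reset_index(drop=True)
        per_step, _, unmatched = A.substitution_effect(m_table, trimmed)
        assert len(unmatched) == 15  # the dropped sulfation steps
        assert not (per_step.reaction_type == "sulfation").any()


class TestRendering:
    def test_outputs_written_and_deterministic(self, tmp_path, m_steps, m_table):
        ladder = A.relative_ladder(m_steps, m_table, "M")
        avg = A.position_type_averages(m_table)
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        files1 = A.render_outputs({"M": ladder}, avg, out1, {"M": m_table})
        files2 = A.render_outputs({"M": ladder}, avg, out2, {"M": m_table})
        assert len(files1) == len(files2) > 0
        for f1, f2 in zip(files1, files2):
            p1, p2 = str(f1), str(f2)
            if p1.endswith(".tsv"):
                assert open(p1, "rb").read() == open(p2, "rb").read()
        ladder_tsv = out1 / "ladder_M.tsv"
        assert sum(1 for _ in open(ladder_tsv)) == 61  # header + 60 codes

    def test_empty_ladder_panel_tolerated(self, tmp_path, m_table):
        avg = A.position_type_averages(m_table)
        files = A.render_outputs({"M": {}}, avg, tmp_path)
        assert files
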