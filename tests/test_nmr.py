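"""Tests for shielding parsing, TMS referencing, symmetry grouping and
two-level averaging."""

import numpy as np
import pytest

from mdspectra.exceptions import (
    InvalidArgumentError,
    InvalidDataError,
    ShieldingParseError,
)
from mdspectra.nmr import (
    AtomGrouping,
    ShieldingFrame,
    TMSReference,
    aggregate_shifts,
    assemble_nmr_record,
    group_equivalent_atoms,
    mol_with_explicit_hs,
    parse_shielding_output,
    reference_to_tms,
    write_shielding,
)
from mdspectra.synth import SyntheticShieldingSpec, synthetic_shielding_frames

METHANE_BLOCK = """\
frame 0 5
1 C 0.0 0.0 0.0 195.5
2 H 0.63 0.63 0.63 28.9
3 H -0.63 -0.63 0.63 28.9
4 H -0.63 0.63 -0.63 28.9
5 H 0.63 -0.63 -0.63 28.9
TMS H 31.0 C 188.0
"""


class TestShieldingDialect:
    def test_methane_block_parses_with_equal_h_shieldings(self):
        frame, ref = parse_shielding_output(METHANE_BLOCK)
        assert frame.n_atoms == 5
        assert frame.elements == ["C", "H", "H", "H", "H"]
        assert np.allclose(frame.sigma_iso_ppm[1:], 28.9)
        assert ref == TMSReference(31.0, 188.0)

    def test_footer_is_optional(self):
        text = "\n".join(METHANE_BLOCK.splitlines()[:-1]) + "\n"
        frame, ref = parse_shielding_output(text)
        assert ref is None

    def test_round_trip(self):
        frame, ref = parse_shielding_output(METHANE_BLOCK)
        again, ref2 = parse_shielding_output(write_shielding(frame, ref))
        assert again.elements == frame.elements
        assert np.allclose(again.sigma_iso_ppm, frame.sigma_iso_ppm)
        assert np.allclose(again.xyz, frame.xyz)
        assert ref2 == ref

    def test_malformed_line_reports_line_number(self):
        bad = METHANE_BLOCK.replace("4 H -0.63 0.63 -0.63 28.9", "4 H oops")
        with pytest.raises(ShieldingParseError, match="line 5"):
            parse_shielding_output(bad)

    def test_duplicate_atom_index_rejected(self):
        bad = METHANE_BLOCK.replace("5 H 0.63", "4 H 0.63")
        with pytest.raises(InvalidDataError, match="duplicate"):
            parse_shielding_output(bad)


class TestTMSReferencing:
    def test_reference_shift_is_zero_at_tms_value(self):
        frame, ref = parse_shielding_output(METHANE_BLOCK)
        frame.sigma_iso_ppm[1] = 31.0
        delta = reference_to_tms(frame, ref)
        assert delta[1] == pytest.approx(0.0)

    def test_arithmetic(self):
        frame = ShieldingFrame("0", ["H"], np.zeros((1, 3)), np.array([26.0]))
        delta = reference_to_tms(frame, TMSReference(31.0, 188.0))
        assert delta[0] == pytest.approx(5.0)

    def test_vectorized_equals_per_atom_loop(self, rng):
        elements = ["H", "C", "O", "H", "C", "N", "H"]
        sigma = rng.normal(100.0, 30.0, len(elements))
        frame = ShieldingFrame("0", elements, np.zeros((len(elements), 3)), sigma)
        ref = TMSReference(31.0, 188.0)
        delta = reference_to_tms(frame, ref)
        for i, el in enumerate(elements):
            if el == "H":
                assert delta[i] == pytest.approx(31.0 - sigma[i])
            elif el == "C":
                assert delta[i] == pytest.approx(188.0 - sigma[i])
            else:
                assert np.isnan(delta[i])


class TestSymmetryGrouping:
    def test_benzene_fully_symmetric(self):
        g = group_equivalent_atoms("c1ccccc1")
        assert len(g.c_groups) == 1 and len(g.c_groups[0]) == 6
        assert len(g.h_groups) == 1 and len(g.h_groups[0]) == 6

    def test_ethanol_three_h_environments(self):
        g = group_equivalent_atoms("CCO")
        sizes = sorted(len(grp) for grp in g.h_groups)
        assert sizes == [1, 2, 3]
        assert len(g.c_groups) == 2

    def test_methane_single_groups(self):
        g = group_equivalent_atoms("C")
        assert g.c_groups == [[0]]
        assert g.h_groups == [[1, 2, 3, 4]]

    def test_para_xylene_ring_symmetry(self):
        # two methyls equivalent, ring carbons fall in 2 classes
        g = group_equivalent_atoms("Cc1ccc(C)cc1")
        assert sorted(len(grp) for grp in g.c_groups) == [2, 2, 4]
        assert sorted(len(grp) for grp in g.h_groups) == [4, 6]

    def test_groups_ordered_by_lowest_member(self):
        g = group_equivalent_atoms("CCO")
        firsts = [grp[0] for grp in g.h_groups]
        assert firsts == sorted(firsts)

    def test_unparseable_smiles_rejected(self):
        with pytest.raises(InvalidArgumentError):
            group_equivalent_atoms("not-a-smiles")

    @pytest.mark.parametrize(
        "smiles",
        [
            "c1ccccc1", "CCO", "C", "CC(C)C", "CC(=O)O", "c1ccncc1", "C1CCCCC1",
            "Cc1ccc(C)cc1", "OCC(O)CO", "CCN(CC)CC", "FC(F)(F)c1ccccc1",
            "CC(=O)Nc1ccc(O)cc1", "c1ccc2ccccc2c1", "CC(C)(C)O", "CSC",
            "O=C(O)c1ccccc1", "NCCO", "CC#N", "ClCCl", "C1COCCO1",
            "CC1CCCCC1", "c1ccsc1", "CNC", "CCOC(=O)C", "ICCI",
        ],
    )
    def test_grouping_is_a_partition(self, smiles):
        g = group_equivalent_atoms(smiles)
        mol = mol_with_explicit_hs(smiles)
        c_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
        h_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "H"]
        assert sorted(i for grp in g.c_groups for i in grp) == sorted(c_idx)
        assert sorted(i for grp in g.h_groups for i in grp) == sorted(h_idx)


class TestAggregateShifts:
    GROUPING = AtomGrouping(c_groups=[], h_groups=[[0, 1]])

    def test_single_frame_mean_and_zero_std(self):
        agg = aggregate_shifts([np.array([1.0, 3.0])], self.GROUPING)
        assert agg["H"].group_means[0] == pytest.approx(2.0)
        assert agg["H"].group_stds[0] == 0.0

    def test_two_frames_population_std(self):
        frames = [np.array([2.0, 2.0]), np.array([4.0, 4.0])]
        agg = aggregate_shifts(frames, self.GROUPING)
        assert agg["H"].group_means[0] == pytest.approx(3.0)
        assert agg["H"].group_stds[0] == pytest.approx(1.0)  # denominator n

    def test_permutation_within_groups_leaves_outputs_unchanged(self, rng):
        grouping = AtomGrouping(c_groups=[[0, 2], [4]], h_groups=[[1, 3], [5]])
        frames = [rng.normal(size=6) for _ in range(5)]
        agg = aggregate_shifts(frames, grouping)
        # swap atoms 0<->2 and 1<->3 (each within its group)
        perm = [2, 3, 0, 1, 4, 5]
        permuted = [f[perm] for f in frames]
        agg_p = aggregate_shifts(permuted, grouping)
        for el in ("H", "C"):
            assert np.allclose(agg[el].group_means, agg_p[el].group_means)
            assert np.allclose(agg[el].group_stds, agg_p[el].group_stds)
            assert agg[el].max_std == pytest.approx(agg_p[el].max_std)

    def test_hierarchical_equals_pooled_mean_when_balanced(self, rng):
        grouping = AtomGrouping(c_groups=[], h_groups=[[0, 1, 2]])
        frames = [rng.normal(size=3) for _ in range(7)]
        hier = aggregate_shifts(frames, grouping)
        pooled = aggregate_shifts(frames, grouping, order="pooled")
        assert np.allclose(hier["H"].group_means, pooled["H"].group_means)

    def test_hierarchical_and_pooled_stds_differ_with_atom_scatter(self, rng):
        grouping = AtomGrouping(c_groups=[], h_groups=[[0, 1]])
        # atoms wildly different within a frame, frames identical: the
        # hierarchical std across frames is 0 while the pooled std is not
        frames = [np.array([0.0, 10.0]), np.array([0.0, 10.0])]
        hier = aggregate_shifts(frames, grouping)
        pooled = aggregate_shifts(frames, grouping, order="pooled")
        assert hier["H"].group_stds[0] == pytest.approx(0.0)
        assert pooled["H"].group_stds[0] == pytest.approx(5.0)

    def test_std_invariant_to_constant_offset(self, rng):
        grouping = AtomGrouping(c_groups=[[0]], h_groups=[[1, 2]])
        frames = [rng.normal(size=3) for _ in range(6)]
        shifted = [f + 7.5 for f in frames]
        a = aggregate_shifts(frames, grouping)
        b = aggregate_shifts(shifted, grouping)
        for el in ("H", "C"):
            assert np.allclose(a[el].group_stds, b[el].group_stds)

    def test_max_std_dominates_group_stds(self, rng):
        grouping = AtomGrouping(c_groups=[[0], [1]], h_groups=[[2], [3, 4]])
        frames = [rng.normal(size=5) for _ in range(8)]
        agg = aggregate_shifts(frames, grouping)
        for el in ("H", "C"):
            assert np.all(agg[el].group_stds >= 0)
            assert agg[el].max_std == pytest.approx(agg[el].group_stds.max())

    def test_frame_length_mismatch_rejected(self):
        with pytest.raises(InvalidDataError):
            aggregate_shifts([np.zeros(3), np.zeros(4)], self.GROUPING)


class TestAssembleRecord:
    def test_counts_and_zero_variance_fixture(self):
        grouping = group_equivalent_atoms("C")
        spec = SyntheticShieldingSpec(
            {"C": [10.0], "H": [1.0]}, 0.0, n_frames=10, seed=0
        )
        frames, ref = synthetic_shielding_frames(spec, grouping)
        record = assemble_nmr_record("C", frames, grouping, ref)
        assert record.number_of_frames == 10
        assert len(record.frame_ids) == 10
        assert record.h_nmr_max_std == 0.0
        assert record.c_nmr_max_std == 0.0
        # unsorted lists preserve atom order: 4 H entries, 1 C entry per frame
        fr = record.frames[record.frame_ids[0]]
        assert len(fr.h_nmr_peaks_unsorted) == 4
        assert len(fr.c_nmr_peaks_unsorted) == 1
        assert fr.nmr_cpmd_text.startswith("frame")

    def test_group_mean_recovery_over_seeds(self):
        # with sigma = 1 ppm over 10 frames, recovered means land within
        # 3 sigma/sqrt(10) of truth for >= 95% of seeds
        grouping = group_equivalent_atoms("CCO")
        means = {"C": [60.0, 18.0], "H": [1.2, 3.7, 2.6]}
        sigma, n_frames = 1.0, 10
        bound = 3.0 * sigma / np.sqrt(n_frames)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = SyntheticShieldingSpec(means, sigma, n_frames, seed=seed)
            frames, ref = synthetic_shielding_frames(spec, grouping)
            record = assemble_nmr_record("CCO", frames, grouping, ref)
            ok_h = np.all(
                np.abs(np.array(record.averaged_frames["h_nmr_peaks_ave"]) - means["H"])
                <= bound
            )
            ok_c = np.all(
                np.abs(np.array(record.averaged_frames["c_nmr_peaks_ave"]) - means["C"])
                <= bound
            )
            hits += ok_h and ok_c
        assert hits / n_seeds >= 0.95

    def test_inconsistent_frames_rejected(self):
        grouping = group_equivalent_atoms("C")
        spec = SyntheticShieldingSpec({"C": [10.0], "H": [1.0]}, 0.0, 2)
        frames, ref = synthetic_shielding_frames(spec, grouping)
        frames[1].elements = ["C", "H", "H", "H", "C"]
        with pytest.raises(InvalidDataError):
            assemble_nmr_record("C", frames, grouping, ref)
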