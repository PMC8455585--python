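import numpy as np
import pytest

from ligandfield import constants, energetics
from ligandfield.chemio import AtomRecord, ComplexStructure, MoleculeRecord
from ligandfield.energetics import (ForceFieldParams, compare_with_contours,
                                    decomposition_to_dataframe,
                                    effective_born_radii, gb_polar_energy,
                                    mmgbsa_binding, pair_energy,
                                    residue_decomposition, sasa)
from ligandfield.qsar import ContourField


def ion_params(charge=1.0, radius=2.0):
    return ForceFieldParams([radius], [0.1], [charge], [radius], [0.8])


class TestGeneralizedBorn:
    def test_born_ion_closed_form(self):
        # single ion: E = -(332.0637/2) (1 - 1/78.5) q^2 / a
        for q, a in ((1.0, 1.5), (-1.0, 2.0), (2.0, 3.0)):
            e = gb_polar_energy(np.zeros((1, 3)), ion_params(q, a))
            ref = (-energetics.GB_SELF_CONSTANT
                   * (1.0 - 1.0 / constants.SOLVENT_DIELECTRIC) * q * q / a)
            assert e == pytest.approx(ref, rel=1e-3)

    def test_isolated_atom_effective_radius_is_intrinsic(self):
        r = effective_born_radii(np.zeros((1, 3)), ion_params(radius=1.7))
        assert r[0] == pytest.approx(1.7, rel=1e-12)

    def test_descreening_grows_effective_radius(self):
        p = ForceFieldParams([1.5, 1.5], [0.1, 0.1], [1.0, 0.0],
                             [1.5, 1.5], [0.8, 0.8])
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        r = effective_born_radii(coords, p)
        assert (r > 1.5).all()      # burial raises both radii

    def test_opposite_ion_pair_solvation_less_negative_than_sum(self):
        # bringing +/- together screens each ion's individual solvation
        p = ForceFieldParams([2.0, 2.0], [0.1, 0.1], [1.0, -1.0],
                             [2.0, 2.0], [0.8, 0.8])
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        pair = gb_polar_energy(coords, p)
        single = gb_polar_energy(np.zeros((1, 3)), ion_params(1.0, 2.0))
        assert pair > 2 * single


class TestPairEnergy:
    def test_lj_minimum_depth(self):
        p = ForceFieldParams([1.7, 1.9], [0.1, 0.2], [0.0, 0.0],
                             [1.7, 1.9], [0.8, 0.8])
        coords = np.array([[0.0, 0.0, 0.0], [3.6, 0.0, 0.0]])  # r = rmin sum
        vdw, ele = pair_energy(coords, p, [0], [1])
        assert vdw == pytest.approx(-np.sqrt(0.1 * 0.2), rel=1e-12)
        assert ele == 0.0

    def test_coulomb_known_value(self):
        p = ForceFieldParams([1.0, 1.0], [0.0, 0.0], [1.0, -1.0],
                             [1.0, 1.0], [0.8, 0.8])
        r = constants.COULOMB_CONSTANT / 100.0   # 3.320637 A
        coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        _, ele = pair_energy(coords, p, [0], [1])
        assert ele == pytest.approx(-100.0, rel=1e-12)

    def test_group_overlap_rejected(self):
        p = ion_params()
        with pytest.raises(ValueError):
            pair_energy(np.zeros((1, 3)), p, [0], [0])


class TestSasa:
    def test_isolated_sphere_analytic(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.7]))
        ref = 4.0 * np.pi * (1.7 + constants.SASA_PROBE_RADIUS) ** 2
        assert areas[0] == pytest.approx(ref, rel=0.01)

    def test_fused_spheres_against_spherical_cap_formula(self):
        # two equal spheres: exposed fraction = 1 - h/(2R) per sphere where
        # h is the buried cap height, h = R_ext - d/2 for equal radii
        r, d = 1.7, 2.0
        R = r + constants.SASA_PROBE_RADIUS
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = sasa(coords, np.array([r, r]), n_points=10000)
        cap_h = R - d / 2.0
        ref = 4.0 * np.pi * R ** 2 - 2.0 * np.pi * R * cap_h
        assert areas[0] == pytest.approx(ref, rel=0.02)
        assert areas[1] == pytest.approx(ref, rel=0.02)

    def test_buried_atom_zero_area(self):
        # small atom fully inside a big one
        coords = np.zeros((2, 3))
        coords[1, 0] = 0.1
        areas = sasa(coords, np.array([3.0, 0.5]))
        assert areas[1] == 0.0

    def test_nonpolar_coefficient_value(self):
        assert constants.NONPOLAR_COEFFICIENT == 0.0072


class TestBinding:
    def test_decomposition_conserves_total(self, toy_complex):
        binding = mmgbsa_binding(toy_complex)
        contribs, correction = residue_decomposition(toy_complex)
        total = sum(c.total for c in contribs) + correction.total
        assert total == pytest.approx(binding["dG_mean"], abs=1e-6)

    def test_binding_translation_invariance_exact(self, toy_complex):
        ref = mmgbsa_binding(toy_complex)["dG_mean"]
        t = np.array([5.0, -3.0, 2.0])
        moved = ComplexStructure(
            toy_complex.protein_atoms, toy_complex.ligand,
            [f + t for f in toy_complex.frames])
        # exact in infinite precision; roundoff in the shifted pairwise
        # distance sums leaves ~1e-8 of noise
        assert mmgbsa_binding(moved)["dG_mean"] == pytest.approx(ref, abs=1e-6)

    def test_binding_rotation_invariance_to_quadrature_error(self, toy_complex):
        # MM and GB terms are exactly rotation invariant; the surface term
        # uses a fixed quadrature direction set, so rotation agreement is
        # limited by the 960-point discretization
        ref = mmgbsa_binding(toy_complex)["dG_mean"]
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0],
                      [0, 0, 1.0]])
        moved = ComplexStructure(
            toy_complex.protein_atoms, toy_complex.ligand,
            [f @ R.T for f in toy_complex.frames])
        assert mmgbsa_binding(moved)["dG_mean"] == pytest.approx(ref, abs=0.05)

    def test_decomposition_frame_covers_all_residues(self, toy_complex):
        contribs, _ = residue_decomposition(toy_complex)
        df = decomposition_to_dataframe(contribs)
        assert len(df) == len(toy_complex.residues())
        assert {"dG_vdw", "dG_ele", "dG_pol", "dG_nonpol"} <= set(df.columns)

    def test_empty_selection_rejected(self):
        lig = MoleculeRecord("L", [AtomRecord("C", [0, 0, 0])])
        with pytest.raises(ValueError):
            mmgbsa_binding(ComplexStructure([], lig))


class TestConcordance:
    def test_vdw_dominant_residue_agrees_with_steric_region(self, toy_complex):
        contribs, _ = residue_decomposition(toy_complex)
        # a synthetic steric contour region right at the strongest residue
        strongest = max(contribs, key=lambda c: abs(c.total))
        grid_origin = tuple(strongest.centroid - 1.0)
        field = ContourField(
            grid=__import__("ligandfield").fieldgen.GridSpec(grid_origin, 1.0,
                                                             (3, 3, 3)),
            values={"S": np.arange(27.0) + 1.0})
        report = compare_with_contours(contribs, field)
        assert 0.0 <= report.concordance <= 1.0
        assert not report.rows.empty

    def test_no_regions_yields_nan(self, toy_complex):
        contribs, _ = residue_decomposition(toy_complex)
        field = ContourField(
            grid=__import__("ligandfield").fieldgen.GridSpec((0, 0, 0), 1.0,
                                                             (2, 2, 2)),
            values={"S": np.zeros(8)})
        report = compare_with_contours(contribs, field)
        assert np.isnan(report.concordance)
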