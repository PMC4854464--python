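"""WCN, ASA/RSA, catalytic distances, interfaces and the site table."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzgrad.exceptions import MetricError
from enzgrad.site_metrics import (
    MAX_ASA_GLY_X_GLY,
    build_site_table,
    detect_interface,
    distance_to_catalytic,
    read_dssp_acc,
    relative_solvent_accessibility,
    shrake_rupley_asa,
    weighted_contact_number,
)
from enzgrad.structure_io import CatalyticAnnotation

from .conftest import random_cloud


def wcn_bruteforce(points: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle for the contact-number sum."""
    n = len(points)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += 1.0 / np.sum((points[i] - points[j]) ** 2)
    return out


class TestWeightedContactNumber:
    def test_two_centers_two_angstrom_apart(self):
        wcn = weighted_contact_number([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(wcn, [0.25, 0.25])

    def test_collinear_three_centers(self):
        wcn = weighted_contact_number([[0, 0, 0], [2, 0, 0], [4, 0, 0]])
        np.testing.assert_allclose(wcn, [0.3125, 0.5, 0.3125])

    def test_inverse_square_homogeneity(self):
        pts = random_cloud(40, seed=3)
        np.testing.assert_allclose(
            weighted_contact_number(2.0 * pts),
            weighted_contact_number(pts) / 4.0,
            rtol=1e-12,
        )

    @pytest.mark.parametrize("n", [2, 25, 200])
    def test_matches_bruteforce_oracle(self, n):
        pts = random_cloud(n, seed=n)
        np.testing.assert_allclose(
            weighted_contact_number(pts), wcn_bruteforce(pts), rtol=1e-10
        )

    def test_coincident_centers_error_names_pair(self):
        with pytest.raises(MetricError, match="0 and 2"):
            weighted_contact_number([[0, 0, 0], [3, 0, 0], [0, 0, 0]])

    def test_single_center_is_zero_by_convention(self):
        np.testing.assert_array_equal(weighted_contact_number([[1, 1, 1]]), [0.0])


class TestDistanceToCatalytic:
    def test_catalytic_sites_get_exactly_zero(self):
        pts = random_cloud(30, seed=5)
        d = distance_to_catalytic(pts, [4, 9])
        assert d[4] == 0.0 and d[9] == 0.0
        assert np.all(d >= 0)

    def test_three_four_five_triangle(self):
        d = distance_to_catalytic([[0, 0, 0], [3, 4, 0]], [0])
        np.testing.assert_allclose(d, [0.0, 5.0])

    def test_nearest_of_several(self):
        pts = np.array([[0, 0, 0], [6, 0, 0], [15, 0, 0]], dtype=float)
        d = distance_to_catalytic(pts, [1, 2])
        assert d[0] == 6.0

    def test_empty_catalytic_set_is_error(self):
        with pytest.raises(MetricError):
            distance_to_catalytic([[0, 0, 0]], [])

    def test_triangle_property(self):
        pts = random_cloud(60, seed=8)
        d = distance_to_catalytic(pts, [0, 7, 33])
        diff = np.abs(d[:, None] - d[None, :])
        pair = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert np.all(diff <= pair + 1e-9)


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley_asa([(np.zeros(3), 1.9)], probe_radius=1.4)
        expected = 4 * np.pi * 3.3**2
        assert area[0] == pytest.approx(expected, rel=0.02)

    def test_distant_spheres_unoccluded(self):
        areas = shrake_rupley_asa(
            [(np.zeros(3), 1.9), (np.array([100.0, 0, 0]), 1.5)]
        )
        np.testing.assert_allclose(
            areas, [4 * np.pi * 3.3**2, 4 * np.pi * 2.9**2], rtol=0.02
        )

    def test_caged_sphere_nearly_buried(self):
        offsets = np.array(
            [
                [i, j, k]
                for i in (-1, 0, 1)
                for j in (-1, 0, 1)
                for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)
            ],
            dtype=float,
        )
        offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
        spheres = [(np.zeros(3), 1.9)] + [(4.0 * o, 1.9) for o in offsets]
        areas = shrake_rupley_asa(spheres)
        assert areas[0] < 0.05 * 4 * np.pi * 3.3**2

    def test_matches_random_point_oracle(self):
        """Independent Monte-Carlo point test on a small cluster."""
        rng = np.random.default_rng(0)
        centers = rng.uniform(-3, 3, size=(5, 3))
        radii = rng.uniform(1.4, 2.0, size=5)
        spheres = list(zip(centers, radii))
        areas = shrake_rupley_asa(spheres, n_points=3000)
        probe = 1.4
        for i in range(5):
            ri = radii[i] + probe
            pts = rng.normal(size=(20000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = centers[i] + ri * pts
            outside = np.ones(len(pts), dtype=bool)
            for j in range(5):
                if j == i:
                    continue
                outside &= (
                    np.linalg.norm(pts - centers[j], axis=1) >= radii[j] + probe
                )
            expected = 4 * np.pi * ri**2 * outside.mean()
            assert areas[i] == pytest.approx(expected, abs=0.03 * 4 * np.pi * ri**2)

    def test_quadrature_convergence(self):
        centers = random_cloud(30, seed=12, scale=8.0)
        spheres = [(c, 1.8) for c in centers]
        a1 = shrake_rupley_asa(spheres, n_points=960)
        a2 = shrake_rupley_asa(spheres, n_points=1920)
        scale = 4 * np.pi * 3.2**2
        assert np.max(np.abs(a1 - a2)) < 0.01 * scale

    def test_agrees_with_biotite_reference(self):
        """Cross-check against an independent Shrake-Rupley implementation."""
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(4)
        coords = rng.uniform(-6, 6, size=(40, 3)).astype(np.float32)
        radii = np.full(40, 1.7)
        arr = biotite_structure.AtomArray(40)
        arr.coord = coords
        arr.set_annotation("element", np.array(["C"] * 40))
        ref = biotite_structure.sasa(
            arr, probe_radius=1.4, point_number=960, vdw_radii=radii
        )
        mine = shrake_rupley_asa([(c, 1.7) for c in coords], n_points=960)
        np.testing.assert_allclose(mine.sum(), ref.sum(), rtol=0.02)

    def test_nonpositive_radius_is_error(self):
        with pytest.raises(MetricError):
            shrake_rupley_asa([(np.zeros(3), 0.0)])


class TestRelativeSolventAccessibility:
    def test_zero_asa_gives_zero_rsa(self):
        assert relative_solvent_accessibility([0.0], ["ALA"])[0] == 0.0

    def test_max_asa_normalizes_to_one(self):
        rsa = relative_solvent_accessibility([MAX_ASA_GLY_X_GLY["ALA"]], ["ALA"])
        assert rsa[0] == pytest.approx(1.0)

    def test_cross_chain_linked_forced_to_zero(self):
        rsa = relative_solvent_accessibility(
            [50.0, 50.0], ["CYS", "CYS"], cross_chain_linked=[1]
        )
        assert rsa[1] == 0.0 and rsa[0] > 0

    def test_values_above_one_unclipped(self):
        rsa = relative_solvent_accessibility([300.0], ["ALA"])
        assert rsa[0] > 1.0

    def test_unknown_residue_type_is_error(self):
        with pytest.raises(MetricError):
            relative_solvent_accessibility([10.0], ["XXX"])


class TestDetectInterface:
    def test_absolute_threshold(self):
        flags = detect_interface([0.30, 0.30, 0.199], [0.15, 0.30, 0.10])
        assert flags.tolist() == [True, False, False]

    def test_identical_vectors_all_false(self):
        assert not detect_interface([0.2, 0.5], [0.2, 0.5]).any()

    def test_just_below_threshold_not_interface(self):
        assert not detect_interface([0.199], [0.10]).any()

    def test_relative_reading_option(self):
        # 50% relative drop but only 0.05 absolute
        flags = detect_interface([0.10], [0.05], relative=True)
        assert flags.tolist() == [True]
        assert not detect_interface([0.10], [0.05]).any()

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            detect_interface([0.1], [0.1, 0.2])


class TestBuildSiteTable:
    def test_single_catalytic_site_table(self, small_protein):
        df = small_protein.site_table.df
        assert len(df) == 60
        assert int(df["is_catalytic"].sum()) == 2
        assert (df.loc[df["is_catalytic"], "d"] == 0.0).all()
        assert (df.loc[df["is_catalytic"], "shell"] == 0).all()
        assert df["K"].mean() == pytest.approx(1.0, abs=1e-9)
        assert (df["wcn"] > 0).all()
        assert (df["rsa"] >= 0).all()

    def test_interfaces_excluded_on_monomer_is_identity(self, small_protein):
        from enzgrad.site_metrics import build_site_table as bst

        kept = small_protein.site_table
        dropped = bst(
            small_protein.structure,
            small_protein.annotation,
            small_protein.rates,
            exclude_interfaces=True,
            atom_radius=3.0,
        )
        assert dropped.provenance == ("assembly", "interfaces_excluded")
        assert len(dropped.df) == len(kept.df)
        np.testing.assert_allclose(dropped.df["wcn"], kept.df["wcn"])

    def test_rate_length_mismatch_is_error(self, small_protein):
        with pytest.raises(MetricError, match="mismatch"):
            build_site_table(
                small_protein.structure,
                small_protein.annotation,
                np.ones(7),
            )

    def test_dimer_interface_flags_and_provenance(self, dimer_assembly_pdb):
        from enzgrad.structure_io import parse_structure

        model = parse_structure(dimer_assembly_pdb)
        ann = CatalyticAnnotation(sites=frozenset({("A", 1), ("A-2", 1)}))
        table = build_site_table(model, ann, None, n_points=240)
        assert table.provenance == ("assembly", "interfaces_kept")
        assert set(table.df["chain"]) == {"A", "A-2"}

    def test_tsv_round_trip(self, small_protein, tmp_path):
        from enzgrad.site_metrics import SiteTable

        path = tmp_path / "sites.tsv"
        small_protein.site_table.to_tsv(path)
        back = SiteTable.from_tsv(path)
        assert back.n_sites == small_protein.site_table.n_sites
        np.testing.assert_allclose(
            back.df["wcn"], small_protein.site_table.df["wcn"], rtol=1e-5
        )


class TestDsspReader:
    DSSP = (
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N\n"
        "    1    2 A M              0   0  155      0, 0.0   2,-0.3\n"
        "    2    3 A K        +     0   0   13      1,-0.1   2,-0.5\n"
    )

    def test_acc_column_parsed(self):
        acc = read_dssp_acc(self.DSSP)
        assert acc[("A", 2, "")] == 155.0
        assert acc[("A", 3, "")] == 13.0

    def test_empty_dssp_is_error(self):
        with pytest.raises(MetricError):
            read_dssp_acc("no residues here\n")


@given(st.integers(0, 2**31 - 1))
def test_rsa_of_caged_residue_below_buried_threshold(seed):
    """A residue enclosed by a tight synthetic cage is detected as buried."""
    rng = np.random.default_rng(seed % 1000)
    offsets = np.array(
        [
            [i, j, k]
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ],
        dtype=float,
    )
    offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
    jitter = rng.uniform(-0.2, 0.2, size=offsets.shape)
    spheres = [(np.zeros(3), 1.9)] + [
        (4.0 * o + e, 1.9) for o, e in zip(offsets, jitter)
    ]
    areas = shrake_rupley_asa(spheres, n_points=480)
    rsa = relative_solvent_accessibility([areas[0]], ["LEU"])
    assert rsa[0] < 0.05
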