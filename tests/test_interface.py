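"""Surface-area operators: analytic oracles, symmetry, contacts, binning."""

import numpy as np
import pytest

from pcdhkit.errors import MappingError, ParameterError, RadiiError, SelectionError
from pcdhkit.interface import (
    DEFAULT_PROBE,
    DEFAULT_RADII,
    InterfaceReport,
    ResidueBsa,
    bin_percent_bsa,
    compute_interface,
    compute_sasa,
    per_position_bsa_profile,
)
from pcdhkit.structure import AtomRecord, ResidueRecord, StructureModel


def _point_structure(points, element="C", name="CA"):
    st = StructureModel("points")
    st.chains["A"] = [
        ResidueRecord("A", i + 1, "GLY",
                      [AtomRecord(i + 1, name, element, "", tuple(p))])
        for i, p in enumerate(points)
    ]
    return st


class TestSasaAnalytic:
    def test_single_atom_matches_sphere_area(self):
        st = _point_structure([(0.0, 0.0, 0.0)])
        result = compute_sasa(st)
        r = DEFAULT_RADII["C"] + DEFAULT_PROBE
        exact = 4.0 * np.pi * r**2
        assert result.total == pytest.approx(exact, rel=0.01)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        # closed-form: each sphere loses a cap of height h = R - d/2
        st = _point_structure([(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
        result = compute_sasa(st, n_points=2000)
        R = DEFAULT_RADII["C"] + DEFAULT_PROBE
        exact = 2.0 * (4.0 * np.pi * R**2 - 2.0 * np.pi * R * (R - d / 2.0))
        assert result.total == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_has_zero_area(self):
        # central atom caged by a dense shell
        shell = []
        golden = np.pi * (3 - np.sqrt(5))
        for i in range(60):
            z = 1 - 2 * (i + 0.5) / 60
            rho = np.sqrt(1 - z * z)
            shell.append((2.2 * rho * np.cos(golden * i), 2.2 * rho * np.sin(golden * i), 2.2 * z))
        st = _point_structure([(0.0, 0.0, 0.0)] + shell)
        result = compute_sasa(st)
        assert result.per_atom_area[0] == 0.0

    def test_doubling_points_converges_below_half_percent(self, c2_dimer):
        dimer, _ = c2_dimer
        a = compute_sasa(dimer, n_points=960).total
        b = compute_sasa(dimer, n_points=1920).total
        assert abs(b - a) / b < 0.005

    def test_unknown_element_without_fallback_raises(self):
        st = _point_structure([(0.0, 0.0, 0.0)], element="XX")
        with pytest.raises(RadiiError):
            compute_sasa(st, fallback_radius=None)

    def test_matches_independent_high_density_oracle(self, rng):
        # cross-check against an independent SASA implementation at high
        # sampling density on a small random cluster (<= 20 atoms)
        biotite_struc = pytest.importorskip("biotite.structure")
        points = rng.normal(size=(15, 3)) * 2.5
        st = _point_structure(points)
        mine = compute_sasa(st, n_points=2000)

        arr = biotite_struc.AtomArray(len(points))
        arr.coord = np.asarray(points, dtype=np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, len(points) + 1)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        oracle = biotite_struc.sasa(
            arr,
            probe_radius=DEFAULT_PROBE,
            point_number=5000,
            vdw_radii=np.full(len(points), DEFAULT_RADII["C"]),
        )
        assert mine.total == pytest.approx(float(oracle.sum()), rel=0.02)


class TestInterface:
    def test_distant_protomers_have_no_interface(self, c2_dimer):
        dimer, _ = c2_dimer
        far = StructureModel(dimer.id)
        far.chains["A"] = dimer.chains["A"]
        far.chains["B"] = dimer.transformed(
            np.eye(3), np.array([100.0, 0.0, 0.0])
        ).chains["B"]
        report = compute_interface(far, ["A"], ["B"])
        assert report.total_bsa == pytest.approx(0.0, abs=1e-9)
        assert report.n_contacts == 0

    def test_c2_symmetry_equal_protomer_bsa(self, c2_dimer):
        dimer, _ = c2_dimer
        report = compute_interface(dimer, ["A"], ["B"])
        bsa_a = sum(r.bsa for r in report.residues_a)
        bsa_b = sum(r.bsa for r in report.residues_b)
        assert bsa_a > 0
        assert abs(bsa_a - bsa_b) / bsa_a < 1e-6

    def test_total_is_sum_of_residue_bsas(self, c2_dimer):
        dimer, _ = c2_dimer
        report = compute_interface(dimer, ["A"], ["B"])
        total = sum(r.bsa for r in report.residues_a + report.residues_b)
        assert report.total_bsa == pytest.approx(total, rel=1e-12)

    def test_contact_count_matches_brute_force(self, c2_dimer):
        dimer, truth = c2_dimer
        report = compute_interface(dimer, ["A"], ["B"])
        ca_a = np.array([r.ca.coords for r in dimer.polymer_residues("A")])
        ca_b = np.array([r.ca.coords for r in dimer.polymer_residues("B")])
        d = np.sqrt(((ca_a[:, None] - ca_b[None]) ** 2).sum(axis=2))
        assert report.n_contacts == int((d < 10.0).sum())
        assert report.n_contacts == truth.planted["n_contacts"]

    def test_every_contact_spans_the_interface(self, c2_dimer):
        dimer, _ = c2_dimer
        report = compute_interface(dimer, ["A"], ["B"])
        assert all(a.chain_id == "A" and b.chain_id == "B"
                   for a, b, _ in report.contact_pairs)

    def test_moving_apart_never_increases_bsa(self, c2_dimer):
        dimer, _ = c2_dimer
        totals = []
        for extra in (0.0, 2.0, 5.0, 20.0):
            sep = StructureModel(dimer.id)
            sep.chains["A"] = dimer.chains["A"]
            sep.chains["B"] = dimer.transformed(
                np.eye(3), np.array([0.0, extra, 0.0])
            ).chains["B"]
            totals.append(compute_interface(sep, ["A"], ["B"]).total_bsa)
        assert all(b <= a + 1e-6 for a, b in zip(totals, totals[1:]))

    def test_relabeling_protomers_is_symmetric(self, c2_dimer):
        dimer, _ = c2_dimer
        ab = compute_interface(dimer, ["A"], ["B"])
        ba = compute_interface(dimer, ["B"], ["A"])
        assert ab.total_bsa == pytest.approx(ba.total_bsa, rel=1e-12)

    def test_overlapping_selections_rejected(self, c2_dimer):
        dimer, _ = c2_dimer
        with pytest.raises(SelectionError):
            compute_interface(dimer, ["A"], ["A"])


class TestBinning:
    def _report(self, percents):
        residues = [
            ResidueBsa("A", i + 1, "GLY", asa_free=100.0, asa_complex=100.0 - p)
            for i, p in enumerate(percents)
        ]
        return InterfaceReport("x", sum(r.bsa for r in residues), residues, [])

    def test_fully_buried_residues_land_in_last_bin(self):
        hist = bin_percent_bsa(self._report([100.0, 100.0, 100.0]))
        assert hist["count"].tolist() == [0] * 9 + [3]

    def test_empty_interface_gives_zero_histogram(self):
        hist = bin_percent_bsa(self._report([0.0, 0.0]))
        assert hist["count"].sum() == 0

    def test_planted_values_binned_by_hand(self):
        hist = bin_percent_bsa(self._report([5.0, 15.0, 75.0]))
        assert hist["count"].tolist() == [1, 1, 0, 0, 0, 0, 0, 1, 0, 0]

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ParameterError):
            bin_percent_bsa(self._report([50.0]), bin_edges=[0, 50, 40, 100])


class TestPerPositionProfile:
    def _report(self, sid, positions_percent):
        residues = [
            ResidueBsa("A", pos, "GLY", asa_free=100.0, asa_complex=100.0 - p)
            for pos, p in positions_percent.items()
        ]
        return InterfaceReport(sid, sum(r.bsa for r in residues), residues, [])

    def test_single_report_identity_reshaping(self):
        rep = self._report("s1", {5: 40.0, 9: 80.0})
        df = per_position_bsa_profile([rep], {"s1": {("A", 5): 105, ("A", 9): 109}})
        assert df.reference_position.tolist() == [105, 109]
        assert df.percent_buried.tolist() == [40.0, 80.0]

    def test_disjoint_reports_union_of_rows(self):
        r1 = self._report("s1", {1: 30.0})
        r2 = self._report("s2", {2: 60.0})
        df = per_position_bsa_profile(
            [r1, r2], {"s1": {("A", 1): 11}, "s2": {("A", 2): 22}}
        )
        assert set(df.reference_position) == {11, 22}

    def test_shared_planted_position_appears_in_all(self):
        reports = [self._report(f"s{i}", {7: 100.0}) for i in range(3)]
        maps = {f"s{i}": {("A", 7): 77} for i in range(3)}
        df = per_position_bsa_profile(reports, maps)
        assert (df.reference_position == 77).all()
        assert (df.percent_buried == 100.0).all()
        assert len(df) == 3

    def test_unmapped_position_lists_offenders(self):
        rep = self._report("s1", {5: 40.0})
        with pytest.raises(MappingError) as err:
            per_position_bsa_profile([rep], {"s1": {}})
        assert err.value.offenders
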