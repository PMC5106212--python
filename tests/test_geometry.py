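"""Superposition and bend-angle operators: exactness, recovery, invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pcdhkit.errors import GeometryError, SelectionError
from pcdhkit.geometry import (
    RigidTransform,
    compare_dimers,
    interdomain_angle,
    kabsch,
    trimmed_align,
)
from pcdhkit.synthetic import gen_c2_dimer, gen_domain_chain


def _random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestKabsch:
    def test_self_alignment_identity(self, rng):
        A = rng.normal(size=(25, 3))
        transform, rmsd = kabsch(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(transform.translation, 0.0, atol=1e-8)

    def test_recovers_random_rigid_motion(self, rng):
        A = rng.normal(size=(30, 3)) * 10
        R = _random_rotation(rng)
        t = rng.normal(size=3) * 5
        transform, rmsd = kabsch(A, A @ R.T + t)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(transform.rotation, R, atol=1e-6)
        np.testing.assert_allclose(transform.translation, t, atol=1e-6)

    def test_matches_generic_nonlinear_optimizer_under_noise(self, rng):
        # independent oracle: numerical minimization of the same least-squares
        # loss over a rotation-vector + translation parameterization
        A = rng.normal(size=(20, 3)) * 8
        B = A @ _random_rotation(rng).T + rng.normal(size=3) + rng.normal(0, 0.5, (20, 3))
        _, rmsd = kabsch(A, B)

        def loss(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            return ((A @ R.T + params[3:] - B) ** 2).sum()

        best = min(
            (
                minimize(loss, np.concatenate([rv, np.zeros(3)]), method="Nelder-Mead",
                         options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
                for rv in [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 2.0, 1.0]),
                           np.array([-1.5, 0.5, 2.5])]
            ),
            key=lambda r: r.fun,
        )
        rmsd_oracle = np.sqrt(best.fun / len(A))
        assert rmsd == pytest.approx(rmsd_oracle, rel=1e-4)
        assert rmsd <= rmsd_oracle + 1e-9  # Kabsch is the exact minimizer

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(GeometryError):
            kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            kabsch(line, line)

    def test_rmsd_symmetric_in_arguments(self, rng):
        A = rng.normal(size=(15, 3)) * 5
        B = A + rng.normal(0, 0.3, size=(15, 3))
        assert kabsch(A, B)[1] == pytest.approx(kabsch(B, A)[1], rel=1e-9)


class TestRigidTransform:
    def test_improper_rotation_rejected(self):
        mirror = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(GeometryError):
            RigidTransform(mirror, np.zeros(3))

    def test_nonorthonormal_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))


class TestTrimmedAlign:
    def test_identical_chains_align_perfectly(self, straight_chain):
        structure, _ = straight_chain
        result = trimmed_align(structure, structure)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_aligned == len(structure.polymer_residues())

    def test_planted_outliers_rejected(self, straight_chain, rng):
        # displace 10% of residues by 10 Å; they must be trimmed away
        structure, _ = straight_chain
        n = len(structure.polymer_residues())
        n_out = n // 10
        outliers = set(rng.choice(n, size=n_out, replace=False).tolist())
        copy = structure.transformed(np.eye(3), np.zeros(3))
        for i, res in enumerate(copy.polymer_residues()):
            if i in outliers:
                moved = [
                    type(a)(a.serial, a.name, a.element, a.alt_loc,
                            (a.coords[0] + 10.0, a.coords[1], a.coords[2]),
                            a.occupancy, a.b_factor, a.is_hetero)
                    for a in res.atoms
                ]
                res.atoms[:] = moved
        result = trimmed_align(structure, copy)
        assert result.n_aligned == n - n_out
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_and_count_nonincreasing_over_cycles(self, straight_chain, rng):
        structure, _ = straight_chain
        noisy = structure.transformed(np.eye(3), np.zeros(3))
        for res in noisy.polymer_residues():
            jitter = rng.normal(0, 1.2, 3)
            res.atoms[:] = [
                type(a)(a.serial, a.name, a.element, a.alt_loc,
                        tuple(np.add(a.coords, jitter)), a.occupancy, a.b_factor,
                        a.is_hetero)
                for a in res.atoms
            ]
        prev_n, prev_rmsd = None, None
        for cycles in range(1, 6):
            r = trimmed_align(structure, noisy, max_cycles=cycles)
            if prev_n is not None:
                assert r.n_aligned <= prev_n
                assert r.rmsd <= prev_rmsd + 1e-9
            prev_n, prev_rmsd = r.n_aligned, r.rmsd

    def test_invariant_under_rigid_motion_of_either_input(self, straight_chain, rng):
        structure, _ = straight_chain
        R = _random_rotation(rng)
        moved = structure.transformed(R, rng.normal(size=3) * 10)
        result = trimmed_align(structure, moved)
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)
        assert result.n_aligned == len(structure.polymer_residues())


class TestCompareDimers:
    def test_swapped_chain_labels_align_to_zero(self, c2_dimer):
        dimer, _ = c2_dimer
        swapped = dimer.renamed_chains({"A": "B", "B": "A"})
        result = compare_dimers(dimer, swapped)
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_known_interprotomer_rotation_matches_grid_minimization(self):
        # two C2 dimers differing by a planted 5° rotation of one protomer;
        # oracle: numerical minimization over a rotation-vector + translation
        # of the concatenated squared loss, over both chain pairings
        chain, _ = gen_domain_chain(2, seed=21)
        dimer_a, _ = gen_c2_dimer(chain, separation=8.0, seed=21)
        dimer_b = dimer_a.transformed(np.eye(3), np.zeros(3))
        ca_b = np.array([r.ca.coords for r in dimer_b.polymer_residues("B")])
        centroid = ca_b.mean(axis=0)
        Rp = Rotation.from_rotvec(np.radians(5.0) * np.array([0, 0, 1.0])).as_matrix()
        rotated = {
            "B": [
                type(res)(
                    res.chain_id, res.author_seq_number, res.residue_name,
                    [
                        type(a)(a.serial, a.name, a.element, a.alt_loc,
                                tuple(Rp @ (np.array(a.coords) - centroid) + centroid),
                                a.occupancy, a.b_factor, a.is_hetero)
                        for a in res.atoms
                    ],
                    res.insertion_code,
                )
                for res in dimer_b.chains["B"]
            ]
        }
        dimer_b.chains["B"] = rotated["B"]

        result = compare_dimers(dimer_a, dimer_b, reject_cutoff=1e6)

        A = np.vstack([
            np.array([r.ca.coords for r in dimer_a.polymer_residues(c)]) for c in "AB"
        ])
        rmsds = []
        for order in ("AB", "BA"):
            B = np.vstack([
                np.array([r.ca.coords for r in dimer_b.polymer_residues(c)]) for c in order
            ])

            def loss(params, B=B):
                R = Rotation.from_rotvec(params[:3]).as_matrix()
                return ((A @ R.T + params[3:] - B) ** 2).sum()

            best = min(
                (minimize(loss, np.concatenate([rv, np.zeros(3)]), method="Powell",
                          options={"maxiter": 20000, "xtol": 1e-10, "ftol": 1e-12})
                 for rv in [np.zeros(3), np.array([0, 0, 0.05]), np.array([3.1, 0, 0])]),
                key=lambda r: r.fun,
            )
            rmsds.append(np.sqrt(best.fun / len(A)))
        assert result.rmsd == pytest.approx(min(rmsds), rel=1e-3)

    def test_wrong_chain_count_rejected(self, c2_dimer, straight_chain):
        dimer, _ = c2_dimer
        single, _ = straight_chain
        with pytest.raises(SelectionError):
            compare_dimers(dimer, single)


class TestInterdomainAngle:
    def test_straight_tandem_is_zero(self, straight_chain):
        structure, truth = straight_chain
        ann = truth.annotation["A"]
        bend = interdomain_angle(structure, ann, ("EC1", "EC2"))
        assert bend.deviation_deg == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("angle", [32.6, 90.0])
    def test_planted_bend_recovered(self, angle):
        structure, truth = gen_domain_chain(2, bend_angles_deg=[angle], seed=int(angle))
        ann = truth.annotation["A"]
        bend = interdomain_angle(structure, ann, ("EC1", "EC2"))
        assert bend.deviation_deg == pytest.approx(angle, abs=0.5)

    def test_identical_under_rigid_motion(self, bent_chain, rng):
        structure, truth = bent_chain
        ann = truth.annotation["A"]
        R = _random_rotation(rng)
        moved = structure.transformed(R, rng.normal(size=3) * 20)
        a = interdomain_angle(structure, ann, ("EC2", "EC3")).deviation_deg
        b = interdomain_angle(moved, ann, ("EC2", "EC3")).deviation_deg
        assert a == pytest.approx(b, abs=1e-6)

    def test_degenerate_domain_raises(self):
        from pcdhkit.structure import AtomRecord, DomainAnnotation, ResidueRecord, StructureModel

        st = StructureModel("flat")
        st.chains["A"] = [
            ResidueRecord("A", i + 1, "GLY",
                          [AtomRecord(i + 1, "CA", "C", "", (float(i), 0.0, 0.0))])
            for i in range(6)
        ]
        ann = DomainAnnotation("A", (("EC1", 1, 3), ("EC2", 4, 6)))
        with pytest.raises(GeometryError):
            interdomain_angle(st, ann, ("EC1", "EC2"))
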