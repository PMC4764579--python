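"""Ensemble geometry: superposition, RMSD-to-mean, greedy clustering,
SASA against analytic sphere/cap oracles, interface area and delta-SASA."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from toxinterface import ensemble, synth
from toxinterface.core_io import Selection, Structure
from toxinterface.ensemble import (buried_interface_area, classify_residues,
                                   daura_cluster, daura_cluster_from_matrix,
                                   delta_sasa, kabsch_superpose, rmsd_to_mean,
                                   sasa)

from conftest import make_atom


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_invariance(self):
        pts = np.random.default_rng(1).normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([4.0, -1.0, 2.0])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_minimization_oracle(self):
        """Optimal RMSD agrees with an independent numerical search over
        rotations parameterized by quaternions."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        sup = kabsch_superpose(a, b)

        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)

        def cost(q):
            q = q / np.linalg.norm(q)
            r = Rotation.from_quat(q).as_matrix()
            return np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1))

        best = min(
            (minimize(cost, q0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-14,
                               "maxiter": 5000})
             for q0 in rng.normal(size=(8, 4))),
            key=lambda r: r.fun)
        assert sup.rmsd == pytest.approx(math.sqrt(best.fun), abs=1e-5)

    def test_count_mismatch_and_degenerate_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 3))
        b = a * [1, 1, -1]  # mirror image
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


class TestRmsdToMean:
    def test_identical_models_zero(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 4, amplitude=0.0, seed=0)
        assert rmsd_to_mean(ens) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_two_model_case(self):
        """Two models whose atoms each sit 0.5 A from the mutual mean."""
        base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        # displace along a direction orthogonal across models: +-0.5 in z
        m1 = base + [0, 0, 0.0]
        m2 = base + [0, 0, 1.0]
        atoms = []
        for mid, pts in ((1, m1), (2, m2)):
            for i, p in enumerate(pts):
                atoms.append(make_atom(i + 1, p, res_seq=i + 1, model_id=mid))
        # pure translation: superposition removes it entirely
        assert rmsd_to_mean(Structure(atoms)) == pytest.approx(0.0, abs=1e-9)
        # now a shape change: stretch one atom by +1 z in model 2 only
        m2b = base.copy()
        m2b[0, 2] += 1.0
        atoms = []
        for mid, pts in ((1, base), (2, m2b)):
            for i, p in enumerate(pts):
                atoms.append(make_atom(i + 1, p, res_seq=i + 1, model_id=mid))
        value = rmsd_to_mean(Structure(atoms))
        # brute-force oracle: independent iterative superposition
        coords = np.stack([base, m2b])
        mean = coords[0].copy()
        for _ in range(200):
            aligned = np.stack([kabsch_superpose(c, mean).apply(c)
                                for c in coords])
            new_mean = aligned.mean(axis=0)
            if np.abs(new_mean - mean).max() < 1e-10:
                break
            mean = new_mean
        expected = np.mean([math.sqrt(np.mean(np.sum((al - mean) ** 2, axis=1)))
                            for al in aligned])
        assert value == pytest.approx(expected, abs=1e-6)

    def test_pairwise_method_flag(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 5, amplitude=0.3, seed=1)
        v1 = rmsd_to_mean(ens, method="iterative_mean")
        v2 = rmsd_to_mean(ens, method="pairwise_mean")
        assert v1 > 0 and v2 > 0 and v1 != v2

    def test_needs_two_models(self, toy_complex):
        s, _ = toy_complex
        with pytest.raises(ValueError):
            rmsd_to_mean(s)


class TestDauraCluster:
    def test_identical_ensemble_single_cluster(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 4, amplitude=0.0, seed=0)
        result = daura_cluster(ens, cutoff=0.5)
        assert result.n_clusters == 1
        assert result.representatives == [0]

    def test_tiny_cutoff_singletons(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 5, amplitude=0.5, seed=2)
        result = daura_cluster(ens, cutoff=1e-6)
        assert result.n_clusters == 5

    def test_hand_traced_five_model_fixture(self):
        """Step-by-step hand execution of the greedy procedure:
        d(0,1)=0.5, d(0,2)=0.6, d(1,2)=0.9, d(3,4)=0.4, rest 5.0,
        cutoff 1.0.  Counts 2,2,2,1,1 -> pick 0 (lowest index among
        ties), cluster {0,1,2}; remaining counts 1,1 -> pick 3,
        cluster {3,4}."""
        mat = np.full((5, 5), 5.0)
        np.fill_diagonal(mat, 0.0)
        for i, j, d in [(0, 1, 0.5), (0, 2, 0.6), (1, 2, 0.9), (3, 4, 0.4)]:
            mat[i, j] = mat[j, i] = d
        result = daura_cluster_from_matrix(mat, cutoff=1.0)
        assert result.representatives == [0, 3]
        np.testing.assert_array_equal(result.labels, [0, 0, 0, 1, 1])
        assert result.most_representative == 0

    def test_order_invariance_up_to_relabeling(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 8, amplitude=0.4, seed=5)
        mat = ensemble.pairwise_rmsd_matrix(ens)
        r1 = daura_cluster_from_matrix(mat, cutoff=0.6)
        perm = np.array([3, 1, 4, 0, 7, 6, 2, 5])
        r2 = daura_cluster_from_matrix(mat[np.ix_(perm, perm)], cutoff=0.6)
        # partitions must coincide after undoing the permutation
        part1 = {frozenset(np.where(r1.labels == c)[0])
                 for c in range(r1.n_clusters)}
        part2 = {frozenset(perm[np.where(r2.labels == c)[0]])
                 for c in range(r2.n_clusters)}
        assert part1 == part2

    def test_members_within_cutoff_of_center(self, toy_complex):
        s, _ = toy_complex
        ens = synth.perturb_ensemble(s, 10, amplitude=0.3, seed=9)
        mat = ensemble.pairwise_rmsd_matrix(ens)
        result = daura_cluster_from_matrix(mat, cutoff=0.5)
        for c, rep in enumerate(result.representatives):
            for m in np.where(result.labels == c)[0]:
                assert mat[rep, m] <= 0.5


CARBON_EXPANDED = 1.70 + 1.4  # vdW + probe


class TestSasa:
    def test_lone_sphere_analytic(self):
        s = Structure([make_atom(1, [0, 0, 0])])
        total = sasa(s).total
        assert total == pytest.approx(4 * math.pi * CARBON_EXPANDED ** 2,
                                      rel=0.01)

    def test_two_sphere_cap_closed_form(self):
        """Equal spheres radius R at separation d: each loses a cap of
        height h = R - d/2, so exposed area per atom = 2 pi R (R + d/2)."""
        d = 1.0
        s = Structure([make_atom(1, [0, 0, 0]),
                       make_atom(2, [0, 0, d], res_seq=2)])
        rep = sasa(s)
        r = CARBON_EXPANDED
        expected = 2 * math.pi * r * (r + d / 2)
        for area in rep.atom_areas["area"]:
            assert area == pytest.approx(expected, rel=0.02)

    def test_fully_enclosed_atom_zero(self):
        atoms = [make_atom(1, [0, 0, 0])]
        # tight shell of neighbors on a small sphere
        shell = ensemble._fibonacci_sphere(30) * 1.2
        for i, p in enumerate(shell):
            atoms.append(make_atom(i + 2, p, res_seq=i + 2))
        rep = sasa(Structure(atoms))
        center = rep.atom_areas.loc[rep.atom_areas["serial"] == 1, "area"]
        assert float(center.iloc[0]) == 0.0

    def test_quadrature_convergence(self):
        s = Structure([make_atom(1, [0, 0, 0])])
        a1 = sasa(s, n_points=960).total
        a2 = sasa(s, n_points=1920).total
        assert abs(a2 - a1) / a1 < 0.005

    def test_rigid_motion_invariance(self, toy_complex):
        s, _ = toy_complex
        single = Structure(s.model(1))
        rot = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        moved = Structure([make_atom(a.serial, rot @ a.coords + [5, 6, 7],
                                     element=a.element, name=a.name,
                                     chain=a.chain_id, res_seq=a.res_seq)
                           for a in single.atoms])
        # quadrature orientations differ, so allow small tolerance
        assert sasa(moved).total == pytest.approx(sasa(single).total, rel=0.01)

    def test_unknown_radius_rejected(self):
        s = Structure([make_atom(1, [0, 0, 0], element="FE", name="FE")])
        with pytest.raises(KeyError, match="radius"):
            sasa(s)


class TestInterfaceArea:
    def test_separated_parts_zero(self):
        a = [make_atom(1, [0, 0, 0], chain="A")]
        b = [make_atom(2, [50, 0, 0], chain="B")]
        s = Structure(a + b)
        area = buried_interface_area(s, Selection.make(chains="A"),
                                     Selection.make(chains="B"))
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, toy_complex):
        s, _ = toy_complex
        sa, sb = Selection.make(chains="A"), Selection.make(chains="B")
        assert buried_interface_area(s, sa, sb) == \
            buried_interface_area(s, sb, sa)

    def test_two_atom_touching_matches_cap_formula(self):
        d = 1.0
        s = Structure([make_atom(1, [0, 0, 0], chain="A"),
                       make_atom(2, [0, 0, d], chain="B")])
        area = buried_interface_area(s, Selection.make(chains="A"),
                                     Selection.make(chains="B"))
        r = CARBON_EXPANDED
        h = r - d / 2
        assert area == pytest.approx(2 * math.pi * r * h, rel=0.02)

    def test_overlapping_selections_rejected(self, toy_complex):
        s, _ = toy_complex
        sel = Selection.make(chains="A")
        with pytest.raises(ValueError, match="overlap"):
            buried_interface_area(s, sel, sel)


class TestDeltaSasa:
    def test_bound_equals_free_gives_zeros(self, toy_complex):
        s, _ = toy_complex
        ds = delta_sasa(s, s)
        assert np.allclose(ds.to_numpy(), 0.0)

    def test_identity_with_buried_interface(self, toy_complex):
        """Sum of delta-SASA over both partners equals twice the buried
        interface area."""
        s, _ = toy_complex
        sa, sb = Selection.make(chains="A"), Selection.make(chains="B")
        free_a = Structure(sa.apply(s.model(1)))
        free_b = Structure(sb.apply(s.model(1)))
        total = (delta_sasa(s, free_a, sa).sum()
                 + delta_sasa(s, free_b, sb).sum())
        bsa = buried_interface_area(s, sa, sb)
        assert total == pytest.approx(2 * bsa, rel=0.03, abs=1e-6)

    def test_fully_buried_residue_loses_all_area(self):
        # one B atom encased by A atoms in the bound state
        shell = ensemble._fibonacci_sphere(40) * 1.2
        bound_atoms = [make_atom(1, [0, 0, 0], chain="B")]
        for i, p in enumerate(shell):
            bound_atoms.append(make_atom(i + 2, p, chain="A", res_seq=i + 2))
        bound = Structure(bound_atoms)
        free = Structure([make_atom(1, [0, 0, 0], chain="B")])
        sel = Selection.make(chains="B")
        ds = delta_sasa(bound, free, sel)
        free_area = sasa(free).total
        assert float(ds.iloc[0]) == pytest.approx(free_area, rel=1e-9)

    def test_roster_mismatch_rejected(self, toy_complex):
        s, _ = toy_complex
        free = Structure(Selection.make(chains="A").apply(s.model(1)))
        with pytest.raises(ValueError, match="residues"):
            delta_sasa(s, free, Selection.make(chains="B"))


class TestClassifyResidues:
    def test_standard_classes(self):
        atoms = [make_atom(1, [0, 0, 0], res_name="TRP", res_seq=1),
                 make_atom(2, [5, 0, 0], res_name="LYS", res_seq=2),
                 make_atom(3, [10, 0, 0], res_name="ASP", res_seq=3),
                 make_atom(4, [15, 0, 0], res_name="SER", res_seq=4),
                 make_atom(5, [20, 0, 0], res_name="HIS", res_seq=5)]
        classes = classify_residues(Structure(atoms))
        values = {k[1]: v for k, v in classes.items()}
        assert values == {1: "hydrophobic", 2: "basic", 3: "acidic",
                          4: "other", 5: "basic"}

    def test_nonstandard_is_other(self):
        s = Structure([make_atom(1, [0, 0, 0], res_name="XYZ")])
        assert classify_residues(s).iloc[0] == "other"
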