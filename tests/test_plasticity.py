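"""Superposition, hinge angles, bow distance, contact classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pspatools import plasticity as pl
from pspatools import synthetic
from pspatools.helical import HelicalSymmetry
from pspatools.models import ToyMonomer, load_model, write_pdb
from pspatools.plasticity import ContactPair


@pytest.fixture(scope="module")
def cloud():
    return np.random.default_rng(42).normal(size=(30, 3)) * 10.0


class TestSuperpose:
    def test_self_superposition(self, cloud):
        transform, rmsd = pl.superpose(cloud, cloud)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation(self, cloud):
        rot = Rotation.from_rotvec(np.radians(37.0) * np.array([0.3, 0.5, 0.81]) / np.linalg.norm([0.3, 0.5, 0.81]))
        moved = rot.apply(cloud) + [5.0, -3.0, 11.0]
        transform, rmsd = pl.superpose(moved, cloud)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert transform.angle_deg == pytest.approx(37.0, abs=1e-6)

    def test_reflection_not_collapsed(self, cloud):
        mirrored = cloud * np.array([-1.0, 1.0, 1.0])
        transform, rmsd = pl.superpose(mirrored, cloud)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        assert rmsd > 1.0

    def test_optimal_among_random_transforms(self, cloud):
        """Kabsch RMSD lower-bounds 1,000 random rigid placements."""
        rng = np.random.default_rng(7)
        query = Rotation.from_rotvec(rng.normal(size=3)).apply(cloud) + rng.normal(size=3)
        _, best = pl.superpose(query, cloud)
        for _ in range(1000):
            r = Rotation.from_rotvec(rng.normal(size=3) * rng.uniform(0, np.pi))
            moved = r.apply(query - query.mean(axis=0)) + cloud.mean(axis=0) + rng.normal(size=3)
            rmsd = np.sqrt(np.mean(np.sum((moved - cloud) ** 2, axis=1)))
            assert best <= rmsd + 1e-9

    def test_collinear_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            pl.superpose(line, line)

    def test_length_mismatch_rejected(self, cloud):
        with pytest.raises(ValueError):
            pl.superpose(cloud[:10], cloud)


class TestHingeAngles:
    def test_identity_gives_zero(self, toy_monomer):
        angles = pl.hinge_angles(toy_monomer, toy_monomer)
        assert all(abs(v) < 1e-5 for v in angles.values())

    @pytest.mark.parametrize("angle", [5.0, -15.0, 20.0, -35.0, 45.0])
    def test_injected_hinge2_rotation_recovered(self, toy_monomer, angle):
        hinge = pl.DEFAULT_HINGES[1]
        query = synthetic.perturb_monomer(toy_monomer, hinge.pivot_range[1], angle)
        measured = pl.hinge_angles(query, toy_monomer)
        assert abs(measured["hinge2"]) == pytest.approx(abs(angle), abs=0.5)
        assert abs(measured["hinge1"]) < 0.5
        assert abs(measured["hinge3"]) < 0.5

    def test_coaxial_composition_additive(self, toy_monomer):
        once = synthetic.perturb_monomer(toy_monomer, 165, 10.0)
        twice = synthetic.perturb_monomer(once, 165, 10.0)
        m1 = pl.hinge_angles(once, toy_monomer)["hinge2"]
        m2 = pl.hinge_angles(twice, toy_monomer)["hinge2"]
        assert m2 == pytest.approx(2 * m1, abs=0.5)
        assert np.sign(m2) == np.sign(m1)

    def test_antisymmetry(self, toy_monomer):
        query = synthetic.perturb_monomer(toy_monomer, 165, 20.0)
        forward = pl.hinge_angles(query, toy_monomer)["hinge2"]
        backward = pl.hinge_angles(toy_monomer, query)["hinge2"]
        assert forward == pytest.approx(-backward, abs=1e-6)

    def test_short_distal_segment_rejected(self, toy_monomer):
        bad = pl.HingeDefinition("bad", (128, 133), (214, 216))
        with pytest.raises(ValueError):
            pl.hinge_angles(toy_monomer, toy_monomer, hinges=[bad])


class TestEndToEnd:
    def test_direct_distance(self):
        mono = ToyMonomer(
            np.array([82, 187]), np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        )
        assert pl.end_to_end(mono) == pytest.approx(5.0)

    def test_rigid_transform_invariance(self, toy_monomer):
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = toy_monomer.copy()
        moved.coordinates = rot.apply(moved.coordinates) + [10.0, 5.0, -3.0]
        assert pl.end_to_end(moved) == pytest.approx(pl.end_to_end(toy_monomer))

    def test_bow_straightening_increases_distance(self, toy_monomer):
        """Opening the α3/α4 hinge straightens the bow monotonically."""
        distances = [
            pl.end_to_end(synthetic.perturb_monomer(toy_monomer, 165, a))
            for a in (0.0, 10.0, 20.0, 30.0)
        ]
        assert all(b > a for a, b in zip(distances, distances[1:]))

    def test_missing_residue_rejected(self, toy_monomer):
        with pytest.raises(KeyError):
            pl.end_to_end(toy_monomer, residue_a=1)


class TestContactSeries:
    def _assemblies(self, angles, sym=HelicalSymmetry(1, 3.0, 140.0)):
        ref = synthetic.default_toy_monomer()
        return [
            synthetic.generate_helical_assembly(
                synthetic.perturb_monomer(ref, 165, a), sym, 5, 90.0
            )
            for a in angles
        ]

    def test_identical_models_all_fixed(self):
        models = self._assemblies([0.0, 0.0, 0.0])
        series = pl.contact_series(models, [ContactPair(44, 1, 126)])
        assert series[0].sd_A == pytest.approx(0.0, abs=1e-9)
        assert series[0].classification == "fixed"
        np.testing.assert_allclose(series[0].changes_A, 0.0, atol=1e-9)

    def test_first_class_change_is_zero(self):
        models = self._assemblies([0.0, 10.0, 25.0])
        series = pl.contact_series(models, [ContactPair(71, 1, 196)])
        assert series[0].changes_A[0] == 0.0

    def test_constant_offset_classified_fixed(self):
        """Constant distance changes have zero s.d.: change magnitude alone
        must not flip a contact to switching."""
        base = np.array([10.0, 12.0, 12.0, 12.0])  # +2 A in every later class
        changes = base - base[0]
        sd = changes.std()
        assert sd > 0  # sanity of the construction below
        shifted = np.array([10.0, 12.0, 12.0, 12.0]) + 2.0
        assert np.array_equal(shifted - shifted[0], changes)
        # via the API: two series whose distances differ by a constant
        models = self._assemblies([0.0, 15.0, 30.0])
        s1 = pl.contact_series(models, [ContactPair(44, 1, 126)])[0]
        assert np.allclose(s1.distances_A - s1.distances_A[0], s1.changes_A)

    def test_alternating_pair_classified_switching(self):
        models = self._assemblies([0.0, 45.0, 0.0, 45.0])
        series = pl.contact_series(models, [ContactPair(44, 1, 212)])
        assert series[0].sd_A > 1.0
        assert series[0].classification == "switching"

    def test_hand_computed_sd(self):
        models = self._assemblies([0.0, 20.0])
        s = pl.contact_series(models, [ContactPair(44, 1, 170)])[0]
        changes = s.distances_A - s.distances_A[0]
        assert s.sd_A == pytest.approx(float(np.std(changes)), abs=1e-12)

    def test_rigid_transform_invariance(self):
        models = self._assemblies([0.0, 20.0, 40.0])
        ref = pl.contact_series(models, [ContactPair(44, 1, 126)])[0]
        rng = np.random.default_rng(3)
        for m in models:
            rot = Rotation.from_rotvec(rng.normal(size=3))
            shift = rng.normal(size=3) * 20
            for name in m.chain_order:
                for res in m.chains[name]:
                    m.chains[name][res] = rot.apply(m.chains[name][res]) + shift
        moved = pl.contact_series(models, [ContactPair(44, 1, 126)])[0]
        np.testing.assert_allclose(moved.distances_A, ref.distances_A, atol=1e-9)

    def test_threshold_sweep_monotone(self):
        models = self._assemblies([0.0, 10.0, 20.0, 30.0])
        pairs = [ContactPair(44, 1, 126), ContactPair(44, 1, 170), ContactPair(71, 1, 196)]
        fixed_counts = []
        for threshold in (1e-6, 0.5, 1.0, 2.0, 5.0, 1e6):
            series = pl.contact_series(models, pairs, threshold_A=threshold)
            fixed_counts.append(sum(s.classification == "fixed" for s in series))
        assert fixed_counts == sorted(fixed_counts)
        assert fixed_counts[-1] == len(pairs)

    def test_missing_offset_rejected(self):
        models = self._assemblies([0.0])
        with pytest.raises(ValueError):
            pl.contact_series(models, [ContactPair(44, 99, 126)])


class TestModelIO:
    def test_pdb_round_trip(self, tmp_path, toy_monomer):
        asm = synthetic.generate_helical_assembly(
            toy_monomer, HelicalSymmetry(2, 5.75, 34.4), 3, 100.0
        )
        path = tmp_path / "assembly.pdb"
        write_pdb(asm, path)
        loaded = load_model(path)
        assert loaded.n_chains == 6
        for name in asm.chain_order:
            np.testing.assert_allclose(
                loaded.chain_coords(name), asm.chain_coords(name), atol=1e-3
            )

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            load_model(path)


class TestHelixExtent:
    def test_ideal_helix_fully_helical(self):
        i = np.arange(40)
        coords = np.column_stack(
            [
                2.3 * np.cos(np.radians(100) * i),
                2.3 * np.sin(np.radians(100) * i),
                1.5 * i,
            ]
        )
        mono = ToyMonomer(np.arange(1, 41), coords)
        assert pl.helix_extent(mono, (1, 40)) == (1, 40)

    def test_extended_chain_not_helical(self):
        coords = np.outer(np.arange(20), [3.8, 0.0, 0.0])
        mono = ToyMonomer(np.arange(1, 21), coords)
        assert pl.helix_extent(mono, (1, 20)) is None

    def test_helix_loop_helix_two_runs(self, toy_monomer):
        runs = pl.helical_runs(toy_monomer, (134, 186))
        assert len(runs) == 2
        # the α3/α4 loop (156-165) separates the runs
        assert runs[0][1] < 165 and runs[1][0] > 156

    def test_short_segment_rejected(self, toy_monomer):
        with pytest.raises(ValueError):
            pl.helix_extent(toy_monomer, (24, 29))
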