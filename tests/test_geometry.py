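import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cdrmap.geometry import (
    FRAMEWORK_RMSD_CUTOFF,
    Rejection,
    align_chain_to_template,
    kabsch_superpose,
    select_template,
    template_from_chain,
)
from cdrmap.io_formats import AnnotationRecord
from cdrmap.synthetic_data import make_framework

from oracles import quaternion_rmsd


def _points(rng, n=10):
    return rng.normal(scale=5.0, size=(n, 3))


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        pts = _points(rng)
        transform, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_recovers_rigid_copy_exactly(self, rng):
        reference = _points(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = reference @ rot.T + np.array([1.0, 2.0, 3.0])
        transform, rmsd = kabsch_superpose(mobile, reference)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.apply(mobile), reference, atol=1e-9)

    def test_rmsd_matches_quaternion_oracle_on_noisy_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            reference = _points(rng, n=int(rng.integers(4, 30)))
            mobile = reference + rng.normal(scale=0.5, size=reference.shape)
            _, rmsd = kabsch_superpose(mobile, reference)
            assert rmsd == pytest.approx(quaternion_rmsd(mobile, reference), abs=1e-9)

    def test_rmsd_invariant_to_rigid_pretransform(self, rng):
        reference = _points(rng)
        mobile = reference + rng.normal(scale=0.3, size=reference.shape)
        _, rmsd0 = kabsch_superpose(mobile, reference)
        for seed in range(5):
            rot = Rotation.random(random_state=seed).as_matrix()
            shift = np.random.default_rng(seed).uniform(-10, 10, 3)
            _, rmsd = kabsch_superpose(mobile @ rot.T + shift, reference)
            assert rmsd == pytest.approx(rmsd0, abs=1e-9)

    def test_rotation_is_always_proper(self, rng):
        reference = _points(rng)
        mobile = -reference  # a reflection of the reference
        transform, _ = kabsch_superpose(mobile, reference)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def _record(structure_id, resolution, representative=True, ordered=True):
    return AnnotationRecord(
        structure_id, "L", "L1", 6, "QSVSSY", "L1-11-1", "L1-11-1",
        ordered, representative, resolution,
    )


class TestSelectTemplate:
    def test_best_resolution_wins(self):
        chosen = select_template([_record("1abc", 2.0), _record("2xyz", 1.2)], "L1", 6)
        assert chosen.structure_id == "2xyz"

    def test_resolution_tie_breaks_lexicographically(self):
        chosen = select_template([_record("2xyz", 1.5), _record("1abc", 1.5)], "L1", 6)
        assert chosen.structure_id == "1abc"

    def test_non_representatives_and_incomplete_excluded(self):
        records = [
            _record("1abc", 0.9, representative=False),
            _record("2bad", 1.0, ordered=False),
            _record("3ok", 2.5),
        ]
        assert select_template(records, "L1", 6).structure_id == "3ok"

    def test_no_eligible_record_errors(self):
        with pytest.raises(ValueError, match="template"):
            select_template([_record("1abc", 1.0, representative=False)], "L1", 6)


class TestAlignToTemplate:
    @pytest.fixture
    def template(self):
        chain = make_framework(seed=0)
        return chain, template_from_chain(chain, "L1", 1.0)

    def test_template_chain_aligns_onto_itself(self, template):
        chain, tpl = template
        aligned = align_chain_to_template(chain, tpl, "L1")
        for a, b in zip(aligned.residues, chain.residues):
            for name in a.atoms:
                assert np.allclose(a.atoms[name], b.atoms[name], atol=1e-9)

    def test_prerotated_chain_aligns_back(self, template):
        chain, tpl = template
        rot = Rotation.from_euler("xyz", [30, -60, 15], degrees=True).as_matrix()
        moved = chain.transformed(rot, np.array([5.0, -3.0, 8.0]))
        aligned = align_chain_to_template(moved, tpl, "L1")
        assert not isinstance(aligned, Rejection)
        for a, b in zip(aligned.residues, chain.residues):
            assert np.allclose(a.atoms["CA"], b.atoms["CA"], atol=1e-6)

    def test_alignment_is_idempotent(self, template):
        chain, tpl = template
        rot = Rotation.random(random_state=3).as_matrix()
        once = align_chain_to_template(chain.transformed(rot, np.zeros(3)), tpl, "L1")
        twice = align_chain_to_template(once, tpl, "L1")
        for a, b in zip(twice.residues, once.residues):
            assert np.allclose(a.atoms["CA"], b.atoms["CA"], atol=1e-9)

    def _radially_perturbed(self, chain, cdr, target_rmsd):
        """Scale anchor CAs away from their centroid so the optimal-fit rmsd
        is exactly target_rmsd (rotation stays identity by symmetry)."""
        from cdrmap.imgt_regions import anchor_positions

        anchors = np.array(
            [chain.residue_at(p).atoms["CA"] for p in anchor_positions(cdr)]
        )
        centroid = anchors.mean(axis=0)
        rms_radius = np.sqrt(np.mean(np.sum((anchors - centroid) ** 2, axis=1)))
        scale = target_rmsd / rms_radius
        moved = chain.transformed(np.eye(3), np.zeros(3))
        for pos in anchor_positions(cdr):
            res = moved.residue_at(pos)
            res.atoms["CA"] = centroid + (1 + scale) * (res.atoms["CA"] - centroid)
        return moved

    def test_calibrated_perturbation_beyond_cutoff_rejected(self, template):
        chain, tpl = template
        bad = self._radially_perturbed(chain, "L1", 1.6)
        outcome = align_chain_to_template(bad, tpl, "L1")
        assert isinstance(outcome, Rejection)
        assert outcome.fit_rmsd == pytest.approx(1.6, abs=1e-6)

    def test_cutoff_is_strict_greater_than(self, template):
        from cdrmap.imgt_regions import anchor_positions

        chain, tpl = template
        for target in (FRAMEWORK_RMSD_CUTOFF - 1e-6, FRAMEWORK_RMSD_CUTOFF + 1e-6):
            perturbed = self._radially_perturbed(chain, "L1", target)
            anchors = np.array(
                [perturbed.residue_at(p).atoms["CA"] for p in anchor_positions("L1")]
            )
            _, fit = kabsch_superpose(anchors, tpl.anchor_ca_coords)
            outcome = align_chain_to_template(perturbed, tpl, "L1")
            assert isinstance(outcome, Rejection) == (fit > FRAMEWORK_RMSD_CUTOFF)

    def test_rejection_monotone_in_perturbation(self, template):
        chain, tpl = template
        outcomes = [
            isinstance(
                align_chain_to_template(
                    self._radially_perturbed(chain, "L1", r), tpl, "L1"
                ),
                Rejection,
            )
            for r in (0.5, 1.0, 1.4, 1.6, 2.0, 3.0)
        ]
        assert outcomes == sorted(outcomes)  # False...True, single switch

    def test_missing_anchor_is_incomplete_framework(self, template):
        chain, tpl = template
        broken = chain.transformed(np.eye(3), np.zeros(3))
        del broken.residue_at(22).atoms["CA"]
        outcome = align_chain_to_template(broken, tpl, "L1")
        assert isinstance(outcome, Rejection)
        assert outcome.reason == "incomplete framework"
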