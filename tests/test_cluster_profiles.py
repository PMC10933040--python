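import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cdrmap.cluster_profiles import (
    ClusterProfile,
    Novelty,
    annotate_cluster,
    centroid_distance,
    classify_novelty,
    consensus_motif,
    insertion_position,
    logo_information,
    medoid,
)
from cdrmap.metrics import DistanceMatrix
from cdrmap.synthetic_data import (
    ClusterSpec,
    SyntheticSpec,
    plant_loop_clusters,
    sample_cluster_sequences,
)

from conftest import make_loop

LOG2_20 = math.log2(20)


def _matrix(points, ids=None):
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    ids = ids or [f"p{i:03d}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(points)))


class TestMedoid:
    def test_singleton_is_its_own_medoid(self):
        D = _matrix([0.0, 5.0], ids=["a", "b"])
        assert medoid(D, ["a"]) == "a"

    def test_middle_of_collinear_triplet(self):
        D = _matrix([0.0, 1.0, 3.0], ids=["a", "b", "c"])
        assert medoid(D, ["a", "b", "c"]) == "b"

    def test_matches_exhaustive_sum_oracle(self, rng):
        points = rng.normal(size=(15, 3))
        D = _matrix(points)
        sums = {
            D.ids[i]: sum(D.values[i, j] for j in range(15)) for i in range(15)
        }
        expected = min(sorted(sums), key=lambda k: sums[k])
        assert medoid(D, D.ids) == expected

    def test_tie_breaks_to_smallest_id(self):
        D = _matrix([0.0, 2.0], ids=["zz", "aa"])
        assert medoid(D, ["zz", "aa"]) == "aa"

    def test_unknown_member_errors(self):
        D = _matrix([0.0, 1.0], ids=["a", "b"])
        with pytest.raises(KeyError):
            medoid(D, ["a", "ghost"])


class TestCentroidDistance:
    def test_same_cluster_is_zero(self):
        D = _matrix([0.0, 1.0, 3.0])
        assert centroid_distance(D, D.ids, D.ids) == 0.0

    def test_equals_single_pair_lookup(self):
        D = _matrix([0.0, 1.0, 5.0, 6.0], ids=list("abcd"))
        assert centroid_distance(D, ["a", "b"], ["c", "d"]) == D.distance("a", "c")

    def test_planted_two_angstrom_separation(self):
        spec = SyntheticSpec(
            cdr="L1", imgt_length=6,
            clusters=[ClusterSpec(0, 30, "AAAAAA", 1.0, None, 0.0),
                      ClusterSpec(0, 30, "CCCCCC", 1.0, None, 2.0)],
            loop_noise_sd=0.05, seed=9,
        )
        loops, truth = plant_loop_clusters(spec)
        from cdrmap.metrics import pairwise_matrix

        D = pairwise_matrix(loops)
        members = {
            c: truth.loc[truth.cluster == c, "loop_id"].tolist() for c in (0, 1)
        }
        assert centroid_distance(D, members[0], members[1]) == pytest.approx(2.0, abs=0.3)


class TestLogoInformation:
    def test_identical_column_reaches_maximum_bits(self):
        logo = logo_information(["A", "A", "A"])
        assert logo.information[0] == pytest.approx(LOG2_20)
        assert logo.frequencies.sum(axis=1) == pytest.approx(1.0)

    def test_uniform_column_has_zero_bits(self):
        logo = logo_information([aa for aa in "ACDEFGHIKLMNPQRSTVWY"])
        assert logo.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_fifty_fifty_column(self):
        logo = logo_information(["A", "C"])
        assert logo.information[0] == pytest.approx(LOG2_20 - 1.0)

    def test_frequencies_sum_to_one_per_position(self, rng):
        seqs = sample_cluster_sequences("QSVxSY", 0.7, 40, rng)
        logo = logo_information(seqs)
        assert np.allclose(logo.frequencies.sum(axis=1), 1.0, atol=1e-9)
        assert ((logo.information >= 0) & (logo.information <= LOG2_20)).all()

    def test_errors_name_the_offending_sequence(self):
        with pytest.raises(ValueError, match="ACX"):
            logo_information(["ACA", "ACX"])
        with pytest.raises(ValueError, match="AC"):
            logo_information(["ACA", "AC"])


class TestConsensusMotif:
    def test_case_thresholds(self):
        seqs = (
            ["A" * 10] * 10  # fully conserved -> uppercase
        )
        seqs = ["AAC", "AAC", "AAG", "ACG", "ATT", "AGT", "AAT", "ACC", "AAA", "AAA"]
        # pos0: A at 1.0 -> 'A'; pos1: A at 0.6 -> 'a'; pos2: top freq 0.3 -> 'x'
        logo = logo_information(seqs)
        assert consensus_motif(logo) == "Aax"


class TestAnnotateCluster:
    def test_predicted_only_cluster_is_empty_tally(self, rng):
        loops = [make_loop(f"l{i}", rng.normal(size=(4, 3, 3))) for i in range(3)]
        tally, unassigned = annotate_cluster(loops)
        assert tally == {} and unassigned == 0

    def test_mixed_labels_and_unassigned(self, rng):
        labels = ["A", "A", "A", "L1-11-*", "B"]
        loops = [
            make_loop(
                f"l{i}", rng.normal(size=(4, 3, 3)),
                source="experimental", annotation=lab,
            )
            for i, lab in enumerate(labels)
        ]
        tally, unassigned = annotate_cluster(loops)
        assert tally == {"A": 3, "B": 1} and unassigned == 1

    def test_tallies_match_generator_ground_truth(self):
        spec = SyntheticSpec(
            cdr="L1", imgt_length=6,
            clusters=[ClusterSpec(7, 20, "QSVSSY", 0.9, "L1-11-1", 0.0),
                      ClusterSpec(5, 15, "GDNIGD", 0.9, None, 2.0)],
            seed=4,
        )
        loops, truth = plant_loop_clusters(spec)
        for ci, expected_label in ((0, "L1-11-1"), (1, None)):
            members = [
                lp for lp in loops
                if truth.set_index("loop_id").loc[lp.loop_id, "cluster"] == ci
            ]
            tally, unassigned = annotate_cluster(members)
            n_exp = int((truth.cluster == ci).sum() - (truth[truth.cluster == ci].source == "predicted").sum())
            if expected_label:
                assert tally == {expected_label: n_exp} and unassigned == 0
            else:
                assert tally == {} and unassigned == n_exp

    def test_missing_annotation_errors(self, rng):
        loop = make_loop("l0", rng.normal(size=(4, 3, 3)), source="experimental")
        with pytest.raises(KeyError):
            annotate_cluster([loop])


def _profile(cluster_id, tally, unassigned=0):
    logo = logo_information(["AAAA"])
    return ClusterProfile(
        cluster_id=cluster_id, size=sum(tally.values()) + unassigned or 1,
        medoid_id="m", logo=logo, consensus="AAAA",
        canonical_tally=dict(tally), unassigned_count=unassigned,
    )


class TestClassifyNovelty:
    def test_shared_majority_label_marks_subdivision(self):
        profiles = classify_novelty(
            [_profile(1, {"H1-13-5": 9, "H1-13-1": 1}), _profile(2, {"H1-13-5": 5})]
        )
        assert [p.novelty for p in profiles] == [Novelty.SUBDIVISION] * 2

    def test_all_unassigned_is_novel_candidate(self):
        (profile,) = classify_novelty([_profile(1, {}, unassigned=32)])
        assert profile.novelty == Novelty.NOVEL_CANDIDATE

    def test_pure_single_cluster_is_known(self):
        (profile,) = classify_novelty([_profile(1, {"L1-11-1": 10})])
        assert profile.novelty == Novelty.KNOWN

    def test_zero_experimental_members_is_novel_candidate(self):
        (profile,) = classify_novelty([_profile(1, {})])
        assert profile.novelty == Novelty.NOVEL_CANDIDATE

    def test_permutation_invariance(self):
        a = [_profile(1, {"X": 5}), _profile(2, {"X": 3}), _profile(3, {}, 4)]
        b = [_profile(3, {}, 4), _profile(1, {"X": 5}), _profile(2, {"X": 3})]
        out_a = {p.cluster_id: p.novelty for p in classify_novelty(a)}
        out_b = {p.cluster_id: p.novelty for p in classify_novelty(b)}
        assert out_a == out_b

    def test_length_independent_flag_takes_precedence(self):
        profile = _profile(1, {})
        profile.novelty = Novelty.LENGTH_INDEPENDENT_CANDIDATE
        (out,) = classify_novelty([profile])
        assert out.novelty == Novelty.LENGTH_INDEPENDENT_CANDIDATE


class TestInsertionPosition:
    def test_fully_conserved_logo_has_no_insertion(self):
        logo = logo_information(["QSVSSY"] * 20)
        assert insertion_position(logo) is None

    def test_scrambled_interior_column_found(self, rng):
        seqs = sample_cluster_sequences("QSVSSY", 1.0, 40, rng)
        scrambled = [
            s[:3] + "ACDEFGHIKLMNPQRSTVWY"[i % 20] + s[4:] for i, s in enumerate(seqs)
        ]
        assert insertion_position(logo_information(scrambled)) == 3

    def test_flattest_of_two_flat_columns_wins(self):
        # column 1 is 50/50+ spread over 4 residues, column 3 over 2 residues
        seqs = [
            "A" + "ACDE"[i % 4] + "A" + "AC"[i % 2] + "A" for i in range(8)
        ]
        # col1 top freq 0.25 (flat), col3 top freq 0.5 (not < 0.3)
        assert insertion_position(logo_information(seqs), flat_t=0.6, flank_t=0.9) == 1

    def test_planted_motif_recovery_single_seed(self, rng):
        seqs = sample_cluster_sequences("QSVSSY", 0.9, 100, rng)
        assert consensus_motif(logo_information(seqs)) == "QSVSSY"
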