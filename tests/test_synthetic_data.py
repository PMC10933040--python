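import numpy as np
import pytest

from cdrmap.geometry import kabsch_superpose
from cdrmap.imgt_regions import anchor_positions, cdr_range
from cdrmap.io_formats import read_annotation_table, read_pdb_chains
from cdrmap.metrics import backbone_array, dtw_normalized, rmsd_common_frame
from cdrmap.synthetic_data import (
    ClusterSpec,
    InsertionSpec,
    SyntheticSpec,
    emit_dataset,
    example_spec,
    make_framework,
    make_insertion_variant,
    occupied_positions,
    plant_loop_clusters,
    sample_cluster_sequences,
)


class TestFramework:
    def test_same_seed_gives_identical_coordinates(self):
        a = make_framework(seed=5, framework_noise_sd=0.1)
        b = make_framework(seed=5, framework_noise_sd=0.1)
        for ra, rb in zip(a.residues, b.residues):
            for name in ra.atoms:
                assert np.array_equal(ra.atoms[name], rb.atoms[name])

    def test_all_anchor_cas_present(self):
        chain = make_framework(seed=0)
        for cdr in ("CDR1", "CDR2", "CDR3"):
            for pos in anchor_positions(cdr):
                assert "CA" in chain.residue_at(pos).atoms

    def test_noisy_frameworks_fit_base_within_cutoff(self):
        base = make_framework(seed=0, framework_noise_sd=0.0)
        ref = np.array(
            [base.residue_at(p).atoms["CA"] for p in anchor_positions("CDR1")]
        )
        for seed in range(25):
            noisy = make_framework(seed=seed, framework_noise_sd=0.2)
            mob = np.array(
                [noisy.residue_at(p).atoms["CA"] for p in anchor_positions("CDR1")]
            )
            _, rmsd = kabsch_superpose(mob, ref)
            assert rmsd < 1.5


class TestPlantedClusters:
    def test_realized_separation_within_ten_percent(self):
        spec = SyntheticSpec(
            cdr="L1", imgt_length=6,
            clusters=[ClusterSpec(0, 10, "AAAAAA", 1.0, None, 0.0),
                      ClusterSpec(0, 10, "CCCCCC", 1.0, None, 2.0)],
            loop_noise_sd=0.0, seed=7,
        )
        loops, truth = plant_loop_clusters(spec)
        a = next(lp for lp, c in zip(loops, truth.cluster) if c == 0)
        b = next(lp for lp, c in zip(loops, truth.cluster) if c == 1)
        sep = rmsd_common_frame(backbone_array(a), backbone_array(b))
        assert 1.8 <= sep <= 2.2

    def test_zero_noise_makes_members_identical(self):
        spec = SyntheticSpec(
            cdr="L1", imgt_length=6,
            clusters=[ClusterSpec(0, 5, "AAAAAA", 1.0, None, 0.0)],
            loop_noise_sd=0.0, seed=1,
        )
        loops, _ = plant_loop_clusters(spec)
        for lp in loops[1:]:
            assert rmsd_common_frame(
                backbone_array(loops[0]), backbone_array(lp)
            ) == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_gives_byte_identical_truth(self):
        spec = example_spec(seed=11)
        _, t1 = plant_loop_clusters(spec)
        _, t2 = plant_loop_clusters(example_spec(seed=11))
        assert t1.to_csv() == t2.to_csv()

    def test_unresolvable_separation_rejected_up_front(self):
        with pytest.raises(ValueError, match="not resolvable"):
            SyntheticSpec(
                cdr="L1", imgt_length=6,
                clusters=[ClusterSpec(0, 5, "AAAAAA", 1.0, None, 0.0),
                          ClusterSpec(0, 5, "CCCCCC", 1.0, None, 0.3)],
                loop_noise_sd=0.1,
            )

    def test_motif_length_must_match_loop_length(self):
        with pytest.raises(ValueError, match="motif length"):
            SyntheticSpec(
                cdr="L1", imgt_length=6,
                clusters=[ClusterSpec(0, 5, "AAAA", 1.0, None, 0.0)],
            )


class TestSampledSequences:
    def test_full_conservation_reproduces_motif(self):
        assert sample_cluster_sequences("QSVSSY", 1.0, 5, 0) == ["QSVSSY"] * 5

    def test_x_positions_are_uniform(self):
        seqs = sample_cluster_sequences("AxA", 1.0, 2000, 3)
        from collections import Counter

        counts = Counter(s[1] for s in seqs)
        top = counts.most_common(1)[0][1] / 2000
        # top frequency tends to 1/20; allow 3 sigma of binomial noise
        assert top < 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000) + 0.02

    def test_invalid_motif_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            sample_cluster_sequences("AZB", 1.0, 1, 0)


class TestInsertionVariant:
    @pytest.fixture
    def scenario(self):
        spec = SyntheticSpec(
            cdr="L1", imgt_length=6,
            clusters=[ClusterSpec(0, 30, "QSVSSY", 0.9, None, 0.0),
                      ClusterSpec(0, 30, "GDNIGD", 0.9, None, 3.0)],
            loop_noise_sd=0.1, seed=13,
        )
        loops, truth = plant_loop_clusters(spec)
        source = [lp for lp, c in zip(loops, truth.cluster) if c == 0]
        other = [lp for lp, c in zip(loops, truth.cluster) if c == 1]
        variant = make_insertion_variant(source, 3, 30, seed=14, motif="QSVSSY")
        return source, other, variant

    def test_every_variant_loop_is_one_longer(self, scenario):
        source, _, variant = scenario
        assert all(lp.length == source[0].length + 1 for lp in variant)

    def test_logo_flattest_column_at_insertion_site(self, scenario):
        from cdrmap.cluster_profiles import insertion_position, logo_information

        _, _, variant = scenario
        logo = logo_information([lp.sequence for lp in variant])
        assert insertion_position(logo) == 3

    def test_variant_closer_to_source_than_to_unrelated_cluster(self, scenario):
        source, other, variant = scenario
        v = backbone_array(variant[0])
        d_source = dtw_normalized(v, backbone_array(source[0]))
        d_other = dtw_normalized(v, backbone_array(other[0]))
        assert d_source < d_other

    def test_non_interior_site_rejected(self, scenario):
        source, _, _ = scenario
        with pytest.raises(ValueError, match="interior"):
            make_insertion_variant(source, 0, 1)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("ds")
    spec = SyntheticSpec(
        cdr="L1", imgt_length=6,
        clusters=[ClusterSpec(4, 10, "QSVSSY", 0.9, "L1-11-1", 0.0),
                  ClusterSpec(3, 8, "GDNIGD", 0.9, None, 2.0)],
        seed=21,
    )
    truth = emit_dataset(spec, out)
    return spec, out, truth


class TestEmitDataset:
    def test_one_pdb_per_loop(self, dataset):
        spec, out, truth = dataset
        pdbs = sorted((out / "structures").glob("*.pdb"))
        assert len(pdbs) == len(truth)

    def test_annotation_rows_cover_experimental_members_only(self, dataset):
        spec, out, truth = dataset
        records = read_annotation_table(out / "annotations.tsv")
        assert len(records) == sum(c.n_experimental for c in spec.clusters)
        assert any(r.is_representative for r in records)
        assert any(r.is_unassigned for r in records)

    def test_reread_loops_occupy_cdr_positions(self, dataset):
        spec, out, truth = dataset
        path = out / "structures" / f"{truth.structure_id.iloc[0]}.pdb"
        (chain,) = read_pdb_chains(path)
        lo, hi = cdr_range(spec.cdr)
        in_range = [r.imgt_number for r in chain.residues if lo <= r.imgt_number <= hi]
        assert in_range == occupied_positions(spec.cdr, spec.imgt_length)

    def test_determinism_of_emitted_annotation_table(self, tmp_path):
        spec = example_spec(seed=2)
        t1 = emit_dataset(spec, tmp_path / "a")
        t2 = emit_dataset(example_spec(seed=2), tmp_path / "b")
        assert t1.to_csv() == t2.to_csv()
        assert (tmp_path / "a" / "annotations.tsv").read_text() == (
            tmp_path / "b" / "annotations.tsv"
        ).read_text()
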