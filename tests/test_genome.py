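"""Genome containers, map functions, genetic maps, kinship, and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedopt import (
    GeneticMap,
    allele_frequency,
    filter_maf,
    haldane,
    ibs_kinship,
    inverse_map_function,
    kosambi,
    map_function,
    minor_allele_frequency,
    read_hdf5,
    read_vcf,
    write_hdf5,
)
from breedopt.genome import PhasedGenomeMatrix, concat_individuals

from conftest import make_genomes

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def write_vcf(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_homozygous_reference(self, tmp_path):
        body = (
            "chr1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|0\n"
            "chr1\t200\tm2\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|0\n"
            "chr2\t50\tm3\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|0\n"
        )
        m = read_vcf(write_vcf(tmp_path, body))
        assert m.alleles.shape == (2, 3, 2)
        assert not m.alleles.any()
        assert m.individual_names == ["s1", "s2"]
        assert m.marker_ids == ["m1", "m2", "m3"]

    def test_dosages_match_hand_parse(self, tmp_path):
        # hand parse: s1 = 0|1 -> dosage 1, s2 = 1|1 -> dosage 2
        body = "chr1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|1\n"
        m = read_vcf(write_vcf(tmp_path, body))
        assert m.dosage[:, 0].tolist() == [1, 2]
        assert m.alleles[0, 0].tolist() == [0, 1]

    def test_markers_resorted_by_position(self, tmp_path):
        body = (
            "chr1\t500\tm1\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|0\n"
            "chr1\t100\tm2\tA\tT\t.\tPASS\t.\tGT\t0|1\t0|0\n"
        )
        m = read_vcf(write_vcf(tmp_path, body))
        assert m.marker_ids == ["m2", "m1"]
        assert m.physical_pos.tolist() == [100, 500]
        assert m.dosage[0].tolist() == [1, 0]

    def test_unphased_genotype_rejected(self, tmp_path):
        body = "chr1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0|0\n"
        with pytest.raises(ValueError, match="unphased genotype"):
            read_vcf(write_vcf(tmp_path, body))

    def test_multiallelic_rejected_by_default_skippable_by_flag(self, tmp_path):
        body = (
            "chr1\t100\tm1\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t0|0\n"
            "chr1\t200\tm2\tA\tT\t.\tPASS\t.\tGT\t0|0\t1|1\n"
        )
        path = write_vcf(tmp_path, body)
        with pytest.raises(ValueError, match="multi-allelic"):
            read_vcf(path)
        m = read_vcf(path, on_multiallelic="skip")
        assert m.marker_ids == ["m2"]


class TestHdf5RoundTrip:
    def test_round_trip_identity(self, small_panel, tmp_path):
        genomes, _ = small_panel
        path = tmp_path / "g.h5"
        write_hdf5(genomes, path)
        assert read_hdf5(path) == genomes

    def test_empty_matrix_round_trip(self, tmp_path):
        empty = make_genomes(np.zeros((0, 3, 2), dtype=np.int8))
        path = tmp_path / "empty.h5"
        write_hdf5(empty, path)
        back = read_hdf5(path)
        assert back.n_individuals == 0
        assert back == empty

    def test_vcf_hdf5_vcf_lossless(self, tmp_path, rng):
        from breedopt import write_fixture_files

        genomes, _, _, paths = write_fixture_files(tmp_path / "fx", rng)
        from_vcf = read_vcf(paths["vcf"])
        h5 = tmp_path / "roundtrip.h5"
        write_hdf5(from_vcf, h5)
        assert read_hdf5(h5) == genomes


class TestMatrixInvariants:
    def test_rejects_non_biallelic_codes(self):
        with pytest.raises(ValueError, match="allele codes"):
            make_genomes(np.full((1, 2, 2), 2))

    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError, match="not sorted"):
            make_genomes(np.zeros((1, 2, 2)), pos=[200, 100])

    def test_rejects_split_chromosome_blocks(self):
        with pytest.raises(ValueError, match="not contiguous"):
            make_genomes(np.zeros((1, 3, 2)), chrom=["chr1", "chr2", "chr1"])

    def test_concat_individuals(self, small_panel):
        genomes, _ = small_panel
        both = concat_individuals([genomes, genomes.take_individuals([0, 1])])
        assert both.n_individuals == genomes.n_individuals + 2
        assert np.array_equal(both.alleles[-2:], genomes.alleles[:2])


class TestAlleleFrequency:
    def test_all_reference_zero(self):
        m = make_genomes(np.zeros((3, 4, 2)))
        assert not allele_frequency(m).any()
        assert not minor_allele_frequency(m).any()

    def test_hand_counted_frequency(self):
        # dosages {1, 2} over 2 diploids: 3 alt alleles of 4 -> f = 3/4
        alleles = np.array([[[0, 1]], [[1, 1]]])
        m = make_genomes(alleles)
        assert allele_frequency(m)[0] == pytest.approx(0.75)
        assert minor_allele_frequency(m)[0] == pytest.approx(0.25)

    def test_maf_filter_is_strict(self):
        # markers with f = 0.1, 0.25, 0.5 over 10 diploids (20 alleles)
        counts = [2, 5, 10]
        alleles = np.zeros((10, 3, 2), dtype=np.int8)
        for k, c in enumerate(counts):
            flat = alleles[:, k, :].reshape(-1)
            flat[:c] = 1
            alleles[:, k, :] = flat.reshape(10, 2)
        m = make_genomes(alleles)
        kept = filter_maf(m, 0.2)
        assert kept.marker_ids == ["m1", "m2"]
        # threshold equal to a MAF is excluded (strict inequality)
        assert filter_maf(m, 0.25).marker_ids == ["m2"]

    def test_zero_individuals_error(self):
        m = make_genomes(np.zeros((0, 2, 2)))
        with pytest.raises(ValueError):
            allele_frequency(m)


class TestMapFunctions:
    def test_zero_distance_no_recombination(self):
        assert map_function("haldane", 0.0) == 0.0
        assert map_function("kosambi", 0.0) == 0.0

    @pytest.mark.parametrize(
        "kind,d,expected",
        [
            ("haldane", 0.1, 0.5 * (1 - np.exp(-0.2))),
            ("kosambi", 0.1, 0.5 * np.tanh(0.2)),
            ("haldane", 0.2, 0.5 * (1 - np.exp(-0.4))),
        ],
    )
    def test_closed_form_values(self, kind, d, expected):
        assert map_function(kind, d) == pytest.approx(expected, abs=1e-12)

    def test_grid_properties(self):
        d = np.arange(0.01, 2.0, 0.01)
        for kind in ("haldane", "kosambi"):
            r = map_function(kind, d)
            assert np.all(r > 0) and np.all(r < 0.5)
            assert np.all(np.diff(r) > 0)  # strictly increasing
        assert np.all(map_function("kosambi", d) >= map_function("haldane", d))

    def test_inverse_round_trip(self):
        d = np.arange(0.01, 2.0, 0.01)
        for kind in ("haldane", "kosambi"):
            back = inverse_map_function(kind, map_function(kind, d))
            assert np.max(np.abs(back - d)) < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            map_function("haldane", -0.1)
        with pytest.raises(ValueError):
            inverse_map_function("kosambi", 0.5)
        with pytest.raises(ValueError):
            map_function("morgan", 0.1)

    @given(st.floats(min_value=1e-6, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, d):
        for fwd, inv in ((haldane, lambda r: inverse_map_function("haldane", r)),
                         (kosambi, lambda r: inverse_map_function("kosambi", r))):
            assert float(inv(fwd(d))) == pytest.approx(d, rel=1e-8, abs=1e-8)


class TestGeneticMap:
    def test_knot_identity_and_midpoint(self):
        gm = GeneticMap({"chr1": ([100, 300], [0.0, 0.2])})
        assert gm.interpolate("chr1", 100) == pytest.approx(0.0)
        assert gm.interpolate("chr1", 300) == pytest.approx(0.2)
        assert gm.interpolate("chr1", 200) == pytest.approx(0.1)

    def test_clamped_extrapolation(self):
        gm = GeneticMap({"chr1": ([100, 300], [0.0, 0.2])})
        assert gm.interpolate("chr1", 50) == pytest.approx(0.0)
        assert gm.interpolate("chr1", 400) == pytest.approx(0.2)

    def test_unknown_chromosome(self):
        gm = GeneticMap({"chr1": ([100, 300], [0.0, 0.2])})
        with pytest.raises(KeyError):
            gm.interpolate("chr9", 100)

    def test_rejects_decreasing_morgans(self):
        with pytest.raises(ValueError):
            GeneticMap({"chr1": ([100, 300], [0.2, 0.1])})

    def test_csv_round_trip(self, tmp_path):
        gm = GeneticMap({"chr1": ([100, 300], [0.0, 0.2]),
                         "chr2": ([10, 20, 30], [0.0, 0.05, 0.3])})
        path = tmp_path / "map.csv"
        gm.to_csv(path)
        back = GeneticMap.from_csv(path)
        for chrom in gm.knots:
            np.testing.assert_allclose(back.knots[chrom][0], gm.knots[chrom][0])
            np.testing.assert_allclose(back.knots[chrom][1], gm.knots[chrom][1])


class TestIbsKinship:
    def test_identical_individuals_unit_kinship(self):
        row = np.array([[1, 0], [0, 0], [1, 1]])
        m = make_genomes(np.stack([row, row]))
        K = ibs_kinship(m)
        assert K[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_zero(self):
        a = np.zeros((1, 4, 2), dtype=np.int8)
        b = np.ones((1, 4, 2), dtype=np.int8)
        m = make_genomes(np.concatenate([a, b]))
        assert ibs_kinship(m)[0, 1] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # dosage rows (0,1,2) vs (2,1,0): K = 1 - (2+0+2)/(2*3) = 1/3
        a = np.array([[0, 0], [1, 0], [1, 1]])
        b = np.array([[1, 1], [0, 1], [0, 0]])
        m = make_genomes(np.stack([a, b]))
        assert ibs_kinship(m)[0, 1] == pytest.approx(1 / 3)

    def test_matches_pairwise_definition(self, small_panel):
        genomes, _ = small_panel
        K = ibs_kinship(genomes)
        D = genomes.dosage
        n, p = D.shape
        expected = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                expected[i, j] = 1 - np.abs(D[i] - D[j]).sum() / (2 * p)
        np.testing.assert_allclose(K, expected, atol=1e-12)
        assert np.all(K >= 0) and np.all(K <= 1)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_permutation_equivariance(self, small_panel, rng):
        genomes, _ = small_panel
        perm = rng.permutation(genomes.n_individuals)
        K = ibs_kinship(genomes)
        K_perm = ibs_kinship(genomes.take_individuals(perm))
        np.testing.assert_allclose(K_perm, K[np.ix_(perm, perm)], atol=1e-12)

    def test_zero_markers_error(self):
        m = make_genomes(np.zeros((2, 0, 2)))
        with pytest.raises(ValueError):
            ibs_kinship(m)
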