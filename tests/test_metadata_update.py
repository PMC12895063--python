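import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eigenstream import metadata_update as mu
from eigenstream.io_formats import EigenstreamError, IndRecord, SnpRecord


IND = [IndRecord("S1", "M", "P1"), IndRecord("S2", "F", "P2")]
SNPS = [
    SnpRecord("rs1", 1, 0.0, 1000, "A", "G"),
    SnpRecord("rs2", 1, 0.0, 2000, "C", "T"),
    SnpRecord("rs3", 2, 0.0, 500, "T", "C"),
]


class TestMappingUpdates:
    def test_update_ind_matches_by_sample_id(self):
        out, changed = mu.update_ind(IND, {"S1": "Px"})
        assert out[0].population == "Px" and out[1].population == "P2"
        assert changed == 1

    def test_empty_mapping_is_identity(self):
        out, changed = mu.update_ind(IND, {})
        assert out == list(IND) and changed == 0

    def test_unmatched_key_warns(self, caplog):
        with caplog.at_level("WARNING", logger="eigenstream"):
            out, changed = mu.update_ind(IND, {"S9": "Px"})
        assert out == list(IND) and changed == 0
        assert "not present" in caplog.text

    def test_duplicate_mapping_key_is_error(self, tmp_path):
        path = tmp_path / "map.txt"
        path.write_text("S1 A\nS1 B\n")
        with pytest.raises(EigenstreamError, match="duplicate"):
            mu.read_mapping(path)

    def test_update_snp_ids_leaves_positions(self):
        out, changed = mu.update_snp_ids(SNPS, {"rs1": "chr1_1000"})
        assert out[0].snp_id == "chr1_1000" and out[0].physical_pos == 1000
        assert changed == 1

    def test_update_creating_duplicate_ids_is_error(self):
        with pytest.raises(EigenstreamError, match="duplicate"):
            mu.update_snp_ids(SNPS, {"rs1": "x", "rs2": "x"})


class TestGeneticMap:
    def gmap(self, points_by_chrom):
        return {
            c: (np.array([p for p, _ in pts]), np.array([g for _, g in pts]))
            for c, pts in points_by_chrom.items()
        }

    def test_linear_interpolation_and_cm_to_morgan(self):
        gmap = self.gmap({1: [(100, 0.0), (200, 1.0)]})
        snp = SnpRecord("rs1", 1, 9.9, 150, "A", "G")
        (out,), _ = mu.interpolate_genetic_map([snp], gmap, "cM")
        assert out.genetic_pos == pytest.approx(0.005)

    def test_clamping_below_and_above_range(self):
        gmap = self.gmap({1: [(100, 0.0), (200, 1.0)]})
        snps = [SnpRecord("a", 1, 1.0, 50, "A", "G"),
                SnpRecord("b", 1, 1.0, 900, "A", "G")]
        out, _ = mu.interpolate_genetic_map(snps, gmap, "cM")
        assert out[0].genetic_pos == 0.0
        assert out[1].genetic_pos == pytest.approx(0.01)

    def test_exact_at_map_point_and_morgan_unit(self):
        gmap = self.gmap({1: [(100, 0.0), (200, 0.5)]})
        (out,), _ = mu.interpolate_genetic_map(
            [SnpRecord("a", 1, 0.0, 200, "A", "G")], gmap, "M")
        assert out.genetic_pos == 0.5

    def test_missing_chromosome_left_unchanged_with_warning(self, caplog):
        gmap = self.gmap({1: [(100, 0.0), (200, 1.0)]})
        with caplog.at_level("WARNING", logger="eigenstream"):
            (out,), n_unmapped = mu.interpolate_genetic_map(
                [SnpRecord("a", 5, 0.123, 150, "A", "G")], gmap, "cM")
        assert out.genetic_pos == 0.123 and n_unmapped == 1

    def test_single_point_chromosome_is_error(self):
        gmap = self.gmap({1: [(100, 0.0)]})
        with pytest.raises(EigenstreamError, match="fewer than 2"):
            mu.interpolate_genetic_map([SnpRecord("a", 1, 0, 150, "A", "G")], gmap)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(0, 1e-6), b=st.floats(0, 0.1),
        positions=st.lists(st.integers(1, 10**7), min_size=1, max_size=20),
    )
    def test_exact_on_affine_maps(self, a, b, positions):
        """If genetic = a*physical + b at all map points, interpolation
        reproduces the same affine relation to machine precision."""
        phys = np.array([1, 5_000_000, 10**7])
        gmap = {1: (phys, a * phys + b)}
        snps = [SnpRecord(f"s{i}", 1, 0.0, p, "A", "G") for i, p in enumerate(positions)]
        out, _ = mu.interpolate_genetic_map(snps, gmap, "M")
        for rec, p in zip(out, positions):
            assert rec.genetic_pos == pytest.approx(a * p + b, abs=1e-12, rel=1e-12)

    def test_map_file_parsing_skips_header(self, tmp_path):
        path = tmp_path / "map.txt"
        path.write_text("chrom position cM\n1 100 0.0\n1 200 1.0\n")
        gmap = mu.read_genetic_map(path)
        assert list(gmap[1][0]) == [100, 200]


class TestFlipStrand:
    def test_complement(self):
        (out,), n = mu.flip_strand([SnpRecord("rs1", 1, 0, 1, "A", "G")], {"rs1"})
        assert (out.allele1, out.allele2) == ("T", "C") and n == 1

    def test_involution(self):
        once, _ = mu.flip_strand(SNPS, {"rs2"})
        twice, _ = mu.flip_strand(once, {"rs2"})
        assert twice == list(SNPS)

    def test_non_acgt_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="eigenstream"):
            (out,), n = mu.flip_strand([SnpRecord("rs1", 1, 0, 1, "A", "0")], {"rs1"})
        assert (out.allele1, out.allele2) == ("A", "0") and n == 0
        assert "non-ACGT" in caplog.text

    def test_unlisted_snps_untouched(self):
        out, n = mu.flip_strand(SNPS, {"nope"})
        assert out == list(SNPS) and n == 0


class TestUpdateOnlyMode:
    def test_in_place_edit_with_backup_restore(self, micro_prefix):
        import os
        ind_path = micro_prefix + ".ind"
        snp_path = micro_prefix + ".snp"
        geno_path = micro_prefix + ".geno"
        original_ind = open(ind_path, "rb").read()
        geno_mtime = os.stat(geno_path).st_mtime_ns
        mapping = micro_prefix + ".map"
        open(mapping, "w").write("S1 NewPop\n")
        counts = mu.apply_update_only(snp_path, ind_path, update_ind_file=mapping)
        assert counts["populations_updated"] == 1
        assert "NewPop" in open(ind_path).read()
        # the original is byte-recoverable and the genotype file untouched
        assert open(ind_path + ".backup", "rb").read() == original_ind
        assert os.stat(geno_path).st_mtime_ns == geno_mtime

    def test_existing_backup_refused(self, micro_prefix):
        ind_path = micro_prefix + ".ind"
        open(ind_path + ".backup", "w").write("old state\n")
        mapping = micro_prefix + ".map"
        open(mapping, "w").write("S1 NewPop\n")
        with pytest.raises(EigenstreamError, match="backup"):
            mu.apply_update_only(micro_prefix + ".snp", ind_path, update_ind_file=mapping)
        assert open(ind_path + ".backup").read() == "old state\n"

    def test_snp_side_updates_share_one_backup(self, micro_prefix):
        snp_path = micro_prefix + ".snp"
        original = open(snp_path, "rb").read()
        rename = micro_prefix + ".rename"
        open(rename, "w").write("rs1 chr1_1000\n")
        flip = micro_prefix + ".flip"
        open(flip, "w").write("rs2\n")
        counts = mu.apply_update_only(
            snp_path, micro_prefix + ".ind",
            update_snp_file=rename, flip_strand_file=flip)
        assert counts == {"snp_ids_updated": 1, "strands_flipped": 1}
        assert open(snp_path + ".backup", "rb").read() == original
        content = open(snp_path).read()
        assert "chr1_1000" in content and "rs2 1 0.0 2000 G A" in content
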