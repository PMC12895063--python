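import numpy as np
import pytest

from eigenstream import stats_filters as sf
from eigenstream.io_formats import EigenstreamError

from conftest import random_fixture


def micro_arrays(micro):
    chroms = np.array([r[1] for r in micro.snp_rows])
    sexes = np.array([r[1] for r in micro.ind_rows])
    return micro.genotypes, chroms, sexes


# hand-computed truth for the micro dataset (6 ind: M,M,F,F,U,M; rows
# rs1..rs10 with chroms 1,1,1,2,2,2,23,23,24,24)
MICRO_SNP_TRUTH = [
    # (n_considered, n_obs, freq, maf, missing_rate)
    (6, 5, 0.6, 0.4, 1 / 6),        # rs1 [2,2,1,9,0,1]
    (6, 5, 0.1, 0.1, 1 / 6),        # rs2 [1,0,0,0,0,9]
    (6, 6, 1.0, 0.0, 0.0),          # rs3 monomorphic
    (6, 0, None, None, 1.0),        # rs4 all missing
    (6, 6, 0.5, 0.5, 0.0),          # rs5 [0,1,2,1,0,2]
    (6, 4, 5 / 8, 3 / 8, 1 / 3),    # rs6 [2,9,0,1,9,2]
    (6, 6, 7 / 12, 5 / 12, 0.0),    # rs7 X: all individuals considered
    (6, 5, 0.4, 0.4, 1 / 6),        # rs8 X
    (3, 3, 2 / 3, 1 / 3, 0.0),      # rs9 Y: males only [2,0,2]
    (3, 2, 1.0, 0.0, 1 / 3),        # rs10 Y: males only [2,9,2]
]

# per-individual missingness; Y SNPs excluded for the F/U individuals
MICRO_IND_TRUTH = [
    ("S1", 10, 1), ("S2", 10, 4), ("S3", 8, 1),
    ("S4", 8, 2), ("S5", 8, 2), ("S6", 10, 2),
]


class TestSnpStats:
    def test_micro_dataset_matches_hand_truth(self, micro):
        values, chroms, sexes = micro_arrays(micro)
        stats = sf.calculate_snp_stats(values, chroms, sexes)
        for i, (nc, nob, freq, maf, miss) in enumerate(MICRO_SNP_TRUTH):
            assert stats.n_considered[i] == nc
            assert stats.n_obs[i] == nob
            if freq is None:
                assert np.isnan(stats.freq[i]) and np.isnan(stats.maf[i])
            else:
                assert stats.freq[i] == pytest.approx(freq)
                assert stats.maf[i] == pytest.approx(maf)
            assert stats.missing_rate[i] == pytest.approx(miss)

    def test_y_snp_male_only_denominator(self):
        stats = sf.calculate_snp_stats(
            np.array([[2, 9, 2]]), np.array([24]), np.array(["M", "M", "F"]))
        assert stats.n_considered[0] == 2
        assert stats.missing_rate[0] == pytest.approx(0.5)
        assert stats.freq[0] == pytest.approx(1.0)

    def test_ignore_sex_treats_y_autosomally(self):
        stats = sf.calculate_snp_stats(
            np.array([[2, 9, 2]]), np.array([24]), np.array(["M", "M", "F"]),
            ignore_sex=True)
        assert stats.n_considered[0] == 3

    def test_ignore_unknown_drops_u_from_x_and_y(self):
        values = np.array([[2, 0, 2], [2, 0, 2]])
        chroms = np.array([23, 24])
        sexes = np.array(["M", "F", "U"])
        stats = sf.calculate_snp_stats(values, chroms, sexes, ignore_unknown=True)
        assert stats.n_considered.tolist() == [2, 1]

    @pytest.mark.parametrize("chunk_size", [1, 3, 7, 1000])
    @pytest.mark.parametrize("seed", range(3))
    def test_chunked_stats_equal_whole_matrix(self, seed, chunk_size):
        fixture = random_fixture(seed)
        chroms = np.array([r[1] for r in fixture.snp_rows])
        sexes = np.array([r[1] for r in fixture.ind_rows])
        whole = sf.calculate_snp_stats(fixture.genotypes, chroms, sexes)
        parts = []
        for start in range(0, fixture.n_snp, chunk_size):
            parts.append(sf.calculate_snp_stats(
                fixture.genotypes[start:start + chunk_size],
                chroms[start:start + chunk_size], sexes))
        freq = np.concatenate([p.freq for p in parts])
        miss = np.concatenate([p.missing_rate for p in parts])
        np.testing.assert_array_equal(freq, whole.freq)
        np.testing.assert_array_equal(miss, whole.missing_rate)

    def test_column_order_invariance(self, micro):
        values, chroms, sexes = micro_arrays(micro)
        perm = np.array([3, 0, 5, 2, 4, 1])
        base = sf.calculate_snp_stats(values, chroms, sexes)
        shuffled = sf.calculate_snp_stats(values[:, perm], chroms, sexes[perm])
        np.testing.assert_array_equal(base.freq, shuffled.freq)
        np.testing.assert_array_equal(base.missing_rate, shuffled.missing_rate)


class TestIndMissing:
    def test_micro_dataset_matches_hand_truth(self, micro):
        values, chroms, sexes = micro_arrays(micro)
        acc = sf.IndMissingAccumulator(sexes)
        acc.update(values, chroms)
        stats = acc.finalize()
        for j, (sid, nc, nm) in enumerate(MICRO_IND_TRUTH):
            assert stats.n_considered[j] == nc, sid
            assert stats.n_missing[j] == nm, sid
            assert stats.missing_rate[j] == pytest.approx(nm / nc)

    @pytest.mark.parametrize("chunk_size", [1, 4, 1000])
    def test_chunked_accumulation_equals_whole_matrix(self, micro, chunk_size):
        values, chroms, sexes = micro_arrays(micro)
        whole = sf.IndMissingAccumulator(sexes)
        whole.update(values, chroms)
        acc = sf.IndMissingAccumulator(sexes)
        for start in range(0, len(values), chunk_size):
            acc.update(values[start:start + chunk_size],
                       chroms[start:start + chunk_size])
        np.testing.assert_array_equal(
            acc.finalize().missing_rate, whole.finalize().missing_rate)

    def test_missing_count_conservation_on_autosomes(self, micro):
        """Sum of per-individual missing counts over autosomal SNPs equals
        the sum of per-SNP missing counts: each missing cell is counted
        exactly once from both directions."""
        values, chroms, sexes = micro_arrays(micro)
        autosomal = ~np.isin(chroms, (23, 24))
        acc = sf.IndMissingAccumulator(sexes)
        acc.update(values[autosomal], chroms[autosomal])
        per_ind_total = acc.finalize().n_missing.sum()
        snp = sf.calculate_snp_stats(values[autosomal], chroms[autosomal], sexes)
        per_snp_total = (snp.n_considered - snp.n_obs).sum()
        assert per_ind_total == per_snp_total

    def test_empty_denominator_is_na_with_warning(self, caplog):
        acc = sf.IndMissingAccumulator(np.array(["F"]))
        acc.update(np.array([[2]]), np.array([24]))  # only a Y SNP
        with caplog.at_level("WARNING", logger="eigenstream"):
            stats = acc.finalize()
        assert np.isnan(stats.missing_rate[0])
        assert "denominator" in caplog.text


class TestSanitize:
    def test_y_and_x_rules(self):
        values = np.array([
            [2, 0, 2],   # Y row, sexes M,F,U -> F/U set missing
            [1, 1, 1],   # X row -> male het set missing
            [1, 1, 1],   # autosomal -> untouched
        ])
        chroms = np.array([24, 23, 1])
        sexes = np.array(["M", "F", "U"])
        out, n_y, n_x = sf.sex_chr_sanitize(values, chroms, sexes)
        assert out.tolist() == [[2, 9, 9], [9, 1, 1], [1, 1, 1]]
        assert (n_y, n_x) == (2, 1)
        assert values[0, 1] == 0  # input untouched

    def test_post_condition_properties(self, micro):
        values, chroms, sexes = micro_arrays(micro)
        out, _, _ = sf.sex_chr_sanitize(values, chroms, sexes)
        y_rows = chroms == 24
        x_rows = chroms == 23
        assert (out[np.ix_(y_rows, sexes != "M")] == 9).all()
        assert not (out[np.ix_(x_rows, sexes == "M")] == 1).any()
        assert np.array_equal(out[~(y_rows | x_rows)], values[~(y_rows | x_rows)])


class TestFilters:
    def stats_for(self, rows, chroms=None, sexes=None):
        rows = np.array(rows)
        chroms = np.ones(len(rows), dtype=int) if chroms is None else chroms
        sexes = np.array(["M"] * rows.shape[1]) if sexes is None else sexes
        return sf.calculate_snp_stats(rows, chroms, sexes)

    def test_geno_strict_inequality(self):
        stats = self.stats_for([[2, 0, 9, 9], [2, 0, 0, 9], [2, 0, 0, 0]])
        # missing rates 0.5, 0.25, 0.0
        assert sf.filter_geno(stats, 0.25).tolist() == [False, True, True]
        assert sf.filter_geno(stats, 1.0).tolist() == [True, True, True]

    def test_geno_boundary_kept(self):
        stats = self.stats_for([[2, 0, 0, 0, 0, 0, 0, 0, 0, 9]])  # rate 0.1
        assert sf.filter_geno(stats, 0.1).tolist() == [True]

    def test_maf_inclusive_bounds_and_monomorphic(self):
        stats = self.stats_for([
            [2, 2, 2, 2, 2],  # maf 0
            [1, 0, 0, 0, 0],  # freq .1, maf .1
            [0, 1, 2, 1, 9],  # freq .5, maf .5 (brute allele count: 4/8)
        ])
        assert sf.filter_maf(stats, min_maf=0.05).tolist() == [False, True, True]
        assert sf.filter_maf(stats, min_maf=0.1).tolist() == [False, True, True]
        assert sf.filter_maf(stats, max_maf=0.5).tolist() == [True, True, True]

    def test_all_missing_snp_removed_by_min_maf(self):
        stats = self.stats_for([[9, 9, 9]])
        assert sf.filter_maf(stats, min_maf=0.01).tolist() == [False]
        assert sf.filter_maf(stats).tolist() == [True]

    def test_threshold_validation(self):
        stats = self.stats_for([[0, 1, 2]])
        with pytest.raises(EigenstreamError):
            sf.filter_geno(stats, 1.5)
        with pytest.raises(EigenstreamError):
            sf.filter_maf(stats, min_maf=0.6)
        with pytest.raises(EigenstreamError):
            sf.filter_maf(stats, min_maf=0.4, max_maf=0.2)
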