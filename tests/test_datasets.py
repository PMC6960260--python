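import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhprs.datasets import (
    EnhancerActivityMatrix,
    GenomicRegion,
    LabeledSequenceSet,
    SequenceRecord,
    SplitSpec,
    fix_length,
    make_kfold,
    make_splits,
    parse_activity_matrix,
    read_bed,
    reduce_redundancy,
    sample_negatives,
    select_pretraining_enhancers,
    select_tissue_enhancers,
    ungapped_identity,
)


def _write_matrix(path, regions, samples, values):
    with open(path, "w") as fh:
        fh.write("region\t" + "\t".join(samples) + "\n")
        for r, row in zip(regions, values):
            fh.write(r + "\t" + "\t".join(str(v) for v in row) + "\n")


class TestActivityMatrixParsing:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "m.tsv"
        _write_matrix(path, ["chr1:0-100", "chr1:200-300", "chr2:0-50"],
                      ["liver", "heart"],
                      [[0, 0.5], [0.1, 0.9], [0, 0]])
        m = parse_activity_matrix(path)
        assert m.shape == (3, 2)
        assert m.sample_names == ["liver", "heart"]
        np.testing.assert_allclose(m.tpm, [[0, 0.5], [0.1, 0.9], [0, 0]])
        assert m.regions[1] == GenomicRegion("chr1", 200, 300)

    def test_empty_file_reports_missing_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="no header"):
            parse_activity_matrix(path)

    def test_inverted_region_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        _write_matrix(path, ["chr1:100-90"], ["s"], [[1.0]])
        with pytest.raises(ValueError, match="start must be < end"):
            parse_activity_matrix(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        _write_matrix(path, ["chr1:0-10", "chr1:20-30"], ["liver"], [[0.1], ["abc"]])
        with pytest.raises(ValueError, match="chr1:20-30.*liver"):
            parse_activity_matrix(path)

    def test_duplicate_region_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        _write_matrix(path, ["chr1:0-10", "chr1:0-10"], ["s"], [[1], [2]])
        with pytest.raises(ValueError, match="duplicate"):
            parse_activity_matrix(path)


def _matrix(values, n_samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, s = values.shape
    return EnhancerActivityMatrix(
        regions=[GenomicRegion("chr1", i * 100, i * 100 + 50) for i in range(n)],
        sample_names=[f"s{j}" for j in range(s)],
        tpm=values,
    )


class TestPositiveSelection:
    def test_min_nonzero_rule(self):
        m = _matrix([[0, 0.5, 0.1],    # min nonzero 0.1 -> kept
                     [0, 0.5, 0.05],   # min nonzero 0.05 -> dropped
                     [0, 0, 0]])       # all-zero -> dropped
        kept = select_pretraining_enhancers(m, 0.08)
        assert kept == [m.regions[0]]

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(5)
        vals = rng.random((1000, 8)) * 0.2
        vals[rng.random((1000, 8)) < 0.3] = 0.0
        m = _matrix(vals)
        kept = {str(r) for r in select_pretraining_enhancers(m, 0.08)}
        expected = set()
        for i, row in enumerate(vals):
            nz = [v for v in row if v > 0]
            if nz and min(nz) >= 0.08:
                expected.add(str(m.regions[i]))
        assert kept == expected

    @pytest.mark.parametrize("cutoffs", [(0.0, 0.05, 0.08, 0.2, 1.0)])
    def test_selection_monotone_in_cutoff(self, cutoffs):
        rng = np.random.default_rng(6)
        m = _matrix(rng.random((200, 5)))
        sizes = [len(select_pretraining_enhancers(m, c)) for c in cutoffs]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            select_pretraining_enhancers(_matrix([[1.0]]), -0.1)

    def test_tissue_selection_is_strict(self):
        m = _matrix([[0.9], [0.8], [0.79]])
        kept = select_tissue_enhancers(m, "s0", 0.8)
        assert kept == [m.regions[0]]

    def test_tissue_cutoff_zero_keeps_positive_tpm(self):
        m = _matrix([[0.9], [0.0], [0.01]])
        assert len(select_tissue_enhancers(m, "s0", 0.0)) == 2

    def test_unknown_sample_lists_names(self):
        with pytest.raises(KeyError, match="s0"):
            select_tissue_enhancers(_matrix([[1.0]]), "nope")


class TestFixLength:
    def test_short_region_rejected(self, toy_genome):
        res = fix_length(GenomicRegion("chr1", 5000, 5099), toy_genome, 1000, 100)
        assert not res.accepted and "minimum length" in res.reason

    def test_exact_length_region_is_identity(self, toy_genome):
        res = fix_length(GenomicRegion("chr1", 4000, 5000), toy_genome, 1000)
        assert res.accepted
        assert res.window.start == 4000 and res.window.end == 5000
        assert res.sequence == toy_genome["chr1"][4000:5000].upper()

    def test_window_centered_on_midpoint(self, toy_genome):
        region = GenomicRegion("chr1", 5100, 5300)  # midpoint 5200
        res = fix_length(region, toy_genome, 1000)
        assert res.accepted
        assert (res.window.start, res.window.end) == (4700, 5700)
        assert res.sequence == toy_genome["chr1"][4700:5700].upper()

    def test_window_beyond_chromosome_end_rejected(self, toy_genome):
        res = fix_length(GenomicRegion("chr1", 11800, 12000), toy_genome, 1000)
        assert not res.accepted and "bounds" in res.reason

    def test_unknown_chromosome_raises(self, toy_genome):
        with pytest.raises(KeyError):
            fix_length(GenomicRegion("chrZ", 0, 1000), toy_genome)

    def test_output_length_is_exact_with_fasta(self, toy_genome_fasta):
        res = fix_length(GenomicRegion("chr2", 3000, 3450), toy_genome_fasta, 1000)
        assert res.accepted and len(res.sequence) == 1000


class TestReduceRedundancy:
    def test_identical_pair_collapses(self):
        assert reduce_redundancy(["ACGTACGTACGT"] * 2) == [0]

    def test_dissimilar_pair_retained(self):
        a = "A" * 40
        b = "CGTG" * 10
        assert reduce_redundancy([a, b]) == [0, 1]

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(20)]
        seqs += [seqs[i] for i in (0, 3, 5, 7, 11)]  # 5 exact duplicates
        got = reduce_redundancy(seqs, 0.8)

        order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
        retained = []
        for i in order:  # greedy all-pairs filter, no k-mer prefilter
            if all(ungapped_identity(seqs[i], seqs[j]) < 0.8 for j in retained):
                retained.append(i)
        assert got == sorted(retained)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(10)
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(15)]
        kept = reduce_redundancy(seqs, 0.8)
        survivors = [seqs[i] for i in kept]
        assert reduce_redundancy(survivors, 0.8) == list(range(len(survivors)))

    @pytest.mark.parametrize("cutoff", [0.0, -0.5, 1.5])
    def test_invalid_cutoff(self, cutoff):
        with pytest.raises(ValueError):
            reduce_redundancy(["ACGT"], cutoff)

    def test_identity_definition(self):
        # one mismatch in 10 at the best (zero) offset
        assert ungapped_identity("ACGTACGTAC", "ACGTACGTAA") == pytest.approx(0.9)
        # shifted copy: best offset recovers full overlap of the shorter
        assert ungapped_identity("TTACGTACGT", "ACGTACGT") == pytest.approx(1.0)


class TestSampleNegatives:
    def test_fully_excluded_genome_errors(self, toy_genome):
        exclusions = {c: [(0, len(s))] for c, s in toy_genome.items()}
        with pytest.raises(RuntimeError):
            sample_negatives(toy_genome, exclusions, n=1, length=1000, seed=0)

    def test_windows_within_bounds(self, toy_genome):
        got = sample_negatives({"chr1": toy_genome["chr1"][:10000]}, {}, n=3,
                               length=1000, seed=1)
        assert len(got) == 3
        for rec in got.records:
            r = rec.source_region
            assert 0 <= r.start and r.end <= 10000
            assert rec.label == 0 and len(rec.sequence) == 1000

    def test_never_overlaps_exclusions(self, toy_genome):
        from intervaltree import IntervalTree

        genome = {"chr1": toy_genome["chr1"][:10000]}
        exclusions = {"chr1": [(2000, 8000)]}
        tree = IntervalTree()
        tree[2000:8000] = True
        got = sample_negatives(genome, exclusions, n=500, length=1000, seed=2,
                               max_attempts_factor=200)
        for rec in got.records:
            r = rec.source_region
            assert not tree.overlap(r.start, r.end)
            assert r.end <= 2000 or r.start >= 8000

    def test_ambiguous_windows_rejected(self, toy_genome):
        got = sample_negatives({"chrN": toy_genome["chrN"]}, {}, n=20,
                               length=500, seed=3)
        assert all("N" not in rec.sequence for rec in got.records)

    def test_seed_reproducibility(self, toy_genome):
        g = {"chr2": toy_genome["chr2"]}
        a = sample_negatives(g, {}, n=10, length=200, seed=7)
        b = sample_negatives(g, {}, n=10, length=200, seed=7)
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_bed_reader(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t10\t100\nchr1\t200\t250\nchr2\t0\t5\n")
        got = read_bed(bed)
        assert got == {"chr1": [(10, 100), (200, 250)], "chr2": [(0, 5)]}


def _toy_set(n_pos, n_neg, length=30, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_pos + n_neg):
        seq = "".join(rng.choice(list("ACGT"), length))
        recs.append(SequenceRecord(f"r{i}", seq, 1 if i < n_pos else 0))
    return LabeledSequenceSet(recs, fixed_length=length)


class TestSplits:
    def test_ten_twelfths_arithmetic(self):
        data = _toy_set(12, 108)
        tr, va, te = make_splits(data, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (100, 10, 10)
        assert (int(tr.labels.sum()), int(va.labels.sum()), int(te.labels.sum())) == (10, 1, 1)

    def test_partition_disjoint_and_exhaustive(self):
        data = _toy_set(10, 40)
        tr, va, te = make_splits(data, SplitSpec(seed=2))
        ids = tr.ids + va.ids + te.ids
        assert sorted(ids) == sorted(data.ids)
        assert len(set(ids)) == len(ids)

    def test_kfold_disjoint_exhaustive(self):
        data = _toy_set(10, 40)
        folds = make_kfold(data, 5, seed=3)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == list(range(50))
        assert len(folds) == 5

    def test_same_seed_identical(self):
        data = _toy_set(12, 36)
        a = make_splits(data, SplitSpec(seed=9))
        b = make_splits(data, SplitSpec(seed=9))
        assert all(x.ids == y.ids for x, y in zip(a, b))

    def test_class_ratio_preserved_within_one(self):
        data = _toy_set(20, 100)
        folds = make_kfold(data, 5, seed=4)
        for f in folds:
            labs = data.labels[f]
            assert abs(int(labs.sum()) - 4) <= 1
            assert abs(int((1 - labs).sum()) - 20) <= 1

    def test_empty_split_errors(self):
        data = _toy_set(2, 6)
        with pytest.raises(ValueError, match="empty"):
            make_splits(data, SplitSpec(seed=0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_split_stratification_property(self, seed):
        data = _toy_set(12, 48)
        tr, va, te = make_splits(data, SplitSpec(seed=seed))
        assert int(tr.labels.sum()) == 10
        assert int(va.labels.sum()) == 1
        assert int(te.labels.sum()) == 1


class TestLabeledSequenceSet:
    def test_length_invariant(self):
        with pytest.raises(ValueError, match="fixed_length"):
            LabeledSequenceSet([SequenceRecord("a", "ACGT", 1)], fixed_length=5)

    def test_duplicate_ids_rejected(self):
        recs = [SequenceRecord("a", "ACGT", 1), SequenceRecord("a", "ACGT", 0)]
        with pytest.raises(ValueError, match="duplicate"):
            LabeledSequenceSet(recs, fixed_length=4)

    def test_fasta_round_trip(self, tmp_path):
        data = _toy_set(3, 5)
        path = tmp_path / "x.fa"
        data.write_fasta(path)
        back = LabeledSequenceSet.read_fasta(path)
        assert back.ids == data.ids
        assert list(back.labels) == list(data.labels)
        assert [r.sequence for r in back.records] == [r.sequence for r in data.records]
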