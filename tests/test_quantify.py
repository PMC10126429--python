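"""Read assignment filtering semantics and FPKM."""

import numpy as np
import pytest

from oracles import brute_force_assign
from y2hseq import (
    BAIT,
    CountTable,
    GeneModel,
    InvalidInputError,
    MappedTotalZeroError,
    ReadSet,
    assign_reads,
    compute_fpkm,
)
from y2hseq.quantify import counts_from_bam, counts_from_tsv


def make_reads(seqs, label=BAIT):
    L = len(seqs[0])
    return ReadSet(screen_label=label, read_length=L,
                   read_ids=[f"r{i}" for i in range(len(seqs))],
                   sequences=list(seqs), origins=[""] * len(seqs))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture()
def toy_library():
    rng = np.random.default_rng(42)
    shared = random_seq(rng, 60)
    g1 = random_seq(rng, 100) + shared + random_seq(rng, 40)  # shared block in g1 and g2
    g2 = random_seq(rng, 60) + shared + random_seq(rng, 80)
    g3 = random_seq(rng, 180)
    return [
        GeneModel("g1", len(g1), g1),
        GeneModel("g2", len(g2), g2),
        GeneModel("g3", len(g3), g3),
    ]


class TestAssignReads:
    def test_unique_exact_match_is_counted(self, toy_library):
        read = toy_library[2].cds_seq[10:70]
        ct = assign_reads(make_reads([read]), toy_library)
        assert ct.counts == {"g3": 1}
        assert (ct.n_assigned, ct.n_ambiguous, ct.n_unassigned) == (1, 0, 0)

    def test_read_in_two_genes_is_ambiguous(self, toy_library):
        read = toy_library[0].cds_seq[100:160]  # inside the shared block
        assert read in toy_library[1].cds_seq
        ct = assign_reads(make_reads([read]), toy_library)
        assert ct.counts == {}
        assert ct.n_ambiguous == 1

    def test_unmatched_read_is_unassigned(self, toy_library):
        rng = np.random.default_rng(7)
        ct = assign_reads(make_reads([random_seq(rng, 60)]), toy_library)
        assert ct.n_unassigned == 1
        assert ct.counts == {}

    def test_mismatches_tolerated_up_to_limit(self, toy_library):
        read = list(toy_library[2].cds_seq[10:70])
        read[5] = "A" if read[5] != "A" else "C"
        read[50] = "A" if read[50] != "A" else "C"
        ct = assign_reads(make_reads(["".join(read)]), toy_library, max_mismatches=2)
        assert ct.counts == {"g3": 1}
        ct0 = assign_reads(make_reads(["".join(read)]), toy_library, max_mismatches=1)
        assert ct0.n_unassigned == 1

    def test_tallies_conserve_input(self, toy_library):
        rng = np.random.default_rng(3)
        seqs = [toy_library[0].cds_seq[:60], toy_library[0].cds_seq[100:160],
                random_seq(rng, 60)]
        ct = assign_reads(make_reads(seqs), toy_library)
        assert ct.n_assigned + ct.n_ambiguous + ct.n_unassigned == len(seqs)

    def test_empty_library_rejected(self, toy_library):
        with pytest.raises(InvalidInputError):
            assign_reads(make_reads([toy_library[0].cds_seq[:60]]), [])

    def test_short_reads_unassigned(self, toy_library):
        ct = assign_reads(make_reads([toy_library[0].cds_seq[:10]]), toy_library,
                          min_seed_len=20)
        assert ct.n_unassigned == 1

    def test_matches_brute_force_recount(self):
        # 20 genes x 200 reads, mismatch counts 0..3 vs max_mismatches=2:
        # full-enumeration oracle must agree exactly
        rng = np.random.default_rng(17)
        genes = [GeneModel(f"g{i}", 150, random_seq(rng, 150)) for i in range(20)]
        reads = []
        for _ in range(200):
            gi = int(rng.integers(0, 20))
            start = int(rng.integers(0, 150 - 60 + 1))
            read = list(genes[gi].cds_seq[start:start + 60])
            for pos in rng.choice(60, size=int(rng.integers(0, 4)), replace=False):
                read[pos] = "ACGT"[int(rng.integers(0, 4))]
            reads.append("".join(read))
        ct = assign_reads(make_reads(reads), genes, min_seed_len=20, max_mismatches=2)
        oracle_counts, n_a, n_amb, n_un = brute_force_assign(
            reads, [g.cds_seq for g in genes], max_mismatches=2
        )
        assert ct.counts == {genes[gi].gene_id: c for gi, c in oracle_counts.items()}
        assert (ct.n_assigned, ct.n_ambiguous, ct.n_unassigned) == (n_a, n_amb, n_un)


class TestFPKM:
    def test_unit_case(self):
        lib = [GeneModel("g1", 1000, None), GeneModel("g2", 500, None)]
        ct = CountTable(BAIT, {"g1": 10, "g2": 999_990}, 1_000_000, 0, 0)
        fpkm = compute_fpkm(ct, lib)
        assert fpkm.fpkm["g1"] == 10.0

    def test_per_million_invariance(self):
        lib = [GeneModel("g1", 1000, None), GeneModel("g2", 2000, None)]
        c1 = CountTable(BAIT, {"g1": 30, "g2": 70}, 100, 0, 0)
        c2 = CountTable(BAIT, {"g1": 300, "g2": 700}, 1000, 0, 0)
        f1, f2 = compute_fpkm(c1, lib), compute_fpkm(c2, lib)
        for g in ("g1", "g2"):
            assert f1.fpkm[g] == pytest.approx(f2.fpkm[g], rel=1e-12)

    def test_length_doubling_halves_fpkm(self):
        ct = CountTable(BAIT, {"g1": 50, "g2": 50}, 100, 0, 0)
        f_short = compute_fpkm(ct, [GeneModel("g1", 1000, None), GeneModel("g2", 100, None)])
        f_long = compute_fpkm(ct, [GeneModel("g1", 2000, None), GeneModel("g2", 100, None)])
        assert f_long.fpkm["g1"] == pytest.approx(f_short.fpkm["g1"] / 2, rel=1e-12)

    def test_zero_count_gene_gets_zero(self):
        lib = [GeneModel("g1", 1000, None), GeneModel("g2", 1000, None)]
        ct = CountTable(BAIT, {"g1": 10}, 10, 0, 0)
        assert compute_fpkm(ct, lib).fpkm["g2"] == 0.0

    def test_zero_mapped_total_is_explicit_error(self):
        with pytest.raises(MappedTotalZeroError):
            compute_fpkm(CountTable(BAIT, {}, 0, 5, 5), [GeneModel("g1", 100, None)])


class TestImports:
    def test_counts_tsv_roundtrip_matches_reads_route(self, tmp_path):
        # generating error-free reads from a count vector, assigning them and
        # recounting reproduces the imported counts and hence identical FPKM
        rng = np.random.default_rng(5)
        genes = [GeneModel(f"g{i}", 200, random_seq(rng, 200)) for i in range(5)]
        target = {"g0": 15, "g2": 7, "g4": 30}
        seqs, n = [], 0
        for gid, c in target.items():
            g = next(x for x in genes if x.gene_id == gid)
            for _ in range(c):
                s = int(rng.integers(0, 200 - 60 + 1))
                seqs.append(g.cds_seq[s:s + 60])
        ct_reads = assign_reads(make_reads(seqs), genes)
        p = tmp_path / "counts.tsv"
        ct_reads.to_tsv(p)
        ct_imported = counts_from_tsv(p, BAIT)
        assert ct_imported.counts == ct_reads.counts == target
        f1 = compute_fpkm(ct_reads, genes)
        f2 = compute_fpkm(ct_imported, genes)
        assert f1.fpkm == f2.fpkm

    def test_bam_import_applies_mapq_and_flag_filters(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        genes = [GeneModel("g1", 100, "A" * 100), GeneModel("g2", 100, "C" * 100)]
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:g1\tLN:100\n"
            "@SQ\tSN:g2\tLN:100\n"
            "r1\t0\tg1\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
            "r2\t0\tg1\t5\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n"
            "r3\t0\tg2\t1\t10\t10M\t*\t0\t0\tCCCCCCCCCC\t*\n"  # below MAPQ 30
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\tGGGGGGGGGG\t*\n"      # unmapped
            "r5\t256\tg2\t1\t60\t10M\t*\t0\t0\tCCCCCCCCCC\t*\n"  # secondary
        )
        ct = counts_from_bam(sam, genes, BAIT)
        assert ct.counts == {"g1": 2}
        assert (ct.n_assigned, ct.n_ambiguous, ct.n_unassigned) == (2, 1, 1)
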