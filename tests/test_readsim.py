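"""Read simulation, truth enumeration and name encoding."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import rc
from varsim_lite.diploid import (DUP_COPY, INS_NOVEL, INV, SEQ, GenomeMap,
                                 build_diploid, build_haplotype)
from varsim_lite.readsim import (AlnSegment, BuiltinSimulator, MateTruth,
                                 NotSimulatedRead, RawPair, ReadSimParams,
                                 TruthRecord, annotate_and_write, decode_truth,
                                 encode_truth, iter_fastq_names, read_sidecar,
                                 simulate_reads, true_alignments)
from varsim_lite.reference import Reference, revcomp
from varsim_lite.variants import Variant, VarType


@pytest.fixture(scope="module")
def inv_genome():
    """400 bp contig with a 100 bp inversion at 0-based [150, 250)."""
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    ref = Reference({"c": seq})
    v = Variant("c", 150, seq[149], "<INV>", VarType.INV, svlen=100,
                genotype=(1, 1), id="inv1")
    return build_diploid(ref, [v])


class TestPairArithmetic:
    def test_pair_count_formula(self):
        ref = Reference({"c": "A" * 5000})
        g = build_diploid(ref, [])
        params = ReadSimParams(coverage=50, read_len=100, frag_mean=400,
                               frag_sd=60, seed=1)
        sim = BuiltinSimulator(g, params)
        # 10,000 bp diploid at 50x with 100 bp reads -> 2,500 pairs
        assert sim.n_pairs == 2500

    def test_short_contig_skipped_with_warning(self, caplog):
        ref = Reference({"long": "A" * 2000, "tiny": "A" * 1000})
        g = build_diploid(ref, [])
        params = ReadSimParams(coverage=10, read_len=100, frag_mean=1500,
                               frag_sd=10, seed=1)
        sim = BuiltinSimulator(g, params)
        assert all(not n.startswith("tiny") for n, _ in sim.contigs)
        assert any("shorter than frag_mean" in r.message
                   for r in caplog.records)


class TestSimulateReads:
    def test_error_free_reads_match_haplotype(self, genome, sim_low):
        names = list(iter_fastq_names(sim_low.fastq1))
        assert len(names) == sim_low.n_pairs
        # error-free full-length alternatives must fetch-match the reference
        # on an SV-free stretch; here we just check coverage bookkeeping
        assert sim_low.n_bases == sim_low.n_pairs * 200

    def test_realized_coverage_within_five_percent(self, sim_full):
        assert abs(sim_full.realized_coverage - 50.0) / 50.0 <= 0.05

    def test_sharding_is_byte_identical(self, genome, tmp_path):
        p1 = ReadSimParams(coverage=2, sub_error_rate=0.0, seed=5, shards=1)
        p4 = ReadSimParams(coverage=2, sub_error_rate=0.0, seed=5, shards=4)
        r1 = simulate_reads(genome, p1, tmp_path / "s1")
        r4 = simulate_reads(genome, p4, tmp_path / "s4")
        assert r1.fastq1.read_bytes() == r4.fastq1.read_bytes()
        assert r1.fastq2.read_bytes() == r4.fastq2.read_bytes()

    def test_errors_change_bases_at_expected_rate(self, genome, tmp_path):
        p = ReadSimParams(coverage=1, sub_error_rate=0.02, seed=7)
        p0 = ReadSimParams(coverage=1, sub_error_rate=0.0, seed=7)
        r = simulate_reads(genome, p, tmp_path / "err")
        r0 = simulate_reads(genome, p0, tmp_path / "noerr")
        diff = total = 0
        for a, b in zip(open(r.fastq1), open(r0.fastq1)):
            if a.startswith(("@", "+")) or set(a.strip()) - set("ACGTN"):
                continue
            diff += sum(x != y for x, y in zip(a.strip(), b.strip()))
            total += len(a.strip())
        assert total > 10000
        rate = diff / total
        sigma = (0.02 * 0.98 / total) ** 0.5
        assert abs(rate - 0.02) <= 4 * sigma

    def test_error_free_full_length_reads_fetch_match(self, smoke, tmp_path):
        # SV-only truth: no substituted bases, so every full-length
        # alternative must reproduce the read from the reference
        svs = [v for v in smoke.db
               if v.var_type in (VarType.DEL, VarType.INV, VarType.DUP)
               and abs(v.svlen) >= 50][:6]
        from dataclasses import replace
        g = build_diploid(smoke.reference, [replace(v, genotype=(1, 1))
                                            for v in svs])
        res = simulate_reads(g, ReadSimParams(coverage=2, sub_error_rate=0.0,
                                              seed=3), tmp_path / "sv")
        sidecar = read_sidecar(res.sidecar)
        with open(res.fastq1) as fh:
            lines = fh.read().splitlines()
        checked = 0
        for i in range(0, len(lines), 4):
            rec = decode_truth(lines[i][1:], sidecar)
            (alt,) = rec.mates[0].alternatives[:1]
            if not alt.full_length:
                continue
            seq = "".join(
                smoke.reference.fetch(s.ref_contig, s.ref_start,
                                      s.ref_start + s.length)
                for s in alt.segments)
            assert seq == lines[i + 1]
            checked += 1
        assert checked > 100


class TestTrueAlignments:
    def test_read_in_single_seq_block_is_full_length(self, inv_genome):
        m = true_alignments(inv_genome.gmap, "c_hapA", 10, 100)
        (alt,) = m.alternatives
        assert alt.full_length and alt.anchor.ref_start == 10

    def test_inversion_edge_enumerates_both_anchors(self, inv_genome):
        # 60 bp before the inversion + 40 bp inside it
        m = true_alignments(inv_genome.gmap, "c_hapA", 90, 100)
        alts = m.alternatives
        assert len(alts) == 2
        a0, a1 = alts[0].anchor, alts[1].anchor
        assert (a0.ref_start, a0.length, a0.strand) == (90, 60, "+")
        assert (a1.ref_start, a1.length, a1.strand) == (210, 40, "-")

    def test_read_inside_duplicate_copy_lifts_to_source(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        ref = Reference({"c": seq})
        v = Variant("c", 100, seq[99], "<DUP:TANDEM>", VarType.DUP, svlen=200,
                    dup_copies=2, genotype=(1, 1), id="dup1")
        g = build_diploid(ref, [v])
        # host [300, 400) sits wholly inside the extra copy -> source [200,300)
        m = true_alignments(g.gmap, "c_hapA", 310, 80)
        (alt,) = m.alternatives
        assert alt.full_length and alt.anchor.feature == DUP_COPY
        assert alt.anchor.ref_start == 110

    def test_read_inside_novel_insertion_anchored_at_breakpoint(self):
        rng = np.random.default_rng(29)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ins = "".join(rng.choice(list("ACGT"), size=300))
        ref = Reference({"c": seq})
        v = Variant("c", 200, seq[199], seq[199] + ins, VarType.INS,
                    svlen=300, ins_seq=ins, genotype=(1, 1), id="ins1")
        g = build_diploid(ref, [v])
        m = true_alignments(g.gmap, "c_hapA", 250, 100)  # wholly inside
        (alt,) = m.alternatives
        assert alt.anchor.feature == INS_NOVEL
        assert alt.anchor.ref_start == 200  # the breakpoint
        assert m.labels == {INS_NOVEL}


class TestNameEncoding:
    def _random_record(self, rng) -> TruthRecord:
        def seg():
            return AlnSegment(f"ctg{int(rng.integers(1, 4))}",
                              int(rng.integers(0, 10**7)),
                              int(rng.integers(1, 150)),
                              "+" if rng.random() < 0.5 else "-",
                              [SEQ, INS_NOVEL, INV, DUP_COPY][int(rng.integers(4))])

        def mate():
            return MateTruth(tuple(seg() for _ in range(int(rng.integers(1, 4)))))

        return TruthRecord(f"s{int(rng.integers(10**6))}", "ctg1_hapA",
                           (mate(), mate()))

    def test_roundtrip_many_random_records(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            rec = self._random_record(rng)
            name, overflow = encode_truth(rec)
            assert len(name) <= 254 and " " not in name and "/" not in name
            sidecar = {rec.read_id: overflow} if overflow else None
            assert decode_truth(name, sidecar) == rec

    def test_simulated_names_roundtrip(self, sim_low):
        sidecar = read_sidecar(sim_low.sidecar)
        n = 0
        for name in iter_fastq_names(sim_low.fastq1):
            rec = decode_truth(name, sidecar)
            name2, _ = encode_truth(rec)
            assert name2 == name or name.endswith(":S")
            n += 1
            if n >= 1000:
                break
        assert n >= 1000

    def test_foreign_name_raises_not_simulated(self):
        with pytest.raises(NotSimulatedRead):
            decode_truth("not_a_simulated_read")

    def test_corrupt_payload_distinguished(self):
        from varsim_lite.readsim import CorruptPayload
        with pytest.raises(CorruptPayload):
            decode_truth("vs:s1:zzz___notbase64___")


class TestAdapterContract:
    def test_builtin_routed_through_contract_matches_direct(self, genome,
                                                            tmp_path):
        params = ReadSimParams(coverage=1, sub_error_rate=0.0, seed=2)
        direct = simulate_reads(genome, params, tmp_path / "direct")
        sim = BuiltinSimulator(genome, params)
        with open(tmp_path / "a1.fq", "w") as f1, \
                open(tmp_path / "a2.fq", "w") as f2, \
                open(tmp_path / "sc.tsv", "w") as sc:
            annotate_and_write(sim, genome.gmap, f1, f2, sc)
        assert (tmp_path / "a1.fq").read_bytes() == direct.fastq1.read_bytes()
        assert (tmp_path / "a2.fq").read_bytes() == direct.fastq2.read_bytes()

    def test_adapter_omitting_truth_is_hard_error(self, genome, tmp_path):
        class Bad:
            def reads(self):
                yield RawPair("x1", None, None, None, 100, "A" * 100,
                              "A" * 100, "I" * 100, "I" * 100)

        with open(tmp_path / "b1.fq", "w") as f1, \
                open(tmp_path / "b2.fq", "w") as f2, \
                open(tmp_path / "bs.tsv", "w") as sc:
            with pytest.raises(ValueError, match="x1"):
                annotate_and_write(Bad(), genome.gmap, f1, f2, sc)

    def test_out_of_range_coordinates_rejected(self, genome, tmp_path):
        class Bad:
            def reads(self):
                yield RawPair("x2", "ctg1_hapA", 10**8, 0, 100, "A" * 100,
                              "A" * 100, "I" * 100, "I" * 100)

        with open(tmp_path / "c1.fq", "w") as f1, \
                open(tmp_path / "c2.fq", "w") as f2, \
                open(tmp_path / "cs.tsv", "w") as sc:
            with pytest.raises(ValueError, match="out of range"):
                annotate_and_write(Bad(), genome.gmap, f1, f2, sc)
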