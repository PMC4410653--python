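"""Variant model, VCF I/O and canonical normalization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import apply_edit, apply_variants, enumerate_indel_encodings, haplotype_of
from varsim_lite.reference import Reference
from varsim_lite.sampling import resolve_truth
from varsim_lite.variants import (DEFAULT_BINS, IdentityVariantError, Variant,
                                  VarType, assign_bin, normalize, read_vcf,
                                  validate_bins, write_vcf)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=c,length={n}>
##ALT=<ID=DEL,Description="Deletion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS
"""


def _write(tmp_path, body, n=1000):
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER.format(n=n) + body)
    return p


@pytest.fixture(scope="module")
def ref1k(rng_seed=7):
    rng = np.random.default_rng(rng_seed)
    return Reference({"c": "".join(rng.choice(list("ACGT"), size=1000))})


class TestReadVcf:
    def test_snv_line_maps_directly(self, tmp_path, ref1k):
        base = ref1k.fetch("c", 9, 10)
        alt = "C" if base != "C" else "G"
        p = _write(tmp_path, f"c\t10\t.\t{base}\t{alt}\t.\t.\t.\tGT\t1|0\n")
        (v,) = read_vcf(p, ref1k)
        assert (v.var_type, v.pos, v.ref_allele, v.alt_allele, v.genotype) == \
            (VarType.SNV, 10, base, alt, (1, 0))

    def test_symbolic_del_uses_end(self, tmp_path, ref1k):
        anchor = ref1k.fetch("c", 499, 500)
        p = _write(tmp_path,
                   f"c\t500\t.\t{anchor}\t<DEL>\t.\t.\tSVTYPE=DEL;END=600\tGT\t1|1\n")
        (v,) = read_vcf(p, ref1k)
        assert v.var_type is VarType.DEL and v.svlen == -100

    def test_multiallelic_decomposed_per_haplotype(self, tmp_path, ref1k):
        # gt 1|2: haplotype A carries ALT1, haplotype B carries ALT2; verify
        # via the naive string-edit oracle on both haplotype sequences
        base = ref1k.fetch("c", 49, 50)
        alts = [b for b in "ACGT" if b != base][:2]
        p = _write(tmp_path,
                   f"c\t50\t.\t{base}\t{alts[0]},{alts[1]}\t.\t.\t.\tGT\t1|2\n")
        vs = read_vcf(p, ref1k)
        assert len(vs) == 2
        seq = ref1k.sequence("c")
        hapA = haplotype_of(seq, vs, 0)
        hapB = haplotype_of(seq, vs, 1)
        assert hapA[49] == alts[0] and hapB[49] == alts[1]
        assert hapA[:49] == seq[:49] and hapA[50:] == seq[50:]

    def test_homref_genotype_skipped(self, tmp_path, ref1k):
        base = ref1k.fetch("c", 9, 10)
        alt = "C" if base != "C" else "G"
        p = _write(tmp_path, f"c\t10\t.\t{base}\t{alt}\t.\t.\t.\tGT\t0|0\n")
        assert read_vcf(p, ref1k) == []

    def test_unknown_contig_skipped(self, tmp_path, ref1k):
        p = _write(tmp_path, "chrUn\t10\t.\tA\tC\t.\t.\t.\tGT\t1|0\n")
        assert read_vcf(p, ref1k) == []


class TestNormalize:
    def test_snv_unchanged(self, ref1k):
        base = ref1k.fetch("c", 9, 10)
        alt = "C" if base != "C" else "G"
        v = Variant("c", 10, base, alt, VarType.SNV, genotype=(1, 0))
        assert normalize(v, ref1k) == v

    def test_left_align_through_repeat(self):
        # insertion of CA inside a CACA tract slides to the tract start
        ref = Reference({"c": "GCACACAT"})
        v = Variant("c", 5, "A", "ACA", VarType.INS, svlen=2, ins_seq="CA",
                    genotype=(1, 0))
        n = normalize(v, ref)
        assert (n.pos, n.ref_allele, n.alt_allele) == (1, "G", "GCA")
        assert normalize(n, ref) == n

    def test_all_equivalent_encodings_collapse(self):
        ref = Reference({"c": "GCACACACACAT" + "GATTACA" * 4})
        encs = enumerate_indel_encodings(ref.sequence("c"), 5, "A", "ACA")
        assert len(encs) >= 2  # the repeat really admits several spellings
        normed = {
            normalize(Variant("c", p, r, a,
                              VarType.INS if len(a) > len(r) else VarType.DEL,
                              svlen=len(a) - len(r),
                              ins_seq=a[1:] if len(a) > len(r) else None,
                              genotype=(1, 0)), ref)
            for p, r, a in encs
        }
        assert len(normed) == 1

    def test_identity_rejected(self, ref1k):
        r2 = ref1k.fetch("c", 9, 11)
        v = Variant("c", 10, r2, r2, VarType.MNP, genotype=(1, 0))
        with pytest.raises(IdentityVariantError):
            normalize(v, ref1k)

    def test_normalization_preserves_edited_sequence(self, smoke):
        rng = np.random.default_rng(3)
        resolved = resolve_truth(smoke.db, smoke.pool, rng, smoke.reference)
        seq = smoke.reference.sequence("ctg1")
        for v in resolved:
            if v.var_type in (VarType.INV, VarType.DUP):
                continue
            n = normalize(v, smoke.reference)
            assert apply_variants(seq, [v]) == apply_variants(seq, [n])
            assert normalize(n, smoke.reference) == n  # idempotent

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_random_indels_normalize_idempotently(self, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = Reference({"c": seq})
        pos = data.draw(st.integers(2, 350))
        size = data.draw(st.integers(1, 12))
        if data.draw(st.booleans()):
            ins = "".join(rng.choice(list("ACGT"), size=size))
            v = Variant("c", pos, seq[pos - 1], seq[pos - 1] + ins,
                        VarType.INS, svlen=size, ins_seq=ins, genotype=(1, 0))
        else:
            v = Variant("c", pos, seq[pos - 1:pos + size], seq[pos - 1],
                        VarType.DEL, svlen=-size, genotype=(1, 0))
        n = normalize(v, ref)
        assert normalize(n, ref) == n
        assert apply_variants(seq, [v]) == apply_variants(seq, [n])


class TestSizeBins:
    def test_default_bins_valid(self):
        validate_bins(DEFAULT_BINS)

    @pytest.mark.parametrize("svlen,expected", [
        (-100, "51-100"), (-101, "101-200"), (-51, "51-100"),
        (-5, "2-5"), (-6000, ">5000"),
    ])
    def test_boundary_inclusion(self, svlen, expected):
        v = Variant("c", 10, "N" * (abs(svlen) + 1), "N", VarType.DEL,
                    svlen=svlen, genotype=(1, 0))
        assert assign_bin(v).label == expected

    def test_snv_goes_to_unit_bin(self):
        v = Variant("c", 10, "A", "C", VarType.SNV, genotype=(1, 0))
        assert assign_bin(v).label == "1"


class TestWriteVcf:
    def test_empty_set_is_header_only(self, tmp_path, ref1k):
        p = tmp_path / "e.vcf"
        write_vcf([], p, ref1k.lengths)
        body = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert body == []
        assert read_vcf(p, ref1k) == []

    def test_unsorted_input_rejected(self, tmp_path, ref1k):
        a = Variant("c", 50, ref1k.fetch("c", 49, 50), "<INV>", VarType.INV,
                    svlen=20, genotype=(1, 0))
        b = Variant("c", 10, ref1k.fetch("c", 9, 10), "<INV>", VarType.INV,
                    svlen=5, genotype=(1, 0))
        with pytest.raises(ValueError):
            write_vcf([a, b], tmp_path / "u.vcf", ref1k.lengths)

    def test_roundtrip_random_truth_set(self, tmp_path, smoke, truth_set):
        p = tmp_path / "rt.vcf"
        write_vcf(truth_set, p, smoke.reference.lengths)
        assert read_vcf(p, smoke.reference) == list(truth_set)

    def test_roundtrip_whole_database(self, tmp_path, smoke):
        rng = np.random.default_rng(11)
        db = resolve_truth(smoke.db, smoke.pool, rng, smoke.reference)
        p = tmp_path / "db.vcf"
        write_vcf(db, p, smoke.reference.lengths)
        assert read_vcf(p, smoke.reference) == db
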