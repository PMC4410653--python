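"""Independent oracles used by the test suite.

Everything here is deliberately naive and self-contained (plain string edits,
brute-force enumeration, exhaustive search) so it cannot share bugs with the
library code it checks.
"""
from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply one VCF-style replacement (1-based pos) as a plain string splice."""
    p0 = pos - 1
    assert seq[p0:p0 + len(ref)] == ref, "oracle: REF mismatch"
    return seq[:p0] + alt + seq[p0 + len(ref):]


def apply_variants(seq: str, variants) -> str:
    """Apply variants right-to-left so earlier coordinates stay valid."""
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        p0 = v.pos - 1
        t = v.var_type.value
        if t in ("SNV", "MNP"):
            assert seq[p0:p0 + len(v.ref_allele)] == v.ref_allele
            seq = seq[:p0] + v.alt_allele + seq[p0 + len(v.ref_allele):]
        elif t == "INS":
            seq = seq[:p0 + 1] + v.ins_seq + seq[p0 + 1:]
        elif t == "DEL":
            ln = abs(v.svlen)
            seq = seq[:p0 + 1] + seq[p0 + 1 + ln:]
        elif t == "INV":
            ln = v.svlen
            seq = seq[:p0 + 1] + rc(seq[p0 + 1:p0 + 1 + ln]) + seq[p0 + 1 + ln:]
        elif t == "DUP":
            span = v.svlen // (v.dup_copies - 1)
            s = p0 + 1
            seq = (seq[:s + span] + seq[s:s + span] * (v.dup_copies - 1)
                   + seq[s + span:])
        else:  # pragma: no cover
            raise AssertionError(t)
    return seq


def haplotype_of(seq: str, variants, hap: int) -> str:
    return apply_variants(seq, [v for v in variants if v.genotype[hap] == 1])


def enumerate_indel_encodings(ref_seq: str, pos: int, ref: str, alt: str,
                              window: int = 60) -> list[tuple[int, str, str]]:
    """All VCF encodings (pos, REF, ALT) of the same pure indel within a
    window, found by brute-force construction and string comparison."""
    target = apply_edit(ref_seq, pos, ref, alt)
    d = abs(len(ref) - len(alt))
    assert d > 0, "oracle: not an indel"
    deletion = len(ref) > len(alt)
    found = []
    for s in range(max(1, pos - window), min(len(ref_seq), pos + window) + 1):
        if deletion:
            if s + d > len(ref_seq):
                continue
            r_c = ref_seq[s - 1:s + d]
            a_c = r_c[0]
        else:
            if s + d > len(target):
                continue
            r_c = ref_seq[s - 1]
            a_c = r_c + target[s:s + d]
        if apply_edit(ref_seq, s, r_c, a_c) == target:
            found.append((s, r_c, a_c))
    assert (pos, ref, alt) in found
    return found


# ---------------------------------------------------------------------------
# Exhaustive one-to-one SV matching
# ---------------------------------------------------------------------------

def sv_compatible(t, c, bp_tolerance: int = 100, size_ratio_min: float = 0.8) -> bool:
    if t.var_type is not c.var_type or t.chrom != c.chrom:
        return False
    if abs(t.pos - c.pos) > bp_tolerance:
        return False
    st, sc = abs(t.svlen), abs(c.svlen)
    return min(st, sc) / max(st, sc) >= size_ratio_min


def all_maximum_matchings(truth, calls, compatible=sv_compatible):
    """(max size, list of maximum matchings as frozensets of (i, j) pairs),
    by exhaustive recursion. Feasible only for small fixtures."""
    compat = {i: [j for j, c in enumerate(calls) if compatible(t, c)]
              for i, t in enumerate(truth)}
    best: list[frozenset] = []
    best_size = 0

    def rec(i, used, acc):
        nonlocal best, best_size
        if i == len(truth):
            size = len(acc)
            if size > best_size:
                best_size, best = size, [frozenset(acc)]
            elif size == best_size:
                fs = frozenset(acc)
                if fs not in best:
                    best.append(fs)
            return
        rec(i + 1, used, acc)  # leave truth i unmatched
        for j in compat[i]:
            if j not in used:
                rec(i + 1, used | {j}, acc + [(i, j)])

    rec(0, frozenset(), [])
    return best_size, best
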