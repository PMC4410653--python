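"""Synthetic reference, variant database and insertion-pool generation.

Everything the pipeline needs is generated programmatically from a seed:
an i.i.d. reference at a target GC content with embedded short tandem repeat
tracts, a variant database emulating public catalogs (dbSNP/DGV-like mixes of
SNVs, indels and SVs), and a donor pool of insertion sequences. A fraction of
indels is deliberately placed at the *right* edge of repeat tracts in a
non-canonical (right-shifted) encoding, so normalization failures surface
immediately in any downstream comparison.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from types import SimpleNamespace
from typing import Sequence

import numpy as np

from .reference import Reference, write_fasta
from .sampling import FootprintTracker, InsertionPool
from .variants import Variant, VarType, normalize, write_vcf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatTract:
    contig: str
    start0: int  # 0-based
    unit: str
    copies: int

    @property
    def end0(self) -> int:
        return self.start0 + len(self.unit) * self.copies


@dataclass(frozen=True)
class FixtureSpec:
    n_contigs: int = 1
    contig_len: int = 100_000
    gc: float = 0.5
    n_repeat_tracts: int = 40
    repeat_units: tuple[str, ...] = ("CA", "A", "CAT")
    repeat_copies: tuple[int, int] = (8, 20)
    n_snv: int = 150
    n_indel: int = 60
    n_del: int = 6
    n_ins: int = 6
    n_dup: int = 4
    n_inv: int = 4
    indel_size: tuple[int, int] = (1, 20)
    sv_size: tuple[int, int] = (60, 2000)
    dup_copies_range: tuple[int, int] = (2, 3)
    repeat_indel_fraction: float = 0.25
    n_pool: int = 4
    pool_len: tuple[int, int] = (2000, 6000)
    seed: int = 0

    def __post_init__(self):
        if self.contig_len < 1000:
            raise ValueError("contig_len must be >= 1000")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")


def make_reference(spec: FixtureSpec) -> tuple[Reference, list[RepeatTract]]:
    """i.i.d. bases at the target GC with recorded repeat tracts embedded."""
    rng = np.random.default_rng((spec.seed, 1))
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2,
                  (1 - spec.gc) / 2])
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    tracts: list[RepeatTract] = []
    per_contig = max(1, spec.n_repeat_tracts // spec.n_contigs)
    for ci in range(spec.n_contigs):
        name = f"ctg{ci + 1}"
        arr = rng.choice(bases, size=spec.contig_len, p=p)
        occupied: list[tuple[int, int]] = []
        for _ in range(per_contig):
            unit = spec.repeat_units[int(rng.integers(len(spec.repeat_units)))]
            copies = int(rng.integers(spec.repeat_copies[0],
                                      spec.repeat_copies[1] + 1))
            tract = unit * copies
            for _attempt in range(50):
                start = int(rng.integers(200, spec.contig_len - len(tract) - 200))
                end = start + len(tract)
                if all(e + 30 <= start or end + 30 <= s for s, e in occupied):
                    occupied.append((start, end))
                    arr[start:end] = list(tract)
                    tracts.append(RepeatTract(name, start, unit, copies))
                    break
        seqs[name] = "".join(arr)
    return Reference(seqs), tracts


def make_insertion_pool(spec: FixtureSpec) -> InsertionPool:
    rng = np.random.default_rng((spec.seed, 3))
    seqs = []
    for _ in range(spec.n_pool):
        n = int(rng.integers(spec.pool_len[0], spec.pool_len[1] + 1))
        seqs.append("".join(rng.choice(list("ACGT"), size=n)))
    return InsertionPool(tuple(seqs))


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


_POS_MARGIN = 150  # keep events away from contig ends


def make_variant_db(reference: Reference, spec: FixtureSpec,
                    tracts: Sequence[RepeatTract]) -> list[Variant]:
    """Generate the synthetic variant database against the reference.

    Records are valid VCF-ready variants; the repeat-tract indels are emitted
    right-shifted (non-canonical) on purpose. All genotypes are 1|1 here —
    phase and zygosity are assigned by sampling, not by the database.
    """
    rng = np.random.default_rng((spec.seed, 2))
    tracker = FootprintTracker(min_gap=10)
    out: list[Variant] = []
    k = 0

    def vid():
        nonlocal k
        k += 1
        return f"db{k}"

    def try_add(v: Variant, canonical: bool = True) -> bool:
        """Accept `v` if its (normalized) footprint is free of collisions.

        Non-tract records are stored in canonical form so the database's
        footprints are exactly the footprints the constructor will see.
        """
        vn = normalize(v, reference) if canonical else v
        s, e = vn.footprint
        if tracker.accepts(vn.chrom, s, e):
            tracker.add(vn.chrom, s, e)
            out.append(vn)
            return True
        return False

    def rand_pos(contig_len: int, span: int) -> int:
        return int(rng.integers(_POS_MARGIN, contig_len - span - _POS_MARGIN))

    # --- repeat-context indels, right-shifted encoding --------------------
    n_repeat = round(spec.n_indel * spec.repeat_indel_fraction)
    tract_order = list(rng.permutation(len(tracts)))
    made = 0
    for ti in tract_order:
        if made >= n_repeat:
            break
        tr = tracts[ti]
        u = len(tr.unit)
        # reserve the whole tract (plus one unit of slack) so the left-aligned
        # form cannot collide with neighbours
        if not tracker.accepts(tr.contig, tr.start0 - 2, tr.end0 + u + 2):
            continue
        tracker.add(tr.contig, tr.start0 - 2, tr.end0 + u + 2)
        if rng.random() < 0.5:
            # deletion of the *last* unit: anchored right of the repeat start
            pos = tr.end0 - u  # 1-based anchor = base before the last unit
            ref = reference.fetch(tr.contig, pos - 1, pos + u)
            out.append(Variant(tr.contig, pos, ref, ref[0], VarType.DEL,
                               svlen=-u, genotype=(1, 1), id=vid()))
        else:
            # insertion of one more unit *after* the tract end
            pos = tr.end0  # 1-based anchor = last tract base
            anchor = reference.fetch(tr.contig, pos - 1, pos)
            out.append(Variant(tr.contig, pos, anchor, anchor + tr.unit,
                               VarType.INS, svlen=u, ins_seq=tr.unit,
                               genotype=(1, 1), id=vid()))
        made += 1
    if made < n_repeat:
        log.warning("placed only %d of %d repeat-context indels", made, n_repeat)

    contigs = reference.contigs

    def contig_for(i):
        return contigs[i % len(contigs)]

    # --- plain indels -----------------------------------------------------
    for i in range(spec.n_indel - made):
        contig = contig_for(i)
        clen = reference.length(contig)
        size = int(rng.integers(spec.indel_size[0], spec.indel_size[1] + 1))
        for _ in range(200):
            pos = rand_pos(clen, size)
            if rng.random() < 0.5:
                ref = reference.fetch(contig, pos - 1, pos + size)
                v = Variant(contig, pos, ref, ref[0], VarType.DEL,
                            svlen=-size, genotype=(1, 1), id=vid())
            else:
                anchor = reference.fetch(contig, pos - 1, pos)
                seq = _rand_seq(rng, size)
                v = Variant(contig, pos, anchor, anchor + seq, VarType.INS,
                            svlen=size, ins_seq=seq, genotype=(1, 1), id=vid())
            if try_add(v):
                break

    # --- SNVs --------------------------------------------------------------
    for i in range(spec.n_snv):
        contig = contig_for(i)
        clen = reference.length(contig)
        for _ in range(200):
            pos = rand_pos(clen, 1)
            ref = reference.fetch(contig, pos - 1, pos)
            alt = "ACGT"[int(rng.integers(4))]
            while alt == ref:
                alt = "ACGT"[int(rng.integers(4))]
            if try_add(Variant(contig, pos, ref, alt, VarType.SNV,
                               genotype=(1, 1), id=vid())):
                break

    # --- SVs ---------------------------------------------------------------
    def sv_size():
        return int(rng.integers(spec.sv_size[0], spec.sv_size[1] + 1))

    def place_sv(make, span):
        for _ in range(200):
            if make(span):
                return True
        return False

    for i in range(spec.n_del):
        contig = contig_for(i)
        size = sv_size()
        place_sv(lambda sz: try_add(Variant(
            contig, (p := rand_pos(reference.length(contig), sz)),
            reference.fetch(contig, p - 1, p), "<DEL>", VarType.DEL,
            svlen=-sz, genotype=(1, 1), id=vid())), size)
    for i in range(spec.n_ins):
        contig = contig_for(i)
        size = sv_size()
        if i % 2 == 0:
            seq = _rand_seq(rng, size)
            place_sv(lambda sz: try_add(Variant(
                contig, (p := rand_pos(reference.length(contig), 1)),
                (a := reference.fetch(contig, p - 1, p)), a + seq,
                VarType.INS, svlen=sz, ins_seq=seq, genotype=(1, 1),
                id=vid())), size)
        else:  # symbolic: sequence to be resolved from the donor pool
            place_sv(lambda sz: try_add(Variant(
                contig, (p := rand_pos(reference.length(contig), 1)),
                reference.fetch(contig, p - 1, p), "<INS>", VarType.INS,
                svlen=sz, genotype=(1, 1), id=vid())), size)
    for i in range(spec.n_dup):
        contig = contig_for(i)
        span = sv_size()
        copies = int(rng.integers(spec.dup_copies_range[0],
                                  spec.dup_copies_range[1] + 1))
        place_sv(lambda sz: try_add(Variant(
            contig, (p := rand_pos(reference.length(contig), sz)),
            reference.fetch(contig, p - 1, p), "<DUP:TANDEM>", VarType.DUP,
            svlen=(copies - 1) * sz, dup_copies=copies, genotype=(1, 1),
            id=vid())), span)
    for i in range(spec.n_inv):
        contig = contig_for(i)
        size = sv_size()
        place_sv(lambda sz: try_add(Variant(
            contig, (p := rand_pos(reference.length(contig), sz)),
            reference.fetch(contig, p - 1, p), "<INV>", VarType.INV,
            svlen=sz, genotype=(1, 1), id=vid())), size)

    out.sort(key=Variant.sort_key)
    return out


# ---------------------------------------------------------------------------
# Presets and on-disk emission
# ---------------------------------------------------------------------------

SMOKE = FixtureSpec()


def smoke_fixture(seed: int = 1) -> SimpleNamespace:
    """The default end-to-end fixture: 1 contig x 100 kb plus database/pool."""
    spec = FixtureSpec(seed=seed)
    reference, tracts = make_reference(spec)
    db_raw = make_variant_db(reference, spec, tracts)
    db = sorted((normalize(v, reference) for v in db_raw),
                key=Variant.sort_key)
    pool = make_insertion_pool(spec)
    return SimpleNamespace(spec=spec, reference=reference, tracts=tracts,
                           db=db, db_raw=db_raw, pool=pool)


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, tracts = make_reference(spec)
    db = make_variant_db(reference, spec, tracts)
    pool = make_insertion_pool(spec)
    paths = {"ref": out / "ref.fa", "db": out / "db.vcf",
             "pool": out / "ins_pool.fa", "manifest": out / "manifest.json"}
    reference.to_fasta(paths["ref"])
    write_vcf(db, paths["db"], reference.lengths)
    write_fasta({f"donor{i + 1}": s for i, s in enumerate(pool.sequences)},
                paths["pool"])
    manifest = {"spec": asdict(spec),
                "tracts": [asdict(t) for t in tracts],
                "n_db_records": len(db)}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return paths
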