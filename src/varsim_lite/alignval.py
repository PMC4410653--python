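"""Score aligner output (SAM/BAM) against the truth encoded in read names.

An alignment is correct when its leftmost aligned reference base (soft clips
excluded) lies within a wiggle tolerance of any admissible true anchor for
either mate of the pair. Checking both mates makes the verdict immune to
aligners swapping mate FLAG bits; strand agreement is deliberately not
required, since a clipped anchor can be legitimately reported in either
orientation.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .readsim import (CorruptPayload, MateTruth, NotSimulatedRead, TruthRecord,
                      decode_truth, read_sidecar)

log = logging.getLogger(__name__)

DEFAULT_WIGGLE = 20

CORRECT = "CORRECT"
INCORRECT_POS = "INCORRECT_POS"
INCORRECT_CHROM = "INCORRECT_CHROM"
UNMAPPED = "UNMAPPED"
UNKNOWN_READ = "UNKNOWN_READ"
VERDICTS = (CORRECT, INCORRECT_POS, INCORRECT_CHROM, UNMAPPED, UNKNOWN_READ)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AlignmentVerdict:
    read_id: str
    mate: int | None  # 0/1 from FLAG when available
    verdict: str
    matched_alternative: int | None
    labels: frozenset[str]
    mapq: int | None  # recorded, never used in the verdict


def is_correct(aligned: tuple[str, int, str],
               alternatives: Sequence, wiggle: int = DEFAULT_WIGGLE
               ) -> tuple[bool, int | None]:
    """Is (contig, 0-based pos, strand) within `wiggle` of any alternative's
    anchor? Returns (correct, matched alternative index)."""
    contig, pos, _strand = aligned
    for i, alt in enumerate(alternatives):
        a = alt.anchor
        if a.ref_contig == contig and abs(pos - a.ref_start) <= wiggle:
            return True, i
    return False, None


@dataclass
class AlignmentReport:
    """Verdict tallies per category: ALL plus each region label seen."""

    wiggle: int
    categories: dict[str, dict[str, int]] = field(default_factory=dict)
    n_secondary: int = 0
    n_supplementary: int = 0

    def add(self, verdict: str, labels: Iterable[str]) -> None:
        cats = ["ALL"] + sorted(labels)
        for c in cats:
            d = self.categories.setdefault(c, {v: 0 for v in VERDICTS})
            d[verdict] += 1

    def fraction_correct(self, category: str = "ALL") -> float:
        d = self.categories.get(category)
        if not d:
            return 0.0
        denom = sum(d.values()) - d[UNKNOWN_READ]
        return d[CORRECT] / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "wiggle": self.wiggle,
            "n_secondary": self.n_secondary,
            "n_supplementary": self.n_supplementary,
            "categories": {
                c: {**counts, "fraction_correct": self.fraction_correct(c)}
                for c, counts in sorted(self.categories.items())
            },
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def validate_alignments(path: str | Path, wiggle: int = DEFAULT_WIGGLE,
                        sidecar: dict[str, str] | str | Path | None = None
                        ) -> tuple[AlignmentReport, list[AlignmentVerdict]]:
    """Validate every primary record of a SAM/BAM against encoded truth.

    Secondary/supplementary records are counted but not judged; unmapped reads
    score UNMAPPED; undecodable names score UNKNOWN_READ and are excluded from
    denominators.
    """
    import pysam

    if sidecar is not None and not isinstance(sidecar, dict):
        sidecar = read_sidecar(sidecar)
    report = AlignmentReport(wiggle=wiggle)
    verdicts: list[AlignmentVerdict] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_secondary:
                report.n_secondary += 1
                continue
            if aln.is_supplementary:
                report.n_supplementary += 1
                continue
            try:
                rec = decode_truth(aln.query_name, sidecar)
            except NotSimulatedRead:
                report.add(UNKNOWN_READ, ())
                verdicts.append(AlignmentVerdict(aln.query_name, None,
                                                 UNKNOWN_READ, None,
                                                 frozenset(), None))
                continue
            except CorruptPayload as exc:
                log.warning("%s", exc)
                report.add(UNKNOWN_READ, ())
                verdicts.append(AlignmentVerdict(aln.query_name, None,
                                                 UNKNOWN_READ, None,
                                                 frozenset(), None))
                continue
            mate = 0 if aln.is_read1 else 1 if aln.is_read2 else None
            labels = rec.mates[mate].labels if mate is not None else rec.labels
            if aln.is_unmapped:
                v = AlignmentVerdict(rec.read_id, mate, UNMAPPED, None,
                                     labels, aln.mapping_quality)
                report.add(UNMAPPED, labels)
                verdicts.append(v)
                continue
            # union of both mates' alternatives: mate-swap cannot hurt scoring
            alts = list(rec.mates[0].alternatives) + list(rec.mates[1].alternatives)
            strand = "-" if aln.is_reverse else "+"
            ok, idx = is_correct((aln.reference_name, aln.reference_start,
                                  strand), alts, wiggle)
            if ok:
                verdict = CORRECT
            else:
                contigs = {a.anchor.ref_contig for a in alts}
                verdict = (INCORRECT_POS if aln.reference_name in contigs
                           else INCORRECT_CHROM)
            report.add(verdict, labels)
            verdicts.append(AlignmentVerdict(rec.read_id, mate, verdict, idx,
                                             labels, aln.mapping_quality))
    return report, verdicts
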