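"""Reference genome access plus small sequence utilities.

All coordinates at this layer are 0-based, half-open. VCF-facing code in
:mod:`varsim_lite.variants` converts to/from the 1-based inclusive convention
at the interface boundary.
"""
from __future__ import annotations

from pathlib import Path

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMP)[::-1]


class Reference:
    """In-memory multi-contig genome.

    Fixture genomes here are at most a few hundred kilobases, so sequences are
    held as plain strings; `fetch` is a slice.
    """

    def __init__(self, seqs: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Reference":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(seqs)

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of `contig[start:end)`, 0-based half-open."""
        if start < 0 or end > len(self._seqs[contig]) or start > end:
            raise ValueError(
                f"fetch out of range: {contig}:{start}-{end} "
                f"(contig length {len(self._seqs[contig])})"
            )
        return self._seqs[contig][start:end]

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        write_fasta(self._seqs, path, width=width)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at `width` columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA file into memory via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return seqs
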