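"""Reference genome container and FASTA I/O (thin wrapper over Biopython)."""

from __future__ import annotations

from typing import Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import revcomp


class Genome(Mapping[str, str]):
    """In-memory multi-contig genome; sequences upper-cased on load."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome has no contigs")
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Substring of a contig; minus strand returns the reverse complement."""
        seq = self._contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq

    def contig_length(self, name: str) -> int:
        return len(self._contigs[name])

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs)

    def to_fasta(self, path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self._contigs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)
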