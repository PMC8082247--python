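"""Genome container and FASTA I/O.

A :class:`Genome` is a named, ordered collection of contig sequences over the
DNA alphabet ``{A, C, G, T, N}``.  Sequences are stored uppercase; ``N`` marks
bases that are excluded from k-mer windows and from background nucleotide
frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = frozenset("ACGTN")

# byte-level code table: A=0, C=1, G=2, T=3, N/other=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class Genome:
    """A named set of contigs over {A,C,G,T,N}."""

    id: str
    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        cleaned = []
        for name, seq in self.contigs:
            if name in seen:
                raise ValueError(f"duplicate contig name {name!r} in genome {self.id!r}")
            seen.add(name)
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-ACGTN symbols: {sorted(bad)}"
                )
            cleaned.append((name, seq))
        self.contigs = cleaned

    @property
    def valid_length(self) -> int:
        """Total bases excluding N."""
        return sum(len(s) - s.count("N") for _, s in self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def contig_codes(self) -> Iterable[tuple[str, np.ndarray]]:
        """Yield (name, uint8 code array) per contig (A=0,C=1,G=2,T=3,N=4)."""
        for name, seq in self.contigs:
            yield name, _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]

    def reverse_complement(self, new_id: str | None = None) -> "Genome":
        rc = [
            (name, seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii"))
            for name, seq in self.contigs
        ]
        return Genome(id=new_id or f"{self.id}_rc", contigs=rc)


def codes_to_seq(codes: np.ndarray) -> str:
    """Inverse of the byte-code mapping (A=0,C=1,G=2,T=3,N=4)."""
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def read_fasta(path: Union[str, Path, io.TextIOBase], genome_id: str | None = None) -> Genome:
    """Read a (possibly line-wrapped, mixed-case) multi-record FASTA file."""
    if isinstance(path, (str, Path)):
        gid = genome_id if genome_id is not None else Path(path).stem
        handle: io.TextIOBase = open(path)
        close = True
    else:
        gid = genome_id or "genome"
        handle, close = path, False
    try:
        contigs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(id=gid, contigs=contigs)


def write_fasta(genome: Genome, path: Union[str, Path]) -> None:
    """Write the genome as FASTA wrapped at 80 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)
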