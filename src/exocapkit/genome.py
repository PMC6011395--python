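"""Reference genome container.

A :class:`GenomeAssembly` is an ordered mapping of chromosome name to an
uppercase nucleotide string over ``{A, C, G, T, N}``.  The toolkit is
assembly-agnostic: anything from a two-contig synthetic fixture to a full
mammalian reference can back it, as long as it fits in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return sequence.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """An in-memory genome: ordered chromosome name -> sequence map.

    Sequences are normalised to uppercase on construction and validated
    against the {A,C,G,T,N} alphabet.
    """

    name: str
    chromosomes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalised: Dict[str, str] = {}
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {chrom!r} has an empty sequence")
            seq = seq.upper()
            extra = set(seq) - _VALID_BASES
            if extra:
                raise ValueError(
                    f"chromosome {chrom!r} contains invalid characters: {sorted(extra)}"
                )
            normalised[chrom] = seq
        self.chromosomes = normalised

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice ``[start, end)`` (0-based half-open) from a chromosome."""
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.chromosomes[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "GenomeAssembly":
        path = Path(path)
        chroms = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not chroms:
            raise ValueError(f"no sequences found in {path}")
        return cls(name=name or path.stem, chromosomes=chroms)

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.chromosomes.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    def gc_fraction(self) -> float:
        gc = total = 0
        for seq in self.chromosomes.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq) - seq.count("N")
        return gc / total if total else 0.0
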