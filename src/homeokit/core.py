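"""Core domain objects shared by every stage of the toolkit.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
reader/writer in :mod:`homeokit.io` is the only place where the 1-based
inclusive convention of the file format appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among A/C/G/T characters."""
    if not seq:
        return 0.0
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class GeneModel:
    """A gene with its exon structure on a haplotype.

    ``exons`` are genomic intervals in increasing coordinate order; for a
    minus-strand gene the coding order is the reverse of the listed order.
    """

    gene_id: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    pseudo: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds(self, seq: str) -> str:
        """Spliced coding sequence in translation order."""
        parts = [seq[s:e] for s, e in self.exons]
        joined = "".join(parts)
        return revcomp(joined) if self.strand == "-" else joined


@dataclass
class TEAnnotation:
    """An annotated (LTR) transposable element on a haplotype."""

    te_id: str
    start: int
    end: int
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    tsd_length: int = 0
    family: str | None = None


@dataclass
class Haplotype:
    """A named haplotype sequence with species label and annotations."""

    name: str
    seq: str
    species: str | None = None
    genes: list[GeneModel] = field(default_factory=list)
    tes: list[TEAnnotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def gene(self, gene_id: str) -> GeneModel | None:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        return None

    def copy(self, **changes) -> "Haplotype":
        hap = replace(self)
        hap.genes = [replace(g, exons=list(g.exons)) for g in self.genes]
        hap.tes = [replace(t) for t in self.tes]
        for key, val in changes.items():
            setattr(hap, key, val)
        return hap
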