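"""Pairwise alignment containers.

An alignment is a list of collinear :class:`AlignmentBlock` objects, each a
run-length list of column operations:

========  =============================================
op        meaning
========  =============================================
``M``     match column (residue in both sequences, equal)
``X``     mismatch column (residue in both, different)
``A``     insertion in A  (gap in B)
``B``     insertion in B  (gap in A)
========  =============================================

``M``/``X`` columns are the *gapless* columns on which identity, SNP and MNP
statistics are computed; ``A``/``B`` columns are InDel columns contributing to
the gap fraction. Reverse-strand blocks keep B coordinates on the
reverse-complemented B axis (MAF semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

Op = tuple[str, int]

GAPLESS_OPS = frozenset("MX")
INDEL_OPS = frozenset("AB")


def merge_ops(ops: list[Op]) -> list[Op]:
    """Coalesce adjacent runs of the same op and drop zero-length runs."""
    out: list[Op] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


@dataclass
class AlignmentBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    ops: list[Op] = field(default_factory=list)
    strand: str = "+"

    def validate(self) -> None:
        la = sum(n for op, n in self.ops if op in ("M", "X", "A"))
        lb = sum(n for op, n in self.ops if op in ("M", "X", "B"))
        if la != self.a_end - self.a_start:
            raise ValueError(
                f"op lengths ({la}) do not cover A interval "
                f"[{self.a_start},{self.a_end})"
            )
        if lb != self.b_end - self.b_start:
            raise ValueError(
                f"op lengths ({lb}) do not cover B interval "
                f"[{self.b_start},{self.b_end})"
            )
        if any(n <= 0 for _, n in self.ops):
            raise ValueError("zero-length op")

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    def walk(self):
        """Yield ``(op, length, a_pos, b_pos)`` for every run."""
        a, b = self.a_start, self.b_start
        for op, n in self.ops:
            yield op, n, a, b
            if op in ("M", "X", "A"):
                a += n
            if op in ("M", "X", "B"):
                b += n


@dataclass
class PairwiseAlignment:
    name_a: str
    name_b: str
    len_a: int
    len_b: int
    blocks: list[AlignmentBlock] = field(default_factory=list)
    inversions: list[AlignmentBlock] = field(default_factory=list)

    def validate(self) -> None:
        prev_a = prev_b = -1
        for blk in self.blocks:
            blk.validate()
            if blk.a_start < prev_a or blk.b_start < prev_b:
                raise ValueError("blocks not monotonically increasing")
            prev_a, prev_b = blk.a_end, blk.b_end
        for blk in self.inversions:
            blk.validate()

    @property
    def n_columns(self) -> int:
        return sum(b.n_columns for b in self.blocks)

    def span_a(self) -> tuple[int, int]:
        """Min/max aligned coordinate on A (0-based half-open)."""
        if not self.blocks:
            return (0, 0)
        return (self.blocks[0].a_start, self.blocks[-1].a_end)

    def span_b(self) -> tuple[int, int]:
        if not self.blocks:
            return (0, 0)
        return (self.blocks[0].b_start, self.blocks[-1].b_end)

    def unaligned(self) -> dict[str, list[tuple[int, int]]]:
        """Flank intervals outside the aligned span on each sequence."""
        out: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
        sa, ea = self.span_a()
        sb, eb = self.span_b()
        if sa > 0:
            out["A"].append((0, sa))
        if ea < self.len_a:
            out["A"].append((ea, self.len_a))
        if sb > 0:
            out["B"].append((0, sb))
        if eb < self.len_b:
            out["B"].append((eb, self.len_b))
        return out

    def walk(self):
        """Yield ``(op, length, a_pos, b_pos)`` over all collinear blocks."""
        for blk in self.blocks:
            yield from blk.walk()

    def swapped(self) -> "PairwiseAlignment":
        """The same alignment with the roles of A and B exchanged."""
        swap = {"M": "M", "X": "X", "A": "B", "B": "A"}

        def _swap_block(blk: AlignmentBlock) -> AlignmentBlock:
            return AlignmentBlock(
                a_start=blk.b_start,
                a_end=blk.b_end,
                b_start=blk.a_start,
                b_end=blk.a_end,
                ops=[(swap[op], n) for op, n in blk.ops],
                strand=blk.strand,
            )

        return PairwiseAlignment(
            name_a=self.name_b,
            name_b=self.name_a,
            len_a=self.len_b,
            len_b=self.len_a,
            blocks=[_swap_block(b) for b in self.blocks],
            inversions=[_swap_block(b) for b in self.inversions],
        )
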