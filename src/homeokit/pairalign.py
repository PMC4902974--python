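"""Collinear pairwise alignment of long homologous haplotypes.

Strategy: exact k-mer anchor seeding (both strands, repeat-filtered), weighted
longest-increasing-subsequence chaining with gap penalties, then base-level
polishing of inter-anchor gaps. Gaps larger than ``max_fill`` on either side
are recorded as unaligned InDel runs without base-level alignment — they count
toward the gap fraction but contribute no gapless columns. Reverse-strand
anchor chains of sufficient extent are reported as candidate inversions in
separate blocks, leaving the collinear block list monotonic.

Designed for the >90 % identity regime of within-locus haplotype comparison
(~1–3 % SNP divergence, uneven multi-kb InDels), not for whole-genome
many-to-many alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np

from .alignment import AlignmentBlock, PairwiseAlignment, merge_ops
from .core import Haplotype, revcomp

DEFAULT_K = 15
DEFAULT_MAX_OCCURRENCE = 4
DEFAULT_MAX_FILL = 5000
MIN_INVERSION_LEN = 500
FILL_MIN_IDENTITY = 0.75  # match columns / all columns; below = non-homologous fill
FILL_MIN_CHECK_LEN = 30

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
# edlib cigar (query=A, target=B): '=' match, 'X' mismatch,
# 'I' base in A only (gap in B), 'D' base in B only (gap in A)
_EDLIB_TO_OP = {"=": "M", "X": "X", "I": "A", "D": "B"}


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match between the two sequences.

    ``b_start`` is a coordinate on the forward B axis for ``+`` anchors and on
    the reverse-complemented B axis for ``-`` anchors.
    """

    a_start: int
    b_start: int
    length: int
    strand: str = "+"

    @property
    def a_end(self) -> int:
        return self.a_start + self.length

    @property
    def b_end(self) -> int:
        return self.b_start + self.length


@dataclass
class Chain:
    primary: list[Anchor] = field(default_factory=list)
    inversion_chains: list[list[Anchor]] = field(default_factory=list)
    empty: bool = False


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _merge_diagonal_hits(hits: list[tuple[int, int]], k: int, strand: str) -> list[Anchor]:
    """Merge k-mer hits on common diagonals into maximal exact matches."""
    anchors = []
    hits.sort(key=lambda h: (h[0] - h[1], h[0]))
    run_start = None
    prev = None
    for i, j in hits:
        if (
            prev is not None
            and i - j == prev[0] - prev[1]
            and i <= prev[0] + 1
        ):
            prev = (i, j)
            continue
        if run_start is not None:
            anchors.append(
                Anchor(run_start[0], run_start[1], prev[0] - run_start[0] + k, strand)
            )
        run_start = (i, j)
        prev = (i, j)
    if run_start is not None:
        anchors.append(
            Anchor(run_start[0], run_start[1], prev[0] - run_start[0] + k, strand)
        )
    return anchors


def find_anchors(
    seq_a: str,
    seq_b: str,
    k: int = DEFAULT_K,
    max_occurrence: int = DEFAULT_MAX_OCCURRENCE,
) -> list[Anchor]:
    """All maximal exact matches of length >= k with repeat filtering.

    K-mers occurring more than ``max_occurrence`` times in either sequence are
    skipped. Output order is deterministic: by strand, then A position.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if min(len(seq_a), len(seq_b)) < k:
        return []
    counts_a = _kmer_counts(seq_a, k)
    index_a: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        if counts_a[kmer] <= max_occurrence:
            index_a.setdefault(kmer, []).append(i)

    anchors: list[Anchor] = []
    for strand, sb in (("+", seq_b), ("-", revcomp(seq_b))):
        counts_b = _kmer_counts(sb, k)
        hits = []
        for j in range(len(sb) - k + 1):
            kmer = sb[j : j + k]
            if counts_b[kmer] > max_occurrence:
                continue
            for i in index_a.get(kmer, ()):
                hits.append((i, j))
        anchors.extend(_merge_diagonal_hits(hits, k, strand))
    anchors.sort(key=lambda a: (a.strand, a.a_start, a.b_start))
    return anchors


def _chain_lis(anchors: list[Anchor], gap_open: float = 10.0, drift: float = 0.05) -> list[Anchor]:
    """Highest-scoring collinear chain by weighted LIS with gap penalties.

    Score = anchored bases − gap-open penalties − drift × diagonal shift.
    Ties break toward the leftmost A coordinate (stable argmax over the sorted
    anchor order).
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a.a_start, a.b_start))
    n = len(anchors)
    a_start = np.array([a.a_start for a in anchors], dtype=np.float64)
    b_start = np.array([a.b_start for a in anchors], dtype=np.float64)
    a_end = np.array([a.a_end for a in anchors], dtype=np.float64)
    b_end = np.array([a.b_end for a in anchors], dtype=np.float64)
    length = np.array([a.length for a in anchors], dtype=np.float64)
    score = length.copy()
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        ok = (a_start[:i] < a_start[i]) & (b_start[:i] < b_start[i])
        if not ok.any():
            continue
        ga = a_start[i] - a_end[:i]
        gb = b_start[i] - b_end[:i]
        pen = gap_open * ((ga > 0) | (gb > 0)) + drift * np.abs(ga - gb)
        cand = np.where(ok, score[:i] - pen, -np.inf)
        j = int(np.argmax(cand))
        if cand[j] > 0:
            score[i] += cand[j]
            parent[i] = j
    best = int(np.argmax(score))
    chain = []
    while best >= 0:
        chain.append(anchors[best])
        best = parent[best]
    chain.reverse()
    return chain


def chain_anchors(
    anchors: list[Anchor],
    min_inversion_len: int = MIN_INVERSION_LEN,
) -> Chain:
    """Chain anchors into a primary collinear chain plus candidate inversions.

    The primary chain is selected on the strand with the higher chained score;
    leftover opposite-strand anchors not overlapping the primary chain on A
    are re-chained and reported as candidate inversions when their chained
    anchor extent reaches ``min_inversion_len``.
    """
    plus = [a for a in anchors if a.strand == "+"]
    minus = [a for a in anchors if a.strand == "-"]
    chain_plus = _chain_lis(plus)
    chain_minus = _chain_lis(minus)
    w_plus = sum(a.length for a in chain_plus)
    w_minus = sum(a.length for a in chain_minus)
    if w_plus == 0 and w_minus == 0:
        return Chain(empty=True)
    if w_plus >= w_minus:
        primary, leftover = chain_plus, minus
    else:
        primary, leftover = chain_minus, plus
    covered = [(a.a_start, a.a_end) for a in primary]

    def _overlaps_primary(anchor: Anchor) -> bool:
        return any(anchor.a_start < e and anchor.a_end > s for s, e in covered)

    inv_candidates = [a for a in leftover if not _overlaps_primary(a)]
    inversion_chains = []
    while inv_candidates:
        chain = _chain_lis(inv_candidates)
        if not chain:
            break
        extent = chain[-1].a_end - chain[0].a_start
        if extent >= min_inversion_len:
            inversion_chains.append(chain)
        span = (chain[0].a_start, chain[-1].a_end)
        inv_candidates = [
            a for a in inv_candidates
            if not (a.a_start < span[1] and a.a_end > span[0])
        ]
        if extent < min_inversion_len:
            break
    inversion_chains.sort(key=lambda c: c[0].a_start)
    return Chain(primary=primary, inversion_chains=inversion_chains)


def _trim_chain(chain: list[Anchor]) -> list[Anchor]:
    """Remove overlaps between consecutive anchors (keep earlier anchor)."""
    out: list[Anchor] = []
    for a in chain:
        if out:
            prev = out[-1]
            cut = max(prev.a_end - a.a_start, prev.b_end - a.b_start, 0)
            if cut >= a.length:
                continue
            if cut > 0:
                a = Anchor(a.a_start + cut, a.b_start + cut, a.length - cut, a.strand)
        out.append(a)
    return out


def _edlib_ops(seg_a: str, seg_b: str) -> list[tuple[str, int]]:
    res = edlib.align(seg_a, seg_b, mode="NW", task="path")
    ops = []
    for num, code in _CIGAR_RE.findall(res["cigar"]):
        ops.append((_EDLIB_TO_OP[code], int(num)))
    return ops


def _fill_identity(ops: list[tuple[str, int]]) -> float:
    """Match columns over *all* columns — gap columns count against identity,
    so unrelated sequences forced together by NW (mostly gaps + scattered
    matches) score low while homologous fills score near 1."""
    m = sum(n for op, n in ops if op == "M")
    total = sum(n for _, n in ops)
    return m / total if total else 0.0


def _trim_fill(ops: list[tuple[str, int]], window: int = 30) -> list[tuple[str, int]]:
    """Keep only the high-identity head and tail of a rejected gap fill.

    The fill is scanned column-wise from each end; once a sliding window drops
    below ``FILL_MIN_IDENTITY`` the remainder is declared non-homologous and
    re-emitted as unaligned insA/insB runs. Handles the case of two unrelated
    insertions sharing an inter-anchor gap, where the anchor boundaries stop
    short of the true insertion junctions.
    """
    cols: list[str] = []
    for op, n in ops:
        cols.extend(op * n)

    def _head_len(seq: list[str]) -> int:
        bad = 0
        kept = 0
        recent: list[str] = []
        for c in seq:
            recent.append(c)
            if len(recent) > window:
                recent.pop(0)
            bad = sum(1 for r in recent if r != "M")
            if len(recent) == window and bad > window * (1.0 - FILL_MIN_IDENTITY):
                break
            kept += 1
        # back off to the last match column to avoid keeping a mismatch tail
        while kept > 0 and seq[kept - 1] != "M":
            kept -= 1
        return kept

    head = _head_len(cols)
    tail = _head_len(cols[::-1])
    if head + tail >= len(cols):
        return merge_ops([(c, 1) for c in cols])
    middle = cols[head : len(cols) - tail]
    ga = sum(1 for c in middle if c in ("M", "X", "A"))
    gb = sum(1 for c in middle if c in ("M", "X", "B"))
    out = [(c, 1) for c in cols[:head]]
    out.append(("A", ga))
    out.append(("B", gb))
    out.extend((c, 1) for c in cols[len(cols) - tail :])
    return merge_ops(out)


def _polish_chain(
    seq_a: str, seq_b: str, chain: list[Anchor], max_fill: int, strand: str
) -> AlignmentBlock:
    chain = _trim_chain(chain)
    ops: list[tuple[str, int]] = []
    prev: Anchor | None = None
    for anchor in chain:
        if prev is not None:
            ga = anchor.a_start - prev.a_end
            gb = anchor.b_start - prev.b_end
            if ga > 0 and gb > 0:
                if max(ga, gb) <= max_fill:
                    fill = _edlib_ops(
                        seq_a[prev.a_end : anchor.a_start],
                        seq_b[prev.b_end : anchor.b_start],
                    )
                    if (
                        min(ga, gb) >= FILL_MIN_CHECK_LEN
                        and _fill_identity(fill) < FILL_MIN_IDENTITY
                    ):
                        # two unrelated insertions share this gap: keep only
                        # the homologous head/tail, unalign the core
                        fill = _trim_fill(fill)
                    ops.extend(fill)
                else:
                    ops.append(("A", ga))
                    ops.append(("B", gb))
            elif ga > 0:
                ops.append(("A", ga))
            elif gb > 0:
                ops.append(("B", gb))
        ops.append(("M", anchor.length))
        prev = anchor
    blk = AlignmentBlock(
        a_start=chain[0].a_start,
        a_end=chain[-1].a_end,
        b_start=chain[0].b_start,
        b_end=chain[-1].b_end,
        ops=merge_ops(ops),
        strand=strand,
    )
    blk.validate()
    return blk


def polish_alignment(
    seq_a: str,
    seq_b: str,
    chain: Chain,
    max_fill: int = DEFAULT_MAX_FILL,
    name_a: str = "A",
    name_b: str = "B",
) -> PairwiseAlignment:
    """Fill inter-anchor gaps and emit the final alignment.

    Gaps <= ``max_fill`` on both sides are aligned at base level with edlib's
    optimal global alignment; larger gaps become unaligned InDel runs.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = PairwiseAlignment(
        name_a=name_a, name_b=name_b, len_a=len(seq_a), len_b=len(seq_b)
    )
    if chain.empty or not chain.primary:
        return aln
    primary_strand = chain.primary[0].strand
    sb = seq_b if primary_strand == "+" else revcomp(seq_b)
    aln.blocks = [_polish_chain(seq_a, sb, chain.primary, max_fill, primary_strand)]
    inv_strand = "-" if primary_strand == "+" else "+"
    sb_inv = seq_b if inv_strand == "+" else revcomp(seq_b)
    for inv in chain.inversion_chains:
        aln.inversions.append(_polish_chain(seq_a, sb_inv, inv, max_fill, inv_strand))
    aln.validate()
    return aln


def align(
    hap_a: Haplotype | str,
    hap_b: Haplotype | str,
    k: int = DEFAULT_K,
    max_occurrence: int = DEFAULT_MAX_OCCURRENCE,
    max_fill: int = DEFAULT_MAX_FILL,
    min_inversion_len: int = MIN_INVERSION_LEN,
) -> PairwiseAlignment:
    """Anchor, chain and polish in one call."""
    seq_a = hap_a.seq if isinstance(hap_a, Haplotype) else hap_a
    seq_b = hap_b.seq if isinstance(hap_b, Haplotype) else hap_b
    name_a = hap_a.name if isinstance(hap_a, Haplotype) else "A"
    name_b = hap_b.name if isinstance(hap_b, Haplotype) else "B"
    anchors = find_anchors(seq_a, seq_b, k=k, max_occurrence=max_occurrence)
    chain = chain_anchors(anchors, min_inversion_len=min_inversion_len)
    return polish_alignment(
        seq_a, seq_b, chain, max_fill=max_fill, name_a=name_a, name_b=name_b
    )
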