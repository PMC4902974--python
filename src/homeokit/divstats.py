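"""Pairwise divergence statistics on gapless alignment columns.

Definitions (applied uniformly; the field reports SNP and MNP percentages
without a formal definition, so the package fixes one):

* *gapless region*: maximal run of match/mismatch columns (no InDel ops).
* *SNP*: an isolated mismatch column — both neighbours within its gapless
  region are matches, or the column sits at a region edge.
* *MNP*: a maximal run of >= 2 contiguous mismatch columns, counted once as an
  event; its column count enters ``mnp_pct``.
* *gap fraction*: InDel columns / all columns within the aligned span
  (unaligned flanks excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import PairwiseAlignment
from .core import GeneModel

WINDOW_SIZES = (100, 250, 500, 1000)
LARGE_INDEL_THRESHOLD = 100
SEGMENTAL_INDEL_THRESHOLD = 1000


@dataclass
class VariantSummary:
    name_a: str = "A"
    name_b: str = "B"
    gapless_length: int = 0
    matches: int = 0
    snp_count: int = 0
    mnp_event_count: int = 0
    mnp_columns: int = 0
    indel_columns: int = 0
    total_columns: int = 0
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)
    empty: bool = False

    @property
    def mismatches(self) -> int:
        return self.gapless_length - self.matches

    @property
    def identity(self) -> float:
        return self.matches / self.gapless_length if self.gapless_length else 0.0

    @property
    def snp_pct(self) -> float:
        return 100.0 * self.snp_count / self.gapless_length if self.gapless_length else 0.0

    @property
    def mnp_pct(self) -> float:
        return 100.0 * self.mnp_columns / self.gapless_length if self.gapless_length else 0.0

    @property
    def gap_fraction(self) -> float:
        return self.indel_columns / self.total_columns if self.total_columns else 0.0


@dataclass
class IndelEvent:
    side: str  # "A-has-insertion" | "B-has-insertion"
    pos_a: int
    pos_b: int
    length: int
    large: bool = False
    segmental: bool = False
    context: str | None = None


@dataclass
class WindowZeroStat:
    window_size: int
    n_windows: int
    sd_of_counts: float
    pct_zero_snp_windows: float


def gapless_regions(aln: PairwiseAlignment) -> list[tuple[int, int]]:
    """Maximal runs of match/mismatch columns, as column-index ranges.

    Column indices count all columns of the collinear blocks in order; the
    concatenated length of the returned ranges is the Table-3-style "aligned
    sequence" length.
    """
    regions = []
    col = 0
    run_start = None
    for op, n, _a, _b in aln.walk():
        if op in ("M", "X"):
            if run_start is None:
                run_start = col
        else:
            if run_start is not None:
                regions.append((run_start, col))
                run_start = None
        col += n
    if run_start is not None:
        regions.append((run_start, col))
    return regions


def _snp_flags(aln: PairwiseAlignment) -> np.ndarray:
    """Per-gapless-column SNP indicator, in gapless column order.

    Mismatch runs of length 1 are SNPs; runs >= 2 are MNP columns (flag 0).
    """
    flags: list[np.ndarray] = []
    for op, n, _a, _b in aln.walk():
        if op == "M":
            flags.append(np.zeros(n, dtype=bool))
        elif op == "X":
            block = np.zeros(n, dtype=bool)
            if n == 1:
                block[0] = True
            flags.append(block)
    if not flags:
        return np.zeros(0, dtype=bool)
    return np.concatenate(flags)


def pairwise_variant_summary(aln: PairwiseAlignment) -> VariantSummary:
    """Table-3-style record: identity, SNP %, MNP %, gap fraction, spans."""
    summary = VariantSummary(name_a=aln.name_a, name_b=aln.name_b)
    matches = mism = indel = total = 0
    snp = mnp_events = mnp_cols = 0
    for op, n, _a, _b in aln.walk():
        total += n
        if op == "M":
            matches += n
        elif op == "X":
            mism += n
            if n == 1:
                snp += 1
            else:
                mnp_events += 1
                mnp_cols += n
        else:
            indel += n
    summary.gapless_length = matches + mism
    summary.matches = matches
    summary.snp_count = snp
    summary.mnp_event_count = mnp_events
    summary.mnp_columns = mnp_cols
    summary.indel_columns = indel
    summary.total_columns = total
    summary.span_a = aln.span_a()
    summary.span_b = aln.span_b()
    if summary.gapless_length == 0:
        summary.empty = True
    return summary


def _context(pos: int, genes: list[GeneModel] | None) -> str | None:
    if genes is None:
        return None
    genes = sorted(genes, key=lambda g: g.start)
    left = None
    for g in genes:
        if g.start <= pos < g.end:
            return f"genic:{g.gene_id}"
        if g.end <= pos:
            left = g.gene_id
        if g.start > pos:
            return f"intergenic:{left or 'start'}-{g.gene_id}"
    return f"intergenic:{left or 'start'}-end"


def indel_inventory(
    aln: PairwiseAlignment,
    genes_a: list[GeneModel] | None = None,
    genes_b: list[GeneModel] | None = None,
    large_threshold: int = LARGE_INDEL_THRESHOLD,
) -> list[IndelEvent]:
    """One event per maximal InDel run, with genic/intergenic context.

    Context is resolved on the haplotype carrying the inserted sequence.
    """
    events = []
    for op, n, a, b in aln.walk():
        if op == "A":
            events.append(
                IndelEvent(
                    side="A-has-insertion",
                    pos_a=a,
                    pos_b=b,
                    length=n,
                    large=n >= large_threshold,
                    segmental=n >= SEGMENTAL_INDEL_THRESHOLD,
                    context=_context(a, genes_a),
                )
            )
        elif op == "B":
            events.append(
                IndelEvent(
                    side="B-has-insertion",
                    pos_a=a,
                    pos_b=b,
                    length=n,
                    large=n >= large_threshold,
                    segmental=n >= SEGMENTAL_INDEL_THRESHOLD,
                    context=_context(b, genes_b),
                )
            )
    return events


def gap_fraction_report(aln: PairwiseAlignment) -> float:
    """InDel columns / total columns within the aligned span."""
    return pairwise_variant_summary(aln).gap_fraction


def window_zero_snp(
    aln: PairwiseAlignment, sizes: tuple[int, ...] = WINDOW_SIZES
) -> list[WindowZeroStat]:
    """Table-4-style fragment statistics on concatenated gapless columns.

    Gapless columns are concatenated in alignment order and tiled per window
    size; the trailing partial window is discarded. Reports the sample SD of
    per-window SNP counts and the percentage of zero-SNP windows.
    """
    flags = _snp_flags(aln)
    return window_zero_from_flags(flags, sizes)


def window_zero_from_flags(
    flags: np.ndarray, sizes: tuple[int, ...] = WINDOW_SIZES
) -> list[WindowZeroStat]:
    out = []
    for size in sizes:
        n_win = len(flags) // size
        if n_win == 0:
            warnings.warn(f"gapless length {len(flags)} < window size {size}; skipped")
            continue
        counts = flags[: n_win * size].reshape(n_win, size).sum(axis=1)
        sd = float(np.std(counts, ddof=1)) if n_win > 1 else 0.0
        pct_zero = 100.0 * float(np.mean(counts == 0))
        out.append(WindowZeroStat(size, n_win, sd, pct_zero))
    return out


def pooled_window_zero_snp(
    alns: list[PairwiseAlignment], sizes: tuple[int, ...] = WINDOW_SIZES
) -> list[WindowZeroStat]:
    """Pool per-pair windows (each pair tiled separately) across alignments."""
    out = []
    for size in sizes:
        counts = []
        for aln in alns:
            flags = _snp_flags(aln)
            n_win = len(flags) // size
            if n_win:
                counts.append(flags[: n_win * size].reshape(n_win, size).sum(axis=1))
        if not counts:
            warnings.warn(f"no alignment long enough for window size {size}")
            continue
        allc = np.concatenate(counts)
        sd = float(np.std(allc, ddof=1)) if len(allc) > 1 else 0.0
        out.append(WindowZeroStat(size, len(allc), sd, 100.0 * float(np.mean(allc == 0))))
    return out


@dataclass
class PooledClassSummary:
    label: str
    n_pairs: int
    aligned_bp: int
    snp_count: int

    @property
    def snp_pct(self) -> float:
        return 100.0 * self.snp_count / self.aligned_bp if self.aligned_bp else 0.0


def pooled_species_summary(
    grouped: dict[str, list[VariantSummary]]
) -> list[PooledClassSummary]:
    """Pool pair summaries per comparison class (within-A/within-B/between)."""
    out = []
    for label, summaries in grouped.items():
        if not summaries:
            warnings.warn(f"comparison class {label!r} empty; omitted")
            continue
        out.append(
            PooledClassSummary(
                label=label,
                n_pairs=len(summaries),
                aligned_bp=sum(s.gapless_length for s in summaries),
                snp_count=sum(s.snp_count for s in summaries),
            )
        )
    return out
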