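"""LTR retrotransposon structural validation and insertion dating.

An intact LTR element carries two long terminal repeats that were identical
at insertion and a short (~5 bp) target-site duplication in the flanking host
sequence. The K2P divergence k between the two LTRs dates the insertion as
T = k / (2 r) with a neutral rate r (default 1.3e-8 substitutions/site/year).

This module *dates* annotated elements (from GFF3 or simulator truth); de novo
LTR structure discovery is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner

from .core import TEAnnotation
from .molevol import DEFAULT_RATE, K2PDistance, divergence_time, k2p_distance

MIN_LTR_IDENTITY = 0.60
MAX_TSD_MISMATCHES = 1


def _ltr_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.3
    return aligner


def _aligned_columns(seq5: str, seq3: str) -> tuple[str, str, float]:
    """Globally align the two LTRs; return gap-free column strings and identity."""
    aln = _ltr_aligner().align(seq5, seq3)[0]
    row5, row3 = str(aln[0]), str(aln[1])
    cols5, cols3 = [], []
    matches = total = 0
    for c5, c3 in zip(row5, row3):
        total += 1
        if c5 != "-" and c3 != "-":
            cols5.append(c5)
            cols3.append(c3)
            if c5 == c3:
                matches += 1
    identity = matches / total if total else 0.0
    return "".join(cols5), "".join(cols3), identity


@dataclass
class LTRValidation:
    identity: float
    tsd_intact: bool
    tsd_mismatches: int | None
    ok: bool
    flags: list[str]


@dataclass
class InsertionAge:
    distance: K2PDistance
    T: float | None  # years
    tsd_intact: bool
    saturated: bool = False


def _check_bounds(seq: str, ann: TEAnnotation) -> None:
    if ann.ltr5 is None or ann.ltr3 is None:
        raise ValueError(f"{ann.te_id}: both LTR intervals required")
    for label, (s, e) in (("element", (ann.start, ann.end)), ("ltr5", ann.ltr5), ("ltr3", ann.ltr3)):
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"{ann.te_id}: {label} interval [{s},{e}) out of bounds")
    if not (ann.start <= ann.ltr5[0] and ann.ltr5[1] <= ann.ltr3[0] and ann.ltr3[1] <= ann.end):
        raise ValueError(f"{ann.te_id}: LTRs must lie inside the element, 5' before 3'")


def validate_ltr(seq: str, ann: TEAnnotation) -> LTRValidation:
    """Check LTR-pair identity and TSD integrity (non-fatal flags)."""
    _check_bounds(seq, ann)
    seq = seq.upper()
    ltr5 = seq[ann.ltr5[0] : ann.ltr5[1]]
    ltr3 = seq[ann.ltr3[0] : ann.ltr3[1]]
    _c5, _c3, identity = _aligned_columns(ltr5, ltr3)
    flags = []
    if identity < MIN_LTR_IDENTITY:
        flags.append("ltr_identity_below_threshold")
    tsd_mismatches: int | None = None
    tsd_intact = False
    if ann.tsd_length > 0:
        left = seq[ann.start - ann.tsd_length : ann.start]
        right = seq[ann.end : ann.end + ann.tsd_length]
        if len(left) == len(right) == ann.tsd_length:
            tsd_mismatches = sum(1 for a, b in zip(left, right) if a != b)
            tsd_intact = tsd_mismatches <= MAX_TSD_MISMATCHES
        else:
            flags.append("tsd_out_of_bounds")
        if not tsd_intact and "tsd_out_of_bounds" not in flags:
            flags.append("tsd_mismatch")
    else:
        flags.append("no_tsd_annotation")
    return LTRValidation(
        identity=identity,
        tsd_intact=tsd_intact,
        tsd_mismatches=tsd_mismatches,
        ok=not flags,
        flags=flags,
    )


def date_insertion(
    seq: str,
    ann: TEAnnotation,
    rate_r: float = DEFAULT_RATE,
    force: bool = False,
) -> InsertionAge:
    """Date one annotated element from its LTR-pair K2P divergence.

    K2P is computed over the ungapped columns of the global LTR alignment;
    T = k/(2 r). Saturated divergence yields an undefined age with a flag.
    """
    report = validate_ltr(seq, ann)
    if "ltr_identity_below_threshold" in report.flags and not force:
        raise ValueError(
            f"{ann.te_id}: LTR pair identity {report.identity:.2f} below "
            f"{MIN_LTR_IDENTITY}; pass force=True to date anyway"
        )
    seq = seq.upper()
    cols5, cols3, _ = _aligned_columns(
        seq[ann.ltr5[0] : ann.ltr5[1]], seq[ann.ltr3[0] : ann.ltr3[1]]
    )
    dist = k2p_distance(cols5, cols3)
    T = divergence_time(dist.k, rate_r)
    return InsertionAge(
        distance=dist, T=T, tsd_intact=report.tsd_intact, saturated=dist.saturated
    )


def date_all(
    seq: str, annotations: list[TEAnnotation], rate_r: float = DEFAULT_RATE
) -> list[tuple[TEAnnotation, InsertionAge | None]]:
    """Date every annotated element with both LTRs; undatable ones yield None."""
    out = []
    for ann in annotations:
        if ann.ltr5 is None or ann.ltr3 is None:
            out.append((ann, None))
            continue
        try:
            out.append((ann, date_insertion(seq, ann, rate_r)))
        except ValueError:
            out.append((ann, None))
    return out
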