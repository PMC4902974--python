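"""Species-origin classification of hybrid haplotypes.

Three evidence channels:

1. *locus votes* — per-gene allele grouping against the two progenitor
   panels (plus species-specific gene presence/absence);
2. *species-diagnostic markers* — segmental InDels present in every
   haplotype of one species and absent from the other; a marker is itself a
   locus-positioned feature, so its vote is slotted into the ordered vote
   sequence after its left flanking gene;
3. *panel identity* — mean gapless identity to each panel, always reported
   but used only as a tiebreak (raw identity can mislead: a haplotype may be
   globally more similar to the wrong species' panel while every informative
   locus groups it with the right one).

A single vote switch along gene order yields a *recombinant* verdict with the
breakpoint bracketed by the flanking loci; two or more switches yield
*unresolved*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import divstats, molevol, pairalign
from .alignment import PairwiseAlignment
from .core import Haplotype

MARKER_MIN_LEN = 500
MARKER_PRESENT_COVERAGE = 0.8
MARKER_ABSENT_COVERAGE = 0.2
MARKER_MERGE_GAP = 100


class AlignmentStore:
    """Cache of pairwise alignments keyed by haplotype name pair."""

    def __init__(self, aligner=None, **align_kwargs):
        self._aligner = aligner or pairalign.align
        self._kwargs = align_kwargs
        self._cache: dict[tuple[str, str], PairwiseAlignment] = {}

    def get(self, hap_a: Haplotype, hap_b: Haplotype) -> PairwiseAlignment:
        key = (hap_a.name, hap_b.name)
        if key in self._cache:
            return self._cache[key]
        rkey = (hap_b.name, hap_a.name)
        if rkey in self._cache:
            aln = self._cache[rkey].swapped()
        else:
            aln = self._aligner(hap_a, hap_b, **self._kwargs)
        self._cache[key] = aln
        return aln


@dataclass
class SpeciesPanel:
    species: str
    members: list[Haplotype]

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty panel")

    @property
    def reference(self) -> Haplotype:
        return max(self.members, key=lambda h: (len(h.seq), h.name))


@dataclass
class SpeciesMarker:
    species: str  # the species that HAS the segment
    reference: str  # panel-A reference haplotype the interval lives on
    start: int
    end: int
    flanking_genes: tuple[str | None, str | None] = (None, None)
    low_confidence: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _coverage(aln: PairwiseAlignment, ref_len: int) -> np.ndarray:
    cov = np.zeros(ref_len, dtype=bool)
    for op, n, a, _b in aln.walk():
        if op in ("M", "X"):
            cov[a : a + n] = True
    return cov


def _runs(mask: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > merge_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _flanks(pos_start: int, pos_end: int, ref: Haplotype) -> tuple[str | None, str | None]:
    left = right = None
    for g in sorted(ref.genes, key=lambda g: g.start):
        if g.end <= pos_start:
            left = g.gene_id
        if g.start >= pos_end and right is None:
            right = g.gene_id
    return left, right


def discover_species_markers(
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    store: AlignmentStore | None = None,
    min_len: int = MARKER_MIN_LEN,
) -> list[SpeciesMarker]:
    """Species-diagnostic intervals on the panel-A reference.

    A marker is a maximal reference interval >= ``min_len`` aligned (>= 80 %
    coverage) in every A member and essentially unaligned (< 20 %) in every B
    member — a strict all/none presence pattern. Single-member panels yield
    low-confidence markers.
    """
    store = store or AlignmentStore()
    ref = panel_a.reference
    ref_len = len(ref.seq)
    cov_a = [
        _coverage(store.get(ref, m), ref_len)
        for m in panel_a.members
        if m.name != ref.name
    ]
    cov_b = [_coverage(store.get(ref, m), ref_len) for m in panel_b.members]
    all_a = np.logical_and.reduce(cov_a) if cov_a else np.ones(ref_len, dtype=bool)
    any_b = np.logical_or.reduce(cov_b) if cov_b else np.zeros(ref_len, dtype=bool)
    low_confidence = len(panel_a.members) < 2 or len(panel_b.members) < 2
    markers = []
    for start, end in _runs(all_a & ~any_b, MARKER_MERGE_GAP):
        if end - start < min_len:
            continue
        span = slice(start, end)
        if any(c[span].mean() < MARKER_PRESENT_COVERAGE for c in cov_a):
            continue
        if any(c[span].mean() > MARKER_ABSENT_COVERAGE for c in cov_b):
            continue
        markers.append(
            SpeciesMarker(
                species=panel_a.species,
                reference=ref.name,
                start=start,
                end=end,
                flanking_genes=_flanks(start, end, ref),
                low_confidence=low_confidence,
            )
        )
    return markers


@dataclass
class MarkerVote:
    marker: str  # "<reference>:<start>-<end>"
    vote: str | None  # species label, or None when coverage is ambiguous
    flanking_genes: tuple[str | None, str | None] = (None, None)


def marker_votes(
    query: Haplotype,
    markers: list[SpeciesMarker],
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    store: AlignmentStore | None = None,
) -> list[MarkerVote]:
    """Per-marker vote: the species whose presence pattern the query matches."""
    store = store or AlignmentStore()
    ref = panel_a.reference
    aln = store.get(ref, query)
    cov = _coverage(aln, len(ref.seq))
    votes = []
    for m in markers:
        frac = float(cov[m.start : m.end].mean())
        if frac >= MARKER_PRESENT_COVERAGE:
            vote = m.species
        elif frac <= MARKER_ABSENT_COVERAGE:
            vote = panel_b.species if m.species == panel_a.species else panel_a.species
        else:
            vote = None
        votes.append(
            MarkerVote(
                marker=f"{m.reference}:{m.start}-{m.end}",
                vote=vote,
                flanking_genes=m.flanking_genes,
            )
        )
    return votes


def identity_vote(
    query: Haplotype,
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    store: AlignmentStore | None = None,
) -> tuple[float, float]:
    """Mean gapless identity (percent) of the query to each panel."""
    store = store or AlignmentStore()

    def _mean(panel: SpeciesPanel) -> float:
        vals = []
        for member in panel.members:
            summary = divstats.pairwise_variant_summary(store.get(query, member))
            if summary.empty:
                warnings.warn(f"no gapless alignment {query.name}/{member.name}; skipped")
                continue
            vals.append(summary.identity)
        return 100.0 * float(np.mean(vals)) if vals else float("nan")

    return _mean(panel_a), _mean(panel_b)


@dataclass
class LocusVote:
    locus: str
    vote: str  # species label | "shared" | "absent"
    present_in: list[str] = field(default_factory=list)
    groups: list[list[str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _clean_cds(hap: Haplotype, gene_id: str) -> str | None:
    g = hap.gene(gene_id)
    if g is None:
        return None
    cds = g.cds(hap.seq)
    if len(cds) < 30 or len(cds) % 3 != 0:
        return None
    return cds


def locus_votes(
    query: Haplotype,
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    rate_r: float = molevol.DEFAULT_RATE,
    metric: str = "k2p",
) -> list[LocusVote]:
    """Per-locus species vote from allele-grouping co-membership, in gene order.

    The vote is the species whose panel alleles share a group with the query
    allele; "shared" when groups mix species or grouping is uninformative,
    "absent" when the query lacks the locus. Two safeguards keep the channel
    conservative: a clique vote only stands when the query's nearest panel
    allele sits inside the query's group, and a locus carried by the panels of
    exactly one species votes by presence/absence (species-specific gene gain
    or loss) rather than by grouping.

    Grouping times default to full coding-region K2P divergence rather than
    Ks: four times as many informative sites, hence stabler per-locus times
    (the divergence-time clock is configurable via ``metric``).
    """
    species_of = {}
    for panel in (panel_a, panel_b):
        for m in panel.members:
            species_of[m.name] = panel.species
    gene_order = [g.gene_id for g in sorted(panel_a.reference.genes, key=lambda g: g.start)]
    for g in sorted(panel_b.reference.genes, key=lambda g: g.start):
        if g.gene_id not in gene_order:
            gene_order.append(g.gene_id)
    votes = []
    for gid in gene_order:
        alleles = {}
        present_in = set()
        for panel in (panel_a, panel_b):
            for m in panel.members:
                cds = _clean_cds(m, gid)
                if cds is not None:
                    alleles[m.name] = cds
                    present_in.add(panel.species)
        q_cds = _clean_cds(query, gid)
        if q_cds is None:
            votes.append(LocusVote(locus=gid, vote="absent", present_in=sorted(present_in)))
            continue
        if len(present_in) == 1:
            # species-specific locus: presence itself is the evidence
            votes.append(
                LocusVote(
                    locus=gid,
                    vote=next(iter(present_in)),
                    present_in=sorted(present_in),
                    flags=["presence_channel"],
                )
            )
            continue
        alleles[query.name] = q_cds
        if len(alleles) < 4:
            votes.append(
                LocusVote(
                    locus=gid,
                    vote="shared",
                    present_in=sorted(present_in),
                    flags=["uninformative_locus"],
                )
            )
            continue
        try:
            grouping = molevol.allele_grouping(
                alleles, rate_r=rate_r, locus=gid, metric=metric
            )
        except ValueError as exc:
            votes.append(
                LocusVote(locus=gid, vote="shared", present_in=sorted(present_in),
                          flags=[f"grouping_failed:{exc}"])
            )
            continue
        q_groups = [g for g in grouping.groups if query.name in g]
        if not q_groups:
            votes.append(
                LocusVote(
                    locus=gid,
                    vote="shared",
                    present_in=sorted(present_in),
                    groups=grouping.groups,
                    flags=["ungrouped_query"],
                )
            )
            continue
        q_times = {
            (set(pair) - {query.name}).pop(): t
            for pair, t in grouping.times.items()
            if query.name in pair and t is not None
        }
        nearest = min(q_times, key=q_times.get) if q_times else None
        mates = {species_of[m] for g in q_groups for m in g if m in species_of}
        in_group = {m for g in q_groups for m in g}
        if len(mates) == 1 and (nearest is None or nearest in in_group):
            vote = mates.pop()
        else:
            vote = "shared"
        votes.append(
            LocusVote(
                locus=gid, vote=vote, present_in=sorted(present_in), groups=grouping.groups
            )
        )
    return votes


@dataclass
class OriginCall:
    haplotype: str
    verdict: str  # species label | "recombinant" | "unresolved"
    marker_votes: list[MarkerVote]
    identity_to_a: float
    identity_to_b: float
    locus_votes: list[LocusVote]
    breakpoint_loci: tuple[str, str] | None = None
    breakpoint_interval: tuple[int, int] | None = None
    notes: list[str] = field(default_factory=list)


def classify_origin(
    query: Haplotype,
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    marker_vote_list: list[MarkerVote],
    identities: tuple[float, float],
    votes: list[LocusVote],
) -> OriginCall:
    """Combine the three evidence channels into a verdict.

    Locus votes and diagnostic-marker votes are merged into one sequence in
    gene order — a marker is itself a locus-positioned InDel, slotted in after
    its left flanking gene. One species across the sequence => that species;
    exactly one switch => recombinant with the breakpoint bracketed by the
    nearest query-annotated loci; more switches => unresolved. Identity is a
    last-resort tiebreak and is always reported.
    """
    label_a, label_b = panel_a.species, panel_b.species
    # evidence entries: (display id, species vote, left-anchor gene, right-anchor gene)
    effective: list[tuple[str, str, str | None, str | None]] = []
    by_left_flank: dict[str | None, list[MarkerVote]] = {}
    for mv in marker_vote_list:
        if mv.vote in (label_a, label_b):
            by_left_flank.setdefault(mv.flanking_genes[0], []).append(mv)

    def _add_markers(after_locus: str | None) -> None:
        for mv in by_left_flank.pop(after_locus, []):
            effective.append(
                (f"marker:{mv.marker}", mv.vote, mv.flanking_genes[0], mv.flanking_genes[1])
            )

    _add_markers(None)
    for v in votes:
        if v.vote in (label_a, label_b):
            effective.append((v.locus, v.vote, v.locus, v.locus))
        elif v.vote == "absent" and len(v.present_in) == 1:
            # species-specific gene absence: consistent with the species lacking it
            lacking = label_b if v.present_in == [label_a] else label_a
            effective.append((v.locus, lacking, v.locus, v.locus))
        _add_markers(v.locus)
    for leftover in list(by_left_flank):
        _add_markers(leftover)

    call = OriginCall(
        haplotype=query.name,
        verdict="unresolved",
        marker_votes=marker_vote_list,
        identity_to_a=identities[0],
        identity_to_b=identities[1],
        locus_votes=votes,
    )
    if effective:
        seq = [sp for _, sp, _, _ in effective]
        switches = sum(1 for x, y in zip(seq, seq[1:]) if x != y)
        if switches == 0:
            call.verdict = seq[0]
            return call
        if switches == 1:
            idx = next(i for i, (x, y) in enumerate(zip(seq, seq[1:])) if x != y)
            call.verdict = "recombinant"
            call.breakpoint_loci = (effective[idx][0], effective[idx + 1][0])
            left_genes = [
                query.gene(anchor)
                for _, _, anchor, _ in effective[: idx + 1]
                if anchor and query.gene(anchor)
            ]
            right_genes = [
                query.gene(anchor)
                for _, _, _, anchor in effective[idx + 1 :]
                if anchor and query.gene(anchor)
            ]
            if left_genes and right_genes:
                lo = max(g.end for g in left_genes)
                hi = min(g.start for g in right_genes)
                if lo <= hi:
                    call.breakpoint_interval = (lo, hi)
            return call
        call.notes = [f"{switches} vote switches along gene order"]
        return call
    # no informative votes at all: identity tiebreak
    ia, ib = identities
    if np.isfinite(ia) and np.isfinite(ib) and ia != ib:
        call.verdict = label_a if ia > ib else label_b
        call.notes = ["verdict from identity tiebreak only (weak evidence)"]
    return call


def classify_all(
    panel_a: SpeciesPanel,
    panel_b: SpeciesPanel,
    queries: list[Haplotype],
    store: AlignmentStore | None = None,
    rate_r: float = molevol.DEFAULT_RATE,
    min_marker_len: int = MARKER_MIN_LEN,
) -> tuple[list[OriginCall], list[SpeciesMarker]]:
    """Run marker discovery plus all three channels for every query."""
    store = store or AlignmentStore()
    markers = discover_species_markers(panel_a, panel_b, store, min_len=min_marker_len)
    calls = []
    for query in queries:
        mv = marker_votes(query, markers, panel_a, panel_b, store)
        ids = identity_vote(query, panel_a, panel_b, store)
        lv = locus_votes(query, panel_a, panel_b, rate_r=rate_r)
        calls.append(classify_origin(query, panel_a, panel_b, mv, ids, lv))
    return calls, markers
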