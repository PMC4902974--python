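"""Synthetic polyploid-locus simulator with full ground truth.

Generates panels of homologous haplotypes for two progenitor species plus
hybrid-derived query haplotypes, with a known evolutionary history: an
ancestral gene-dense locus, species ancestors, independent within-species
divergence, species-specific segmental insertions/deletions (diagnostic
markers), dated LTR retrotransposon insertions with target-site duplications,
pseudogenizing insertions, and a single-breakpoint recombinant. Every planted
feature is recorded in a JSON-serialisable truth set so downstream stages can
be tested by parameter recovery.

The default :class:`SimulationConfig` emulates the study conditions of a
sugarcane-like locus: ~80-130 kb haplotypes carrying 13 genes, within-species
SNP divergence near 1.8 % (species A) and 1.3 % (species B), between-species
divergence near 2 %, uneven multi-kb InDels driving gap fractions of roughly
20-50 % of aligned columns, and a neutral clock of 1.3e-8
substitutions/site/year.

The mutation process is independent-site substitution with a two-rate
transition/transversion scheme (the generating process of the K2P estimator);
there is no rate heterogeneity across sites. Small InDels have geometric
lengths; multi-kb events come from an explicit segmental channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GeneModel, Haplotype, TEAnnotation, revcomp
from .io import write_bundle, read_bundle  # noqa: F401  (re-exported bundle API)

_STOPS = ("TAA", "TAG", "TGA")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


# ---------------------------------------------------------------------------
# templates


@dataclass
class GeneSpec:
    gene_id: str
    strand: str
    exon_lengths: list[int]
    intron_lengths: list[int]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if len(self.intron_lengths) != max(len(self.exon_lengths) - 1, 0):
            raise ValueError(f"{self.gene_id}: need one intron fewer than exons")
        for length in self.exon_lengths:
            if length <= 0 or length % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}: exon length {length} not a positive multiple of 3"
                )
        if sum(self.exon_lengths) < 9:
            raise ValueError(f"{self.gene_id}: CDS too short")


@dataclass
class LocusTemplate:
    genes: list[GeneSpec]
    intergenic_lengths: list[int]  # n_genes + 1 entries (leading ... trailing)
    target_gc: float = 0.452

    def validate(self) -> None:
        if not 0.0 < self.target_gc < 1.0:
            raise ValueError("target_gc must be in (0, 1)")
        if len(self.intergenic_lengths) != len(self.genes) + 1:
            raise ValueError("need len(genes) + 1 intergenic lengths")
        if any(x < 0 for x in self.intergenic_lengths):
            raise ValueError("negative intergenic length")
        for gene in self.genes:
            gene.validate()

    @property
    def total_length(self) -> int:
        total = sum(self.intergenic_lengths)
        for g in self.genes:
            total += sum(g.exon_lengths) + sum(g.intron_lengths)
        return total


def default_template(n_genes: int = 13, target_gc: float = 0.452) -> LocusTemplate:
    """Deterministic locus layout emulating a gene-dense ~85 kb grass locus."""
    exon_counts = [1, 2, 7, 10, 14, 8, 8, 5, 1, 6, 7, 6, 3]
    genes = []
    for i in range(n_genes):
        n_ex = exon_counts[i % len(exon_counts)]
        exons = [3 * (50 + 20 * ((i + j) % 4)) for j in range(n_ex)]
        introns = [180 + 90 * ((i + j) % 5) for j in range(max(n_ex - 1, 0))]
        genes.append(
            GeneSpec(
                gene_id=f"g{i + 1:02d}",
                strand="+" if i % 3 else "-",
                exon_lengths=exons,
                intron_lengths=introns,
            )
        )
    intergenic = [2500 + 700 * (i % 5) for i in range(n_genes + 1)]
    return LocusTemplate(genes=genes, intergenic_lengths=intergenic, target_gc=target_gc)


def small_template(n_genes: int = 4, target_gc: float = 0.45) -> LocusTemplate:
    """Compact layout for fast tests (~2.5 kb per gene)."""
    genes = [
        GeneSpec(
            gene_id=f"g{i + 1:02d}",
            strand="+" if i % 2 else "-",
            exon_lengths=[300, 300, 300],
            intron_lengths=[200, 200],
        )
        for i in range(n_genes)
    ]
    intergenic = [1200] * (n_genes + 1)
    return LocusTemplate(genes=genes, intergenic_lengths=intergenic, target_gc=target_gc)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_study`.

    Divergences are expected substitutions/site along a lineage: a pair of
    haplotypes drawn within species X differs by ~2x ``within_species_divergence[X]``;
    a between-species pair by ``species_divergence`` plus both within terms.
    """

    seed: int = 0
    species_divergence: float = 0.005
    within_species_divergence: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0089, "B": 0.0065}
    )
    member_branch_factors: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"A": (0.35, 0.35, 1.0, 2.4), "B": (1.0, 1.0)}
    )
    query_attachment_divergence: float = 0.001
    ts_tv_ratio: float = 2.0
    indel_rate: float = 2e-4
    indel_length_mean: float = 4.0
    rate_r: float = 1.3e-8
    n_members: dict[str, int] = field(default_factory=lambda: {"A": 4, "B": 2})
    # 7 hybrid queries: 4 species-A-origin (one of them the recombinant) + 2 B
    n_queries: dict[str, int] = field(default_factory=lambda: {"A": 5, "B": 2})
    with_recombinant: bool = True
    n_segmental_per_haplotype: int = 2
    segmental_length_range: tuple[int, int] = (2000, 8000)
    marker_length: int = 3000
    te_ages_years: tuple[float, ...] = (
        0.0,
        0.02e6,
        0.44e6,
        0.88e6,
        0.99e6,
        1.0e6,
        1.0e6,
        1.06e6,
        1.28e6,
    )
    ltr_length: int = 1000
    te_internal_length: int = 3000
    tsd_length: int = 5
    species_b_deleted_genes: tuple[str, ...] = ("g10", "g11")

    def validate(self) -> None:
        for name, val in (
            ("species_divergence", self.species_divergence),
            ("indel_rate", self.indel_rate),
            ("indel_length_mean", self.indel_length_mean),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.within_species_divergence.values()):
            raise ValueError("within_species_divergence must be >= 0")
        if self.rate_r <= 0:
            raise ValueError("rate_r must be > 0")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")


# ---------------------------------------------------------------------------
# primitive machinery


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random sense codons + stop, drawn near the target GC."""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(bases, size=3, p=probs))
        if codon in _STOPS:
            continue
        codons.append(codon)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


Edit = tuple  # ('ins', pos, seq) | ('del', start, end), in parent coordinates


def _apply_edits(seq: str, edits: list[Edit]) -> tuple[str, np.ndarray]:
    """Apply non-overlapping insertions/deletions; return (child, parent->child map).

    The map has -1 for deleted parent positions. Insertions at position p are
    placed before parent base p.
    """
    L = len(seq)
    p2c = np.full(L, -1, dtype=np.int64)
    order = sorted(edits, key=lambda e: (e[1], 0 if e[0] == "ins" else 1))
    pieces: list[str] = []
    cur_parent = 0
    cur_child = 0
    for edit in order:
        if edit[0] == "ins":
            _, pos, ins_seq = edit
            if pos < cur_parent:
                raise ValueError("overlapping edits")
            if pos > cur_parent:
                pieces.append(seq[cur_parent:pos])
                p2c[cur_parent:pos] = np.arange(
                    cur_child, cur_child + pos - cur_parent
                )
                cur_child += pos - cur_parent
                cur_parent = pos
            pieces.append(ins_seq)
            cur_child += len(ins_seq)
        else:
            _, start, end = edit
            if start < cur_parent:
                raise ValueError("overlapping edits")
            if start > cur_parent:
                pieces.append(seq[cur_parent:start])
                p2c[cur_parent:start] = np.arange(
                    cur_child, cur_child + start - cur_parent
                )
                cur_child += start - cur_parent
            cur_parent = end
    if cur_parent < L:
        pieces.append(seq[cur_parent:])
        p2c[cur_parent:] = np.arange(cur_child, cur_child + L - cur_parent)
    return "".join(pieces), p2c


def _lift_interval(p2c: np.ndarray, start: int, end: int) -> tuple[int, int] | None:
    sub = p2c[start:end]
    kept = sub[sub >= 0]
    if kept.size == 0:
        return None
    return int(kept.min()), int(kept.max()) + 1


def _lift_annotations(hap: Haplotype, p2c: np.ndarray) -> tuple[list[GeneModel], list[TEAnnotation]]:
    genes = []
    for g in hap.genes:
        exons = []
        lost = False
        for s, e in g.exons:
            iv = _lift_interval(p2c, s, e)
            if iv is None:
                lost = True
            else:
                exons.append(iv)
        if not exons:
            continue
        genes.append(
            GeneModel(gene_id=g.gene_id, strand=g.strand, exons=exons, pseudo=g.pseudo or lost)
        )
    tes = []
    for t in hap.tes:
        iv = _lift_interval(p2c, t.start, t.end)
        if iv is None:
            continue
        ltr5 = _lift_interval(p2c, *t.ltr5) if t.ltr5 else None
        ltr3 = _lift_interval(p2c, *t.ltr3) if t.ltr3 else None
        tes.append(
            TEAnnotation(
                te_id=t.te_id,
                start=iv[0],
                end=iv[1],
                ltr5=ltr5,
                ltr3=ltr3,
                tsd_length=t.tsd_length,
                family=t.family,
            )
        )
    return genes, tes


def _exon_intervals(hap: Haplotype) -> list[tuple[int, int]]:
    out = []
    for g in hap.genes:
        out.extend(g.exons)
    return sorted(out)


def _overlaps(iv: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    s, e = iv
    return any(s < b and e > a for a, b in intervals)


# ---------------------------------------------------------------------------
# operations


def simulate_ancestor(
    template: LocusTemplate, seed: int, name: str = "ancestor"
) -> Haplotype:
    """Build the ancestral haplotype for a locus template.

    Coding exons begin with ATG, end with a stop, carry no internal stop, and
    respect the template's exon phase (every exon a whole number of codons).
    """
    template.validate()
    rng = np.random.default_rng(seed)
    gc = template.target_gc
    pieces: list[str] = []
    genes: list[GeneModel] = []
    cursor = 0

    def _emit(segment: str) -> None:
        nonlocal cursor
        pieces.append(segment)
        cursor += len(segment)

    for idx, gene in enumerate(template.genes):
        _emit(_random_seq(rng, template.intergenic_lengths[idx], gc))
        cds = _random_cds(rng, sum(gene.exon_lengths) // 3, gc)
        chunks = []
        off = 0
        for length in gene.exon_lengths:
            chunks.append(cds[off : off + length])
            off += length
        if gene.strand == "-":
            chunks = [revcomp(c) for c in reversed(chunks)]
        exons = []
        for j, chunk in enumerate(chunks):
            start = cursor
            _emit(chunk)
            exons.append((start, cursor))
            if j < len(chunks) - 1:
                _emit(_random_seq(rng, gene.intron_lengths[j], gc))
        genes.append(GeneModel(gene_id=gene.gene_id, strand=gene.strand, exons=exons))
    _emit(_random_seq(rng, template.intergenic_lengths[-1], gc))
    return Haplotype(name=name, seq="".join(pieces), genes=genes)


@dataclass
class EvolutionRecord:
    """Ground truth of one :func:`evolve_haplotype` call."""

    parent: str
    child: str
    sub_positions_parent: np.ndarray
    sub_positions_child: np.ndarray
    n_transitions: int
    n_transversions: int
    indels: list[dict]
    p2c: np.ndarray  # parent->child coordinate map (-1 = deleted)


def evolve_haplotype(
    parent: Haplotype,
    divergence: float,
    config: SimulationConfig | None = None,
    seed: int = 0,
    name: str | None = None,
    species: str | None = None,
    protect_exons: bool = True,
) -> tuple[Haplotype, EvolutionRecord]:
    """Mutate a haplotype: Bernoulli substitutions at ``divergence`` per site
    with the configured ts/tv ratio, plus geometric-length InDels at
    ``indel_rate`` events/site; annotations are lifted through the InDels."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    L = len(parent.seq)
    seq = list(parent.seq)

    # genomic position -> (strand, genomic positions of its codon in CDS order)
    codon_of: dict[int, tuple[str, tuple[int, int, int]]] = {}
    for g in parent.genes:
        cds_positions: list[int] = []
        for s, e in g.exons:
            cds_positions.extend(range(s, e))
        if g.strand == "-":
            cds_positions.reverse()
        for k in range(0, len(cds_positions) - 2, 3):
            codon = (cds_positions[k], cds_positions[k + 1], cds_positions[k + 2])
            for p in codon:
                codon_of[p] = (g.strand, codon)

    def _codon_str(codon: tuple[int, int, int], strand: str) -> str:
        bases = "".join(seq[p] for p in codon)
        return "".join(_COMPLEMENT[b] for b in bases) if strand == "-" else bases

    n_sub = rng.binomial(L, divergence) if divergence > 0 else 0
    sub_pos_all = (
        np.sort(rng.choice(L, size=n_sub, replace=False))
        if n_sub
        else np.empty(0, dtype=np.int64)
    )
    kappa = config.ts_tv_ratio
    is_ts = rng.random(n_sub) < kappa / (kappa + 1.0)
    n_transitions = n_transversions = 0
    applied: list[int] = []
    for pos, ts in zip(sub_pos_all, is_ts):
        old = seq[pos]
        if old not in _TRANSITION:
            continue
        if ts:
            candidates = [_TRANSITION[old]] + list(_TRANSVERSIONS[old][:: 1 if rng.random() < 0.5 else -1])
        else:
            tv = list(_TRANSVERSIONS[old][:: 1 if rng.random() < 0.5 else -1])
            candidates = tv + [_TRANSITION[old]]
        chosen = None
        hit = codon_of.get(int(pos))
        for cand in candidates:
            if hit is None:
                chosen = cand
                break
            strand, codon = hit
            seq[pos] = cand
            stop = _codon_str(codon, strand) in _STOPS
            seq[pos] = old
            if not stop:  # nonsense mutations are purged (purifying selection)
                chosen = cand
                break
        if chosen is None:
            continue
        seq[pos] = chosen
        applied.append(int(pos))
        if chosen == _TRANSITION[old]:
            n_transitions += 1
        else:
            n_transversions += 1
    sub_pos = np.array(applied, dtype=np.int64)

    exons = _exon_intervals(parent) if protect_exons else []
    n_indel = rng.poisson(L * config.indel_rate) if config.indel_rate > 0 else 0
    edits: list[Edit] = []
    spans: list[tuple[int, int]] = []
    indel_truth = []
    for _ in range(n_indel):
        for _try in range(30):
            pos = int(rng.integers(L))
            length = int(rng.geometric(1.0 / config.indel_length_mean))
            kind = "ins" if rng.random() < 0.5 else "del"
            span = (pos, pos + length) if kind == "del" else (pos, pos + 1)
            if span[1] > L:
                continue
            if protect_exons and _overlaps(span, exons):
                continue
            if _overlaps(span, spans):
                continue
            spans.append(span)
            if kind == "ins":
                edits.append(("ins", pos, _random_seq(rng, length)))
            else:
                edits.append(("del", pos, pos + length))
            indel_truth.append({"kind": kind, "parent_pos": pos, "length": length})
            break

    child_seq, p2c = _apply_edits("".join(seq), edits)
    genes, tes = _lift_annotations(parent, p2c)
    child_name = name or f"{parent.name}-child"
    child = Haplotype(
        name=child_name,
        seq=child_seq,
        species=species if species is not None else parent.species,
        genes=genes,
        tes=tes,
    )
    record = EvolutionRecord(
        parent=parent.name,
        child=child_name,
        sub_positions_parent=sub_pos,
        sub_positions_child=p2c[sub_pos] if n_sub else sub_pos,
        n_transitions=n_transitions,
        n_transversions=n_transversions,
        indels=indel_truth,
        p2c=p2c,
    )
    return child, record


def insert_ltr_element(
    hap: Haplotype,
    position: int,
    age_years: float,
    ltr_length: int,
    tsd_length: int,
    rate_r: float,
    seed: int,
    internal_length: int = 3000,
    te_id: str | None = None,
    family: str = "LTR/unknown",
    ts_tv_ratio: float = 2.0,
) -> tuple[Haplotype, dict]:
    """Insert a dated LTR retrotransposon with a duplicated target site.

    The element is built with two identical LTRs; each LTR is then mutated
    independently at probability ``rate_r * age_years`` per site, so the
    expected LTR-pair divergence is k = 2 r T. Positions inside an exon are
    allowed but warn (pseudogenization channel).
    """
    if not 0 <= position <= len(hap.seq) - tsd_length:
        raise ValueError("position outside haplotype")
    if age_years < 0:
        raise ValueError("age_years must be >= 0")
    rng = np.random.default_rng(seed)
    in_exon = _overlaps((position, position + 1), _exon_intervals(hap))
    if in_exon:
        warnings.warn(
            f"{hap.name}: LTR insertion at {position} lands in an exon "
            "(pseudogenizing insertion)"
        )
    ltr = _random_seq(rng, ltr_length)
    internal = _random_seq(rng, internal_length)

    def _age(seq: str) -> str:
        p = rate_r * age_years
        if p <= 0:
            return seq
        arr = list(seq)
        hits = np.nonzero(rng.random(len(arr)) < p)[0]
        kappa = ts_tv_ratio
        for pos in hits:
            if rng.random() < kappa / (kappa + 1.0):
                arr[pos] = _TRANSITION[arr[pos]]
            else:
                arr[pos] = _TRANSVERSIONS[arr[pos]][rng.integers(2)]
        return "".join(arr)

    element = _age(ltr) + internal + _age(ltr)
    tsd = hap.seq[position : position + tsd_length]
    child_seq, p2c = _apply_edits(hap.seq, [("ins", position, tsd + element)])
    genes, tes = _lift_annotations(hap, p2c)
    if in_exon:
        hit = {
            g.gene_id
            for g in hap.genes
            if any(s <= position < e for s, e in g.exons)
        }
        for g in genes:
            if g.gene_id in hit:
                g.pseudo = True
    start = position + tsd_length
    end = start + len(element)
    te_id = te_id or f"{hap.name}-te{len(tes) + 1}"
    ann = TEAnnotation(
        te_id=te_id,
        start=start,
        end=end,
        ltr5=(start, start + ltr_length),
        ltr3=(end - ltr_length, end),
        tsd_length=tsd_length,
        family=family,
    )
    tes.append(ann)
    tes.sort(key=lambda t: t.start)
    child = Haplotype(
        name=hap.name, seq=child_seq, species=hap.species, genes=genes, tes=tes
    )
    truth = {
        "te_id": te_id,
        "haplotype": hap.name,
        "position": int(start),
        "age_years": float(age_years),
        "ltr_length": int(ltr_length),
        "internal_length": int(internal_length),
        "tsd_length": int(tsd_length),
        "rate_r": float(rate_r),
        "family": family,
    }
    return child, truth


def insert_species_marker(
    panel: list[Haplotype],
    species: str,
    slot: tuple[str, str],
    length: int,
    seed: int,
    within_divergence: float = 0.0,
    marker_id: str | None = None,
) -> tuple[list[Haplotype], dict | None]:
    """Insert a species-diagnostic segment into every member of one species.

    The same base segment (independently mutated per ``within_divergence``) is
    placed at the midpoint of the named intergenic slot in every haplotype
    whose species matches; other species are untouched.
    """
    if length == 0:
        return panel, None
    if length < 0:
        raise ValueError("length must be >= 0")
    left_id, right_id = slot
    for hap in panel:
        left, right = hap.gene(left_id), hap.gene(right_id)
        if left is None or right is None:
            raise ValueError(f"slot {slot} absent from {hap.name}")
        if left.end >= right.start:
            raise ValueError(f"slot {slot} overlaps a gene on {hap.name}")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, length)
    marker_id = marker_id or f"marker-{species}-{left_id}-{right_id}"
    intervals = {}
    out = []
    for hap in panel:
        if hap.species != species:
            out.append(hap)
            continue
        seg = list(base)
        n_mut = rng.binomial(length, within_divergence) if within_divergence > 0 else 0
        for pos in rng.choice(length, size=n_mut, replace=False):
            seg[pos] = _TRANSITION[seg[pos]] if rng.random() < 2 / 3 else _TRANSVERSIONS[seg[pos]][rng.integers(2)]
        left, right = hap.gene(left_id), hap.gene(right_id)
        pos = (left.end + right.start) // 2
        child_seq, p2c = _apply_edits(hap.seq, [("ins", pos, "".join(seg))])
        genes, tes = _lift_annotations(hap, p2c)
        out.append(
            Haplotype(name=hap.name, seq=child_seq, species=hap.species, genes=genes, tes=tes)
        )
        intervals[hap.name] = [int(pos), int(pos + length)]
    truth = {
        "marker_id": marker_id,
        "species": species,
        "slot": list(slot),
        "length": int(length),
        "intervals": intervals,
    }
    return out, truth


def make_recombinant(
    hap_a: Haplotype,
    hap_b: Haplotype,
    breakpoint: tuple[str, str],
    seed: int,
    name: str = "recombinant",
) -> tuple[Haplotype, dict]:
    """Single-breakpoint recombinant: A prefix + B suffix.

    The crossover point is drawn uniformly inside the intergenic interval
    between the two named genes, at homologous relative positions in both
    parents; the exact coordinates go into the truth record.
    """
    left_id, right_id = breakpoint
    for hap in (hap_a, hap_b):
        if hap.gene(left_id) is None or hap.gene(right_id) is None:
            raise ValueError(f"breakpoint interval {breakpoint} absent from {hap.name}")
    rng = np.random.default_rng(seed)
    frac = float(rng.uniform(0.1, 0.9))
    la, ra = hap_a.gene(left_id), hap_a.gene(right_id)
    lb, rb = hap_b.gene(left_id), hap_b.gene(right_id)
    pos_a = la.end + int(frac * (ra.start - la.end))
    pos_b = lb.end + int(frac * (rb.start - lb.end))
    seq = hap_a.seq[:pos_a] + hap_b.seq[pos_b:]
    shift = pos_a - pos_b
    genes = [
        GeneModel(g.gene_id, g.strand, [tuple(iv) for iv in g.exons], g.pseudo)
        for g in hap_a.genes
        if g.end <= pos_a
    ]
    genes += [
        GeneModel(
            g.gene_id, g.strand, [(s + shift, e + shift) for s, e in g.exons], g.pseudo
        )
        for g in hap_b.genes
        if g.start >= pos_b
    ]
    tes = [t for t in hap_a.tes if t.end <= pos_a]
    for t in hap_b.tes:
        if t.start >= pos_b:
            tes.append(
                TEAnnotation(
                    t.te_id,
                    t.start + shift,
                    t.end + shift,
                    (t.ltr5[0] + shift, t.ltr5[1] + shift) if t.ltr5 else None,
                    (t.ltr3[0] + shift, t.ltr3[1] + shift) if t.ltr3 else None,
                    t.tsd_length,
                    t.family,
                )
            )
    hap = Haplotype(name=name, seq=seq, species="recombinant", genes=genes, tes=tes)
    truth = {
        "name": name,
        "parent_a": hap_a.name,
        "parent_b": hap_b.name,
        "breakpoint_genes": [left_id, right_id],
        "pos_child": int(pos_a),
        "pos_parent_a": int(pos_a),
        "pos_parent_b": int(pos_b),
    }
    return hap, truth


# ---------------------------------------------------------------------------
# study-level orchestration


@dataclass
class StudyBundle:
    panels: dict[str, list[Haplotype]]
    queries: list[Haplotype]
    truth: dict

    @property
    def all_haplotypes(self) -> list[Haplotype]:
        return [h for members in self.panels.values() for h in members] + list(
            self.queries
        )


def _delete_genes(hap: Haplotype, gene_ids: tuple[str, ...]) -> Haplotype:
    """Remove whole gene regions (with 100 bp flanks) from a haplotype."""
    edits: list[Edit] = []
    for gid in gene_ids:
        g = hap.gene(gid)
        if g is None:
            continue
        edits.append(("del", max(g.start - 100, 0), min(g.end + 100, len(hap.seq))))
    edits.sort(key=lambda e: e[1])
    merged: list[Edit] = []
    for e in edits:
        if merged and e[1] <= merged[-1][2]:
            merged[-1] = ("del", merged[-1][1], max(merged[-1][2], e[2]))
        else:
            merged.append(e)
    seq, p2c = _apply_edits(hap.seq, merged)
    genes, tes = _lift_annotations(hap, p2c)
    genes = [g for g in genes if g.gene_id not in gene_ids]
    return Haplotype(name=hap.name, seq=seq, species=hap.species, genes=genes, tes=tes)


def _intergenic_position(
    rng: np.random.Generator,
    hap: Haplotype,
    margin: int = 200,
    avoid: tuple[tuple[int, int], ...] = (),
) -> int:
    """A random position in a random intergenic stretch, outside ``avoid``."""
    genes = sorted(hap.genes, key=lambda g: g.start)
    slots = []
    prev = 0
    for g in genes:
        if g.start - prev > 2 * margin:
            slots.append((prev + margin, g.start - margin))
        prev = g.end
    if len(hap.seq) - prev > 2 * margin:
        slots.append((prev + margin, len(hap.seq) - margin))
    for _ in range(50):
        lo, hi = slots[rng.integers(len(slots))]
        pos = int(rng.integers(lo, hi))
        if not any(s - margin <= pos < e + margin for s, e in avoid):
            return pos
    raise RuntimeError("no intergenic position available outside avoided intervals")


def simulate_study(
    config: SimulationConfig | None = None,
    template: LocusTemplate | None = None,
) -> StudyBundle:
    """Simulate the full two-species + hybrid-queries study design.

    Produces species panels A and B, hybrid query haplotypes of known origin
    (including one single-breakpoint recombinant when configured), a
    species-diagnostic inserted marker carried by every A-lineage haplotype, a
    species-specific gene-deletion region in species B, segmental insertions,
    and dated LTR elements — all recorded in the truth set.
    """
    config = config or SimulationConfig()
    config.validate()
    template = template or default_template()
    template.validate()
    gene_ids = [g.gene_id for g in template.genes]
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(ss.generate_state(4096).tolist())

    ancestor = simulate_ancestor(template, next(seeds))
    anc_a, _ = evolve_haplotype(
        ancestor, config.species_divergence / 2, config, next(seeds), name="ancA", species="A"
    )
    anc_b, _ = evolve_haplotype(
        ancestor, config.species_divergence / 2, config, next(seeds), name="ancB", species="B"
    )
    deleted = tuple(g for g in config.species_b_deleted_genes if g in gene_ids)
    if deleted:
        anc_b = _delete_genes(anc_b, deleted)

    within = config.within_species_divergence

    def _evolve(parent, divergence, species, name):
        hap, rec = evolve_haplotype(
            parent, divergence, config, next(seeds), name=name, species=species
        )
        return hap, rec

    # panel members: branch length = base within-species divergence x a
    # per-member depth factor (heterogeneous homeolog depths)
    panels: dict[str, list[Haplotype]] = {"A": [], "B": []}
    recent: dict[str, list[Haplotype]] = {"A": [], "B": []}
    sub_counts = {}
    for sp, anc in (("A", anc_a), ("B", anc_b)):
        base = within.get(sp, 0.008)
        factors = config.member_branch_factors.get(
            sp, (1.0,) * config.n_members.get(sp, 0)
        )
        order = sorted(range(len(factors)), key=lambda i: factors[i])
        n_recent = max(1, sum(1 for f in factors if f <= min(factors) + 1e-9))
        for i in range(config.n_members.get(sp, 0)):
            f = factors[i % len(factors)]
            hap, rec = _evolve(anc, base * f, sp, f"{sp}{i + 1}")
            panels[sp].append(hap)
            sub_counts[hap.name] = len(rec.sub_positions_parent)
        recent[sp] = [panels[sp][i] for i in order[:n_recent]] or panels[sp]

    # hybrid queries: recent descendants of specific panel lineages
    eps = config.query_attachment_divergence
    queries: list[Haplotype] = []
    origins: dict[str, str] = {}
    attachments: dict[str, str] = {}
    for sp in ("A", "B"):
        n_q = config.n_queries.get(sp, 0)
        if config.with_recombinant and sp == "A":
            n_q = max(n_q - 1, 0)  # the recombinant replaces one A-origin query
        for i in range(n_q):
            parent = recent[sp][i % len(recent[sp])]
            hap, rec = _evolve(parent, eps, sp, f"q{sp}{i + 1}")
            queries.append(hap)
            origins[hap.name] = sp
            attachments[hap.name] = parent.name
            sub_counts[hap.name] = len(rec.sub_positions_parent)

    rec_truth = None
    rec_parents: list[Haplotype] = []
    if config.with_recombinant:
        p_a, _ = _evolve(recent["A"][0], eps, "A", "recParentA")
        p_b, _ = _evolve(recent["B"][0], eps, "B", "recParentB")
        rec_parents = [p_a, p_b]
        attachments["recParentA"] = recent["A"][0].name
        attachments["recParentB"] = recent["B"][0].name

    # species-diagnostic inserted marker: carried by every A-lineage haplotype
    marker_truth = None
    if config.marker_length > 0 and len(gene_ids) >= 3:
        slot = None
        for left, right in zip(gene_ids, gene_ids[1:]):
            if left not in deleted and right not in deleted:
                slot = (left, right)
                break
        if slot is None:
            raise ValueError("no shared adjacent gene pair available for the marker slot")
        a_lineage = panels["A"] + [q for q in queries if origins[q.name] == "A"] + (
            [rec_parents[0]] if rec_parents else []
        )
        others = panels["B"] + [q for q in queries if origins[q.name] == "B"] + (
            [rec_parents[1]] if rec_parents else []
        )
        combined, marker_truth = insert_species_marker(
            a_lineage + others,
            species="A",
            slot=slot,
            length=config.marker_length,
            seed=next(seeds),
            within_divergence=within.get("A", 0.008),
        )
        by_name = {h.name: h for h in combined}
        panels["A"] = [by_name[h.name] for h in panels["A"]]
        panels["B"] = [by_name[h.name] for h in panels["B"]]
        queries = [by_name[h.name] for h in queries]
        rec_parents = [by_name[h.name] for h in rec_parents]

    if config.with_recombinant:
        shared = [g for g in gene_ids if g not in deleted]
        bp = (shared[-2], shared[-1])
        if deleted:
            # place the crossover just upstream of the species-specific region,
            # so the suffix carries the diagnostic absence
            first_del = gene_ids.index(deleted[0])
            before = [g for g in gene_ids[:first_del] if g not in deleted]
            if len(before) >= 2:
                bp = (before[-2], before[-1])
        rec_hap, rec_truth = make_recombinant(
            rec_parents[0], rec_parents[1], bp, next(seeds), name="qRec"
        )
        queries.append(rec_hap)
        origins["qRec"] = "recombinant"
        if marker_truth is not None:
            # the A parent is not emitted; its marker lives on in the
            # recombinant's prefix at unchanged coordinates
            iv = marker_truth["intervals"].pop(rec_parents[0].name, None)
            if iv is not None and iv[1] <= rec_truth["pos_parent_a"]:
                marker_truth["intervals"][rec_hap.name] = iv

    # later insertions shift earlier-recorded truth coordinates; keep them live
    def _shift_truth(hap_name: str, at: int, by: int) -> None:
        if rec_truth is not None and hap_name == rec_truth["name"]:
            if rec_truth["pos_child"] >= at:
                rec_truth["pos_child"] += by
        if marker_truth is not None and hap_name in marker_truth["intervals"]:
            iv = marker_truth["intervals"][hap_name]
            marker_truth["intervals"][hap_name] = [
                x + by if x > at else x for x in iv
            ]
        for entry in segmental:
            if entry["haplotype"] == hap_name and entry["position"] >= at:
                entry["position"] += by
        for entry in te_truth:
            if entry["haplotype"] == hap_name and entry["position"] >= at:
                entry["position"] += by

    def _avoid(hap_name: str) -> tuple[tuple[int, int], ...]:
        if marker_truth is not None and hap_name in marker_truth["intervals"]:
            return (tuple(marker_truth["intervals"][hap_name]),)
        return ()

    # segmental insertions (multi-kb InDel channel) on every final haplotype
    segmental = []
    te_truth = []
    all_haps = panels["A"] + panels["B"] + queries
    lo, hi = config.segmental_length_range
    for idx, hap in enumerate(all_haps):
        rng = np.random.default_rng(next(seeds))
        new = hap
        for _ in range(config.n_segmental_per_haplotype):
            pos = _intergenic_position(rng, new, avoid=_avoid(new.name))
            length = int(rng.integers(lo, hi + 1))
            seq, p2c = _apply_edits(new.seq, [("ins", pos, _random_seq(rng, length))])
            genes, tes = _lift_annotations(new, p2c)
            new = Haplotype(new.name, seq, new.species, genes, tes)
            _shift_truth(new.name, pos, length)
            segmental.append(
                {"haplotype": new.name, "position": int(pos), "length": int(length)}
            )
        all_haps[idx] = new
    n_a, n_b = len(panels["A"]), len(panels["B"])
    panels["A"] = all_haps[:n_a]
    panels["B"] = all_haps[n_a : n_a + n_b]
    queries = all_haps[n_a + n_b :]

    # dated LTR elements spread over the haplotypes
    all_haps = panels["A"] + panels["B"] + queries
    for i, age in enumerate(config.te_ages_years):
        idx = i % len(all_haps)
        hap = all_haps[idx]
        rng = np.random.default_rng(next(seeds))
        pos = _intergenic_position(rng, hap, avoid=_avoid(hap.name))
        new, truth = insert_ltr_element(
            hap,
            position=pos,
            age_years=age,
            ltr_length=config.ltr_length,
            tsd_length=config.tsd_length,
            rate_r=config.rate_r,
            seed=next(seeds),
            internal_length=config.te_internal_length,
            te_id=f"te{i + 1:02d}",
            family="LTR/copia" if i % 3 else "LTR/gypsy",
            ts_tv_ratio=config.ts_tv_ratio,
        )
        all_haps[idx] = new
        _shift_truth(
            new.name,
            pos,
            config.tsd_length + 2 * config.ltr_length + config.te_internal_length,
        )
        te_truth.append(truth)
    panels["A"] = all_haps[:n_a]
    panels["B"] = all_haps[n_a : n_a + n_b]
    queries = all_haps[n_a + n_b :]

    for sp in ("A", "B"):
        for h in panels[sp]:
            origins[h.name] = sp

    def _mean_pair(sp: str) -> float:
        factors = [
            config.member_branch_factors.get(sp, (1.0,))[i % len(config.member_branch_factors.get(sp, (1.0,)))]
            for i in range(len(panels[sp]))
        ]
        base = within.get(sp, 0.008)
        pair_sums = [
            factors[i] + factors[j]
            for i in range(len(factors))
            for j in range(i + 1, len(factors))
        ]
        return base * float(np.mean(pair_sums)) if pair_sums else 0.0

    def _mean_branch(sp: str) -> float:
        factors = config.member_branch_factors.get(sp, (1.0,))
        return within.get(sp, 0.008) * float(np.mean(factors))

    truth = {
        "config": {
            "seed": config.seed,
            "species_divergence": config.species_divergence,
            "within_species_divergence": dict(within),
            "ts_tv_ratio": config.ts_tv_ratio,
            "indel_rate": config.indel_rate,
            "rate_r": config.rate_r,
        },
        "panels": {sp: [h.name for h in panels[sp]] for sp in panels},
        "queries": [h.name for h in queries],
        "origins": origins,
        "query_attachments": attachments,
        "member_branch_factors": {
            sp: list(config.member_branch_factors.get(sp, ()))
            for sp in panels
        },
        "species_b_deleted_genes": list(deleted),
        "marker": marker_truth,
        "recombinant": rec_truth,
        "segmental_insertions": segmental,
        "tes": te_truth,
        "substitution_counts": sub_counts,
        "expected_pairwise_divergence": {
            "within_A": _mean_pair("A"),
            "within_B": _mean_pair("B"),
            "between": _mean_branch("A")
            + _mean_branch("B")
            + config.species_divergence,
        },
    }
    return StudyBundle(panels=panels, queries=queries, truth=truth)
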