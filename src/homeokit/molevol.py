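"""Molecular-evolution primitives.

* Kimura 2-parameter distance: k = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q), with P
  the transition and Q the transversion fraction over unambiguous columns.
* Divergence-time conversion T = k / (2 r) with a neutral substitution rate r
  (default 1.3e-8 substitutions/site/year, the grass rate used for LTR and
  allele dating).
* Ka/Ks by Nei-Gojobori (1986) site and pathway counting with Jukes-Cantor
  correction, plus the Fisher exact test of Sd/S = Nd/N.
* Allele grouping: pairwise synonymous divergence times, the most divergent
  allele, and maximal groups (>= 3 members) whose pairwise times all fall
  below one third of the locus maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import networkx as nx
import numpy as np
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

DEFAULT_RATE = 1.3e-8

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _TABLE.forward_table[codon]


def is_transition(b1: str, b2: str) -> bool:
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


# ---------------------------------------------------------------------------
# K2P


@dataclass
class K2PDistance:
    P: float
    Q: float
    k: float | None
    n_sites: int
    saturated: bool = False


def k2p_distance(seq_a: str, seq_b: str) -> K2PDistance:
    """Kimura 2-parameter distance over unambiguous, equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) == 0:
        raise ValueError("empty sequences")
    ts = tv = used = 0
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        if ca not in _BASES or cb not in _BASES:
            continue
        used += 1
        if ca == cb:
            continue
        if is_transition(ca, cb):
            ts += 1
        else:
            tv += 1
    if used == 0:
        raise ValueError("no unambiguous columns")
    P, Q = ts / used, tv / used
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PDistance(P=P, Q=Q, k=None, n_sites=used, saturated=True)
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PDistance(P=P, Q=Q, k=k, n_sites=used)


def divergence_time(k: float | None, rate_r: float = DEFAULT_RATE) -> float | None:
    """T = k / (2 r), in years; undefined (saturated) k propagates."""
    if rate_r <= 0:
        raise ValueError("rate_r must be > 0")
    if k is None:
        return None
    if k < 0:
        raise ValueError("k must be >= 0")
    return k / (2.0 * rate_r)


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    pairs: list[tuple[str | None, str | None]]  # aligned codons; None = gap

    @property
    def n_aligned(self) -> int:
        return sum(1 for a, b in self.pairs if a is not None and b is not None)


def _translate_cds(cds: str, label: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    prot = []
    for idx, codon in enumerate(codons):
        if codon in _STOPS:
            raise ValueError(f"{label}: internal stop codon at codon {idx}")
        if any(b not in _BASES for b in codon):
            prot.append("X")
        else:
            prot.append(_TABLE.forward_table[codon])
    return "".join(prot)


def _align_proteins(prot_a: str, prot_b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aln = aligner.align(prot_a.replace("X", "A"), prot_b.replace("X", "A"))[0]
    return str(aln[0]), str(aln[1])


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_aln: tuple[str, str] | None = None,
) -> CodonAlignment:
    """Back-translate a protein alignment into a codon alignment.

    Gaps come in whole codons; each aligned residue pair maps to its source
    codon. The protein alignment is checked against both CDS translations.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = _translate_cds(cds_a, "cdsA")
    prot_b = _translate_cds(cds_b, "cdsB")
    if protein_aln is None:
        protein_aln = _align_proteins(prot_a, prot_b)
    row_a, row_b = protein_aln
    if len(row_a.replace("-", "")) != len(prot_a):
        raise ValueError("protein alignment inconsistent with cdsA length")
    if len(row_b.replace("-", "")) != len(prot_b):
        raise ValueError("protein alignment inconsistent with cdsB length")
    codons_a = [cds_a[i : i + 3] for i in range(0, 3 * len(prot_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, 3 * len(prot_b), 3)]
    pairs: list[tuple[str | None, str | None]] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = codons_a[ia]
            if prot_a[ia] != "X" and ca != "X" and ca != prot_a[ia]:
                raise ValueError(
                    f"protein alignment residue {ca!r} != cdsA translation "
                    f"{prot_a[ia]!r} at codon {ia}"
                )
            ia += 1
        if cb != "-":
            codon_b = codons_b[ib]
            if prot_b[ib] != "X" and cb != "X" and cb != prot_b[ib]:
                raise ValueError(
                    f"protein alignment residue {cb!r} != cdsB translation "
                    f"{prot_b[ib]!r} at codon {ib}"
                )
            ib += 1
        pairs.append((codon_a, codon_b))
    return CodonAlignment(pairs=pairs)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes to stop codons count as nonsynonymous, so
    S + N = 3 exactly.
    """
    aa0 = _aa(codon)
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(mutated) == aa0 and mutated not in _STOPS:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over substitution
    pathways; pathways passing through stop codons are excluded when any
    stop-free pathway exists."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diffs):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _aa(cur) is not None and _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in pathways if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in pathways]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    fisher_p: float
    n_codons: int
    method: str = "NG86"
    saturated: bool = False


def kaks(codon_aln: CodonAlignment, method: str = "NG86") -> KaKsResult:
    """Nei-Gojobori Ka/Ks over gap-free aligned codons."""
    if method != "NG86":
        raise NotImplementedError(f"method {method!r}; only NG86 is implemented")
    pairs = [
        (a, b)
        for a, b in codon_aln.pairs
        if a is not None
        and b is not None
        and all(x in _BASES for x in a + b)
    ]
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 aligned codons, got {len(pairs)}")
    for a, b in pairs:
        if a in _STOPS or b in _STOPS:
            raise ValueError("internal stop codon in alignment")
    S = N = Sd = Nd = 0.0
    for a, b in pairs:
        sa, na = _codon_sites(a)
        sb, nb = _codon_sites(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    saturated = Ks is None or Ka is None
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        N=N,
        S=S,
        Nd=Nd,
        Sd=Sd,
        Ka=Ka,
        Ks=Ks,
        ratio=ratio,
        fisher_p=kaks_fisher(Sd, S, Nd, N),
        n_codons=len(pairs),
        saturated=saturated,
    )


def kaks_fisher(Sd: float, S: float, Nd: float, N: float) -> float:
    """Two-sided Fisher exact test of Sd/S = Nd/N (the neutral null).

    Fractional counts are rounded half-up to build the 2x2 table; a table with
    a zero margin gives p = 1.
    """
    if min(Sd, S, Nd, N) < 0 or Sd > S or Nd > N:
        raise ValueError("require 0 <= Sd <= S and 0 <= Nd <= N")

    def _round(x: float) -> int:
        return int(math.floor(x + 0.5))

    table = [[_round(Sd), _round(S - Sd)], [_round(Nd), _round(N - Nd)]]
    if any(sum(row) == 0 for row in table) or any(
        table[0][j] + table[1][j] == 0 for j in range(2)
    ):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# allele grouping (locus-wise divergence-time clustering)


@dataclass
class AlleleGroupingResult:
    locus: str
    alleles: list[str]
    times: dict[tuple[str, str], float | None]  # My, None = saturated
    t_max: float
    most_divergent: str | None
    groups: list[list[str]]
    ungrouped: list[str]
    threshold: float = 0.0


def _pairwise_time(
    cds_a: str, cds_b: str, rate_r: float, metric: str
) -> float | None:
    if metric == "ks":
        try:
            res = kaks(codon_align(cds_a, cds_b))
        except ValueError:
            return None
        if res.Ks is None:
            return None
        t = divergence_time(res.Ks, rate_r)
    elif metric == "k2p":
        aln = codon_align(cds_a, cds_b)
        sa = "".join(a for a, b in aln.pairs if a and b)
        sb = "".join(b for a, b in aln.pairs if a and b)
        dist = k2p_distance(sa, sb)
        t = divergence_time(dist.k, rate_r)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return None if t is None else t / 1e6  # My


def allele_grouping(
    alleles: dict[str, str],
    rate_r: float = DEFAULT_RATE,
    locus: str = "locus",
    metric: str = "ks",
) -> AlleleGroupingResult:
    """Group locus alleles by pairwise divergence time.

    Times come from synonymous divergence (Ks) through the neutral clock
    T = Ks/(2r). Groups are maximal cliques of >= 3 alleles whose pairwise
    times are all below T_max/3 (exact clique search; allele counts here are
    small). With T_max = 0 every allele is identical and forms one group.
    """
    names = sorted(alleles)
    if len(names) < 3:
        raise ValueError("need >= 3 alleles")
    times: dict[tuple[str, str], float | None] = {}
    saturated_pairs = []
    for a, b in combinations(names, 2):
        t = _pairwise_time(alleles[a], alleles[b], rate_r, metric)
        times[(a, b)] = t
        if t is None:
            saturated_pairs.append((a, b))
    if saturated_pairs:
        warnings.warn(f"{locus}: {len(saturated_pairs)} saturated pair(s) excluded")
    defined = {pair: t for pair, t in times.items() if t is not None}
    t_max = max(defined.values(), default=0.0)
    most_divergent = None
    if defined and t_max > 0:
        pair = max(defined, key=lambda p: defined[p])
        mean_t = {
            name: np.mean(
                [t for (a, b), t in defined.items() if name in (a, b)]
            )
            for name in pair
        }
        most_divergent = max(pair, key=lambda nm: (mean_t[nm], nm))
    threshold = t_max / 3.0
    if t_max == 0.0:
        groups = [list(names)] if len(names) >= 3 else []
    else:
        graph = nx.Graph()
        graph.add_nodes_from(names)
        for (a, b), t in defined.items():
            if t < threshold:
                graph.add_edge(a, b)
        groups = sorted(
            (sorted(c) for c in nx.find_cliques(graph) if len(c) >= 3),
            key=lambda g: (-len(g), g),
        )
    grouped = {m for g in groups for m in g}
    return AlleleGroupingResult(
        locus=locus,
        alleles=names,
        times=times,
        t_max=t_max,
        most_divergent=most_divergent,
        groups=groups,
        ungrouped=[m for m in names if m not in grouped],
        threshold=threshold,
    )
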