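"""Multi-haplotype neutrality statistics on reference-projected columns.

A set of pairwise alignments to a common reference is projected onto the
reference coordinate axis: a reference position is retained only when every
member aligns a residue there (complete deletion of gapped sites; insertions
relative to the reference are invisible). Windowed Tajima's D and Fu & Li's
D* scans then run over reference coordinates.

Tajima's D follows the 1989 constants (a1, a2, b1, b2, c1, c2, e1, e2) and the
beta-distribution approximation for its p-value. Fu & Li's D* is the
no-outgroup statistic driven by the singleton count, with the corrected
n-dependent coefficients in common use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy import stats

from .alignment import PairwiseAlignment
from .core import Haplotype, revcomp, seq_to_array

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 100
DEFAULT_MIN_SITES = 100


@dataclass
class ProjectedAlignment:
    reference: str
    members: list[str]
    positions: np.ndarray  # retained reference positions, strictly increasing
    columns: np.ndarray  # shape (n_positions, n_members), uint8 ASCII

    @property
    def n(self) -> int:
        return len(self.members)

    def slice(self, start: int, end: int) -> np.ndarray:
        mask = (self.positions >= start) & (self.positions < end)
        return self.columns[mask]


@dataclass
class NeutralityWindow:
    ref_start: int
    ref_end: int
    n_sites: int
    S: int
    pi: float | None
    tajima_d: float | None
    fu_li_dstar: float | None
    flags: list[str] = field(default_factory=list)


def project_multiple_alignment(
    reference: Haplotype,
    member_alignments: dict[str, PairwiseAlignment],
    member_seqs: dict[str, str],
) -> ProjectedAlignment:
    """Project members onto reference positions aligned in *every* pairwise
    alignment (reference must be sequence A of each alignment)."""
    ref_len = len(reference.seq)
    names = sorted(member_alignments)
    missing = [m for m in names if m not in member_seqs]
    if missing:
        raise ValueError(f"missing member sequence(s): {', '.join(missing)}")
    matrix = np.zeros((ref_len, len(names) + 1), dtype=np.uint8)
    matrix[:, 0] = seq_to_array(reference.seq)
    for idx, name in enumerate(names, start=1):
        aln = member_alignments[name]
        for blk in aln.blocks:
            seq_b = member_seqs[name]
            sb = seq_to_array(seq_b if blk.strand == "+" else revcomp(seq_b))
            for op, n, a, b in blk.walk():
                if op in ("M", "X"):
                    matrix[a : a + n, idx] = sb[b : b + n]
    keep = (matrix > 0).all(axis=1)
    return ProjectedAlignment(
        reference=reference.name,
        members=[reference.name] + names,
        positions=np.nonzero(keep)[0],
        columns=matrix[keep],
    )


# ---------------------------------------------------------------------------
# per-column machinery


def _allele_counts(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per column: number of distinct alleles, pairwise-difference count and
    singleton-allele count."""
    n = columns.shape[1]
    counts = np.stack(
        [(columns == ord(b)).sum(axis=1) for b in "ACGT"], axis=1
    )  # (L, 4)
    n_alleles = (counts > 0).sum(axis=1)
    same_pairs = (counts * (counts - 1) // 2).sum(axis=1)
    diff_pairs = n * (n - 1) // 2 - same_pairs
    singletons = (counts == 1).sum(axis=1)
    segregating = n_alleles > 1
    singletons = np.where(segregating, singletons, 0)
    return n_alleles, diff_pairs, singletons


def nucleotide_diversity(columns: np.ndarray) -> float | None:
    """Per-site pi: average pairwise difference fraction, averaged over columns."""
    if columns.shape[0] == 0:
        return None
    n = columns.shape[1]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    _, diff_pairs, _ = _allele_counts(columns)
    total_pairs = n * (n - 1) / 2
    return float(diff_pairs.sum() / total_pairs / columns.shape[0])


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_pvalue(D: float, n: int, const: dict[str, float]) -> float:
    """Two-sided p under the beta-distribution approximation."""
    a1, e2 = const["a1"], const["e2"]
    dmin = (2.0 / n - 1.0 / a1) / sqrt(e2)
    if n % 2 == 0:
        dmax = (n / (2.0 * (n - 1)) - 1.0 / a1) / sqrt(e2)
    else:
        dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / sqrt(e2)
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


def tajimas_D(columns: np.ndarray) -> tuple[float | None, float | None]:
    """Tajima's D and its beta-approximation p-value.

    ``None`` when there are no segregating sites (excluded from window
    averages by callers).
    """
    n = columns.shape[1]
    if n < 4:
        raise ValueError("need >= 4 sequences for Tajima's D")
    n_alleles, diff_pairs, _ = _allele_counts(columns)
    S = int((n_alleles > 1).sum())
    if S == 0:
        return None, None
    total_pairs = n * (n - 1) / 2
    pi_total = float(diff_pairs.sum() / total_pairs)  # mean pairwise differences
    const = _tajima_constants(n)
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    D = (pi_total - S / const["a1"]) / sqrt(var)
    return D, _tajima_pvalue(D, n, const)


def fu_li_Dstar(columns: np.ndarray) -> float | None:
    """Fu & Li's D* (no outgroup) from total mutations and singleton count."""
    n = columns.shape[1]
    if n < 4:
        raise ValueError("need >= 4 sequences for Fu & Li's D*")
    n_alleles, _, singletons = _allele_counts(columns)
    eta = int((n_alleles - 1).clip(min=0).sum())  # total mutations
    eta_s = int(singletons.sum())
    if eta == 0:
        return None
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2.0) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
    )
    nr = n / (n - 1.0)
    v = (nr**2 * bn + an**2 * dn - 2.0 * n * an * (an + 1) / (n - 1) ** 2) / (
        an**2 + bn
    )
    u = nr * (an - nr) - v
    return float((nr * eta - an * eta_s) / sqrt(u * eta + v * eta**2))


def sliding_windows(
    proj: ProjectedAlignment,
    ref_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[NeutralityWindow]:
    """Windowed pi / Tajima's D / Fu & Li's D* over reference coordinates."""
    out = []
    compute_d = proj.n >= 4
    for start in range(0, max(ref_length - window, 0) + 1, step):
        cols = proj.slice(start, start + window)
        flags = []
        n_sites = cols.shape[0]
        if n_sites < min_sites:
            flags.append("low_coverage")
        pi = nucleotide_diversity(cols) if n_sites else None
        if compute_d and n_sites:
            D, _p = tajimas_D(cols)
            dstar = fu_li_Dstar(cols)
        else:
            D = dstar = None
        if n_sites and D is None:
            flags.append("no_segregating_sites")
        S = 0
        if n_sites:
            n_alleles, _, _ = _allele_counts(cols)
            S = int((n_alleles > 1).sum())
        out.append(
            NeutralityWindow(
                ref_start=start,
                ref_end=start + window,
                n_sites=n_sites,
                S=S,
                pi=pi,
                tajima_d=D,
                fu_li_dstar=dstar,
                flags=flags,
            )
        )
    return out


def mean_windowed(values: list[float | None]) -> float | None:
    """Mean over defined window values (undefined windows excluded)."""
    defined = [v for v in values if v is not None]
    if not defined:
        return None
    return float(np.mean(defined))


def compare_groups_pi(
    values_a: list[float], values_b: list[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on windowed diversity values.

    Exact enumeration when both groups have n <= 8; normal approximation with
    tie correction otherwise. All-tied input yields p = 1.
    """
    if not values_a or not values_b:
        raise ValueError("both groups must be nonempty")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def plot_tajima_scan(
    windows: list[NeutralityWindow], path, title: str | None = None
) -> None:
    """Plot windowed Tajima's D along the reference (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [w.ref_start + (w.ref_end - w.ref_start) / 2 for w in windows]
    ds = [w.tajima_d for w in windows]
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(
        [x for x, d in zip(xs, ds) if d is not None],
        [d for d in ds if d is not None],
        lw=1,
        color="tab:blue",
    )
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("Tajima's D")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
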