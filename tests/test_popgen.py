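"""Neutrality statistics: closed-form oracles, coalescent calibration,
invariances and the Mann-Whitney group comparison."""

import math
from fractions import Fraction as F
from itertools import combinations, permutations

import msprime
import numpy as np
import pytest

from homeokit import pairalign, popgen
from homeokit.core import Haplotype

from conftest import random_dna


def cols_from_strings(rows):
    """Column matrix from equal-length haplotype strings."""
    arr = np.array([[ord(c) for c in r] for r in rows], dtype=np.uint8)
    return arr.T.copy()


# the spec'd worked micro-case: n = 4, 100 columns, pairwise differences
# {AB:1, AC:1, AD:0, BC:2, BD:1, CD:1}; S = 2 segregating sites
MICRO = cols_from_strings(
    [
        "C" + "A" + "A" * 98,
        "A" + "A" + "A" * 98,
        "C" + "C" + "A" * 98,
        "C" + "A" + "A" * 98,
    ]
)


def tajima_constants_oracle(n):
    """Independent transcription of the 1989 constants, in exact rationals."""
    a1 = sum((F(1, i) for i in range(1, n)), F(0))
    a2 = sum((F(1, i * i) for i in range(1, n)), F(0))
    b1 = F(n + 1, 3 * (n - 1))
    b2 = F(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - F(n + 2, 1) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


def tajima_oracle(columns):
    n = columns.shape[1]
    npairs = n * (n - 1) // 2
    diffs = 0
    S = 0
    for col in columns:
        if len(set(col)) > 1:
            S += 1
        diffs += sum(1 for a, b in combinations(col, 2) if a != b)
    a1, e1, e2 = tajima_constants_oracle(n)
    k_hat = F(diffs, npairs)
    return float(k_hat - S / a1) / math.sqrt(float(e1 * S + e2 * S * (S - 1)))


class TestPi:
    def test_two_sequences_two_differences(self):
        cols = cols_from_strings(["AC" + "A" * 98, "CA" + "A" * 98])
        assert popgen.nucleotide_diversity(cols) == pytest.approx(0.02)

    def test_identical_sequences_zero(self):
        cols = cols_from_strings(["ACGT" * 25] * 3)
        assert popgen.nucleotide_diversity(cols) == 0.0

    def test_four_sequence_pairwise_enumeration(self):
        # diffs sum to 6 over 6 pairs and 100 columns -> pi = 0.01
        assert popgen.nucleotide_diversity(MICRO) == pytest.approx(0.01)

    def test_zero_columns_undefined(self):
        assert popgen.nucleotide_diversity(np.zeros((0, 4), dtype=np.uint8)) is None


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        cols = cols_from_strings(["A" * 50] * 4)
        assert popgen.tajimas_D(cols) == (None, None)

    def test_worked_micro_case(self):
        D, p = popgen.tajimas_D(MICRO)
        assert D == pytest.approx(-0.710, abs=1e-3)
        assert D == pytest.approx(tajima_oracle(MICRO), abs=1e-9)
        assert 0 < p <= 1

    def test_matches_oracle_on_exhaustive_micro_cases(self):
        """All n=4 column assignments over <= 4 sites, alphabet {A, C}."""
        checked = 0
        for pattern in range(1, 2**4):
            rows = ["".join("AC"[(pattern >> s) & 1] for s in range(4)) for _ in range(4)]
            # make row r differ at site r when the pattern bit is set
            rows = []
            for r in range(4):
                rows.append(
                    "".join(
                        "C" if ((pattern >> s) & 1 and s == r) else "A"
                        for s in range(4)
                    )
                )
            cols = cols_from_strings([row + "A" * 20 for row in rows])
            D, _ = popgen.tajimas_D(cols)
            assert D == pytest.approx(tajima_oracle(cols), abs=1e-9)
            checked += 1
        assert checked == 15

    def test_invariant_under_relabeling(self, rng):
        cols = cols_from_strings(
            [random_dna(rng, 30) for _ in range(5)]
        )
        base, _ = popgen.tajimas_D(cols)
        perm = rng.permutation(5)
        shuffled, _ = popgen.tajimas_D(cols[:, perm])
        assert shuffled == pytest.approx(base, abs=1e-12)

    def test_consistency_with_nucleotide_diversity(self, rng):
        cols = cols_from_strings([random_dna(rng, 200) for _ in range(4)])
        n = 4
        npairs = n * (n - 1) / 2
        _, diff_pairs, _ = popgen._allele_counts(cols)
        pi_total = diff_pairs.sum() / npairs
        assert pi_total / cols.shape[0] == pytest.approx(
            popgen.nucleotide_diversity(cols)
        )


class TestFuLiDstar:
    def test_no_segregating_sites_undefined(self):
        assert popgen.fu_li_Dstar(cols_from_strings(["A" * 30] * 4)) is None

    def test_single_singleton_matches_transcription(self):
        cols = cols_from_strings(["C" + "A" * 99] + ["A" * 100] * 3)
        n, eta, eta_s = 4, 1, 1
        an = sum(1.0 / i for i in range(1, n))
        bn = sum(1.0 / i**2 for i in range(1, n))
        an1 = an + 1.0 / n
        cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
        dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
            1.5 - (2 * an1 - 3) / (n - 2) - 1 / n
        )
        v = (
            (n / (n - 1)) ** 2 * bn
            + an**2 * dn
            - 2 * n * an * (an + 1) / (n - 1) ** 2
        ) / (an**2 + bn)
        u = n / (n - 1) * (an - n / (n - 1)) - v
        expected = (n / (n - 1) * eta - an * eta_s) / math.sqrt(u * eta + v * eta**2)
        assert popgen.fu_li_Dstar(cols) == pytest.approx(expected, abs=1e-12)

    def test_coalescent_mean_near_zero(self):
        """Under the neutral coalescent the expected D* is ~0; 80 replicates."""
        vals = []
        for rep in range(80):
            ts = msprime.sim_ancestry(
                samples=3, ploidy=2, sequence_length=2e4,
                recombination_rate=0, random_seed=rep + 1,
            )
            mts = msprime.sim_mutations(ts, rate=5e-5, random_seed=rep + 1000)
            G = mts.genotype_matrix()
            if G.shape[0] < 2:
                continue
            cols = np.where(G > 0, ord("C"), ord("A")).astype(np.uint8)
            d = popgen.fu_li_Dstar(cols)
            if d is not None:
                vals.append(d)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 0.05


class TestSlidingWindows:
    def make_proj(self, rows, ref_len=None):
        cols = cols_from_strings(rows)
        return popgen.ProjectedAlignment(
            reference="r",
            members=[f"h{i}" for i in range(len(rows))],
            positions=np.arange(cols.shape[0]),
            columns=cols,
        )

    def test_window_count_five_kb(self, rng):
        proj = self.make_proj([random_dna(rng, 5000) for _ in range(4)])
        windows = popgen.sliding_windows(proj, 5000, window=1000, step=100)
        assert len(windows) == 41
        assert windows[0].ref_start == 0
        assert windows[-1].ref_start == 4000

    def test_monomorphic_region_all_undefined(self):
        proj = self.make_proj(["A" * 3000] * 4)
        windows = popgen.sliding_windows(proj, 3000, window=1000, step=500)
        assert all(w.tajima_d is None for w in windows)
        assert all("no_segregating_sites" in w.flags for w in windows)

    def test_uniform_polymorphism_gives_stable_d(self, rng):
        rows = []
        base = random_dna(rng, 8000)
        for _ in range(5):
            row = list(base)
            pos = rng.choice(8000, 80, replace=False)
            for p in pos:
                row[p] = rng.choice([c for c in "ACGT" if c != row[p]])
            rows.append("".join(row))
        proj = self.make_proj(rows)
        windows = popgen.sliding_windows(proj, 8000, window=1000, step=500)
        vals = [w.tajima_d for w in windows if w.tajima_d is not None]
        assert len(vals) > 5
        assert np.std(vals) < 0.5


class TestProjection:
    def test_identical_members_retain_all_positions(self, rng):
        seq = random_dna(rng, 3000)
        ref = Haplotype("ref", seq)
        alns = {
            "m1": pairalign.align(ref, Haplotype("m1", seq)),
            "m2": pairalign.align(ref, Haplotype("m2", seq)),
        }
        proj = popgen.project_multiple_alignment(
            ref, alns, {"m1": seq, "m2": seq}
        )
        assert len(proj.positions) == 3000
        assert popgen.nucleotide_diversity(proj.columns) == 0.0

    def test_member_deletion_drops_reference_columns(self, rng):
        seq = random_dna(rng, 6000)
        deleted = seq[:2000] + seq[3000:]
        ref = Haplotype("ref", seq)
        alns = {"m1": pairalign.align(ref, Haplotype("m1", deleted))}
        proj = popgen.project_multiple_alignment(ref, alns, {"m1": deleted})
        inside = (proj.positions >= 2050) & (proj.positions < 2950)
        assert inside.sum() == 0

    def test_missing_member_sequence_raises(self, rng):
        seq = random_dna(rng, 1000)
        ref = Haplotype("ref", seq)
        alns = {"m1": pairalign.align(ref, Haplotype("m1", seq))}
        with pytest.raises(ValueError, match="m1"):
            popgen.project_multiple_alignment(ref, alns, {})


class TestMannWhitney:
    def test_exact_enumeration_small_case(self):
        u, p = popgen.compare_groups_pi([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_exact_matches_full_permutation(self):
        a, b = [0.1, 0.5, 0.9, 1.3], [0.2, 0.7, 1.5]
        pooled = a + b
        n_a = len(a)

        def u_stat(group_a, group_b):
            return sum(
                1.0 if x > y else 0.5 if x == y else 0.0
                for x in group_a for y in group_b
            )

        observed = u_stat(a, b)
        count = total = 0
        for idx in combinations(range(len(pooled)), n_a):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
            u = u_stat(ga, gb)
            mu = n_a * len(gb) / 2
            if abs(u - mu) >= abs(observed - mu) - 1e-12:
                count += 1
            total += 1
        _, p = popgen.compare_groups_pi(a, b)
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_identical_groups_p_one(self):
        _, p = popgen.compare_groups_pi([2.0] * 5, [2.0] * 5)
        assert p == 1.0

    def test_detects_two_fold_diversity_difference(self, rng):
        a = rng.poisson(5, 100) / 1000
        b = rng.poisson(10, 100) / 1000
        _, p = popgen.compare_groups_pi(list(a), list(b))
        assert p < 0.01
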