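"""Molecular evolution: K2P, codon alignment, NG86 Ka/Ks, Fisher test and
allele grouping, each against an independent oracle."""

import math
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom
from Bio.Data import CodonTable

from homeokit import molevol as me

from conftest import random_dna

TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(TABLE.stop_codons)
SENSE = sorted(set(TABLE.forward_table) - STOPS)


class TestK2P:
    def test_identical_sequences(self):
        d = me.k2p_distance("ACGTACGT", "ACGTACGT")
        assert (d.P, d.Q, d.k) == (0.0, 0.0, 0.0)

    def test_closed_form_p_q_point_one(self):
        # 10 sites: 1 transition, 1 transversion -> P = Q = 0.1
        d = me.k2p_distance("A" * 10, "G" + "C" + "A" * 8)
        expected = -0.5 * math.log(1 - 0.2 - 0.1) - 0.25 * math.log(1 - 0.2)
        assert d.k == pytest.approx(expected, abs=1e-12)
        assert d.k == pytest.approx(0.23412, abs=5e-6)

    def test_saturation_flagged(self):
        # 2P + Q >= 1
        d = me.k2p_distance("AAAA", "GGGC")
        assert d.saturated and d.k is None

    def test_ambiguity_codes_skipped(self):
        d = me.k2p_distance("ANGT", "AAGT")
        assert d.n_sites == 3 and d.k == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_identity_iff_zero(self, seed):
        rng = np.random.default_rng(seed)
        a = random_dna(rng, 60)
        b = random_dna(rng, 60)
        d_ab = me.k2p_distance(a, b)
        d_ba = me.k2p_distance(b, a)
        assert d_ab.P == d_ba.P and d_ab.Q == d_ba.Q and d_ab.k == d_ba.k
        if d_ab.k == 0.0:
            assert a == b


class TestDivergenceTime:
    def test_zero_and_forced_arithmetic(self):
        assert me.divergence_time(0.0) == 0.0
        assert me.divergence_time(0.026, 1.3e-8) == pytest.approx(1.0e6)

    def test_scales_inversely_with_rate(self):
        assert me.divergence_time(0.01, 0.65e-8) == pytest.approx(
            2 * me.divergence_time(0.01, 1.3e-8)
        )

    def test_saturated_distance_propagates(self):
        assert me.divergence_time(None) is None


class TestCodonAlign:
    def test_identical_cds_identity_alignment(self):
        cds = "ATG" + "AAA" * 12 + "TAA"
        aln = me.codon_align(cds, cds)
        assert all(a == b for a, b in aln.pairs)

    def test_protein_gap_becomes_codon_gap(self):
        cds_a = "ATG" + "AAA" * 12 + "TAA"
        cds_b = "ATG" + "AAA" * 11 + "TAA"
        aln = me.codon_align(cds_a, cds_b)
        gaps = [(a, b) for a, b in aln.pairs if a is None or b is None]
        assert len(gaps) == 1
        assert gaps[0][1] is None  # B is the shorter sequence

    def test_inconsistent_protein_alignment_rejected(self):
        cds_a = "ATG" + "AAA" * 12 + "TAA"
        cds_b = "ATG" + "CCC" * 12 + "TAA"
        rows = ("M" + "K" * 12, "M" + "K" * 12)  # claims B is poly-Lys; it is not
        with pytest.raises(ValueError, match="codon"):
            me.codon_align(cds_a, cds_b, protein_aln=rows)

    def test_internal_stop_rejected_with_index(self):
        cds = "ATG" + "AAA" * 3 + "TAA" + "AAA" * 3 + "TAA"
        with pytest.raises(ValueError, match="codon 4"):
            me.codon_align(cds, cds)


def site_counts_oracle(codon):
    """Brute-force synonymous-site count of one codon (stop targets count
    as nonsynonymous)."""
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut not in STOPS and TABLE.forward_table[mut] == TABLE.forward_table[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def diff_counts_oracle(ca, cb):
    """Pathway-averaged Sd/Nd with stop-free pathways preferred."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diffs):
        cur, sd, nd, bad = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                bad = True
            if cur not in STOPS and nxt not in STOPS and (
                TABLE.forward_table[cur] == TABLE.forward_table[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, bad))
    ok = [(s, n) for s, n, bad in results if not bad] or [
        (s, n) for s, n, _ in results
    ]
    return (
        sum(s for s, _ in ok) / len(ok),
        sum(n for _, n in ok) / len(ok),
    )


class TestKaKs:
    def pad(self, codons_a, codons_b, n=12):
        filler = ["GGG"] * n
        return "".join(codons_a + filler), "".join(codons_b + filler)

    def test_identical_cds_zero_rates(self):
        cds = "".join(SENSE[:15])
        res = me.kaks(me.codon_align(cds, cds))
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None

    def test_lysine_synonymous_change(self):
        a, b = self.pad(["AAA"], ["AAG"])
        res = me.kaks(me.codon_align(a, b))
        assert res.Sd == pytest.approx(1.0)
        assert res.Nd == pytest.approx(0.0)

    def test_site_counting_matches_codon_table_enumeration(self):
        for codon in SENSE:
            assert me._codon_sites(codon) == pytest.approx(site_counts_oracle(codon))

    def test_pathway_counting_matches_enumeration(self, rng):
        for _ in range(200):
            ca, cb = rng.choice(SENSE, 2)
            assert me._pair_differences(ca, cb) == pytest.approx(
                diff_counts_oracle(ca, cb)
            )

    def test_site_conservation_n_plus_s(self, rng):
        codons = list(rng.choice(SENSE, 40))
        cds = "".join(codons)
        res = me.kaks(me.codon_align(cds, cds))
        assert res.N + res.S == pytest.approx(3 * res.n_codons, abs=1e-9)

    def test_neutral_simulation_ratio_near_one(self, rng):
        """Codon-symmetric mutation should give Ka/Ks ~ 1 (NG86)."""
        ratios = []
        for _ in range(50):
            codons = []
            while len(codons) < 200:
                c = "".join(rng.choice(list("ACGT"), 3))
                if c not in STOPS:
                    codons.append(c)
            cds = "".join(codons)
            mutant = list(cds)
            for p in rng.choice(len(mutant), int(0.05 * len(mutant)), replace=False):
                for alt in rng.permutation([x for x in "ACGT" if x != mutant[p]]):
                    old = mutant[p]
                    mutant[p] = alt
                    ci = p // 3 * 3
                    if "".join(mutant[ci : ci + 3]) in STOPS:
                        mutant[p] = old
                        continue
                    break
            res = me.kaks(me.codon_align(cds, "".join(mutant)))
            if res.ratio is not None:
                ratios.append(res.ratio)
        assert 0.8 <= np.mean(ratios) <= 1.2

    def test_internal_stop_raises(self):
        a = "".join(SENSE[:12])
        b = a[:3] + "TAA" + a[6:]
        with pytest.raises(ValueError, match="stop"):
            me.codon_align(a, b)


def fisher_oracle(table):
    """Two-sided Fisher exact by direct hypergeometric summation."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_balanced_table_p_one(self):
        # Sd/S == Nd/N exactly
        assert me.kaks_fisher(5, 50, 10, 100) == pytest.approx(1.0)

    def test_against_hypergeometric_summation(self):
        p = me.kaks_fisher(5, 100, 0, 300)
        assert p == pytest.approx(fisher_oracle([[5, 95], [0, 300]]), abs=1e-9)

    def test_row_swap_symmetry(self):
        assert me.kaks_fisher(3, 40, 9, 60) == pytest.approx(
            me.kaks_fisher(9, 60, 3, 40)
        )

    def test_zero_margin_p_one(self):
        assert me.kaks_fisher(0, 0, 5, 50) == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            me.kaks_fisher(5, 3, 0, 10)


def brute_force_groups(names, times, threshold):
    """All maximal cliques of size >= 3 by subset enumeration."""
    def is_clique(subset):
        return all(
            times[tuple(sorted((a, b)))] < threshold
            for a, b in combinations(subset, 2)
        )

    cliques = [
        set(sub)
        for r in range(3, len(names) + 1)
        for sub in combinations(names, r)
        if is_clique(sub)
    ]
    return sorted(
        sorted(c) for c in cliques
        if not any(c < other for other in cliques)
    )


class TestAlleleGrouping:
    def make_alleles(self, rng, n_groups=2, per_group=3, d_within=0.002, d_between=0.05):
        base = []
        while len(base) < 220:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in STOPS:
                base.append(c)
        cds = "".join(base)

        def mutate(seq, rate):
            out = list(seq)
            for p in rng.choice(len(out), int(rate * len(out)), replace=False):
                for alt in rng.permutation([x for x in "ACGT" if x != out[p]]):
                    old = out[p]
                    out[p] = alt
                    ci = p // 3 * 3
                    if "".join(out[ci : ci + 3]) in STOPS:
                        out[p] = old
                        continue
                    break
            return "".join(out)

        alleles = {}
        for g in range(n_groups):
            ancestor = mutate(cds, d_between) if g else cds
            for i in range(per_group):
                alleles[f"sp{g}_{i}"] = mutate(ancestor, d_within)
        return alleles

    def test_identical_alleles_single_group(self):
        cds = "".join(SENSE[:20])
        res = me.allele_grouping({"a": cds, "b": cds, "c": cds, "d": cds})
        assert res.t_max == 0.0
        assert res.groups == [["a", "b", "c", "d"]]
        assert res.ungrouped == []

    def test_two_species_panel_recovers_species_labels(self, rng):
        """Within-species divergence << between: two clean groups."""
        alleles = self.make_alleles(rng)
        res = me.allele_grouping(alleles, metric="k2p")
        groups = {frozenset(g) for g in res.groups}
        assert frozenset(["sp0_0", "sp0_1", "sp0_2"]) in groups
        assert frozenset(["sp1_0", "sp1_1", "sp1_2"]) in groups

    def test_groups_match_brute_force_cliques(self, rng):
        alleles = self.make_alleles(rng, n_groups=3, per_group=3, d_within=0.01)
        res = me.allele_grouping(alleles, metric="k2p")
        times = {
            tuple(sorted(k)): (v if v is not None else float("inf"))
            for k, v in res.times.items()
        }
        expected = brute_force_groups(sorted(alleles), times, res.threshold)
        assert sorted(res.groups) == expected

    def test_invariant_under_allele_reordering(self, rng):
        alleles = self.make_alleles(rng)
        res1 = me.allele_grouping(alleles, metric="k2p")
        shuffled = dict(reversed(list(alleles.items())))
        res2 = me.allele_grouping(shuffled, metric="k2p")
        assert sorted(res1.groups) == sorted(res2.groups)
        assert res1.most_divergent == res2.most_divergent

    def test_fewer_than_three_alleles_rejected(self):
        cds = "".join(SENSE[:15])
        with pytest.raises(ValueError):
            me.allele_grouping({"a": cds, "b": cds})
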