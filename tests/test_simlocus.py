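"""Simulator: determinism, composition targets and planted-feature truth."""

import numpy as np
import pytest
from Bio.Seq import Seq

from homeokit import io, simlocus as sl
from homeokit.core import gc_fraction

from conftest import small_study


@pytest.fixture(scope="module")
def template():
    return sl.small_template(4)


@pytest.fixture(scope="module")
def ancestor(template):
    return sl.simulate_ancestor(template, seed=11)


class TestAncestor:
    def test_deterministic_under_fixed_seed(self, template, tmp_path):
        a = sl.simulate_ancestor(template, seed=3)
        b = sl.simulate_ancestor(template, seed=3)
        io.write_bundle([a], {}, tmp_path / "x")
        io.write_bundle([b], {}, tmp_path / "y")
        assert (tmp_path / "x" / "haplotypes.fasta").read_bytes() == (
            tmp_path / "y" / "haplotypes.fasta"
        ).read_bytes()
        assert (tmp_path / "x" / "annotations.gff3").read_bytes() == (
            tmp_path / "y" / "annotations.gff3"
        ).read_bytes()

    def test_gc_within_two_points_of_target(self, template, ancestor):
        assert 0.43 <= gc_fraction(ancestor.seq) <= 0.47

    def test_gene_features_in_template_order(self, ancestor, template):
        assert [g.gene_id for g in ancestor.genes] == [
            g.gene_id for g in template.genes
        ]
        starts = [g.start for g in ancestor.genes]
        assert starts == sorted(starts)

    def test_coding_sequences_are_complete_orfs(self, ancestor):
        for g in ancestor.genes:
            prot = str(Seq(g.cds(ancestor.seq)).translate())
            assert prot.startswith("M")
            assert prot.endswith("*")
            assert "*" not in prot[:-1]

    def test_infeasible_template_rejected(self):
        bad = sl.LocusTemplate(
            genes=[sl.GeneSpec("g1", "+", [301], [])],  # not a codon multiple
            intergenic_lengths=[100, 100],
        )
        with pytest.raises(ValueError, match="multiple of 3"):
            sl.simulate_ancestor(bad, seed=0)


class TestEvolve:
    def test_zero_rates_give_identical_child(self, ancestor):
        cfg = sl.SimulationConfig(indel_rate=0.0)
        child, rec = sl.evolve_haplotype(ancestor, 0.0, cfg, seed=5)
        assert child.seq == ancestor.seq
        assert len(rec.sub_positions_parent) == 0

    def test_mismatch_fraction_matches_requested_divergence(self, ancestor):
        """Truth-position (alignment-free) binomial check at d = 1.3 %."""
        d = 0.013
        cfg = sl.SimulationConfig(indel_rate=0.0)
        total_subs = 0
        total_sites = 0
        for seed in range(10):
            child, rec = sl.evolve_haplotype(ancestor, d, cfg, seed=seed)
            total_subs += len(rec.sub_positions_parent)
            total_sites += len(ancestor.seq)
        p_hat = total_subs / total_sites
        se = np.sqrt(d * (1 - d) / total_sites)
        assert abs(p_hat - d) < 3 * se

    def test_ts_tv_ratio_recovered(self, ancestor):
        cfg = sl.SimulationConfig(ts_tv_ratio=2.0, indel_rate=0.0)
        ts = tv = 0
        for seed in range(10):
            _, rec = sl.evolve_haplotype(ancestor, 0.02, cfg, seed=100 + seed)
            ts += rec.n_transitions
            tv += rec.n_transversions
        assert 1.6 <= ts / tv <= 2.4

    def test_coordinate_map_preserves_untouched_bases(self, ancestor):
        cfg = sl.SimulationConfig()
        child, rec = sl.evolve_haplotype(ancestor, 0.01, cfg, seed=9)
        mutated = set(rec.sub_positions_parent.tolist())
        kept = np.nonzero(rec.p2c >= 0)[0][::257]
        for p in kept:
            if p not in mutated:
                assert child.seq[rec.p2c[p]] == ancestor.seq[p]

    def test_no_nonsense_substitutions(self, ancestor):
        cfg = sl.SimulationConfig(indel_rate=0.0)
        child, _ = sl.evolve_haplotype(ancestor, 0.05, cfg, seed=2)
        for g in child.genes:
            prot = str(Seq(g.cds(child.seq)).translate())
            assert "*" not in prot[:-1]


class TestLTRInsertion:
    def test_zero_age_gives_identical_ltrs_and_exact_tsd(self, ancestor):
        hap, truth = sl.insert_ltr_element(
            ancestor, position=500, age_years=0.0, ltr_length=400,
            tsd_length=5, rate_r=1.3e-8, seed=1,
        )
        te = hap.tes[-1]
        assert hap.seq[te.ltr5[0] : te.ltr5[1]] == hap.seq[te.ltr3[0] : te.ltr3[1]]
        assert (
            hap.seq[te.start - te.tsd_length : te.start]
            == hap.seq[te.end : te.end + te.tsd_length]
        )

    def test_expected_ltr_divergence_is_2rT(self, ancestor):
        """Mean LTR-pair mismatch over 20 replicates within 3 SE of 2rT."""
        rate, age, ltr = 1.3e-8, 1.0e6, 1000
        mism = sites = 0
        for seed in range(20):
            hap, _ = sl.insert_ltr_element(
                ancestor, 500, age, ltr, 5, rate, seed=seed, internal_length=200
            )
            te = hap.tes[-1]
            l5 = hap.seq[te.ltr5[0] : te.ltr5[1]]
            l3 = hap.seq[te.ltr3[0] : te.ltr3[1]]
            mism += sum(1 for a, b in zip(l5, l3) if a != b)
            sites += ltr
        k = 2 * rate * age  # 0.026 expected pair divergence
        se = np.sqrt(k * (1 - k) / sites)
        # 2e-4 allows for same-site double hits that restore identity
        assert abs(mism / sites - k) < 3 * se + 2e-4

    def test_intronic_insertion_leaves_exons_intact(self, ancestor):
        g = ancestor.genes[0]
        intron_pos = g.exons[0][1] + 50  # inside intron 1
        hap, _ = sl.insert_ltr_element(
            ancestor, intron_pos, 1e6, 300, 5, 1.3e-8, seed=4, internal_length=100
        )
        old_cds = g.cds(ancestor.seq)
        new_cds = hap.gene(g.gene_id).cds(hap.seq)
        assert old_cds == new_cds

    def test_exonic_insertion_warns_and_marks_pseudo(self, ancestor):
        g = ancestor.genes[0]
        pos = g.exons[0][0] + 10
        with pytest.warns(UserWarning, match="pseudogenizing"):
            hap, _ = sl.insert_ltr_element(
                ancestor, pos, 0.0, 300, 5, 1.3e-8, seed=4, internal_length=100
            )
        assert hap.gene(g.gene_id).pseudo


class TestMarkerAndRecombinant:
    def test_zero_length_marker_is_noop(self, ancestor):
        panel = [ancestor.copy(name="x", species="A")]
        out, truth = sl.insert_species_marker(panel, "A", ("g01", "g02"), 0, seed=1)
        assert truth is None
        assert out[0].seq == ancestor.seq

    def test_marker_present_in_species_only(self, ancestor):
        a = ancestor.copy(name="a1", species="A")
        b = ancestor.copy(name="b1", species="B")
        out, truth = sl.insert_species_marker([a, b], "A", ("g01", "g02"), 800, seed=1)
        assert len(out[0].seq) == len(ancestor.seq) + 800
        assert out[1].seq == ancestor.seq
        assert set(truth["intervals"]) == {"a1"}

    def test_gene_overlapping_slot_rejected(self, ancestor):
        a = ancestor.copy(name="a1", species="A")
        with pytest.raises(ValueError, match="absent"):
            sl.insert_species_marker([a], "A", ("g01", "nope"), 800, seed=1)

    def test_recombinant_of_identical_parents_is_identity(self, ancestor):
        pa = ancestor.copy(name="pa")
        pb = ancestor.copy(name="pb")
        rec, truth = sl.make_recombinant(pa, pb, ("g02", "g03"), seed=2)
        assert rec.seq == ancestor.seq
        g2, g3 = ancestor.gene("g02"), ancestor.gene("g03")
        assert g2.end <= truth["pos_child"] <= g3.start

    def test_breakpoint_between_last_two_genes_keeps_prefix_alleles(self, ancestor):
        cfg = sl.SimulationConfig(indel_rate=0.0)
        pa, _ = sl.evolve_haplotype(ancestor, 0.02, cfg, seed=5, name="pa")
        pb, _ = sl.evolve_haplotype(ancestor, 0.02, cfg, seed=6, name="pb")
        rec, truth = sl.make_recombinant(pa, pb, ("g03", "g04"), seed=2)
        for gid in ("g01", "g02", "g03"):
            assert rec.gene(gid).cds(rec.seq) == pa.gene(gid).cds(pa.seq)
        assert rec.gene("g04").cds(rec.seq) == pb.gene("g04").cds(pb.seq)

    def test_missing_breakpoint_gene_rejected(self, ancestor):
        pa = ancestor.copy(name="pa")
        pb = sl._delete_genes(ancestor.copy(name="pb"), ("g04",))
        with pytest.raises(ValueError, match="absent"):
            sl.make_recombinant(pa, pb, ("g03", "g04"), seed=2)


class TestStudyBundle:
    def test_fixed_seed_gives_byte_identical_bundle(self, tmp_path):
        for sub in ("one", "two"):
            study = small_study(seed=42)
            io.write_bundle(study.all_haplotypes, study.truth, tmp_path / sub)
        for name in ("haplotypes.fasta", "annotations.gff3", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_bundle_round_trip(self, study, tmp_path):
        io.write_bundle(study.all_haplotypes, study.truth, tmp_path / "b")
        haps, truth = io.read_bundle(tmp_path / "b")
        assert [h.name for h in haps] == [h.name for h in study.all_haplotypes]
        assert [h.seq for h in haps] == [h.seq for h in study.all_haplotypes]
        orig = {h.name: h for h in study.all_haplotypes}
        for h in haps:
            assert [(g.gene_id, g.exons) for g in h.genes] == [
                (g.gene_id, g.exons) for g in orig[h.name].genes
            ]
        assert truth == study.truth

    def test_truth_features_map_to_valid_coordinates(self, study):
        haps = {h.name: h for h in study.all_haplotypes}
        for te in study.truth["tes"]:
            hap = haps[te["haplotype"]]
            ann = next(a for a in hap.tes if a.te_id == te["te_id"])
            assert ann.start == te["position"]
            assert 0 <= ann.start < ann.end <= len(hap.seq)
        marker = study.truth["marker"]
        for name, (s, e) in marker["intervals"].items():
            assert 0 <= s < e <= len(haps[name].seq)
        rec = study.truth["recombinant"]
        assert 0 <= rec["pos_child"] <= len(haps[rec["name"]].seq)

    def test_species_b_lacks_deleted_gene(self, study):
        deleted = study.truth["species_b_deleted_genes"]
        assert deleted
        for h in study.panels["B"]:
            for gid in deleted:
                assert h.gene(gid) is None
        for h in study.panels["A"]:
            for gid in deleted:
                assert h.gene(gid) is not None
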