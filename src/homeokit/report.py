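"""Pipeline orchestration and publication-style report generation.

``run_pipeline`` executes the full comparative analysis — pairwise alignment,
divergence tables, windowed neutrality scans, per-locus allele grouping,
species-origin classification and LTR insertion dating — on either a
simulated bundle or user-supplied FASTA/GFF3, and writes TSV reports plus a
JSON manifest. All randomness flows from the single config seed; rerunning on
the same inputs reproduces the same outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, divstats, io, molevol, origin, popgen, simlocus, tedate
from .core import Haplotype

log = logging.getLogger("homeokit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(config: dict, seed: int | None):
    if "simulate" in config:
        sim = dict(config["simulate"])
        tmpl_kind = sim.pop("template", "default")
        n_genes = sim.pop("n_genes", None)
        if seed is not None:
            sim["seed"] = seed
        known = {f for f in simlocus.SimulationConfig.__dataclass_fields__}
        sim_cfg = simlocus.SimulationConfig(**{k: v for k, v in sim.items() if k in known})
        if tmpl_kind == "small":
            template = simlocus.small_template(n_genes or 4)
        else:
            template = simlocus.default_template(n_genes or 13)
        study = simlocus.simulate_study(sim_cfg, template)
        return study.panels, study.queries, study.truth
    inputs = config["inputs"]
    for key in ("fasta", "panels"):
        if key not in inputs:
            raise ValueError(f"config.inputs missing {key!r}")
    fasta = Path(inputs["fasta"])
    if not fasta.exists():
        raise FileNotFoundError(f"FASTA not found: {fasta}")
    haps = {h.name: h for h in io.read_fasta(fasta)}
    if inputs.get("gff3"):
        gff_path = Path(inputs["gff3"])
        if not gff_path.exists():
            raise FileNotFoundError(f"GFF3 not found: {gff_path}")
        io.attach_annotations(list(haps.values()), io.read_gff3(gff_path))
    elif config.get("require_gff3"):
        raise ValueError("genic context requested but no GFF3 configured")
    panels = {}
    for sp, names in inputs["panels"].items():
        missing = [n for n in names if n not in haps]
        if missing:
            raise ValueError(f"panel {sp}: sequences not in FASTA: {missing}")
        for n in names:
            haps[n].species = sp
        panels[sp] = [haps[n] for n in names]
    queries = [haps[n] for n in inputs.get("queries", [])]
    return panels, queries, None


def _table3(summaries: list[divstats.VariantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "seq_a": s.name_a,
                "seq_b": s.name_b,
                "span_a": f"{s.span_a[0] + 1}-{s.span_a[1]}",
                "span_b": f"{s.span_b[0] + 1}-{s.span_b[1]}",
                "aligned_sequence_bp": s.gapless_length,
                "identity_pct": round(100.0 * s.identity, 2),
                "snp_count": s.snp_count,
                "snp_pct": round(s.snp_pct, 2),
                "mnp_events": s.mnp_event_count,
                "mnp_pct": round(s.mnp_pct, 2),
                "gap_fraction_pct": round(100.0 * s.gap_fraction, 1),
            }
        )
    return pd.DataFrame(rows)


def _table4(
    class_alns: dict[str, list], class_summaries: dict[str, list]
) -> pd.DataFrame:
    rows = []
    pooled = divstats.pooled_species_summary(class_summaries)
    for cls in pooled:
        row = {
            "class": cls.label,
            "aligned_sequence_bp": cls.aligned_bp,
            "snp_count": cls.snp_count,
            "snp_pct": round(cls.snp_pct, 2),
        }
        for stat in divstats.pooled_window_zero_snp(class_alns[cls.label]):
            row[f"sd_{stat.window_size}nt"] = round(stat.sd_of_counts, 2)
            row[f"zero_snp_pct_{stat.window_size}nt"] = round(
                stat.pct_zero_snp_windows, 2
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fig2_matrix(
    panels: dict[str, list[Haplotype]],
    queries: list[Haplotype],
    rate_r: float,
) -> pd.DataFrame:
    """Fig.-2-style matrix: allele x locus cell codes.

    Codes: ``black`` most divergent allele, ``white:<i>`` grouped (group
    index), ``ungrouped``, ``absent``; the locus T_max (My) is carried in a
    trailing row.
    """
    all_haps = [h for hs in panels.values() for h in hs] + list(queries)
    gene_ids: list[str] = []
    for h in all_haps:
        for g in sorted(h.genes, key=lambda g: g.start):
            if g.gene_id not in gene_ids:
                gene_ids.append(g.gene_id)
    matrix: dict[str, dict[str, str]] = {h.name: {} for h in all_haps}
    tmax_row: dict[str, str] = {}
    for gid in sorted(gene_ids):
        alleles = {}
        for h in all_haps:
            cds = origin._clean_cds(h, gid)
            if cds is None:
                matrix[h.name][gid] = "absent"
            else:
                alleles[h.name] = cds
        if len(alleles) < 3:
            for name in alleles:
                matrix[name][gid] = "ungrouped"
            tmax_row[gid] = ""
            continue
        try:
            res = molevol.allele_grouping(alleles, rate_r=rate_r, locus=gid)
        except ValueError:
            for name in alleles:
                matrix[name][gid] = "ungrouped"
            tmax_row[gid] = ""
            continue
        for name in alleles:
            codes = [
                f"white:{i + 1}" for i, grp in enumerate(res.groups) if name in grp
            ]
            matrix[name][gid] = codes[0] if codes else "ungrouped"
        if res.most_divergent:
            matrix[res.most_divergent][gid] = "black"
        tmax_row[gid] = f"{res.t_max:.2f}"
    df = pd.DataFrame(matrix).T
    df.index.name = "allele"
    df.loc["T_max_My"] = pd.Series(tmax_row)
    return df.reset_index()


def _kaks_table(
    panels: dict[str, list[Haplotype]], queries: list[Haplotype]
) -> pd.DataFrame:
    all_haps = [h for hs in panels.values() for h in hs] + list(queries)
    gene_ids = sorted({g.gene_id for h in all_haps for g in h.genes})
    rows = []
    for gid in gene_ids:
        alleles = {
            h.name: cds
            for h in all_haps
            if (cds := origin._clean_cds(h, gid)) is not None
        }
        for a, b in combinations(sorted(alleles), 2):
            try:
                res = molevol.kaks(molevol.codon_align(alleles[a], alleles[b]))
            except ValueError:
                continue
            rows.append(
                {
                    "locus": gid,
                    "allele_a": a,
                    "allele_b": b,
                    "N": round(res.N, 1),
                    "S": round(res.S, 1),
                    "Nd": round(res.Nd, 2),
                    "Sd": round(res.Sd, 2),
                    "Ka": None if res.Ka is None else round(res.Ka, 4),
                    "Ks": None if res.Ks is None else round(res.Ks, 4),
                    "ka_ks": None if res.ratio is None else round(res.ratio, 3),
                    "fisher_p": round(res.fisher_p, 4),
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)


def _neutrality_scan(
    group: list[Haplotype], store: origin.AlignmentStore, window: int, step: int
) -> tuple[pd.DataFrame, list[popgen.NeutralityWindow]]:
    reference = max(group, key=lambda h: (len(h.seq), h.name))
    alns = {
        h.name: store.get(reference, h) for h in group if h.name != reference.name
    }
    seqs = {h.name: h.seq for h in group}
    proj = popgen.project_multiple_alignment(reference, alns, seqs)
    windows = popgen.sliding_windows(proj, len(reference.seq), window, step)
    rows = [
        {
            "ref_start": w.ref_start,
            "n_sites": w.n_sites,
            "S": w.S,
            "pi": None if w.pi is None else round(w.pi, 5),
            "tajima_d": None if w.tajima_d is None else round(w.tajima_d, 4),
            "fu_li_dstar": None if w.fu_li_dstar is None else round(w.fu_li_dstar, 4),
            "flags": ";".join(w.flags),
        }
        for w in windows
    ]
    return pd.DataFrame(rows), windows


def run_pipeline(config: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute align -> divstats -> popgen -> molevol -> origin -> tedate.

    Returns the manifest (also written to ``manifest.json``). Any stage
    failure raises :class:`PipelineError` naming the stage; outputs of earlier
    stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rate_r = config.get("rate_r", molevol.DEFAULT_RATE)
    window = config.get("window", popgen.DEFAULT_WINDOW)
    step = config.get("step", popgen.DEFAULT_STEP)
    manifest: dict = {
        "homeokit_version": __version__,
        "seed": seed if seed is not None else config.get("simulate", {}).get("seed"),
        "parameters": {"rate_r": rate_r, "window": window, "step": step},
        "outputs": {},
    }

    stage = "load"
    try:
        panels, queries, truth = _load_inputs(config, seed)
        if truth is not None:
            io.write_bundle(
                [h for hs in panels.values() for h in hs] + list(queries),
                truth,
                out / "bundle",
            )
            manifest["outputs"]["bundle"] = "bundle/"
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    species = sorted(panels)
    if len(species) != 2:
        raise PipelineError("load", ValueError("exactly two species panels required"))
    sp_a, sp_b = species
    store = origin.AlignmentStore()

    stage = "align+divstats"
    try:
        class_alns: dict[str, list] = {}
        class_summaries: dict[str, list] = {}
        summaries = []
        for label, pairs in (
            (f"within-{sp_a}", list(combinations(panels[sp_a], 2))),
            (f"within-{sp_b}", list(combinations(panels[sp_b], 2))),
            (
                f"{sp_a}-vs-{sp_b}",
                [(a, b) for a in panels[sp_a] for b in panels[sp_b]],
            ),
        ):
            class_alns[label] = []
            class_summaries[label] = []
            for hap_a, hap_b in pairs:
                aln = store.get(hap_a, hap_b)
                summary = divstats.pairwise_variant_summary(aln)
                summaries.append(summary)
                class_alns[label].append(aln)
                class_summaries[label].append(summary)
        _table3(summaries).to_csv(out / "pairwise_summary.tsv", sep="\t", index=False)
        _table4(class_alns, class_summaries).to_csv(
            out / "snp_windows.tsv", sep="\t", index=False
        )
        manifest["outputs"]["pairwise_summary"] = "pairwise_summary.tsv"
        manifest["outputs"]["snp_windows"] = "snp_windows.tsv"
        manifest["gap_fraction_mean_pct"] = round(
            100.0 * float(np.mean([s.gap_fraction for s in summaries])), 1
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "origin"
    calls = []
    try:
        if queries:
            panel_a = origin.SpeciesPanel(sp_a, panels[sp_a])
            panel_b = origin.SpeciesPanel(sp_b, panels[sp_b])
            calls, markers = origin.classify_all(
                panel_a,
                panel_b,
                queries,
                store,
                rate_r=rate_r,
                min_marker_len=config.get("min_marker_len", origin.MARKER_MIN_LEN),
            )
            pd.DataFrame(
                [
                    {
                        "query": c.haplotype,
                        "verdict": c.verdict,
                        "identity_to_" + sp_a: round(c.identity_to_a, 2),
                        "identity_to_" + sp_b: round(c.identity_to_b, 2),
                        "marker_votes": ";".join(
                            f"{mv.marker}={mv.vote}" for mv in c.marker_votes
                        ),
                        "locus_votes": ";".join(
                            f"{v.locus}={v.vote}" for v in c.locus_votes
                        ),
                        "breakpoint_loci": "-".join(c.breakpoint_loci or ()),
                        "breakpoint_interval": (
                            f"{c.breakpoint_interval[0]}-{c.breakpoint_interval[1]}"
                            if c.breakpoint_interval
                            else ""
                        ),
                    }
                    for c in calls
                ]
            ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {
                        "species": m.species,
                        "reference": m.reference,
                        "start": m.start,
                        "end": m.end,
                        "length": m.length,
                        "flanking_genes": "-".join(g or "?" for g in m.flanking_genes),
                        "low_confidence": m.low_confidence,
                    }
                    for m in markers
                ]
            ).to_csv(out / "species_markers.tsv", sep="\t", index=False)
            (out / "origin_evidence.json").write_text(
                json.dumps(
                    [
                        {
                            "query": c.haplotype,
                            "verdict": c.verdict,
                            "marker_votes": [asdict(mv) for mv in c.marker_votes],
                            "identity": [c.identity_to_a, c.identity_to_b],
                            "locus_votes": [asdict(v) for v in c.locus_votes],
                            "breakpoint_loci": c.breakpoint_loci,
                            "breakpoint_interval": c.breakpoint_interval,
                            "notes": c.notes,
                        }
                        for c in calls
                    ],
                    indent=1,
                )
            )
            manifest["outputs"]["origin_calls"] = "origin_calls.tsv"
            manifest["verdicts"] = {c.haplotype: c.verdict for c in calls}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "popgen"
    try:
        group_pis: dict[str, list[float]] = {}
        for sp in (sp_a, sp_b):
            group = list(panels[sp]) + [
                q for q, c in zip(queries, calls) if c.verdict == sp
            ]
            if len(group) < 3:
                log.info("popgen: species %s has < 3 haplotypes; scan skipped", sp)
                continue
            df, windows = _neutrality_scan(group, store, window, step)
            df.to_csv(out / f"neutrality_windows_{sp}.tsv", sep="\t", index=False)
            manifest["outputs"][f"neutrality_windows_{sp}"] = (
                f"neutrality_windows_{sp}.tsv"
            )
            manifest[f"mean_windowed_tajima_d_{sp}"] = popgen.mean_windowed(
                [w.tajima_d for w in windows]
            )
            group_pis[sp] = [w.pi for w in windows if w.pi is not None]
        if len(group_pis) == 2:
            u, p = popgen.compare_groups_pi(group_pis[sp_a], group_pis[sp_b])
            manifest["pi_mannwhitney"] = {"U": u, "p": p}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "molevol"
    try:
        _fig2_matrix(panels, queries, rate_r).to_csv(
            out / "allele_grouping_matrix.tsv", sep="\t", index=False
        )
        _kaks_table(panels, queries).to_csv(
            out / "kaks_pairs.tsv", sep="\t", index=False
        )
        manifest["outputs"]["allele_grouping_matrix"] = "allele_grouping_matrix.tsv"
        manifest["outputs"]["kaks_pairs"] = "kaks_pairs.tsv"
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "tedate"
    try:
        rows = []
        for hap in [h for hs in panels.values() for h in hs] + list(queries):
            for ann, age in tedate.date_all(hap.seq, hap.tes, rate_r):
                if age is None:
                    continue
                rows.append(
                    {
                        "haplotype": hap.name,
                        "te_id": ann.te_id,
                        "family": ann.family or "",
                        "k": None if age.distance.k is None else round(age.distance.k, 5),
                        "P": round(age.distance.P, 5),
                        "Q": round(age.distance.Q, 5),
                        "T_my": None if age.T is None else round(age.T / 1e6, 3),
                        "tsd_intact": age.tsd_intact,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "te_ages.tsv", sep="\t", index=False)
        manifest["outputs"]["te_ages"] = "te_ages.tsv"
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
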