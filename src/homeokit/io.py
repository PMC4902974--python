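"""Readers and writers: FASTA, GFF3, MAF and simulation bundles.

All coordinate-convention conversions live here. Internally everything is
0-based half-open; GFF3 is written 1-based inclusive; MAF follows its own
strand-relative start/size convention (handled by Biopython).
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import AlignmentBlock, PairwiseAlignment, merge_ops
from .core import GeneModel, Haplotype, TEAnnotation, revcomp

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(haplotypes: list[Haplotype], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(h.seq), id=h.name, description=h.species or "")
        for h in haplotypes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> list[Haplotype]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - I/O error path
        raise OSError(f"failed to read FASTA {path}: {exc}") from exc
    haps = []
    for rec in records:
        species = rec.description.split(None, 1)[1] if " " in rec.description else None
        haps.append(Haplotype(name=rec.id, seq=str(rec.seq).upper(), species=species))
    return haps


# ---------------------------------------------------------------------------
# GFF3 (flat gene/exon + TE features; deliberately small — the bundles written
# here only ever contain these feature types)


def write_gff3(haplotypes: list[Haplotype], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for hap in haplotypes:
        lines.append(f"##sequence-region {hap.name} 1 {len(hap.seq)}")
        for g in hap.genes:
            attrs = f"ID={g.gene_id}"
            if g.pseudo:
                attrs += ";pseudo=true"
            lines.append(
                "\t".join(
                    [
                        hap.name, "homeokit", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                    ]
                )
            )
            for i, (s, e) in enumerate(g.exons, 1):
                lines.append(
                    "\t".join(
                        [
                            hap.name, "homeokit", "exon",
                            str(s + 1), str(e), ".", g.strand, ".",
                            f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                        ]
                    )
                )
        for te in hap.tes:
            attrs = f"ID={te.te_id};tsd_length={te.tsd_length}"
            if te.family:
                attrs += f";family={te.family}"
            lines.append(
                "\t".join(
                    [
                        hap.name, "homeokit", "mobile_element",
                        str(te.start + 1), str(te.end), ".", "+", ".", attrs,
                    ]
                )
            )
            for tag, iv in (("five_prime_LTR", te.ltr5), ("three_prime_LTR", te.ltr3)):
                if iv is not None:
                    lines.append(
                        "\t".join(
                            [
                                hap.name, "homeokit", tag,
                                str(iv[0] + 1), str(iv[1]), ".", "+", ".",
                                f"ID={te.te_id}.{tag};Parent={te.te_id}",
                            ]
                        )
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_gff3(path: str | Path) -> dict[str, dict]:
    """Parse a GFF3 into per-sequence gene and TE annotation lists.

    Returns ``{seqid: {"genes": [GeneModel], "tes": [TEAnnotation]}}``.
    """
    per_seq: dict[str, dict] = {}
    genes: dict[tuple[str, str], GeneModel] = {}
    tes: dict[tuple[str, str], TEAnnotation] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        s, e = int(start) - 1, int(end)
        att = _parse_attrs(attrs)
        bucket = per_seq.setdefault(seqid, {"genes": [], "tes": []})
        if ftype == "gene":
            g = GeneModel(
                gene_id=att.get("ID", f"gene{lineno}"),
                strand=strand,
                exons=[],
                pseudo=att.get("pseudo", "").lower() == "true",
            )
            genes[(seqid, g.gene_id)] = g
            bucket["genes"].append(g)
        elif ftype == "exon":
            parent = att.get("Parent")
            key = (seqid, parent)
            if key in genes:
                genes[key].exons.append((s, e))
        elif ftype == "mobile_element":
            te = TEAnnotation(
                te_id=att.get("ID", f"te{lineno}"),
                start=s,
                end=e,
                tsd_length=int(att.get("tsd_length", 0)),
                family=att.get("family"),
            )
            tes[(seqid, te.te_id)] = te
            bucket["tes"].append(te)
        elif ftype in ("five_prime_LTR", "three_prime_LTR"):
            parent = att.get("Parent")
            key = (seqid, parent)
            if key in tes:
                if ftype == "five_prime_LTR":
                    tes[key].ltr5 = (s, e)
                else:
                    tes[key].ltr3 = (s, e)
    for bucket in per_seq.values():
        for g in bucket["genes"]:
            g.exons.sort()
    return per_seq


def attach_annotations(haps: list[Haplotype], gff: dict[str, dict]) -> None:
    for hap in haps:
        if hap.name in gff:
            hap.genes = gff[hap.name]["genes"]
            hap.tes = gff[hap.name]["tes"]


# ---------------------------------------------------------------------------
# MAF


def _aligned_strings(aln: PairwiseAlignment, seq_a: str, seq_b: str, blk) -> tuple[str, str]:
    sa = seq_a
    sb = seq_b if blk.strand == "+" else revcomp(seq_b)
    out_a, out_b = [], []
    for op, n, a, b in blk.walk():
        if op in ("M", "X"):
            out_a.append(sa[a : a + n])
            out_b.append(sb[b : b + n])
        elif op == "A":
            out_a.append(sa[a : a + n])
            out_b.append("-" * n)
        else:
            out_a.append("-" * n)
            out_b.append(sb[b : b + n])
    return "".join(out_a), "".join(out_b)


def export_maf(
    aln: PairwiseAlignment, seq_a: str, seq_b: str, path: str | Path
) -> None:
    """Write the alignment (collinear blocks then inversions) as MAF."""
    msas = []
    for blk in list(aln.blocks) + list(aln.inversions):
        text_a, text_b = _aligned_strings(aln, seq_a, seq_b, blk)
        rec_a = SeqRecord(Seq(text_a), id=aln.name_a)
        rec_a.annotations = {
            "start": blk.a_start,
            "size": blk.a_end - blk.a_start,
            "strand": 1,
            "srcSize": aln.len_a,
        }
        rec_b = SeqRecord(Seq(text_b), id=aln.name_b)
        rec_b.annotations = {
            "start": blk.b_start,
            "size": blk.b_end - blk.b_start,
            "strand": 1 if blk.strand == "+" else -1,
            "srcSize": aln.len_b,
        }
        msas.append(MultipleSeqAlignment([rec_a, rec_b]))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


def import_maf(path: str | Path) -> PairwiseAlignment:
    """Read a two-species MAF into a :class:`PairwiseAlignment`.

    Reverse-strand blocks are kept on the reverse-complement B axis exactly as
    stored in the file; overlapping collinear blocks are rejected.
    """
    try:
        msas = list(AlignIO.parse(str(path), "maf"))
    except Exception as exc:
        raise ValueError(f"failed to parse MAF {path}: {exc}") from exc
    name_a = name_b = None
    len_a = len_b = 0
    blocks: list[AlignmentBlock] = []
    inversions: list[AlignmentBlock] = []
    for msa in msas:
        if len(msa) != 2:
            raise ValueError(f"{path}: MAF block with {len(msa)} rows; need exactly 2")
        rec_a, rec_b = msa[0], msa[1]
        if name_a is None:
            name_a, name_b = rec_a.id, rec_b.id
            len_a = rec_a.annotations["srcSize"]
            len_b = rec_b.annotations["srcSize"]
        text_a, text_b = str(rec_a.seq).upper(), str(rec_b.seq).upper()
        ops = []
        for ca, cb in zip(text_a, text_b):
            if ca == "-" and cb == "-":
                continue
            if ca == "-":
                ops.append(("B", 1))
            elif cb == "-":
                ops.append(("A", 1))
            elif ca == cb:
                ops.append(("M", 1))
            else:
                ops.append(("X", 1))
        strand = "+" if rec_b.annotations["strand"] in (1, "+") else "-"
        blk = AlignmentBlock(
            a_start=rec_a.annotations["start"],
            a_end=rec_a.annotations["start"] + rec_a.annotations["size"],
            b_start=rec_b.annotations["start"],
            b_end=rec_b.annotations["start"] + rec_b.annotations["size"],
            ops=merge_ops(ops),
            strand=strand,
        )
        blk.validate()
        (blocks if strand == "+" else inversions).append(blk)
    blocks.sort(key=lambda b: (b.a_start, b.b_start))
    prev = None
    for blk in blocks:
        if prev is not None and (blk.a_start < prev.a_end or blk.b_start < prev.b_end):
            raise ValueError(
                f"{path}: overlapping MAF blocks at A:[{blk.a_start},{blk.a_end}) "
                f"B:[{blk.b_start},{blk.b_end})"
            )
        prev = blk
    aln = PairwiseAlignment(
        name_a=name_a or "A",
        name_b=name_b or "B",
        len_a=len_a,
        len_b=len_b,
        blocks=blocks,
        inversions=inversions,
    )
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# Simulation bundles (FASTA + GFF3 + truth JSON)


def write_bundle(panel: list[Haplotype], truth: dict, directory: str | Path) -> dict:
    """Write a simulated panel as FASTA + GFF3 + truth JSON; return paths."""
    if not panel:
        raise ValueError("empty panel")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "haplotypes.fasta",
        "gff3": directory / "annotations.gff3",
        "truth": directory / "truth.json",
    }
    write_fasta(panel, paths["fasta"])
    write_gff3(panel, paths["gff3"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def read_bundle(directory: str | Path) -> tuple[list[Haplotype], dict]:
    directory = Path(directory)
    haps = read_fasta(directory / "haplotypes.fasta")
    gff = read_gff3(directory / "annotations.gff3")
    attach_annotations(haps, gff)
    truth = json.loads((directory / "truth.json").read_text())
    return haps, truth
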