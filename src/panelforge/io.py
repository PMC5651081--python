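"""Readers and writers for the external formats the toolkit touches.

VCF goes through pysam, FASTA through Biopython, GFF3 through gffutils.
All tabular sidecars are UTF-8 TSV with a header row.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AnchorEntry,
    AnchorMap,
    CandidateSet,
    CandidateVariant,
    DNA,
    GeneModel,
    GenomeReference,
    GenotypeMatrix,
    ManifestRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> GenomeReference:
    chroms = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id}")
        chroms[rec.id] = str(rec.seq).upper()
    return GenomeReference(chromosomes=chroms)


def write_fasta(reference: GenomeReference, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Candidate variants (VCF + design-score sidecar)

def read_score_sidecar(path) -> dict[str, float]:
    """TSV with columns ``id`` and ``design_score``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "design_score" not in df.columns:
        raise ValueError("score sidecar needs columns: id, design_score")
    return dict(zip(df["id"], df["design_score"].astype(float)))


def _gt_to_call(gt) -> str:
    alleles = [a for a in (gt or ()) if a is not None]
    if not alleles:
        return "missing"
    if all(a == 0 for a in alleles):
        return "RR"
    if all(a == 1 for a in alleles):
        return "AA"
    return "RA"


def read_candidates(vcf_path, score_sidecar=None) -> CandidateSet:
    """Load biallelic SNPs from a VCF; indels and multiallelic records are
    skipped (count kept on the returned list and logged).

    ``score_sidecar`` maps marker id -> design score (a path to the TSV or a
    ready dict).  Records absent from the sidecar are flagged scoreless
    (``design_score is None``) and fall out of every selection filter.
    """
    scores: dict[str, float] = {}
    if score_sidecar is not None:
        scores = (
            score_sidecar
            if isinstance(score_sidecar, dict)
            else read_score_sidecar(score_sidecar)
        )

    out = CandidateSet()
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in DNA
                or alts[0] not in DNA
            ):
                skipped += 1
                continue
            vid = rec.id or f"{rec.chrom}_{rec.pos}"
            calls = tuple(
                _gt_to_call(rec.samples[s].get("GT")) for s in rec.samples
            )
            missing = (
                calls.count("missing") / len(calls) if calls else 0.0
            )
            out.append(
                CandidateVariant(
                    id=vid,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                    calls=calls or None,
                    missing_rate=missing,
                    design_score=scores.get(vid),
                )
            )
    out.n_skipped = skipped
    if skipped:
        logger.info("read_candidates: skipped %d non-biallelic-SNP records", skipped)
    return out


def write_candidates_vcf(candidates: Sequence[CandidateVariant], samples: Sequence[str],
                         contig_lengths: dict[str, int], path) -> None:
    """Write candidates (with per-sample calls) as an uncompressed VCF."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    call_to_gt = {"RR": (0, 0), "AA": (1, 1), "RA": (0, 1), "missing": (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for cv in sorted(candidates, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=cv.chrom, start=cv.pos - 1, stop=cv.pos,
                alleles=(cv.ref, cv.alt), id=cv.id,
            )
            calls = cv.calls or ("missing",) * len(samples)
            for s, call in zip(samples, calls):
                rec.samples[s]["GT"] = call_to_gt[call]
            out.write(rec)


def write_score_sidecar(candidates: Sequence[CandidateVariant], path) -> None:
    rows = [
        {"id": cv.id, "design_score": cv.design_score}
        for cv in candidates
        if cv.design_score is not None
    ]
    pd.DataFrame(rows, columns=["id", "design_score"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (GFF3)

def read_gene_models(gff3_path) -> list[GeneModel]:
    """One GeneModel per mRNA.  Transcripts whose CDS falls outside their
    exons are rejected with a warning rather than raising."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = cds[:]
        try:
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=mrna.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        except ValueError as exc:
            warnings.warn(f"rejecting transcript {mrna.id}: {exc}")
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\tpanelforge\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            tid = f"{m.gene_id}.1"
            fh.write(
                f"{m.chrom}\tpanelforge\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tpanelforge\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.chrom}\tpanelforge\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Manifests

def write_manifest_table(records: Sequence[ManifestRecord], path, rendering="iupac") -> None:
    """TSV with columns marker_id, sequence, allele_a, allele_b."""
    seen = set()
    rows = []
    for rec in records:
        if rec.marker_id in seen:
            raise ValueError(f"duplicate marker_id {rec.marker_id}")
        seen.add(rec.marker_id)
        a, b = sorted(rec.alleles)
        rows.append(
            {
                "marker_id": rec.marker_id,
                "sequence": rec.sequence(rendering),
                "allele_a": a,
                "allele_b": b,
            }
        )
    pd.DataFrame(rows, columns=["marker_id", "sequence", "allele_a", "allele_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest_table(path) -> list[ManifestRecord]:
    """Read a manifest TSV; the polymorphism encoding (bracket or IUPAC) is
    detected per row."""
    from .manifest import alleles_from_iupac

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        seq = row["sequence"].upper()
        if "[" in seq:
            left, rest = seq.split("[", 1)
            mid, right = rest.split("]", 1)
            a, b = mid.split("/")
            rendering = "bracket"
        else:
            if len(seq) != 121:
                raise ValueError(f"{row['marker_id']}: IUPAC sequence must be 121 bases")
            left, code, right = seq[:60], seq[60], seq[61:]
            a, b = alleles_from_iupac(code)
            rendering = "iupac"
        out.append(
            ManifestRecord(
                marker_id=row["marker_id"],
                left_flank=left,
                right_flank=right,
                alleles=(a, b),
                rendering=rendering,
            )
        )
    return out


def write_manifest_fasta(records: Sequence[ManifestRecord], path) -> None:
    """IUPAC-rendered manifest sequences as FASTA alignment queries."""
    seqs = [
        SeqRecord(Seq(rec.sequence("iupac")), id=rec.marker_id, description="")
        for rec in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Genotype matrices, anchor maps, partitions

def read_genotype_matrix(path) -> GenotypeMatrix:
    """TSV: rows = markers, columns = samples, calls AA/AB/BB/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return GenotypeMatrix.from_dataframe(df)


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="marker_id")


def read_anchor_map(path) -> AnchorMap:
    """TSV with columns chrom, marker_id, genetic_pos_cM, physical_pos_bp
    and optionally physical_chrom."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker_id": str})
    entries: dict[str, list[AnchorEntry]] = {}
    for _, row in df.iterrows():
        entries.setdefault(row["chrom"], []).append(
            AnchorEntry(
                marker_id=row["marker_id"],
                genetic_pos=float(row["genetic_pos_cM"]),
                physical_pos=int(row["physical_pos_bp"]),
                physical_chrom=row.get("physical_chrom", row["chrom"]),
            )
        )
    return AnchorMap(entries=entries)


def write_anchor_map(amap: AnchorMap, path) -> None:
    rows = []
    for chrom, items in amap.entries.items():
        for e in items:
            rows.append(
                {
                    "chrom": chrom,
                    "marker_id": e.marker_id,
                    "genetic_pos_cM": e.genetic_pos,
                    "physical_pos_bp": e.physical_pos,
                    "physical_chrom": e.physical_chrom,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
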