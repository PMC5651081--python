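"""Single-effect SNP classifier over gene models.

Each SNP receives exactly one of 17 categories (coding changes, splice
sites, UTRs, intron, up/downstream, intergenic).  When several features or
genes overlap a position, the most severe applicable label wins, with ties
between genes broken by lower gene start then gene id.

Non-coding transcripts (no CDS) contribute only their up/downstream
windows: the category set has no label for non-coding exons, so their
bodies are transparent to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .core import CandidateVariant, EffectClass, GeneModel, GenomeReference, revcomp

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})

# Alternative initiation codons of the standard code; a start codon mutated
# into one of these keeps a (weaker) start.
_ALT_STARTS = {"TTG", "CTG"}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Highest severity first; the reported label is the most severe applicable.
SEVERITY_ORDER = [
    EffectClass.SPLICE_SITE_ACCEPTOR,
    EffectClass.SPLICE_SITE_DONOR,
    EffectClass.STOP_GAINED,
    EffectClass.STOP_LOST,
    EffectClass.START_LOST,
    EffectClass.NON_SYNONYMOUS_START,
    EffectClass.NON_SYNONYMOUS_CODING,
    EffectClass.SYNONYMOUS_STOP,
    EffectClass.START_GAINED,
    EffectClass.SYNONYMOUS_CODING,
    EffectClass.SPLICE_SITE_REGION,
    EffectClass.UTR5,
    EffectClass.UTR3,
    EffectClass.INTRON,
    EffectClass.UPSTREAM,
    EffectClass.DOWNSTREAM,
    EffectClass.INTERGENIC,
]
_SEVERITY_RANK = {label: i for i, label in enumerate(SEVERITY_ORDER)}


def translate_codon(codon: str) -> str:
    """Standard-code translation of one codon; stop codons give '*'."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"cannot translate {codon!r}: need 3 unambiguous bases")
    return _CODON_TABLE[codon]


@dataclass
class EffectConfig:
    """Knobs of the classifier (SnpEff-style conventions).

    ``donor_acceptor_intron_bases`` intronic bases at each intron end that
    count as the splice donor/acceptor site; ``splice_region_intron`` the
    intronic base range (from the exon boundary) of the extended splice
    region; ``splice_region_exon`` its exonic counterpart.
    """

    upstream_window: int = 5000
    downstream_window: int = 5000
    donor_acceptor_intron_bases: int = 2
    splice_region_intron: tuple[int, int] = (3, 8)
    splice_region_exon: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.upstream_window <= 0 or self.downstream_window <= 0:
            raise ValueError("up/downstream windows must be positive")
        for lo, hi in (self.splice_region_intron, self.splice_region_exon):
            if lo < 1 or hi < lo:
                raise ValueError("invalid splice region range")


@dataclass
class EffectAnnotation:
    effect: EffectClass
    gene_id: Optional[str] = None


class EffectAnnotator:
    """Bulk classifier; caches spliced-CDS context per transcript."""

    def __init__(
        self,
        gene_models: Sequence[GeneModel],
        reference: GenomeReference,
        config: Optional[EffectConfig] = None,
    ):
        self.config = config or EffectConfig()
        self.reference = reference
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in gene_models:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for genes in self.by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.gene_id))
        self._cds_cache: dict[int, tuple[str, dict[int, int]]] = {}

    # -- CDS context -------------------------------------------------------

    def _cds_context(self, gene: GeneModel) -> tuple[str, dict[int, int]]:
        """Spliced CDS in transcription order and genomic pos -> CDS index."""
        key = id(gene)
        if key not in self._cds_cache:
            parts = []
            pos_to_idx: dict[int, int] = {}
            off = 0
            for s, e in gene.cds:
                parts.append(self.reference.fetch(gene.chrom, s, e))
                for p in range(s, e + 1):
                    pos_to_idx[p] = off + (p - s)
                off += e - s + 1
            seq = "".join(parts)
            if gene.strand == "-":
                n = len(seq)
                seq = revcomp(seq)
                pos_to_idx = {p: n - 1 - i for p, i in pos_to_idx.items()}
            self._cds_cache[key] = (seq, pos_to_idx)
        return self._cds_cache[key]

    # -- per-gene label sets ----------------------------------------------

    def _coding_label(self, gene: GeneModel, pos: int, alt: str) -> EffectClass:
        cds_seq, pos_to_idx = self._cds_context(gene)
        idx = pos_to_idx[pos]
        alt_t = alt if gene.strand == "+" else _COMP[alt]
        codon_i, within = divmod(idx, 3)
        ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
        if len(ref_codon) < 3:  # trailing partial codon in a malformed model
            return EffectClass.NON_SYNONYMOUS_CODING
        alt_codon = ref_codon[:within] + alt_t + ref_codon[within + 1 :]
        if codon_i == 0 and ref_codon == "ATG":
            if alt_codon in _ALT_STARTS:
                return EffectClass.NON_SYNONYMOUS_START
            return EffectClass.START_LOST
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        if aa_ref == "*":
            return EffectClass.SYNONYMOUS_STOP if aa_alt == "*" else EffectClass.STOP_LOST
        if aa_alt == "*":
            return EffectClass.STOP_GAINED
        if aa_ref == aa_alt:
            return EffectClass.SYNONYMOUS_CODING
        return EffectClass.NON_SYNONYMOUS_CODING

    def _start_gained(self, gene: GeneModel, pos: int, alt: str) -> bool:
        """Does the alternate allele create an ATG in the transcript reading
        direction (frame-agnostic scan of the genomic sequence)?"""
        chrom_len = self.reference.lengths[gene.chrom]
        for off in range(3):
            if gene.strand == "+":
                lo, hi = pos - off, pos - off + 2
                if lo < 1 or hi > chrom_len:
                    continue
                ref_trip = self.reference.fetch(gene.chrom, lo, hi)
                alt_trip = ref_trip[:off] + alt + ref_trip[off + 1 :]
            else:
                lo, hi = pos + off - 2, pos + off
                if lo < 1 or hi > chrom_len:
                    continue
                ref_trip = revcomp(self.reference.fetch(gene.chrom, lo, hi))
                alt_trip = ref_trip[:off] + _COMP[alt] + ref_trip[off + 1 :]
            if alt_trip == "ATG" and ref_trip != "ATG":
                return True
        return False

    def _gene_labels(self, gene: GeneModel, pos: int, alt: str) -> list[EffectClass]:
        cfg = self.config
        if pos < gene.start or pos > gene.end:
            dist = gene.start - pos if pos < gene.start else pos - gene.end
            before = pos < gene.start  # genomically left of the gene
            if before == (gene.strand == "+"):
                return [EffectClass.UPSTREAM] if dist <= cfg.upstream_window else []
            return [EffectClass.DOWNSTREAM] if dist <= cfg.downstream_window else []

        if not gene.coding:
            return []  # non-coding bodies are transparent (see module docstring)

        labels: list[EffectClass] = []
        exon = next(((s, e) for s, e in gene.exons if s <= pos <= e), None)

        if exon is None:
            # intronic: distances from the flanking exon boundaries
            prev_end = max(e for _, e in gene.exons if e < pos)
            next_start = min(s for s, _ in gene.exons if s > pos)
            d_left = pos - prev_end  # 1 = first intron base right of an exon
            d_right = next_start - pos
            d_donor, d_acceptor = (
                (d_left, d_right) if gene.strand == "+" else (d_right, d_left)
            )
            if d_donor <= cfg.donor_acceptor_intron_bases:
                labels.append(EffectClass.SPLICE_SITE_DONOR)
            if d_acceptor <= cfg.donor_acceptor_intron_bases:
                labels.append(EffectClass.SPLICE_SITE_ACCEPTOR)
            lo, hi = cfg.splice_region_intron
            if lo <= d_left <= hi or lo <= d_right <= hi:
                labels.append(EffectClass.SPLICE_SITE_REGION)
            labels.append(EffectClass.INTRON)
            return labels

        # exonic splice region: first/last exon bases next to an intron
        s, e = exon
        lo, hi = cfg.splice_region_exon
        if s != gene.start and lo <= pos - s + 1 <= hi:
            labels.append(EffectClass.SPLICE_SITE_REGION)
        if e != gene.end and lo <= e - pos + 1 <= hi:
            labels.append(EffectClass.SPLICE_SITE_REGION)

        if any(cs <= pos <= ce for cs, ce in gene.cds):
            labels.append(self._coding_label(gene, pos, alt))
        else:
            cds_lo, cds_hi = gene.cds_span
            left_of_cds = pos < cds_lo
            is_utr5 = left_of_cds == (gene.strand == "+")
            if is_utr5:
                labels.append(EffectClass.UTR5)
                if self._start_gained(gene, pos, alt):
                    labels.append(EffectClass.START_GAINED)
            else:
                labels.append(EffectClass.UTR3)
        return labels

    # -- public ------------------------------------------------------------

    def annotate(self, variant: CandidateVariant) -> EffectAnnotation:
        best: Optional[tuple[int, int, str, EffectClass]] = None
        for gene in self.by_chrom.get(variant.chrom, []):
            labels = self._gene_labels(gene, variant.pos, variant.alt)
            if not labels:
                continue
            top = min(labels, key=_SEVERITY_RANK.__getitem__)
            key = (_SEVERITY_RANK[top], gene.start, gene.gene_id, top)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            return EffectAnnotation(EffectClass.INTERGENIC, None)
        return EffectAnnotation(best[3], best[2])


def annotate_effect(
    variant: CandidateVariant,
    gene_models: Sequence[GeneModel],
    reference: GenomeReference,
    config: Optional[EffectConfig] = None,
) -> EffectAnnotation:
    """Classify one SNP.  For bulk work build an :class:`EffectAnnotator`
    once and reuse it (the CDS context cache matters)."""
    return EffectAnnotator(gene_models, reference, config).annotate(variant)


def annotate_variants(
    variants: Sequence[CandidateVariant],
    gene_models: Sequence[GeneModel],
    reference: GenomeReference,
    config: Optional[EffectConfig] = None,
) -> Sequence[CandidateVariant]:
    """Annotate in place: sets ``effect`` and, when genic, ``gene_id``."""
    annotator = EffectAnnotator(gene_models, reference, config)
    for v in variants:
        ann = annotator.annotate(v)
        v.effect = ann.effect
        if ann.gene_id is not None:
            v.gene_id = ann.gene_id
    return variants


def effect_spectrum(variants: Sequence) -> dict[EffectClass, float]:
    """Percentage of annotated variants per category, rounded to 2 decimals
    (so the column sums to 100 up to rounding)."""
    labels = []
    for v in variants:
        label = v.effect if isinstance(v, CandidateVariant) else v
        if label is None:
            continue
        labels.append(EffectClass(label))
    if not labels:
        raise ValueError("effect_spectrum: no annotated variants")
    n = len(labels)
    out: dict[EffectClass, float] = {}
    for label in labels:
        out[label] = out.get(label, 0) + 1
    return {label: round(100.0 * count / n, 2) for label, count in out.items()}
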