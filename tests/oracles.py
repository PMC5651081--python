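"""Independent brute-force oracles used by the test suite.

These re-derive expected results by direct enumeration or explicit
arithmetic, structured differently from the library code they check.
"""

from __future__ import annotations

from fractions import Fraction

from panelforge.core import EffectClass, revcomp
from panelforge.effects import EffectConfig, translate_codon

_SEVERITY = [
    "splice_site_acceptor", "splice_site_donor", "stop_gained", "stop_lost",
    "start_lost", "non_synonymous_start", "non_synonymous_coding",
    "synonymous_stop", "start_gained", "synonymous_coding",
    "splice_site_region", "utr5", "utr3", "intron", "upstream", "downstream",
    "intergenic",
]
_RANK = {name: i for i, name in enumerate(_SEVERITY)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def largest_remainder_quota(spans, budget):
    """Exact rational apportionment of ``budget`` over ``spans`` (ordered),
    remainder ties broken by list order."""
    total = sum(Fraction(s) for s in spans)
    shares = [Fraction(budget) * Fraction(s) / total for s in spans]
    floors = [int(sh) for sh in shares]
    remainders = [(sh - fl, -i) for i, (sh, fl) in enumerate(zip(shares, floors))]
    leftover = budget - sum(floors)
    for _, neg_i in sorted(remainders, reverse=True)[:leftover]:
        floors[-neg_i] += 1
    return floors


# ---------------------------------------------------------------------------
# effect classification by per-position enumeration


def _spliced_cds(gene, reference):
    seq = "".join(reference.fetch(gene.chrom, s, e) for s, e in gene.cds)
    return seq if gene.strand == "+" else revcomp(seq)


def _cds_index(gene, pos):
    off = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            idx = off + (pos - s)
            total = sum(e2 - s2 + 1 for s2, e2 in gene.cds)
            return idx if gene.strand == "+" else total - 1 - idx
        off += e - s + 1
    return None


def _coding_label(gene, reference, pos, alt):
    cds = _spliced_cds(gene, reference)
    idx = _cds_index(gene, pos)
    base = alt if gene.strand == "+" else _COMP[alt]
    ci, off = divmod(idx, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]
    if len(ref_codon) < 3:
        return "non_synonymous_coding"
    alt_codon = ref_codon[:off] + base + ref_codon[off + 1 :]
    if ci == 0 and ref_codon == "ATG":
        return "non_synonymous_start" if alt_codon in ("TTG", "CTG") else "start_lost"
    aa_r, aa_a = translate_codon(ref_codon), translate_codon(alt_codon)
    if aa_r == "*":
        return "synonymous_stop" if aa_a == "*" else "stop_lost"
    if aa_a == "*":
        return "stop_gained"
    return "synonymous_coding" if aa_r == aa_a else "non_synonymous_coding"


def _start_gained(gene, reference, pos, alt):
    length = reference.lengths[gene.chrom]
    for off in range(3):
        if gene.strand == "+":
            lo, hi = pos - off, pos - off + 2
            if lo < 1 or hi > length:
                continue
            trip = reference.fetch(gene.chrom, lo, hi)
            mut = trip[:off] + alt + trip[off + 1 :]
        else:
            lo, hi = pos + off - 2, pos + off
            if lo < 1 or hi > length:
                continue
            trip = revcomp(reference.fetch(gene.chrom, lo, hi))
            mut = trip[:off] + _COMP[alt] + trip[off + 1 :]
        if mut == "ATG" and trip != "ATG":
            return True
    return False


def _labels_for_gene(gene, reference, pos, alt, cfg: EffectConfig):
    labels = set()
    if pos < gene.start or pos > gene.end:
        d = gene.start - pos if pos < gene.start else pos - gene.end
        left = pos < gene.start
        if (left and gene.strand == "+") or (not left and gene.strand == "-"):
            if d <= cfg.upstream_window:
                labels.add("upstream")
        else:
            if d <= cfg.downstream_window:
                labels.add("downstream")
        return labels
    if not gene.coding:
        return labels

    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if not in_exon:
        labels.add("intron")
        prev_end = max(e for _, e in gene.exons if e < pos)
        next_start = min(s for s, _ in gene.exons if s > pos)
        d_left, d_right = pos - prev_end, next_start - pos
        dd, da = (d_left, d_right) if gene.strand == "+" else (d_right, d_left)
        if dd <= cfg.donor_acceptor_intron_bases:
            labels.add("splice_site_donor")
        if da <= cfg.donor_acceptor_intron_bases:
            labels.add("splice_site_acceptor")
        lo, hi = cfg.splice_region_intron
        if lo <= d_left <= hi or lo <= d_right <= hi:
            labels.add("splice_site_region")
        return labels

    s, e = next((s, e) for s, e in gene.exons if s <= pos <= e)
    lo, hi = cfg.splice_region_exon
    if s != gene.start and lo <= pos - s + 1 <= hi:
        labels.add("splice_site_region")
    if e != gene.end and lo <= e - pos + 1 <= hi:
        labels.add("splice_site_region")
    if any(cs <= pos <= ce for cs, ce in gene.cds):
        labels.add(_coding_label(gene, reference, pos, alt))
    else:
        cds_lo, cds_hi = gene.cds_span
        if (pos < cds_lo) == (gene.strand == "+"):
            labels.add("utr5")
            if _start_gained(gene, reference, pos, alt):
                labels.add("start_gained")
        else:
            labels.add("utr3")
    return labels


def effect_oracle(pos, alt, chrom, genes, reference, cfg=None):
    """Most severe applicable label over all genes (ties: lower gene start,
    then gene id), or intergenic."""
    cfg = cfg or EffectConfig()
    best = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        labels = _labels_for_gene(gene, reference, pos, alt, cfg)
        if not labels:
            continue
        top = min(labels, key=_RANK.__getitem__)
        key = (_RANK[top], gene.start, gene.gene_id)
        if best is None or key < best[0]:
            best = (key, top, gene.gene_id)
    if best is None:
        return EffectClass.INTERGENIC, None
    return EffectClass(best[1]), best[2]
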