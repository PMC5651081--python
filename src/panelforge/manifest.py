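"""Manifest (probe-design sequence) construction and polymorphism encoding.

A manifest is the SNP base plus 60 bp of flanking reference sequence either
side.  Manifests are always emitted on the forward strand of the reference;
legacy markers keep their historic orientation as metadata.
"""

from __future__ import annotations

from .core import DNA, GenomeReference, ManifestRecord

# Two-base IUPAC ambiguity codes.
IUPAC_BY_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
PAIR_BY_IUPAC = {code: pair for pair, code in IUPAC_BY_PAIR.items()}

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def iupac_code(allele_a: str, allele_b: str) -> str:
    """The unique IUPAC ambiguity character for two distinct bases
    (order-insensitive): R=A/G, Y=C/T, W=A/T, S=C/G, K=G/T, M=A/C."""
    pair = frozenset((allele_a.upper(), allele_b.upper()))
    if len(pair) != 2 or not pair <= DNA:
        raise ValueError(f"need two distinct A/C/G/T alleles, got {allele_a}/{allele_b}")
    return IUPAC_BY_PAIR[pair]


def alleles_from_iupac(code: str) -> tuple[str, str]:
    """Invert :func:`iupac_code`; alleles returned in alphabetical order."""
    try:
        pair = PAIR_BY_IUPAC[code.upper()]
    except KeyError:
        raise ValueError(f"{code!r} is not a two-base IUPAC ambiguity code") from None
    a, b = sorted(pair)
    return a, b


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for purine<->purine / pyrimidine<->pyrimidine pairs
    (A/G, C/T), 'transversion' otherwise."""
    pair = frozenset((ref.upper(), alt.upper()))
    if len(pair) != 2 or not pair <= DNA:
        raise ValueError(f"need two distinct A/C/G/T alleles, got {ref}/{alt}")
    return "transition" if pair in TRANSITIONS else "transversion"


def build_manifest(
    reference: GenomeReference,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    flank: int = 60,
    marker_id: str | None = None,
) -> ManifestRecord:
    """Extract the manifest for a SNP at ``pos`` (1-based).

    Fails if the reference base at ``pos`` is not ``ref`` or if fewer than
    ``flank`` bases remain on either side (probes need full context; SNPs
    too close to a chromosome end are rejected, never padded).
    """
    length = reference.lengths[chrom]
    if pos - flank < 1 or pos + flank > length:
        raise ValueError(
            f"insufficient flank: {chrom}:{pos} needs {flank} bp each side "
            f"within 1-{length}"
        )
    genome_base = reference.base(chrom, pos)
    if genome_base != ref.upper():
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: genome has "
            f"{genome_base}, ref given as {ref}"
        )
    return ManifestRecord(
        marker_id=marker_id or f"{chrom}_{pos}",
        left_flank=reference.fetch(chrom, pos - flank, pos - 1),
        right_flank=reference.fetch(chrom, pos + 1, pos + flank),
        alleles=(ref.upper(), alt.upper()),
    )
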