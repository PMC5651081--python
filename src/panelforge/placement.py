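"""Best-hit marker placement and cross-set redundancy removal.

Placement of a legacy marker on an assembly keeps hits with >= 95%
identity, picks the unique top bit score (rounded to 1 decimal, the
precision alignment tools report), calls markers with tied top scores
"ambiguously mappable", and cross-validates mapped markers against an
independent variant catalog: a marker is validated when the catalog holds
a SNP at the predicted position with the same unordered, strand-normalised
allele pair.

Redundancy between a new manifest set and a legacy set is declared when
the best hit between the two (IUPAC-encoded) manifests reaches >= 98%
query coverage and >= 95% identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alignment import AlignmentHit, KmerAligner
from .core import ManifestRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: 1-based index of the SNP base in an IUPAC-rendered 121-base manifest.
SNP_QUERY_INDEX = 61


def _normalise_pair(alleles: Iterable[str]) -> frozenset:
    return frozenset(a.upper() for a in alleles)


def _complement_pair(pair: frozenset) -> frozenset:
    return frozenset(_COMP[a] for a in pair)


@dataclass
class VariantCatalog:
    """(chrom, pos) -> allele pair from an independent call set."""

    entries: dict[tuple[str, int], frozenset]

    @classmethod
    def from_variants(cls, variants) -> "VariantCatalog":
        entries = {}
        for v in variants:
            key = (v.chrom, v.pos)
            if key in entries:
                raise ValueError(f"duplicate catalog entry at {key}")
            entries[key] = _normalise_pair((v.ref, v.alt))
        return cls(entries=entries)

    def matches(self, chrom: str, pos: int, alleles: Iterable[str]) -> bool:
        """Unordered, strand-normalised allele-pair match at (chrom, pos)."""
        got = self.entries.get((chrom, pos))
        if got is None:
            return False
        want = _normalise_pair(alleles)
        return got == want or got == _complement_pair(want)


@dataclass
class PlacementResult:
    marker_id: str
    status: str  # mapped_validated | mapped_unvalidated | ambiguous | unmapped
    locations: list[tuple[str, int]] = field(default_factory=list)
    matched_polymorphism: bool = False

    def __post_init__(self) -> None:
        n = len(self.locations)
        if self.status.startswith("mapped") and n != 1:
            raise ValueError(f"{self.marker_id}: mapped status needs exactly 1 location")
        if self.status == "ambiguous" and n < 2:
            raise ValueError(f"{self.marker_id}: ambiguous needs >= 2 locations")
        if self.status == "unmapped" and n != 0:
            raise ValueError(f"{self.marker_id}: unmapped must carry no location")


def predicted_snp_position(hit: AlignmentHit, snp_index: int = SNP_QUERY_INDEX) -> Optional[int]:
    """Subject coordinate aligned opposite the query's SNP base, or None
    when the aligned segment excludes it."""
    if not (hit.query_start <= snp_index <= hit.query_end):
        return None
    if hit.strand == "+":
        return hit.subject_start + (snp_index - hit.query_start)
    return hit.subject_start + (hit.query_end - snp_index)


def place_marker(
    hits: Sequence[AlignmentHit],
    catalog: Optional[VariantCatalog],
    expected_alleles: Iterable[str],
    min_ident: float = 95.0,
    marker_id: Optional[str] = None,
    snp_index: int = SNP_QUERY_INDEX,
) -> PlacementResult:
    """Resolve one marker's hits to a placement status.

    Hits below ``min_ident`` identity, and hits whose aligned segment does
    not cover the SNP base (no position could be predicted), are discarded.
    A unique top bit score (1-decimal precision) maps the marker; ties make
    it ambiguous with all tied locations exported.
    """
    marker_id = marker_id or (hits[0].query_id if hits else "marker")
    usable = []
    for h in hits:
        if h.identity_pct < min_ident:
            continue
        pos = predicted_snp_position(h, snp_index)
        if pos is None:
            continue
        usable.append((round(h.bit_score, 1), h, pos))
    if not usable:
        return PlacementResult(marker_id=marker_id, status="unmapped")
    usable.sort(key=lambda t: (-t[0], t[1].subject_id, t[2]))
    top_bits = usable[0][0]
    tied = [(h.subject_id, pos) for bits, h, pos in usable if bits == top_bits]
    if len(tied) > 1:
        # drop exact duplicate locations before declaring a tie
        uniq = sorted(set(tied))
        if len(uniq) > 1:
            return PlacementResult(marker_id=marker_id, status="ambiguous", locations=uniq)
        tied = uniq
    chrom, pos = tied[0]
    matched = catalog.matches(chrom, pos, expected_alleles) if catalog else False
    status = "mapped_validated" if matched else "mapped_unvalidated"
    return PlacementResult(
        marker_id=marker_id, status=status, locations=[(chrom, pos)],
        matched_polymorphism=matched,
    )


def place_markers(
    records: Sequence[ManifestRecord],
    aligner: KmerAligner,
    catalog: Optional[VariantCatalog] = None,
    min_ident: float = 95.0,
    max_subjects: int = 3,
    max_hsps_per_subject: int = 3,
) -> list[PlacementResult]:
    """Align each manifest (IUPAC rendering) against the indexed assembly
    and resolve its placement."""
    out = []
    for rec in records:
        hits = aligner.align(
            rec.sequence("iupac"),
            query_id=rec.marker_id,
            max_subjects=max_subjects,
            max_hsps_per_subject=max_hsps_per_subject,
        )
        out.append(
            place_marker(
                hits, catalog, rec.alleles, min_ident=min_ident, marker_id=rec.marker_id
            )
        )
    return out


def find_duplicates(
    new_manifests: Sequence[ManifestRecord],
    legacy_manifests: Sequence[ManifestRecord],
    min_qcov: float = 98.0,
    min_ident: float = 95.0,
) -> set[tuple[str, str]]:
    """(legacy_id, new_id) pairs whose manifests are effectively the same
    assay.  Legacy manifests are the queries (coverage is computed on the
    query side); the new set is the subject database.  Thresholds are
    inclusive."""
    if not new_manifests or not legacy_manifests:
        return set()
    db = {rec.marker_id: rec.sequence("iupac") for rec in new_manifests}
    aligner = KmerAligner(db)
    pairs: set[tuple[str, str]] = set()
    for legacy in legacy_manifests:
        hits = aligner.align(legacy.sequence("iupac"), query_id=legacy.marker_id)
        if not hits:
            continue
        best = hits[0]
        if best.query_coverage_pct >= min_qcov and best.identity_pct >= min_ident:
            pairs.add((legacy.marker_id, best.subject_id))
    return pairs


def duplicate_new_ids(pairs: set[tuple[str, str]]) -> set[str]:
    """New-set members flagged for removal from the design."""
    return {new_id for _, new_id in pairs}


@dataclass
class PlacementSummary:
    counts: dict[str, int]
    mappable_pct: float
    validated_pct: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts(cls, mapped: int, total: int, validated: int = 0,
                    ambiguous: int = 0) -> "PlacementSummary":
        if not 0 <= validated <= mapped <= total:
            raise ValueError("need 0 <= validated <= mapped <= total")
        counts = {
            "mapped_validated": validated,
            "mapped_unvalidated": mapped - validated,
            "ambiguous": ambiguous,
            "unmapped": total - mapped - ambiguous,
        }
        mappable = round(100.0 * mapped / total, 1) if total else 0.0
        validated_pct = round(100.0 * validated / mapped, 1) if mapped else 0.0
        return cls(counts=counts, mappable_pct=mappable, validated_pct=validated_pct)


def placement_summary(results: Sequence[PlacementResult]) -> PlacementSummary:
    """Counts and the headline percentages: mappable = mapped / total,
    validated = validated / mapped (1 decimal)."""
    if not results:
        raise ValueError("placement_summary: no results")
    counts = {k: 0 for k in ("mapped_validated", "mapped_unvalidated", "ambiguous", "unmapped")}
    for r in results:
        counts[r.status] += 1
    mapped = counts["mapped_validated"] + counts["mapped_unvalidated"]
    total = len(results)
    return PlacementSummary(
        counts=counts,
        mappable_pct=round(100.0 * mapped / total, 1),
        validated_pct=round(100.0 * counts["mapped_validated"] / mapped, 1) if mapped else 0.0,
    )


def placement_table(results: Sequence[PlacementResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.locations:
            for chrom, pos in r.locations:
                rows.append({"marker_id": r.marker_id, "status": r.status,
                             "chrom": chrom, "pos": pos,
                             "matched": r.matched_polymorphism})
        else:
            rows.append({"marker_id": r.marker_id, "status": r.status,
                         "chrom": "", "pos": "", "matched": False})
    return pd.DataFrame(rows, columns=["marker_id", "status", "chrom", "pos", "matched"])
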