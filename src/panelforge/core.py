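"""Domain types shared across the toolkit.

Coordinate convention: every position exposed at a public interface is
1-based inclusive (the VCF/GFF3 dialect).  Slicing helpers convert to
Python's 0-based half-open internally; the conversion never leaks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

# Per-sample genotype call alphabets.  Candidate variants use reference /
# alternate bookkeeping (RR, AA, RA); array call matrices use cluster labels
# (AA, BB, AB).  "missing" / "NA" denote no-calls.
CANDIDATE_CALLS = ("RR", "AA", "RA", "missing")
MATRIX_CALLS = ("AA", "BB", "AB", "NA")

DNA = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYKMWSNacgtrykmwsn", "TGCAYRMKWSNtgcayrmkwsn")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class EffectClass(str, enum.Enum):
    """The 17 single-effect categories assigned to array SNPs."""

    INTRON = "intron"
    DOWNSTREAM = "downstream"
    UPSTREAM = "upstream"
    UTR3 = "utr3"
    UTR5 = "utr5"
    SYNONYMOUS_CODING = "synonymous_coding"
    NON_SYNONYMOUS_CODING = "non_synonymous_coding"
    SPLICE_SITE_REGION = "splice_site_region"
    START_GAINED = "start_gained"
    INTERGENIC = "intergenic"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    SPLICE_SITE_ACCEPTOR = "splice_site_acceptor"
    SPLICE_SITE_DONOR = "splice_site_donor"
    SYNONYMOUS_STOP = "synonymous_stop"
    START_LOST = "start_lost"
    NON_SYNONYMOUS_START = "non_synonymous_start"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class CandidateVariant:
    """One biallelic SNP considered for inclusion on the array.

    ``design_score`` is the assay-design tool's predicted convertibility in
    [0, 1]; ``None`` marks a scoreless record, which every selection filter
    drops.  ``missing_rate`` is the fraction of samples without a genotype
    call at this site.
    """

    id: str
    chrom: str
    pos: int  # 1-based position of the variant base
    ref: str
    alt: str
    calls: Optional[tuple[str, ...]] = None
    missing_rate: float = 0.0
    design_score: Optional[float] = None
    gene_id: Optional[str] = None
    effect: Optional[EffectClass] = None

    def __post_init__(self) -> None:
        if self.ref not in DNA or self.alt not in DNA:
            raise ValueError(f"{self.id}: alleles must be A/C/G/T, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical ({self.ref})")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.id}: missing_rate {self.missing_rate} outside [0, 1]")
        if self.design_score is not None and not 0.0 <= self.design_score <= 1.0:
            raise ValueError(f"{self.id}: design_score {self.design_score} outside [0, 1]")
        if self.calls is not None:
            bad = set(self.calls) - set(CANDIDATE_CALLS)
            if bad:
                raise ValueError(f"{self.id}: unknown calls {sorted(bad)}")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.ref, self.alt))


class CandidateSet(list):
    """A list of :class:`CandidateVariant` that remembers how many input
    records were skipped (indels, multiallelic sites)."""

    def __init__(self, items: Sequence[CandidateVariant] = (), n_skipped: int = 0):
        super().__init__(items)
        self.n_skipped = n_skipped


@dataclass
class GenomeReference:
    """Chromosome name -> uppercase sequence, with length bookkeeping."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        self.chromosomes = {name: seq.upper() for name, seq in self.chromosomes.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        seq = self.chromosomes[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"{chrom}:{start}-{end} outside 1-{len(seq)}")
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


@dataclass
class GeneModel:
    """One transcript: sorted non-overlapping exons, CDS segments, and the
    UTRs derived from exon-minus-CDS on the strand-appropriate side."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end before start")
            prev_end = e
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"{self.gene_id}: CDS segment {s}-{e} outside exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]

    def _utr(self, five_prime: bool) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        lo, hi = self.cds_span
        # genomic-left UTR is 5' on + strand, 3' on -
        want_left = five_prime == (self.strand == "+")
        out = []
        for s, e in self.exons:
            if want_left and s < lo:
                out.append((s, min(e, lo - 1)))
            elif not want_left and e > hi:
                out.append((max(s, hi + 1), e))
        return out

    @property
    def utr5(self) -> list[tuple[int, int]]:
        return self._utr(five_prime=True)

    @property
    def utr3(self) -> list[tuple[int, int]]:
        return self._utr(five_prime=False)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ManifestRecord:
    """Probe-design sequence for one marker: the SNP base plus 60 bp of
    flanking sequence on each side, with the polymorphism encoded either as
    an IUPAC ambiguity character (121-base sequence) or in bracket notation
    ``...[A/G]...`` (125 characters)."""

    marker_id: str
    left_flank: str
    right_flank: str
    alleles: tuple[str, str]
    rendering: str = "iupac"
    strand: str = "+"  # historic probe orientation, kept as metadata

    def __post_init__(self) -> None:
        self.left_flank = self.left_flank.upper()
        self.right_flank = self.right_flank.upper()
        a, b = self.alleles
        if a == b or a not in DNA or b not in DNA:
            raise ValueError(f"{self.marker_id}: bad allele pair {self.alleles}")
        if len(self.left_flank) != 60 or len(self.right_flank) != 60:
            raise ValueError(
                f"{self.marker_id}: flanks must be 60 bases "
                f"(got {len(self.left_flank)}/{len(self.right_flank)})"
            )
        if self.rendering not in {"iupac", "bracket"}:
            raise ValueError(f"{self.marker_id}: rendering must be iupac or bracket")

    def sequence(self, rendering: Optional[str] = None) -> str:
        from .manifest import iupac_code  # local import avoids a cycle

        rendering = rendering or self.rendering
        a, b = sorted(self.alleles)
        if rendering == "iupac":
            middle = iupac_code(a, b)
        elif rendering == "bracket":
            middle = f"[{a}/{b}]"
        else:
            raise ValueError(f"unknown rendering {rendering!r}")
        return self.left_flank + middle + self.right_flank


@dataclass
class GenotypeMatrix:
    """Rectangular samples x markers call table with the array alphabet
    {AA, BB, AB, NA}."""

    samples: list[str]
    markers: list[str]
    calls: dict  # (sample, marker) -> call

    @classmethod
    def from_dataframe(cls, df) -> "GenotypeMatrix":
        """Build from a pandas DataFrame with markers as rows, samples as
        columns (the on-disk TSV layout)."""
        import pandas as pd

        df = df.fillna("NA").astype(str)
        bad = set(df.values.ravel()) - set(MATRIX_CALLS)
        if bad:
            raise ValueError(f"unknown genotype calls {sorted(bad)}")
        calls = {
            (sample, marker): df.at[marker, sample]
            for marker in df.index
            for sample in df.columns
        }
        return cls(samples=list(df.columns), markers=list(df.index), calls=calls)

    def to_dataframe(self):
        import pandas as pd

        data = {
            sample: [self.calls[(sample, marker)] for marker in self.markers]
            for sample in self.samples
        }
        return pd.DataFrame(data, index=self.markers, columns=self.samples)

    def __post_init__(self) -> None:
        expected = {(s, m) for s in self.samples for m in self.markers}
        if set(self.calls) != expected:
            raise ValueError("genotype matrix is not rectangular")
        bad = set(self.calls.values()) - set(MATRIX_CALLS)
        if bad:
            raise ValueError(f"unknown genotype calls {sorted(bad)}")


@dataclass
class AnchorEntry:
    marker_id: str
    genetic_pos: float  # cM
    physical_pos: int  # bp
    physical_chrom: Optional[str] = None  # set when it differs from the map chromosome


@dataclass
class AnchorMap:
    """Per-chromosome lists of markers with genetic (cM) and physical (bp)
    positions, used for collinearity checks and partition fitting."""

    entries: dict[str, list[AnchorEntry]]

    def __post_init__(self) -> None:
        for chrom, rows in self.entries.items():
            for row in rows:
                if row.genetic_pos < 0:
                    raise ValueError(f"{row.marker_id}: negative genetic position")
                if row.physical_chrom is None:
                    row.physical_chrom = chrom

    def chromosomes(self) -> list[str]:
        return list(self.entries)
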