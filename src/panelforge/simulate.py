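"""Deterministic synthetic fixtures with planted ground truth.

Generates genomes, gene models, candidate variants, legacy marker
manifests and paired call sets whose true properties (zone membership,
qualifying counts, duplicated loci, disagreement rates) are logged, so
every downstream stage can be audited without re-derivation.

A single root seed drives named substreams, one per generator, so adding a
generator never perturbs the draws of another.  Two runs with the same
spec are byte-identical.

What is emulated: the statistical shape of an exome-capture candidate set
(per-SNP design scores and missingness, genic placement, a transition
bias), legacy probe sequences extracted verbatim from the assembly, and
array-vs-sequencing call comparisons with a planted disagreement rate.
What is not: linkage disequilibrium, demography, capture bias, or any
real polymorphism spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CandidateSet,
    CandidateVariant,
    GeneModel,
    GenomeReference,
    GenotypeMatrix,
    ManifestRecord,
    revcomp,
)
from .placement import VariantCatalog
from .selection import ChromosomePartition, ZONE_LABELS

_STREAMS = {
    "reference": 0,
    "legacy_loci": 1,
    "genes": 2,
    "candidates": 3,
    "callsets": 4,
    "array_matrix": 5,
    "anchor_map": 6,
}

# Published 1H zone geometry, used as the template partition: physical
# breakpoints 0/30/60/380/470/560 Mb scaled to the synthetic chromosome
# length, distal genetic spans (40, 7, 18, 66) cM, and a token 3 cM across
# the recombination-poor pericentromere.
_ZONE_FRACTIONS = (0.0, 30 / 560, 60 / 560, 380 / 560, 470 / 560, 1.0)
_ZONE_CM = (40.0, 7.0, 3.0, 18.0, 66.0)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimulationSpec:
    """Study-condition knobs of the generator.

    Defaults give two 500 kb chromosomes partitioned like a scaled barley
    1H, 40 genes per chromosome, 10,000 candidate SNPs over 50 samples,
    200 legacy markers (10% planted at duplicated loci for ambiguity
    tests, 1.7% coinciding with candidate positions, the published
    cross-set overlap scale), a 1.92 transition:transversion odds, and
    call-set disagreement/missing rates at the exome-capture comparison
    scale.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int | Sequence[int] = 500_000
    genes_per_chromosome: int = 40
    gene_length_range: tuple[int, int] = (1500, 4000)
    exon_count_range: tuple[int, int] = (1, 4)
    n_samples: int = 50
    n_candidates: int = 10_000
    genic_fraction: float = 0.85  # exome-capture candidates are mostly genic
    design_score_beta: tuple[float, float] = (7.0, 2.0)
    missing_rate_beta: tuple[float, float] = (1.0, 12.0)
    het_call_rate: float = 0.02
    zone_density: tuple[float, float, float, float, float] = (2.0, 1.0, 1.0, 1.0, 2.0)
    n_legacy: int = 200
    planted_ambiguous_fraction: float = 0.10
    planted_duplicate_fraction: float = 0.017
    callset_disagreement: float = 0.061
    callset_missing: float = 0.02
    ts_tv_odds: float = 1.92
    polymorphic_fraction: float = 0.973

    def __post_init__(self) -> None:
        for name in (
            "planted_ambiguous_fraction",
            "planted_duplicate_fraction",
            "callset_disagreement",
            "callset_missing",
            "het_call_rate",
            "polymorphic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )

    def chrom_names(self) -> list[str]:
        return [f"{i + 1}H" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        names = self.chrom_names()
        if isinstance(self.chromosome_length, int):
            return {n: self.chromosome_length for n in names}
        lengths = list(self.chromosome_length)
        if len(lengths) != len(names):
            raise ValueError("need one chromosome length per chromosome")
        return dict(zip(names, (int(l) for l in lengths)))


@dataclass
class LegacyLocus:
    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ambiguous: bool = False
    copy_chrom: Optional[str] = None
    copy_pos: Optional[int] = None
    duplicate_candidate_id: Optional[str] = None


@dataclass
class TruthLog:
    """Planted ground truth sufficient to audit every downstream stage."""

    legacy_loci: list[LegacyLocus] = field(default_factory=list)
    zone_counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    candidate_genes: dict[str, str] = field(default_factory=dict)
    planted_duplicates: list[tuple[str, str]] = field(default_factory=list)
    n_polymorphic_planted: Optional[int] = None

    def ambiguous_loci(self) -> list[LegacyLocus]:
        return [l for l in self.legacy_loci if l.ambiguous]

    def legacy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker_id": l.marker_id, "chrom": l.chrom, "pos": l.pos,
                    "ref": l.ref, "alt": l.alt, "ambiguous": l.ambiguous,
                    "copy_chrom": l.copy_chrom or "", "copy_pos": l.copy_pos or "",
                }
                for l in self.legacy_loci
            ]
        )


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    arr = rng.integers(0, 4, size=n, dtype=np.uint8)
    return bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes())


def _draw_alt(rng: np.random.Generator, ref: str, odds: float) -> str:
    if rng.random() < odds / (1.0 + odds):
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(0, 2)]


# ---------------------------------------------------------------------------
# reference with planted legacy loci

def make_reference(spec: SimulationSpec) -> tuple[GenomeReference, TruthLog]:
    """Random uppercase ACGT chromosomes with the legacy marker loci (and
    the verbatim second copies of the 'ambiguous' subset) planted.  No
    121-mer repeats exist except the planted copies (accidental collisions
    are resampled away)."""
    lengths = spec.chrom_lengths()
    margin, separation = 100, 300
    demand = spec.n_legacy * separation * 2
    if demand > sum(lengths.values()):
        raise ValueError(
            f"chromosomes too small for {spec.n_legacy} legacy loci "
            f"({demand} bp needed, {sum(lengths.values())} available)"
        )
    rng_ref = spec.rng("reference")
    seqs = {name: _random_seq(rng_ref, n) for name, n in lengths.items()}

    rng = spec.rng("legacy_loci")
    truth = TruthLog()
    total = sum(lengths.values())
    names = spec.chrom_names()
    per_chrom = {n: int(round(spec.n_legacy * lengths[n] / total)) for n in names}
    per_chrom[names[-1]] += spec.n_legacy - sum(per_chrom.values())

    planted: dict[str, list[int]] = {n: [] for n in names}

    def pick_site(chrom: str) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(margin, lengths[chrom] - margin))
            if all(abs(pos - p) >= separation for p in planted[chrom]):
                return pos
        raise ValueError(f"could not place loci on {chrom}: too crowded")

    idx = 0
    for chrom in names:
        for _ in range(per_chrom[chrom]):
            pos = pick_site(chrom)
            planted[chrom].append(pos)
            ref = chr(seqs[chrom][pos - 1])
            alt = _draw_alt(rng, ref, spec.ts_tv_odds)
            truth.legacy_loci.append(
                LegacyLocus(marker_id=f"LG_{idx:04d}", chrom=chrom, pos=pos, ref=ref, alt=alt)
            )
            idx += 1

    n_ambiguous = int(round(spec.planted_ambiguous_fraction * spec.n_legacy))
    for locus in (truth.legacy_loci[i] for i in rng.choice(len(truth.legacy_loci),
                                                           size=n_ambiguous, replace=False)):
        copy_chrom = names[int(rng.integers(0, len(names)))]
        copy_pos = None
        for _ in range(10_000):
            cand = int(rng.integers(margin, lengths[copy_chrom] - margin))
            if all(abs(cand - p) >= separation for p in planted[copy_chrom]):
                copy_pos = cand
                break
        if copy_pos is None:
            raise ValueError("could not place a duplicated locus: too crowded")
        window = bytes(seqs[locus.chrom][locus.pos - 61 : locus.pos + 60])
        seqs[copy_chrom][copy_pos - 61 : copy_pos + 60] = window
        planted[copy_chrom].append(copy_pos)
        locus.ambiguous = True
        locus.copy_chrom, locus.copy_pos = copy_chrom, copy_pos

    _enforce_unique_windows(seqs, truth, rng)
    reference = GenomeReference(
        chromosomes={n: seqs[n].decode("ascii") for n in names}
    )
    return reference, truth


def _enforce_unique_windows(seqs, truth: TruthLog, rng: np.random.Generator) -> None:
    """Resample accidental repeats so each planted 121-mer occurs exactly
    once (twice when its locus was duplicated on purpose)."""
    for locus in truth.legacy_loci:
        window = bytes(seqs[locus.chrom][locus.pos - 61 : locus.pos + 60])
        expected = {(locus.chrom, locus.pos - 61)}
        if locus.ambiguous:
            expected.add((locus.copy_chrom, locus.copy_pos - 61))
        for _ in range(100):
            found = {
                (chrom, hit)
                for chrom, seq in seqs.items()
                for hit in _find_all(bytes(seq), window)
            }
            extras = found - expected
            if not extras:
                break
            for chrom, start in extras:  # mutate one base of the accidental copy
                offset = start + int(rng.integers(0, 121))
                old = chr(seqs[chrom][offset])
                seqs[chrom][offset] = ord(_TRANSITION[old])
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not make {locus.marker_id} window unique")


def _find_all(haystack: bytes, needle: bytes) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


# ---------------------------------------------------------------------------
# gene models (planted ORFs)

def make_genes(
    spec: SimulationSpec, reference: GenomeReference, truth: TruthLog
) -> list[GeneModel]:
    """Place non-overlapping genes, avoiding planted legacy windows, and
    rewrite the reference so every CDS is a valid ORF (ATG ... stop, no
    internal stops, length divisible by 3)."""
    rng = spec.rng("genes")
    lengths = reference.lengths
    seqs = {n: bytearray(s, "ascii") for n, s in reference.chromosomes.items()}

    forbidden: dict[str, list[tuple[int, int]]] = {n: [] for n in lengths}
    for l in truth.legacy_loci:
        forbidden[l.chrom].append((l.pos - 70, l.pos + 70))
        if l.ambiguous:
            forbidden[l.copy_chrom].append((l.copy_pos - 70, l.copy_pos + 70))

    partitions = make_partitions(spec)
    models: list[GeneModel] = []
    for chrom, length in lengths.items():
        max_len = spec.gene_length_range[1]
        if spec.genes_per_chromosome * (max_len + 200) > length:
            raise ValueError(
                f"{chrom}: cannot fit {spec.genes_per_chromosome} genes of up to "
                f"{max_len} bp in {length} bp"
            )
        # gene density follows the zone multipliers (distally enriched, as
        # in real cereal genomes)
        zones = partitions[chrom].zones
        zweights = np.array(
            [(z.phys_end - z.phys_start) * d for z, d in zip(zones, spec.zone_density)],
            float,
        )
        zweights /= zweights.sum()
        occupied = list(forbidden[chrom])
        for g in range(spec.genes_per_chromosome):
            glen = int(rng.integers(*spec.gene_length_range))
            start = None
            for _ in range(10_000):
                z = zones[int(rng.choice(len(zones), p=zweights))]
                lo = max(z.phys_start + 1, 200)
                hi = min(z.phys_end, length - glen - 200)
                if hi <= lo:
                    continue
                cand = int(rng.integers(lo, hi))
                span = (cand - 100, cand + glen + 100)
                if all(span[1] < s or span[0] > e for s, e in occupied):
                    start = cand
                    break
            if start is None:
                raise ValueError(f"{chrom}: could not place gene {g}: too crowded")
            occupied.append((start - 100, start + glen + 100))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"GENE_{chrom}_{g:03d}"
            model = _layout_gene(rng, spec, gene_id, chrom, strand, start, glen)
            _plant_orf(rng, seqs[chrom], model)
            models.append(model)

    for n in seqs:
        reference.chromosomes[n] = seqs[n].decode("ascii")
    return models


def _layout_gene(rng, spec, gene_id, chrom, strand, start, glen) -> GeneModel:
    n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
    min_exon, min_intron = 90, 25
    while n_exons > 1 and n_exons * min_exon + (n_exons - 1) * min_intron > glen:
        n_exons -= 1
    intron_total = glen - n_exons * min_exon - (n_exons - 1) * min_intron
    # distribute the slack over exons and introns
    parts = n_exons + (n_exons - 1)
    slack = rng.multinomial(max(intron_total, 0), [1.0 / parts] * parts) if parts else []
    exon_lens = [min_exon + int(slack[i]) for i in range(n_exons)]
    intron_lens = [min_intron + int(slack[n_exons + i]) for i in range(n_exons - 1)]

    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]

    total_exonic = sum(e - s + 1 for s, e in exons)
    utr5 = int(rng.integers(10, 61))
    utr3 = int(rng.integers(10, 61))
    cds_len = total_exonic - utr5 - utr3
    cds_len -= cds_len % 3
    utr3 = total_exonic - utr5 - cds_len
    if cds_len < 30:
        raise ValueError(f"{gene_id}: gene too short for a CDS")

    # transcript-order walk: positions in transcription direction
    tx_positions: list[int] = []
    order = exons if strand == "+" else list(reversed(exons))
    for s, e in order:
        rng_pos = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        tx_positions.extend(rng_pos)
    cds_positions = sorted(tx_positions[utr5 : utr5 + cds_len])
    cds_segs = _runs(cds_positions)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, cds=cds_segs)


def _runs(positions: list[int]) -> list[tuple[int, int]]:
    segs = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            segs.append((start, prev))
            start = p
        prev = p
    segs.append((start, prev))
    return segs


def _plant_orf(rng, seq: bytearray, model: GeneModel) -> None:
    cds_len = sum(e - s + 1 for s, e in model.cds)
    n_codons = cds_len // 3
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    orf = "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + _STOPS[int(rng.integers(0, 3))]
    tx_positions: list[int] = []
    order = model.cds if model.strand == "+" else list(reversed(model.cds))
    for s, e in order:
        rng_pos = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        tx_positions.extend(rng_pos)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, pos in enumerate(tx_positions):
        base = orf[i] if model.strand == "+" else comp[orf[i]]
        seq[pos - 1] = ord(base)


# ---------------------------------------------------------------------------
# partitions

def make_partitions(spec: SimulationSpec) -> dict[str, ChromosomePartition]:
    """Scaled copies of the published five-zone 1H template for every
    synthetic chromosome."""
    out = {}
    for chrom, length in spec.chrom_lengths().items():
        breakpoints = [int(round(f * length)) for f in _ZONE_FRACTIONS]
        breakpoints[0], breakpoints[-1] = 0, length
        out[chrom] = ChromosomePartition.from_breakpoints(chrom, breakpoints, _ZONE_CM)
    return out


# ---------------------------------------------------------------------------
# candidates

def make_candidates(
    spec: SimulationSpec,
    reference: GenomeReference,
    genes: Sequence[GeneModel],
    partitions: dict[str, ChromosomePartition],
    truth: TruthLog,
) -> CandidateSet:
    """Candidate SNPs with zone-weighted placement, Beta-distributed scores
    and missingness, transition-biased alleles, and structural gene links.
    The truth log gains per-zone qualifying counts under the stage-A and
    stage-B thresholds, and the planted legacy/candidate duplicate pairs."""
    rng = spec.rng("candidates")
    lengths = reference.lengths
    names = list(lengths)
    total = sum(lengths.values())

    gene_index: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_index.setdefault(g.chrom, []).append(g)
    for lst in gene_index.values():
        lst.sort(key=lambda g: g.start)

    legacy_positions = {
        (l.chrom, l.pos) for l in truth.legacy_loci
    } | {(l.copy_chrom, l.copy_pos) for l in truth.legacy_loci if l.ambiguous}

    out = CandidateSet()
    margin = 100
    a_beta, b_beta = spec.design_score_beta
    am, bm = spec.missing_rate_beta

    per_chrom = {n: int(round(spec.n_candidates * lengths[n] / total)) for n in names}
    per_chrom[names[-1]] += spec.n_candidates - sum(per_chrom.values())

    for chrom in names:
        part = partitions[chrom]
        zones = part.zones
        weights = np.array(
            [max(z.phys_end - z.phys_start, 0) * d for z, d in zip(zones, spec.zone_density)],
            float,
        )
        weights /= weights.sum()
        counts = rng.multinomial(per_chrom[chrom], weights)
        positions: set[int] = set()
        for zone, cnt in zip(zones, counts):
            lo = max(zone.phys_start + 1, margin)
            hi = min(zone.phys_end, lengths[chrom] - margin)
            pool = hi - lo
            if pool <= cnt:
                raise ValueError(f"{chrom}/{zone.label}: zone too small for {cnt} candidates")
            # genic positions: gene bodies intersected with this zone
            genic_pool = []
            for g in gene_index.get(chrom, []):
                s, e = max(g.start, lo), min(g.end, hi)
                if s <= e:
                    genic_pool.append((s, e))
            genic_cum = np.cumsum([e - s + 1 for s, e in genic_pool]) if genic_pool else None
            n_genic = int(round(cnt * spec.genic_fraction)) if genic_pool else 0
            picks = []
            if n_genic:
                offs = rng.integers(0, genic_cum[-1], size=n_genic)
                for off in offs:
                    k = int(np.searchsorted(genic_cum, off, side="right"))
                    base = genic_cum[k - 1] if k else 0
                    picks.append(genic_pool[k][0] + int(off - base))
            picks.extend(int(p) + lo for p in rng.integers(0, pool, size=cnt - n_genic))
            for pos in sorted(picks):
                if pos in positions or any(
                    (chrom, q) in legacy_positions for q in range(pos - 5, pos + 6)
                ):
                    continue
                positions.add(pos)
        for pos in sorted(positions):
            ref = reference.base(chrom, pos)
            alt = _draw_alt(rng, ref, spec.ts_tv_odds)
            score = float(rng.beta(a_beta, b_beta))
            target_missing = float(rng.beta(am, bm))
            p_allele = float(rng.uniform(0.05, 0.95))
            draws = rng.random(spec.n_samples)
            kinds = rng.random(spec.n_samples)
            calls = tuple(
                "missing"
                if draws[i] < target_missing
                else ("RA" if kinds[i] < spec.het_call_rate
                      else ("RR" if kinds[i] < spec.het_call_rate + (1 - spec.het_call_rate) * p_allele
                            else "AA"))
                for i in range(spec.n_samples)
            )
            cid = f"EC_{chrom}_{pos}"
            gene_id = _containing_gene(gene_index.get(chrom, []), pos)
            cv = CandidateVariant(
                id=cid, chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls,
                missing_rate=calls.count("missing") / spec.n_samples,
                design_score=score, gene_id=gene_id,
            )
            out.append(cv)
            if gene_id:
                truth.candidate_genes[cid] = gene_id

    # planted duplicates: candidates sitting exactly on legacy loci
    n_dup = int(round(spec.planted_duplicate_fraction * spec.n_legacy))
    dup_loci = [truth.legacy_loci[i] for i in rng.choice(len(truth.legacy_loci),
                                                         size=n_dup, replace=False)]
    for locus in dup_loci:
        cid = f"EC_{locus.chrom}_{locus.pos}"
        p_allele = float(rng.uniform(0.05, 0.95))
        kinds = rng.random(spec.n_samples)
        calls = tuple(
            "RA" if k < spec.het_call_rate
            else ("RR" if k < spec.het_call_rate + (1 - spec.het_call_rate) * p_allele else "AA")
            for k in kinds
        )
        cv = CandidateVariant(
            id=cid, chrom=locus.chrom, pos=locus.pos, ref=locus.ref, alt=locus.alt,
            calls=calls, missing_rate=0.0,
            design_score=float(rng.beta(a_beta, b_beta)),
            gene_id=_containing_gene(gene_index.get(locus.chrom, []), locus.pos),
        )
        out.append(cv)
        locus.duplicate_candidate_id = cid
        truth.planted_duplicates.append((locus.marker_id, cid))

    # bookkeeping: per-zone qualifying counts under both stages' thresholds
    from .selection import assign_zone

    for cv in out:
        zone = assign_zone(partitions[cv.chrom], cv.pos)
        key = (cv.chrom, zone)
        rec = truth.zone_counts.setdefault(key, {"total": 0, "stage_a": 0, "stage_b": 0})
        rec["total"] += 1
        if cv.missing_rate <= 0.20 and cv.design_score >= 0.6:
            rec["stage_a"] += 1
        if cv.missing_rate < 0.05 and cv.design_score > 0.8:
            rec["stage_b"] += 1
    return out


def _containing_gene(genes: list[GeneModel], pos: int) -> Optional[str]:
    for g in genes:
        if g.start > pos:
            return None
        if g.contains(pos):
            return g.gene_id
    return None


# ---------------------------------------------------------------------------
# legacy manifests & catalog

def make_legacy_manifests(
    spec: SimulationSpec, reference: GenomeReference, truth: TruthLog
) -> list[ManifestRecord]:
    """Manifests extracted verbatim from the planted loci."""
    from .manifest import build_manifest

    return [
        build_manifest(
            reference, l.chrom, l.pos, l.ref, l.alt, marker_id=l.marker_id
        )
        for l in truth.legacy_loci
    ]


def make_catalog(truth: TruthLog) -> VariantCatalog:
    """Independent variant catalog holding every planted legacy SNP."""
    entries = {}
    for l in truth.legacy_loci:
        entries[(l.chrom, l.pos)] = frozenset((l.ref, l.alt))
    return VariantCatalog(entries=entries)


# ---------------------------------------------------------------------------
# call sets

_STATE_CODES = np.array(["AA", "BB", "AB", "NA"])


def make_callsets(
    spec: SimulationSpec,
    n_markers: Optional[int] = None,
    n_samples: Optional[int] = None,
    disagreement: Optional[float] = None,
    missing: Optional[float] = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Two call matrices where B disagrees with A independently per call
    with probability e, and each matrix has calls masked missing with
    probability m."""
    e = spec.callset_disagreement if disagreement is None else disagreement
    m = spec.callset_missing if missing is None else missing
    if not (0 <= e <= 1 and 0 <= m <= 1):
        raise ValueError("rates must lie in [0, 1]")
    n_markers = n_markers or 2000
    n_samples = n_samples or spec.n_samples
    rng = spec.rng("callsets")

    shape = (n_markers, n_samples)
    a = rng.choice(3, size=shape, p=[0.49, 0.49, 0.02])
    b = a.copy()
    flip = rng.random(shape) < e
    shift = rng.integers(1, 3, size=shape)
    b[flip] = (b[flip] + shift[flip]) % 3
    a_na = rng.random(shape) < m
    b_na = rng.random(shape) < m

    markers = [f"M_{i:05d}" for i in range(n_markers)]
    samples = [f"S_{j:03d}" for j in range(n_samples)]

    def build(states, na_mask):
        coded = states.copy()
        coded[na_mask] = 3
        labels = _STATE_CODES[coded]
        calls = {
            (samples[j], markers[i]): labels[i, j]
            for i in range(n_markers)
            for j in range(n_samples)
        }
        return GenotypeMatrix(samples=list(samples), markers=list(markers), calls=calls)

    return build(a, a_na), build(b, b_na)


def make_array_matrix(
    spec: SimulationSpec,
    n_markers: int = 1000,
    n_samples: Optional[int] = None,
    polymorphic_fraction: Optional[float] = None,
    truth: Optional[TruthLog] = None,
) -> GenotypeMatrix:
    """Call matrix with an exact planted count of polymorphic markers."""
    frac = spec.polymorphic_fraction if polymorphic_fraction is None else polymorphic_fraction
    n_samples = n_samples or spec.n_samples
    rng = spec.rng("array_matrix")
    n_poly = int(round(frac * n_markers))
    poly_idx = set(rng.choice(n_markers, size=n_poly, replace=False).tolist())
    markers = [f"A_{i:05d}" for i in range(n_markers)]
    samples = [f"S_{j:03d}" for j in range(n_samples)]
    calls = {}
    for i, marker in enumerate(markers):
        if i in poly_idx:
            while True:
                p = rng.uniform(0.2, 0.8)
                row = np.where(rng.random(n_samples) < p, "AA", "BB")
                if len(set(row)) >= 2:
                    break
        else:
            row = np.full(n_samples, "AA" if rng.random() < 0.5 else "BB", dtype=object)
        for j, sample in enumerate(samples):
            calls[(sample, marker)] = str(row[j])
    if truth is not None:
        truth.n_polymorphic_planted = n_poly
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# anchor maps

def make_anchor_map(
    spec: SimulationSpec,
    partitions: dict[str, ChromosomePartition],
    markers_per_chromosome: int = 50,
    n_adjacent_swaps: int = 0,
) -> "AnchorMap":
    """Markers along each chromosome with genetic positions from the
    piecewise-linear zone geometry (collinear by construction); optional
    planted adjacent-order swaps."""
    from .core import AnchorEntry, AnchorMap

    rng = spec.rng("anchor_map")
    entries = {}
    for chrom, part in partitions.items():
        length = part.length
        phys = np.sort(rng.choice(length - 200, size=markers_per_chromosome, replace=False) + 100)
        cum = np.concatenate([[0.0], np.cumsum([z.genetic_span for z in part.zones])])
        edges = np.array([z.phys_start for z in part.zones] + [length], float)
        gen = np.interp(phys, edges, cum)
        gen = np.maximum.accumulate(gen + np.linspace(0, 1e-6, len(gen)))
        rows = [
            AnchorEntry(marker_id=f"AM_{chrom}_{i:03d}", genetic_pos=float(g),
                        physical_pos=int(p))
            for i, (g, p) in enumerate(zip(gen, phys))
        ]
        for _ in range(n_adjacent_swaps):
            k = int(rng.integers(0, len(rows) - 1))
            rows[k].physical_pos, rows[k + 1].physical_pos = (
                rows[k + 1].physical_pos, rows[k].physical_pos
            )
        entries[chrom] = rows
    return AnchorMap(entries=entries)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimulatedData:
    spec: SimulationSpec
    reference: GenomeReference
    genes: list[GeneModel]
    partitions: dict[str, ChromosomePartition]
    candidates: CandidateSet
    legacy_manifests: list[ManifestRecord]
    catalog: VariantCatalog
    truth: TruthLog

    @property
    def samples(self) -> list[str]:
        return [f"S_{j:03d}" for j in range(self.spec.n_samples)]

    def write_all(self, out_dir) -> None:
        from pathlib import Path

        from . import io
        from .selection import write_partitions

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.reference, out / "genome.fasta")
        io.write_gff3(self.genes, out / "genes.gff3")
        io.write_candidates_vcf(
            self.candidates, self.samples, self.reference.lengths, out / "candidates.vcf"
        )
        io.write_score_sidecar(self.candidates, out / "design_scores.tsv")
        write_partitions(self.partitions, out / "partitions.tsv")
        io.write_manifest_table(self.legacy_manifests, out / "legacy_manifests.tsv")
        self.truth.legacy_table().to_csv(out / "truth_legacy.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"chrom": c, "zone": z, **counts}
                for (c, z), counts in self.truth.zone_counts.items()
            ]
        ).to_csv(out / "truth_zone_counts.tsv", sep="\t", index=False)
        a, b = make_callsets(self.spec)
        io.write_genotype_matrix(a, out / "callset_a.tsv")
        io.write_genotype_matrix(b, out / "callset_b.tsv")


def simulate(spec: SimulationSpec) -> SimulatedData:
    """Run every generator under the spec's seed and bundle the results."""
    reference, truth = make_reference(spec)
    genes = make_genes(spec, reference, truth)
    partitions = make_partitions(spec)
    candidates = make_candidates(spec, reference, genes, partitions, truth)
    legacy = make_legacy_manifests(spec, reference, truth)
    catalog = make_catalog(truth)
    return SimulatedData(
        spec=spec, reference=reference, genes=genes, partitions=partitions,
        candidates=candidates, legacy_manifests=legacy, catalog=catalog, truth=truth,
    )
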