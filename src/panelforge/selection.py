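"""Two-stage, recombination-aware marker selection.

Stage A maximises gene coverage: permissive quality thresholds, one SNP per
gene.  Stage B tops the panel up from the recombining distal chromosome
zones only, with per-zone quotas proportional to each zone's share of the
genetic map, stricter thresholds (optionally relaxed for named zones), and
a combined two-SNPs-per-gene cap across both stages.  Pericentromeric zones
receive no stage-B quota: markers there sit in near-complete linkage
disequilibrium and add little mapping information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CandidateVariant

ZONE_LABELS = ("short_high", "short_low", "pericentromeric", "long_low", "long_high")
DISTAL_ZONES = ("short_high", "short_low", "long_low", "long_high")


@dataclass
class Zone:
    label: str
    phys_start: int  # bp, half-open [start, end); final zone closed at chrom end
    phys_end: int
    genetic_span: float  # cM


@dataclass
class ChromosomePartition:
    """Five contiguous physical zones per chromosome, each with the genetic
    distance (cM) it spans on the linkage map."""

    chrom: str
    zones: list[Zone]

    def __post_init__(self) -> None:
        if tuple(z.label for z in self.zones) != ZONE_LABELS:
            raise ValueError(
                f"{self.chrom}: zones must be exactly {ZONE_LABELS} in order"
            )
        if self.zones[0].phys_start != 0:
            raise ValueError(f"{self.chrom}: first zone must start at 0")
        for a, b in zip(self.zones, self.zones[1:]):
            if a.phys_end != b.phys_start:
                raise ValueError(f"{self.chrom}: zones not contiguous at {a.phys_end}")
        if any(z.genetic_span < 0 for z in self.zones):
            raise ValueError(f"{self.chrom}: negative genetic span")

    @property
    def length(self) -> int:
        return self.zones[-1].phys_end

    @classmethod
    def from_breakpoints(
        cls, chrom: str, breakpoints: Sequence[int], genetic_spans: Sequence[float]
    ) -> "ChromosomePartition":
        """``breakpoints`` are the 6 zone edges (0 ... chromosome length);
        ``genetic_spans`` the 5 per-zone cM spans."""
        if len(breakpoints) != 6 or len(genetic_spans) != 5:
            raise ValueError("need 6 breakpoints and 5 genetic spans")
        zones = [
            Zone(label, int(breakpoints[i]), int(breakpoints[i + 1]), float(genetic_spans[i]))
            for i, label in enumerate(ZONE_LABELS)
        ]
        return cls(chrom=chrom, zones=zones)


@dataclass
class StageThresholds:
    max_missing: float
    min_score: float
    per_gene_cap: int
    inclusive: bool  # <=' / '>=' when True, strict when False


@dataclass
class ZoneOverride:
    chrom: str
    zone: str
    max_missing: float
    min_score: float


@dataclass
class SelectionConfig:
    """Defaults follow the published design: stage A keeps records with
    missing <= 20% and score >= 0.6 (one SNP/gene); stage B requires
    score > 0.8 and missing < 5% (two SNPs/gene in total), relaxed to
    stage-A levels on the short arm of 5H where the genetic::physical
    ratio is extreme."""

    stage_a: StageThresholds = field(
        default_factory=lambda: StageThresholds(0.20, 0.6, 1, inclusive=True)
    )
    stage_b: StageThresholds = field(
        default_factory=lambda: StageThresholds(0.05, 0.8, 2, inclusive=False)
    )
    overrides: list[ZoneOverride] = field(
        default_factory=lambda: [ZoneOverride("5H", "short_high", 0.20, 0.6)]
    )
    stage_b_budget: int | dict[str, int] = 0

    def budget_for(self, chrom: str) -> int:
        if isinstance(self.stage_b_budget, dict):
            return int(self.stage_b_budget.get(chrom, 0))
        return int(self.stage_b_budget)

    def override_for(self, chrom: str, zone: str) -> Optional[ZoneOverride]:
        for ov in self.overrides:
            if ov.chrom == chrom and ov.zone == zone:
                return ov
        return None


# ---------------------------------------------------------------------------
# filtering and dedup

def _passes(cv: CandidateVariant, max_missing: float, min_score: float, inclusive: bool) -> bool:
    if cv.design_score is None:
        return False
    if inclusive:
        return cv.missing_rate <= max_missing and cv.design_score >= min_score
    return cv.missing_rate < max_missing and cv.design_score > min_score


def filter_candidates(
    candidates: Sequence[CandidateVariant],
    max_missing: float,
    min_score: float,
    inclusive: bool = True,
) -> list[CandidateVariant]:
    """Quality filter.  ``inclusive`` keeps the boundary values (<=, >=);
    strict mode drops them (<, >).  Scoreless records never pass."""
    return [cv for cv in candidates if _passes(cv, max_missing, min_score, inclusive)]


def _rank_key(cv: CandidateVariant):
    # deterministic: best score first, then least missing, then position
    return (-(cv.design_score or 0.0), cv.missing_rate, cv.pos, cv.id)


def dedupe_per_gene(candidates: Sequence[CandidateVariant], cap: int) -> list[CandidateVariant]:
    """Keep at most ``cap`` candidates per gene (best design score, then
    lowest missing rate, then position).  Geneless candidates are singleton
    groups and always survive."""
    if cap < 1:
        raise ValueError(f"per-gene cap must be >= 1, got {cap}")
    kept: list[CandidateVariant] = []
    by_gene: dict[str, list[CandidateVariant]] = {}
    for cv in candidates:
        if cv.gene_id is None:
            kept.append(cv)
        else:
            by_gene.setdefault(cv.gene_id, []).append(cv)
    for group in by_gene.values():
        kept.extend(sorted(group, key=_rank_key)[:cap])
    order = {id(cv): i for i, cv in enumerate(candidates)}
    kept.sort(key=lambda cv: order[id(cv)])
    return kept


def select_stage_a(
    candidates: Sequence[CandidateVariant], config: Optional[SelectionConfig] = None
) -> list[CandidateVariant]:
    """Stage A: permissive quality filter, then one SNP per gene."""
    config = config or SelectionConfig()
    th = config.stage_a
    passing = filter_candidates(candidates, th.max_missing, th.min_score, th.inclusive)
    return dedupe_per_gene(passing, th.per_gene_cap)


# ---------------------------------------------------------------------------
# zones and quotas

def assign_zone(partition: ChromosomePartition, physical_pos: int) -> str:
    """Zone whose half-open [start, end) interval contains the position;
    the final zone is closed at the chromosome end."""
    if physical_pos < 0 or physical_pos > partition.length:
        raise ValueError(
            f"position {physical_pos} outside {partition.chrom} (0-{partition.length})"
        )
    for zone in partition.zones[:-1]:
        if zone.phys_start <= physical_pos < zone.phys_end:
            return zone.label
    return partition.zones[-1].label


def allocate_quota(partition: ChromosomePartition, budget: int,
                   zones: Optional[Sequence[str]] = None) -> dict[str, int]:
    """Apportion ``budget`` across the distal zones in proportion to their
    genetic-map spans, by largest remainder (ties by distal-zone order).
    The pericentromeric quota is always 0."""
    if budget < 0:
        raise ValueError("budget must be >= 0")
    zones = tuple(zones) if zones is not None else DISTAL_ZONES
    spans = {z.label: Fraction(z.genetic_span).limit_denominator(10**9)
             for z in partition.zones}
    total = sum(spans[z] for z in zones)
    quotas = {label: 0 for label in ZONE_LABELS}
    if budget == 0:
        return quotas
    if total == 0:
        raise ValueError(
            f"{partition.chrom}: all distal genetic spans are zero, cannot allocate"
        )
    shares = {z: Fraction(budget) * spans[z] / total for z in zones}
    for z in zones:
        quotas[z] = int(shares[z])  # floor
    leftover = budget - sum(quotas[z] for z in zones)
    # largest remainder; ties resolved by distal-zone order
    by_remainder = sorted(
        zones, key=lambda z: (-(shares[z] - int(shares[z])), DISTAL_ZONES.index(z))
    )
    for z in by_remainder[:leftover]:
        quotas[z] += 1
    return quotas


# ---------------------------------------------------------------------------
# stage B

@dataclass
class StageBResult:
    selected: list[CandidateVariant]
    quotas: dict[str, dict[str, int]]  # chrom -> zone -> initial quota
    taken: dict[str, dict[str, int]]  # chrom -> zone -> selected count
    shortfall: dict[str, int]  # chrom -> unfilled budget


def select_stage_b(
    candidates: Sequence[CandidateVariant],
    partitions: dict[str, ChromosomePartition],
    config: SelectionConfig,
    stage_a_selected: Sequence[CandidateVariant] = (),
) -> StageBResult:
    """Distal-weighted stage B.

    Per zone, candidates passing the stage-B thresholds (or the zone's
    override) are ranked (score desc, missing asc, pos asc) and taken up to
    quota; the per-gene cap counts stage-A picks.  Zone shortfalls are
    redistributed by re-running largest-remainder over the chromosome's
    remaining distal zones; what cannot be placed is reported.
    """
    chroms = {cv.chrom for cv in candidates}
    missing_parts = chroms - set(partitions)
    if missing_parts:
        raise ValueError(f"no partition for chromosome(s) {sorted(missing_parts)}")

    a_ids = {id(cv) for cv in stage_a_selected}
    gene_count: dict[str, int] = {}
    for cv in stage_a_selected:
        if cv.gene_id is not None:
            gene_count[cv.gene_id] = gene_count.get(cv.gene_id, 0) + 1
    cap = config.stage_b.per_gene_cap

    # eligible candidates per chromosome/zone, ranked
    eligible: dict[str, dict[str, list[CandidateVariant]]] = {}
    for cv in candidates:
        if id(cv) in a_ids:
            continue
        part = partitions[cv.chrom]
        zone = assign_zone(part, cv.pos)
        if zone == "pericentromeric":
            continue
        ov = config.override_for(cv.chrom, zone)
        th = config.stage_b
        ok = (
            _passes(cv, ov.max_missing, ov.min_score, th.inclusive)
            if ov is not None
            else _passes(cv, th.max_missing, th.min_score, th.inclusive)
        )
        if ok:
            eligible.setdefault(cv.chrom, {}).setdefault(zone, []).append(cv)
    for zones in eligible.values():
        for lst in zones.values():
            lst.sort(key=_rank_key)

    selected: list[CandidateVariant] = []
    quotas: dict[str, dict[str, int]] = {}
    taken: dict[str, dict[str, int]] = {}
    shortfall: dict[str, int] = {}

    for chrom in sorted(set(partitions) & chroms):
        budget = config.budget_for(chrom)
        part = partitions[chrom]
        quotas[chrom] = allocate_quota(part, budget)
        taken[chrom] = {label: 0 for label in ZONE_LABELS}
        cursors = {z: 0 for z in DISTAL_ZONES}
        zone_lists = eligible.get(chrom, {})

        def take_from(zone: str, quota: int) -> int:
            got = 0
            lst = zone_lists.get(zone, [])
            while got < quota and cursors[zone] < len(lst):
                cv = lst[cursors[zone]]
                cursors[zone] += 1
                if cv.gene_id is not None and gene_count.get(cv.gene_id, 0) >= cap:
                    continue
                selected.append(cv)
                if cv.gene_id is not None:
                    gene_count[cv.gene_id] = gene_count.get(cv.gene_id, 0) + 1
                got += 1
            return got

        remaining = budget
        active = list(DISTAL_ZONES)
        round_quota = dict(quotas[chrom])
        while remaining > 0 and active:
            progress = 0
            exhausted = []
            for zone in active:
                got = take_from(zone, round_quota.get(zone, 0))
                taken[chrom][zone] += got
                progress += got
                if cursors[zone] >= len(zone_lists.get(zone, [])):
                    exhausted.append(zone)
            remaining -= progress
            active = [z for z in active if z not in exhausted]
            if remaining <= 0 or not active or progress == 0 and not exhausted:
                break
            # redistribute the unfilled budget over the still-supplied zones
            try:
                redo = allocate_quota(part, remaining, zones=active)
            except ValueError:
                break
            round_quota = {z: redo[z] for z in active}
            if all(v == 0 for v in round_quota.values()):
                break
        shortfall[chrom] = remaining

    return StageBResult(selected=selected, quotas=quotas, taken=taken, shortfall=shortfall)


# ---------------------------------------------------------------------------
# funnel report

@dataclass
class FunnelReport:
    stages: list[tuple[str, int]]
    derived: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


def design_funnel(
    stage_counts: Sequence[tuple[str, int]],
    duplicates: Optional[int] = None,
    legacy: Optional[int] = None,
) -> FunnelReport:
    """Ordered stage -> count table with the redundancy/legacy arithmetic:
    the last stage count minus cross-set duplicates gives the new-marker
    total, plus carried-over legacy markers gives the final design size."""
    stages = [(str(label), int(n)) for label, n in stage_counts]
    derived: dict[str, float] = {}
    if stages and duplicates is not None:
        pre = stages[-1][1]
        derived["new_after_dedup"] = pre - duplicates
        if legacy is not None:
            derived["final_design"] = pre - duplicates + legacy
    return FunnelReport(stages=stages, derived=derived)


# ---------------------------------------------------------------------------
# partition suggestion (piecewise-linear genetic~physical fit)

def suggest_partition(
    physical_bp: Sequence[float],
    genetic_cM: Sequence[float],
    chrom: str = "chr",
    chrom_length: Optional[int] = None,
    n_zones: int = 5,
) -> ChromosomePartition:
    """Suggest zone breakpoints by fitting a 5-segment piecewise-linear
    genetic~physical curve (dynamic programming, segmented least squares
    over candidate breakpoints at the anchor positions).

    Suggestions support, never replace, explicit user partitions.
    """
    x = np.asarray(physical_bp, float)
    y = np.asarray(genetic_cM, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 2 * n_zones:
        raise ValueError(f"need at least {2 * n_zones} anchors, got {n}")

    # prefix sums for O(1) per-segment least-squares error
    sx, sy = np.concatenate([[0], np.cumsum(x)]), np.concatenate([[0], np.cumsum(y)])
    sxx = np.concatenate([[0], np.cumsum(x * x)])
    sxy = np.concatenate([[0], np.cumsum(x * y)])
    syy = np.concatenate([[0], np.cumsum(y * y)])

    def seg_err(i: int, j: int) -> float:  # anchors i..j inclusive
        m = j - i + 1
        Sx, Sy = sx[j + 1] - sx[i], sy[j + 1] - sy[i]
        Sxx, Sxy = sxx[j + 1] - sxx[i], sxy[j + 1] - sxy[i]
        Syy = syy[j + 1] - syy[i]
        den = m * Sxx - Sx * Sx
        if den <= 0:
            return Syy - Sy * Sy / m if m else 0.0
        slope = (m * Sxy - Sx * Sy) / den
        intercept = (Sy - slope * Sx) / m
        err = Syy - 2 * slope * Sxy - 2 * intercept * Sy + slope * slope * Sxx \
            + 2 * slope * intercept * Sx + m * intercept * intercept
        return max(err, 0.0)

    INF = float("inf")
    cost = [[INF] * (n_zones + 1) for _ in range(n + 1)]
    back = [[-1] * (n_zones + 1) for _ in range(n + 1)]
    cost[0][0] = 0.0
    for j in range(1, n + 1):
        for k in range(1, n_zones + 1):
            for i in range(k - 1, j):
                if j - i < 2:  # at least 2 anchors per segment
                    continue
                c = cost[i][k - 1] + seg_err(i, j - 1)
                if c < cost[j][k]:
                    cost[j][k] = c
                    back[j][k] = i
    cuts = []
    j, k = n, n_zones
    while k > 0:
        i = back[j][k]
        cuts.append((i, j - 1))
        j, k = i, k - 1
    cuts.reverse()

    length = int(chrom_length if chrom_length is not None else x[-1])
    breakpoints = [0]
    for (i0, j0), (i1, _) in zip(cuts, cuts[1:]):
        breakpoints.append(int(round((x[j0] + x[i1]) / 2)))
    breakpoints.append(length)
    spans = [max(float(y[j0] - y[i0]), 0.0) for i0, j0 in cuts]
    return ChromosomePartition.from_breakpoints(chrom, breakpoints, spans)


# ---------------------------------------------------------------------------
# partition TSV I/O

def read_partitions(path) -> dict[str, ChromosomePartition]:
    """TSV columns: chrom, zone, start_bp, end_bp, cM."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "zone": str})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.set_index("zone").loc[list(ZONE_LABELS)]
        zones = [
            Zone(label, int(row["start_bp"]), int(row["end_bp"]), float(row["cM"]))
            for label, row in sub.iterrows()
        ]
        out[chrom] = ChromosomePartition(chrom=chrom, zones=zones)
    return out


def write_partitions(partitions: dict[str, ChromosomePartition], path) -> None:
    rows = [
        {"chrom": chrom, "zone": z.label, "start_bp": z.phys_start,
         "end_bp": z.phys_end, "cM": z.genetic_span}
        for chrom, part in partitions.items()
        for z in part.zones
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
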