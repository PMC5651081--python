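"""Post-genotyping QC metrics.

Agreement between two call sets (per sample, missing-excluded), marker
polymorphism rate, transition/transversion ratio, assay conversion
statistics, and genetic-vs-physical order concordance.  Reported
percentages are rounded to 1 decimal and ratios to 2 decimals, matching
conventional reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnchorMap, GenotypeMatrix
from .manifest import classify_substitution


# ---------------------------------------------------------------------------
# call-set agreement

@dataclass
class AgreementReport:
    per_sample: pd.DataFrame  # sample_id, compared, agreeing, agreement_pct
    summary: dict[str, float]  # mean/median/q1/q3/min/max of agreement_pct
    stratum: str = "all"
    excluded_samples: list[str] = field(default_factory=list)


def agreement_rate(
    calls_a: GenotypeMatrix,
    calls_b: GenotypeMatrix,
    stratum_filter: Optional[Callable[[str], bool]] = None,
    stratum: str = "all",
    het_is_disagreement: bool = True,
) -> AgreementReport:
    """Per-sample agreement between two call matrices.

    Sample and marker universes are intersected; marker pairs where either
    call is missing are excluded from the denominator.  AB vs a homozygous
    call counts as a disagreement unless ``het_is_disagreement`` is off, in
    which case pairs with a heterozygous call are excluded entirely.
    Samples with zero comparable markers are flagged and left out of the
    summary statistics.
    """
    samples = [s for s in calls_a.samples if s in set(calls_b.samples)]
    markers = [m for m in calls_a.markers if m in set(calls_b.markers)]
    if stratum_filter is not None:
        markers = [m for m in markers if stratum_filter(m)]

    rows = []
    excluded = []
    for s in samples:
        compared = agreeing = 0
        for m in markers:
            a = calls_a.calls[(s, m)]
            b = calls_b.calls[(s, m)]
            if a == "NA" or b == "NA":
                continue
            if not het_is_disagreement and ("AB" in (a, b)) and a != b:
                continue
            compared += 1
            agreeing += a == b
        if compared == 0:
            excluded.append(s)
            continue
        rows.append(
            {
                "sample_id": s,
                "compared": compared,
                "agreeing": agreeing,
                "agreement_pct": round(100.0 * agreeing / compared, 1),
            }
        )
    per_sample = pd.DataFrame(rows, columns=["sample_id", "compared", "agreeing", "agreement_pct"])
    if len(per_sample):
        pct = per_sample["agreement_pct"].to_numpy(float)
        summary = {
            "mean": round(float(pct.mean()), 1),
            "median": round(float(np.median(pct)), 1),
            "q1": round(float(np.percentile(pct, 25)), 1),
            "q3": round(float(np.percentile(pct, 75)), 1),
            "min": round(float(pct.min()), 1),
            "max": round(float(pct.max()), 1),
        }
    else:
        summary = {}
    return AgreementReport(
        per_sample=per_sample, summary=summary, stratum=stratum, excluded_samples=excluded
    )


# ---------------------------------------------------------------------------
# variant-set statistics

def tstv_ratio(variants) -> float:
    """Transitions / transversions over (ref, alt) pairs, 2 decimals."""
    ts = tv = 0
    for v in variants:
        pair = (v.ref, v.alt) if hasattr(v, "ref") else tuple(v)
        if classify_substitution(*pair) == "transition":
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError(f"Ts/Tv undefined: {ts} transitions, 0 transversions")
    return round(ts / tv, 2)


def polymorphism_rate(matrix: GenotypeMatrix) -> float:
    """Percent of markers showing >= 2 distinct non-missing call states
    across samples (1 decimal)."""
    if not matrix.markers:
        raise ValueError("polymorphism_rate: empty matrix")
    poly = 0
    for m in matrix.markers:
        states = {matrix.calls[(s, m)] for s in matrix.samples} - {"NA"}
        poly += len(states) >= 2
    return round(100.0 * poly / len(matrix.markers), 1)


@dataclass
class ConversionStats:
    designed: int
    working: int
    scorable: int
    conversion_pct: float
    scorable_pct: float
    degenerate: bool = False  # scorable rate undefined (no working assays)


def conversion_stats(designed: int, working: int, scorable: int) -> ConversionStats:
    """Conversion = working/designed, scorable = scorable/working (both as
    1-decimal percentages).  Requires scorable <= working <= designed."""
    if not 0 <= scorable <= working <= designed:
        raise ValueError(
            f"need scorable <= working <= designed, got {scorable}/{working}/{designed}"
        )
    conversion = round(100.0 * working / designed, 1) if designed else 0.0
    if working == 0:
        return ConversionStats(designed, working, scorable, conversion, 0.0, degenerate=True)
    return ConversionStats(
        designed, working, scorable, conversion, round(100.0 * scorable / working, 1)
    )


# ---------------------------------------------------------------------------
# genetic vs physical order

@dataclass
class ChromConcordance:
    chrom: str
    n_markers: int
    rank_correlation: float  # Spearman rho; NaN when undefined
    adjacent_inversions: int
    unlinked_markers: list[str]
    defined: bool = True


@dataclass
class ConcordanceReport:
    per_chromosome: dict[str, ChromConcordance]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": c.chrom,
                "n_markers": c.n_markers,
                "rank_correlation": c.rank_correlation,
                "adjacent_inversions": c.adjacent_inversions,
                "n_unlinked": len(c.unlinked_markers),
            }
            for c in self.per_chromosome.values()
        ]
        return pd.DataFrame(rows)


def order_concordance(
    anchor_map: AnchorMap,
    max_interpolation_residual_bp: Optional[float] = None,
) -> ConcordanceReport:
    """Collinearity of the genetic and physical orders per chromosome.

    Spearman's rho (average-tie ranks) between genetic and physical
    positions; adjacent-pair inversions counted on markers sorted by
    genetic position; markers flagged unlinked when their physical position
    is on a different chromosome or, when a threshold is given, further
    than ``max_interpolation_residual_bp`` from the physical position
    interpolated from the rest of the map.
    """
    out = {}
    for chrom, entries in anchor_map.entries.items():
        unlinked = [e.marker_id for e in entries if e.physical_chrom != chrom]
        linked = [e for e in entries if e.physical_chrom == chrom]

        if max_interpolation_residual_bp is not None and len(linked) >= 3:
            flagged = []
            for i, e in enumerate(linked):
                others = [o for j, o in enumerate(linked) if j != i]
                others.sort(key=lambda o: o.genetic_pos)
                xs = [o.genetic_pos for o in others]
                ys = [o.physical_pos for o in others]
                expected = float(np.interp(e.genetic_pos, xs, ys))
                if abs(e.physical_pos - expected) > max_interpolation_residual_bp:
                    flagged.append(e.marker_id)
            unlinked.extend(flagged)
            linked = [e for e in linked if e.marker_id not in set(flagged)]

        n = len(linked)
        if n < 3:
            out[chrom] = ChromConcordance(
                chrom=chrom, n_markers=n, rank_correlation=float("nan"),
                adjacent_inversions=0, unlinked_markers=unlinked, defined=False,
            )
            continue
        gen = np.array([e.genetic_pos for e in linked], float)
        phys = np.array([e.physical_pos for e in linked], float)
        rho = float(stats.spearmanr(gen, phys).statistic)
        by_gen = sorted(linked, key=lambda e: (e.genetic_pos, e.physical_pos))
        inversions = sum(
            1 for a, b in zip(by_gen, by_gen[1:]) if b.physical_pos < a.physical_pos
        )
        out[chrom] = ChromConcordance(
            chrom=chrom, n_markers=n, rank_correlation=rho,
            adjacent_inversions=inversions, unlinked_markers=unlinked,
        )
    return ConcordanceReport(per_chromosome=out)
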