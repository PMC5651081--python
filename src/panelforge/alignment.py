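"""Pairwise nucleotide alignment for short manifest queries.

A k-mer-seeded (k = 11), ungapped diagonal aligner: every shared exact
11-mer nominates a (subject, diagonal); the best-scoring ungapped segment
on each diagonal is found exactly by maximum-subarray over per-base scores
(match +1, mismatch -2).  Gaps are not modelled -- queries are 121-base
probe sequences and the consumers of these hits only need identity,
coverage, coordinates and a bit score monotone in the raw score.

IUPAC ambiguity characters in either sequence match any of their bases, so
an encoded polymorphism never counts against identity.

Bit scores use fixed published Karlin-Altschul constants for the +1/-2
scoring scheme (lambda = 1.28, K = 0.46) and are conventionally reported
to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import revcomp

MATCH = 1
MISMATCH = -2
LAMBDA = 1.28
K_PARAM = 0.46
_LN2 = math.log(2.0)

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "W": frozenset("AT"),
    "S": frozenset("CG"), "K": frozenset("GT"), "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}


def bases_match(a: str, b: str) -> bool:
    """IUPAC-aware: true when the base sets intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def bit_score(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(K_PARAM)) / _LN2


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    identity_pct: float
    query_coverage_pct: float
    bit_score: float
    subject_start: int  # 1-based, forward subject coordinates
    subject_end: int
    strand: str  # '+' query as given, '-' reverse complement aligned
    query_start: int = 0  # 1-based in the original query orientation
    query_end: int = 0
    matches: int = 0
    length: int = 0
    raw_score: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.identity_pct <= 100 and 0 <= self.query_coverage_pct <= 100):
            raise ValueError("identity/coverage must be percentages")
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start after subject_end")


class KmerAligner:
    """Index a set of subject sequences and align queries against them."""

    def __init__(self, subjects: Mapping[str, str], k: int = 11):
        self.k = k
        self.subjects = {name: seq.upper() for name, seq in subjects.items()}
        if not self.subjects:
            raise ValueError("empty subject database")
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.subjects.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if set(kmer) <= set("ACGT"):
                    self.index.setdefault(kmer, []).append((name, i))

    def _diagonal_hsp(self, q: str, subject: str, diag: int):
        """Best ungapped segment of query vs subject offset by ``diag``
        (subject_pos = query_pos + diag), by maximum subarray."""
        sseq = self.subjects[subject]
        q_lo = max(0, -diag)
        q_hi = min(len(q), len(sseq) - diag)
        best = cur = 0
        best_span = None
        cur_start = q_lo
        for qi in range(q_lo, q_hi):
            s = MATCH if bases_match(q[qi], sseq[qi + diag]) else MISMATCH
            if cur <= 0:
                cur = s
                cur_start = qi
            else:
                cur += s
            if cur > best:
                best = cur
                best_span = (cur_start, qi)
        if best_span is None:
            return None
        qs, qe = best_span
        matches = sum(
            1 for qi in range(qs, qe + 1) if bases_match(q[qi], sseq[qi + diag])
        )
        return best, qs, qe, matches

    def align(
        self,
        query_seq: str,
        query_id: str = "query",
        max_subjects: int = 3,
        max_hsps_per_subject: int = 3,
    ) -> list[AlignmentHit]:
        """Hits sorted by bit score descending, truncated to the best
        ``max_hsps_per_subject`` segments of the best ``max_subjects``
        subjects."""
        query_seq = query_seq.upper()
        if not query_seq:
            raise ValueError("empty query")
        qlen = len(query_seq)
        per_subject: dict[str, dict] = {}

        for strand in ("+", "-"):
            q = query_seq if strand == "+" else revcomp(query_seq)
            seen: set[tuple[str, int]] = set()
            for i in range(qlen - self.k + 1):
                kmer = q[i : i + self.k]
                for name, spos in self.index.get(kmer, ()):
                    key = (name, spos - i)
                    if key in seen:
                        continue
                    seen.add(key)
                    hsp = self._diagonal_hsp(q, name, spos - i)
                    if hsp is None:
                        continue
                    raw, qs, qe, matches = hsp
                    length = qe - qs + 1
                    diag = spos - i
                    if strand == "+":
                        oqs, oqe = qs + 1, qe + 1
                    else:  # map back to original query orientation
                        oqs, oqe = qlen - qe, qlen - qs
                    hit = AlignmentHit(
                        query_id=query_id,
                        subject_id=name,
                        identity_pct=100.0 * matches / length,
                        query_coverage_pct=100.0 * length / qlen,
                        bit_score=bit_score(raw),
                        subject_start=qs + diag + 1,
                        subject_end=qe + diag + 1,
                        strand=strand,
                        query_start=oqs,
                        query_end=oqe,
                        matches=matches,
                        length=length,
                        raw_score=raw,
                    )
                    bucket = per_subject.setdefault(name, {})
                    span_key = (strand, diag)
                    prev = bucket.get(span_key)
                    if prev is None or hit.raw_score > prev.raw_score:
                        bucket[span_key] = hit

        subject_hits = []
        for name, bucket in per_subject.items():
            hsps = sorted(
                bucket.values(), key=lambda h: (-h.raw_score, h.subject_start, h.strand)
            )[:max_hsps_per_subject]
            subject_hits.append((name, hsps))
        subject_hits.sort(key=lambda t: (-t[1][0].raw_score, t[0]))
        out: list[AlignmentHit] = []
        for _, hsps in subject_hits[:max_subjects]:
            out.extend(hsps)
        out.sort(key=lambda h: (-h.bit_score, h.subject_id, h.subject_start))
        return out


def align(
    query_seq: str,
    subject_db,
    query_id: str = "query",
    max_subjects: int = 3,
    max_hsps_per_subject: int = 3,
) -> list[AlignmentHit]:
    """One-shot convenience wrapper; for many queries build a
    :class:`KmerAligner` once (indexing dominates)."""
    aligner = subject_db if isinstance(subject_db, KmerAligner) else KmerAligner(subject_db)
    return aligner.align(
        query_seq,
        query_id=query_id,
        max_subjects=max_subjects,
        max_hsps_per_subject=max_hsps_per_subject,
    )


def parse_tabular_hits(path, query_lengths: Optional[Mapping[str, int]] = None) -> list[AlignmentHit]:
    """Shim for users who prefer an external aligner: read standard
    12-column tabular output (query, subject, identity, length, mismatches,
    gapopens, qstart, qend, sstart, send, evalue, bitscore).  Coverage is
    computed on the query side when ``query_lengths`` is given."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            qid, sid = f[0], f[1]
            ident, length = float(f[2]), int(f[3])
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            bits = float(f[11])
            strand = "+" if sstart <= send else "-"
            if strand == "-":
                sstart, send = send, sstart
            qlen = (query_lengths or {}).get(qid)
            cov = 100.0 * (abs(qend - qstart) + 1) / qlen if qlen else 100.0
            hits.append(
                AlignmentHit(
                    query_id=qid, subject_id=sid, identity_pct=ident,
                    query_coverage_pct=min(cov, 100.0), bit_score=bits,
                    subject_start=sstart, subject_end=send, strand=strand,
                    query_start=min(qstart, qend), query_end=max(qstart, qend),
                    matches=round(ident * length / 100), length=length,
                )
            )
    hits.sort(key=lambda h: -h.bit_score)
    return hits
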