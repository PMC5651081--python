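"""Best-hit placement, validation, and cross-set redundancy."""

import pytest

from panelforge.alignment import AlignmentHit, KmerAligner
from panelforge.core import ManifestRecord, revcomp
from panelforge.placement import (
    PlacementResult,
    PlacementSummary,
    VariantCatalog,
    find_duplicates,
    place_marker,
    place_markers,
    placement_summary,
    predicted_snp_position,
)


def _hit(subject="1H", bits=200.0, ident=99.0, sstart=1000, send=1120,
         qstart=1, qend=121, strand="+"):
    return AlignmentHit(
        query_id="m", subject_id=subject, identity_pct=ident,
        query_coverage_pct=100.0 * (qend - qstart + 1) / 121, bit_score=bits,
        subject_start=sstart, subject_end=send, strand=strand,
        query_start=qstart, query_end=qend,
    )


CATALOG = VariantCatalog(entries={("1H", 1060): frozenset("AG")})


class TestPlaceMarker:
    def test_single_good_hit_with_matching_catalog_validates(self):
        res = place_marker([_hit(ident=96.0)], CATALOG, ("A", "G"))
        assert res.status == "mapped_validated"
        assert res.locations == [("1H", 1060)]
        assert res.matched_polymorphism

    def test_wrong_allele_pair_maps_unvalidated(self):
        catalog = VariantCatalog(entries={("1H", 1060): frozenset("AC")})
        res = place_marker([_hit(ident=96.0)], catalog, ("A", "G"))
        assert res.status == "mapped_unvalidated"

    def test_position_absent_from_catalog_maps_unvalidated(self):
        res = place_marker([_hit(sstart=2000, send=2120)], CATALOG, ("A", "G"))
        assert res.status == "mapped_unvalidated"

    def test_equal_bit_scores_are_ambiguous_with_all_locations(self):
        hits = [_hit(subject="1H"), _hit(subject="2H")]
        res = place_marker(hits, CATALOG, ("A", "G"))
        assert res.status == "ambiguous"
        assert len(res.locations) == 2

    def test_bit_ties_compared_at_one_decimal(self):
        hits = [_hit(subject="1H", bits=200.04), _hit(subject="2H", bits=200.01)]
        assert place_marker(hits, None, ("A", "G")).status == "ambiguous"
        hits = [_hit(subject="1H", bits=200.16), _hit(subject="2H", bits=200.01)]
        assert place_marker(hits, None, ("A", "G")).status == "mapped_unvalidated"

    def test_low_identity_hits_filtered_leads_to_unmapped(self):
        assert place_marker([_hit(ident=94.9)], None, ("A", "G")).status == "unmapped"

    def test_hit_not_covering_snp_base_is_useless(self):
        partial = _hit(qstart=70, qend=121, sstart=1069, send=1120)
        assert place_marker([partial], None, ("A", "G")).status == "unmapped"

    def test_predicted_position_minus_strand(self):
        h = _hit(strand="-")
        # minus-strand: subject base opposite query index 61 counted from the end
        assert predicted_snp_position(h) == 1000 + (121 - 61)

    def test_no_hits_is_unmapped(self):
        assert place_marker([], None, ("A", "G")).status == "unmapped"


class TestPlantedTruth:
    def test_unique_loci_all_map_and_validate(self, sim_bundle):
        aligner = KmerAligner(sim_bundle.reference.chromosomes)
        results = place_markers(
            sim_bundle.legacy_manifests, aligner, sim_bundle.catalog
        )
        by_id = {r.marker_id: r for r in results}
        truth = {l.marker_id: l for l in sim_bundle.truth.legacy_loci}
        for locus in truth.values():
            got = by_id[locus.marker_id]
            if locus.ambiguous:
                assert got.status == "ambiguous"
                assert set(got.locations) == {
                    (locus.chrom, locus.pos), (locus.copy_chrom, locus.copy_pos)
                }
            else:
                assert got.status == "mapped_validated"
                assert got.locations == [(locus.chrom, locus.pos)]

    def test_strand_normalised_validation(self, sim_bundle):
        """A reverse-complemented manifest still validates (A/G == T/C)."""
        locus = next(l for l in sim_bundle.truth.legacy_loci if not l.ambiguous)
        rec = next(r for r in sim_bundle.legacy_manifests if r.marker_id == locus.marker_id)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped = ManifestRecord(
            marker_id=rec.marker_id + "_rc",
            left_flank=revcomp(rec.right_flank),
            right_flank=revcomp(rec.left_flank),
            alleles=(comp[rec.alleles[0]], comp[rec.alleles[1]]),
        )
        aligner = KmerAligner(sim_bundle.reference.chromosomes)
        (res,) = place_markers([flipped], aligner, sim_bundle.catalog)
        assert res.status == "mapped_validated"
        assert res.locations == [(locus.chrom, locus.pos)]

    def test_validation_flips_when_catalog_pair_perturbed(self, sim_bundle):
        locus = next(l for l in sim_bundle.truth.legacy_loci if not l.ambiguous)
        rec = next(r for r in sim_bundle.legacy_manifests if r.marker_id == locus.marker_id)
        other = ({"A", "C", "G", "T"} - {locus.ref, locus.alt}).pop()
        perturbed = VariantCatalog(entries={(locus.chrom, locus.pos): frozenset((locus.ref, other))})
        aligner = KmerAligner(sim_bundle.reference.chromosomes)
        (res,) = place_markers([rec], aligner, perturbed)
        assert res.status == "mapped_unvalidated"


class TestDuplicates:
    @staticmethod
    def _record(mid, seq, alleles=("A", "G")):
        return ManifestRecord(mid, seq[:60], seq[61:], alleles)

    def test_identical_manifests_are_duplicates(self, sim_bundle):
        rec = sim_bundle.legacy_manifests[0]
        clone = ManifestRecord("new0", rec.left_flank, rec.right_flank, rec.alleles)
        pairs = find_duplicates([clone], [rec])
        assert pairs == {(rec.marker_id, "new0")}

    @pytest.mark.parametrize("n_mismatches, expected", [(6, True), (7, False)])
    def test_identity_boundary_at_95_percent(self, sim_bundle, n_mismatches, expected):
        rec = sim_bundle.legacy_manifests[0]
        seq = list(rec.left_flank + "N" + rec.right_flank)
        offsets = [15, 25, 35, 45, 55, 75, 85, 95, 105, 110][:n_mismatches]
        for off in offsets:
            seq[off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[off]]
        mutated = ManifestRecord(
            "mut", "".join(seq[:60]), "".join(seq[61:]), rec.alleles
        )
        pairs = find_duplicates([mutated], [rec])
        # hand count: identity (121 - n)/121 against the 95% threshold
        hand_identity = 100 * (121 - n_mismatches) / 121
        assert (hand_identity >= 95.0) == expected
        assert bool(pairs) == expected

    def test_empty_sets_give_no_pairs(self):
        assert find_duplicates([], []) == set()


class TestSummary:
    def test_published_counts_reproduce_percentages(self):
        s = PlacementSummary.from_counts(mapped=6094, total=6251, validated=4500)
        assert s.mappable_pct == 97.5
        assert s.validated_pct == 73.8

    def test_all_unmapped_is_zero(self):
        results = [PlacementResult(f"m{i}", "unmapped") for i in range(4)]
        assert placement_summary(results).mappable_pct == 0.0

    def test_empty_results_is_error(self):
        with pytest.raises(ValueError):
            placement_summary([])

    def test_counts_ordering_enforced(self):
        with pytest.raises(ValueError):
            PlacementSummary.from_counts(mapped=10, total=5, validated=2)
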