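"""Single-effect classifier: codon changes, splice features, windows."""

import pytest

from panelforge.core import CandidateVariant, EffectClass, GeneModel, GenomeReference, revcomp
from panelforge.effects import (
    EffectAnnotator,
    EffectConfig,
    annotate_effect,
    effect_spectrum,
    translate_codon,
)

from oracles import effect_oracle


@pytest.mark.parametrize(
    "codon, aa", [("ATG", "M"), ("TAA", "*"), ("GCT", "A"), ("TGG", "W"), ("TGA", "*")]
)
def test_translate_codon(codon, aa):
    assert translate_codon(codon) == aa


def test_translate_codon_rejects_ambiguity():
    with pytest.raises(ValueError):
        translate_codon("ATR")


def _variant(chrom, pos, ref, alt):
    return CandidateVariant(f"v_{pos}", chrom, pos, ref, alt)


class TestCodingChanges:
    """Single-exon + strand gene: ATG GCT TAC GGT TAA at positions 101-115."""

    @pytest.fixture()
    def fixture(self):
        orf = "ATGGCTTACGGTTAA"
        seq = "C" * 100 + orf + "C" * 100
        ref = GenomeReference({"c": seq})
        gene = GeneModel("g1", "c", "+", exons=[(101, 115)], cds=[(101, 115)])
        return ref, [gene]

    @pytest.mark.parametrize(
        "pos, ref_base, alt, expected",
        [
            (106, "T", "C", EffectClass.SYNONYMOUS_CODING),     # GCT -> GCC (Ala)
            (104, "G", "C", EffectClass.NON_SYNONYMOUS_CODING), # GCT -> CCT (Ala->Pro)
            (109, "C", "A", EffectClass.STOP_GAINED),           # TAC -> TAA
            (101, "A", "C", EffectClass.NON_SYNONYMOUS_START),  # ATG -> CTG
            (102, "T", "A", EffectClass.START_LOST),            # ATG -> AAG
            (114, "A", "G", EffectClass.SYNONYMOUS_STOP),       # TAA -> TGA
            (113, "T", "C", EffectClass.STOP_LOST),             # TAA -> CAA
        ],
    )
    def test_codon_change_labels(self, fixture, pos, ref_base, alt, expected):
        ref, genes = fixture
        assert ref.base("c", pos) == ref_base
        ann = annotate_effect(_variant("c", pos, ref_base, alt), genes, ref)
        assert ann.effect == expected
        assert ann.gene_id == "g1"


class TestSpliceAndWindows:
    @pytest.fixture()
    def fixture(self):
        seq = "A" * 100 + "G" * 400 + "A" * 9500
        ref = GenomeReference({"c": seq})
        # two-exon + strand gene; intron 151-180
        gene = GeneModel(
            "g1", "c", "+",
            exons=[(101, 150), (181, 230)],
            cds=[(111, 150), (181, 218)],  # 40 + 38 = 78 bases, divisible by 3
        )
        return ref, [gene]

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (151, EffectClass.SPLICE_SITE_DONOR),     # first intron base after exon
            (152, EffectClass.SPLICE_SITE_DONOR),
            (155, EffectClass.SPLICE_SITE_REGION),    # intron base 5 from donor side
            (165, EffectClass.INTRON),
            (179, EffectClass.SPLICE_SITE_ACCEPTOR),
            (180, EffectClass.SPLICE_SITE_ACCEPTOR),
            (175, EffectClass.SPLICE_SITE_REGION),    # intron base 6 from acceptor side
        ],
    )
    def test_intron_features(self, fixture, pos, expected):
        ref, genes = fixture
        ann = annotate_effect(_variant("c", pos, "G", "C"), genes, ref)
        assert ann.effect == expected

    def test_upstream_within_window(self, fixture):
        ref, genes = fixture
        ann = annotate_effect(_variant("c", 95, "A", "T"), genes, ref)
        assert ann.effect == EffectClass.UPSTREAM and ann.gene_id == "g1"

    def test_intergenic_outside_windows(self, fixture):
        ref, genes = fixture
        ann = annotate_effect(_variant("c", 8000, "A", "T"), genes, ref)
        assert ann.effect == EffectClass.INTERGENIC and ann.gene_id is None

    def test_utr_labels(self, fixture):
        ref, genes = fixture
        assert annotate_effect(_variant("c", 105, "G", "C"), genes, ref).effect == EffectClass.UTR5
        assert annotate_effect(_variant("c", 225, "G", "C"), genes, ref).effect == EffectClass.UTR3


def test_strand_symmetry_on_mirrored_fixture():
    """Reverse-complementing the genome and flipping gene strands and
    coordinates must reproduce every label."""
    orf = "ATGGCTTACGGTACCTTA" + "TAA"
    seq = "CA" * 60 + orf + "GT" * 60
    length = len(seq)
    ref = GenomeReference({"c": seq})
    gene = GeneModel("g1", "c", "+", exons=[(121, 121 + len(orf) - 1)],
                     cds=[(121, 121 + len(orf) - 1)])
    mirrored_ref = GenomeReference({"c": revcomp(seq)})
    m_exons = [(length - e + 1, length - s + 1) for s, e in gene.exons]
    mirrored_gene = GeneModel("g1", "c", "-", exons=m_exons, cds=m_exons)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos in range(110, length - 100):
        base = ref.base("c", pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        fwd = annotate_effect(_variant("c", pos, base, alt), [gene], ref)
        mpos = length - pos + 1
        rev = annotate_effect(
            _variant("c", mpos, comp[base], comp[alt]), [mirrored_gene], mirrored_ref
        )
        assert fwd.effect == rev.effect, f"pos {pos}: {fwd.effect} != {rev.effect}"


def test_classifier_matches_enumeration_oracle_on_synthetic_genes(sim_bundle):
    """Spot version of the exhaustive check: both strands, every position of
    a few simulated genes plus a window margin."""
    genes = sorted(sim_bundle.genes, key=lambda g: g.gene_id)[:6]
    annotator = EffectAnnotator(sim_bundle.genes, sim_bundle.reference)
    for gene in genes:
        for pos in range(gene.start - 150, gene.end + 151):
            base = sim_bundle.reference.base(gene.chrom, pos)
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
            got = annotator.annotate(_variant(gene.chrom, pos, base, alt))
            want_label, _ = effect_oracle(
                pos, alt, gene.chrom, sim_bundle.genes, sim_bundle.reference
            )
            assert got.effect == want_label, f"{gene.gene_id} pos {pos}"


class TestSpectrum:
    def test_planted_proportions(self):
        labels = [EffectClass.INTRON] * 2 + [EffectClass.SYNONYMOUS_CODING] * 2
        assert effect_spectrum(labels) == {
            EffectClass.INTRON: 50.0,
            EffectClass.SYNONYMOUS_CODING: 50.0,
        }

    def test_single_variant_is_100(self):
        assert effect_spectrum([EffectClass.UTR5]) == {EffectClass.UTR5: 100.0}

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            effect_spectrum([])

    def test_percentages_sum_to_100_under_rounding(self, sim_bundle):
        annotator = EffectAnnotator(sim_bundle.genes, sim_bundle.reference)
        labels = [annotator.annotate(cv).effect for cv in sim_bundle.candidates[:500]]
        spectrum = effect_spectrum(labels)
        assert sum(spectrum.values()) == pytest.approx(100.0, abs=0.05)
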