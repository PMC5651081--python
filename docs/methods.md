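# Methods

This note records the models, conventions and design choices behind
panelforge, in the order the pipeline runs.

## Coordinates and calls

All public interfaces use 1-based inclusive coordinates (the VCF/GFF3
dialect); any 0-based arithmetic is internal and the conversions are
bijective. Genotypes from candidate VCFs collapse to {RR, AA, RA,
missing}: `0/0` → RR, `1/1` → AA, any mixed genotype → RA, any genotype
containing a missing allele → missing; phased separators are treated as
unphased because the intended material is inbred crop germplasm where
phase carries no information. Multiallelic records and indels are dropped
(not split) with a logged count — array assays are biallelic. Heterozygous
calls count as *non-missing* when computing a candidate's missing rate;
this is a convention choice, exposed through the data rather than
hard-coded logic, since either treatment is defensible for
sequencing-derived calls in inbred lines.

## Manifests

A manifest is the SNP base plus exactly 60 bp of reference flank either
side: 121 bases with the polymorphism as a single IUPAC ambiguity
character, or 125 characters in `[A/G]` bracket notation. Manifests are
always emitted on the forward strand of the reference; legacy markers
keep their historic probe orientation as metadata only, so their
sequence and allele calling stay comparable with earlier array
generations. SNPs closer than 60 bp to a chromosome end are rejected
rather than padded — a probe without full context is not assayable.

## Two-stage selection

**Stage A** filters on missing rate ≤ 0.20 and design score ≥ 0.6
(boundaries inclusive) and keeps at most one SNP per gene, ranked by
design score (desc), missing rate (asc), position (asc). Records without
a design score never pass any filter. Geneless candidates form singleton
groups and survive deduplication.

**Stage B** uses strict inequalities (score > 0.8, missing < 0.05) as the
defaults, with per-zone overrides; the shipped default relaxes the short
arm of 5H to stage-A levels, reflecting chromosome arms whose
genetic::physical ratio is so extreme that the strict filter would starve
them. Both inclusivity modes are flags: the inclusive/strict split follows
the thresholds exactly as conventionally stated, and users who consider
the distinction spurious can normalise it in one line of config.

Zone quotas are apportioned over the four distal zones by largest
remainder on exact rationals (`fractions.Fraction`), remainder ties broken
in fixed distal-zone order, so every quota is within 1 of its exact share
and totals always equal the budget. The per-gene cap (2) counts stage-A
picks: a gene already represented in stage A gets at most one stage-B
addition. Zone shortfalls are redistributed by re-running largest
remainder over the chromosome's still-supplied distal zones; budget that
cannot be placed within the chromosome is reported, never silently filled
from elsewhere — redistribution across chromosomes would break the
per-chromosome genetic-map proportionality that motivates the quotas.

Partition breakpoints are user input. Because published designs set them
empirically from genetic-vs-physical scatter plots, `suggest_partition`
offers a 5-segment piecewise-linear fit (dynamic programming over
candidate breakpoints, exact per-segment least squares via prefix sums) as
a starting point; suggestions never override explicit configuration.

## Alignment and placement

The aligner is deliberately minimal: k-mer-seeded (k = 11), ungapped,
match +1 / mismatch −2, with the best segment per (subject, diagonal)
found exactly by maximum subarray. Queries are 121-base manifests, so
gapped alignment adds nothing the downstream logic consumes — the
contract is identity, query-side coverage, coordinates, stated hit limits
(3 subjects × 3 HSPs) and a bit score strictly monotone in raw score.
Bit scores use fixed published Karlin–Altschul constants for the +1/−2
scheme (λ = 1.28, K = 0.46). IUPAC ambiguity characters match any of
their bases on either side, so an encoded polymorphism never costs
identity. A shim (`parse_tabular_hits`) accepts standard 12-column
tabular output for users who prefer an external aligner.

Placement keeps hits at ≥ 95% identity (inclusive, as stated), discards
hits whose aligned segment does not cover the SNP base (no position could
be predicted from them), and compares bit scores after rounding to one
decimal — the precision alignment tools report, which is what "equal bit
scores" can mean in practice. A unique top score maps the marker at the
subject base aligned opposite query index 61; ties export all tied
locations as "ambiguously mappable". Validation against an independent
variant catalog matches the unordered, strand-normalised allele pair
(A/G ≡ T/C), because catalogs and historic probes may disagree in strand.

Redundancy between marker sets uses the legacy manifests as queries
(coverage is computed on the query side) against the new set, both in
IUPAC rendering, with inclusive thresholds of ≥ 98% coverage and ≥ 95%
identity on the best hit. On 121-mers this puts the identity boundary
between 6 mismatches (115/121 = 95.04%) and 7 (114/121 = 94.2%).

## Effect classification

Each SNP gets exactly one of 17 categories. When several features or
genes apply, the most severe wins, in this fixed order: splice-site
acceptor/donor > stop gained > stop lost > start lost > non-synonymous
start > non-synonymous coding > synonymous stop > start gained >
synonymous coding > splice-site region > 5′ UTR > 3′ UTR > intron >
upstream > downstream > intergenic. Gene ties break by lower gene start,
then gene id — determinism over biological nuance. Defaults follow
common annotation-tool conventions and are all configurable: 5 kb
up/downstream windows, 2 intronic bases for donor/acceptor sites,
intronic bases 3–8 and exonic bases 1–3 for the extended splice region.

Coding changes are classified from the spliced CDS in transcription
order: a variant in an ATG initiation codon is `start_lost` unless the
mutated codon is an alternative initiation codon (TTG/CTG →
`non_synonymous_start`); a variant in the terminal stop codon is
`synonymous_stop` if the mutated codon still terminates, else
`stop_lost`; elsewhere the standard genetic code decides synonymous /
non-synonymous / `stop_gained`. `start_gained` is a 5′-UTR variant whose
alternate allele creates an ATG in a frame-agnostic scan of the
transcript reading direction; the scan uses genomic context and does not
follow splice junctions across the triplet — a simplification that only
matters within 2 bp of a UTR splice boundary.

Non-coding transcripts contribute only their up/downstream windows: the
17-category vocabulary has no label for non-coding exons, so their bodies
are transparent to the classifier. The annotator caches spliced-CDS
context per transcript; classification of ~10k variants against ~100
gene models runs in well under a second.

## QC metrics

Agreement between two call matrices is computed per sample over the
intersection of samples and markers; pairs with a missing call on either
side leave the denominator, and a heterozygous call against a homozygous
call is a disagreement (the most common concordance convention; a flag
excludes heterozygous pairs instead). Samples with zero comparable
markers are flagged and excluded from summary statistics. Reported
percentages are rounded to 1 decimal and ratios to 2, matching
conventional reporting. Order concordance is Spearman's rho with
average-tie ranks (scipy), plus a count of adjacent-pair inversions on
the genetic order and optional flagging of markers whose physical
position is on another chromosome or beyond a configured distance from
the position interpolated from the rest of the map.

`conversion_stats` enforces scorable ≤ working ≤ designed and reports
working/designed and scorable/working. On the published design counts
(49,267 / 44,040 / 43,461) this gives 89.4% conversion and a 98.7%
scorable rate — the latter is sometimes quoted as 98.6, which is the
truncated rather than rounded value of the same quotient.

## Synthetic data

The generator's defaults are the study conditions the tests run under:
two 500 kb chromosomes partitioned like a scaled 1H (physical breakpoints
at 30/560, 60/560, 380/560, 470/560 of the length; distal genetic spans
40, 7, 18, 66 cM; a token 3 cM across the pericentromere), 40 genes per
chromosome with planted ORFs (ATG start, no internal stops, terminal
stop, CDS length divisible by 3), 10,000 candidate SNPs over 50 samples,
200 legacy loci, call-set disagreement 6.1% and missingness 2%,
transition:transversion odds 1.92, and a 97.3% polymorphic marker
fraction. Candidates are 85% genic (exome-capture data is genic by
construction) and both genes and candidates are distally enriched (zone
density multipliers 2/1/1/1/2), mirroring real cereal gene distributions;
design scores are Beta(7, 2) and per-candidate missingness Beta(1, 12),
chosen once as plausible shapes for assay-design scores and
capture-depth dropout. 10% of legacy loci are planted in two verbatim
genomic copies (ambiguity truth) and 1.7% coincide exactly with candidate
positions (cross-set redundancy truth, at the scale of the published
732/43,048 overlap).

A single root seed drives named substreams (one `SeedSequence` spawn key
per generator), so adding a generator never perturbs the draws of
another, and two runs with one spec are byte-identical. Planted 121-mer
windows are checked for genome-wide uniqueness and accidental repeats are
resampled away, so placement tests can demand exact recovery.

What passing tests on this material shows: the selection, placement,
annotation and metric machinery is arithmetically correct against
planted truth and independent oracles. What it does not show: behaviour
under linkage disequilibrium, capture bias, paralogy, or real
polymorphism spectra — none of which the generator models.

## Problem sizes

The test suite and the acceptance script run the generator at its default
scale (≈10k candidates, 1 Mb of genome, 200 legacy markers, 50 × 2,000
call matrices; 20 seeds for the selection oracle), sizes at which every
planted quantity is recoverable with comfortable statistical margins
while the whole suite stays fast.
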