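# Methods

## Scope and coordinate model

All geometry questions — exon vs intron, distance to the nearest splice
junction, which residue a coding base belongs to — are answered by a
single-transcript model (`dicerclass.transcript`). Internal coordinates
are 0-based half-open; VCF and HGVS positions are 1-based and converted
at the module boundary. Intronic distance counts intronic bases only:
the first base of an intron is at distance 1 and exonic bases are at
distance 0. Distances 1–2 define the canonical splice site (pathogenic
if disrupted), 3–9 the splice region (uncertain), and ≥ 10 deep intronic
(out of scope). This is the only non-overlapping reading of the two
thresholds the scheme uses ("within 10 intronic bp" for inclusion,
"≤ 2 intronic bp" for the canonical site). Positions outside the
transcript span report deep-intronic with the distance floored at 10;
at the exact midpoint of an even-length intron, where donor and acceptor
are equidistant, the donor side is reported (a deterministic tie-break;
no bin boundary depends on it).

The geometry engine is strand-generic. *DICER1* lies on the minus strand
of chromosome 14; the orientation is carried by the transcript record,
never assumed by code, so plus-strand toy transcripts exercise identical
code paths in tests. The packaged transcript is a synthetic stand-in for
RefSeq NM_177438.2 (flagged in its filename and header): its structure —
27 exons, minus strand, 5,769-bp CDS encoding 1,922 residues plus stop,
an exon ending at c.4206 — is faithful, while exon and intron sizes are
generated. No genome FASTA is consulted anywhere; protein consequences
are consumed from the annotation fields, not recomputed.

Hotspot membership is decided on the residue index alone (1705, 1709,
1809, 1810, 1813): any substitution at a registered codon qualifies,
whatever the alternate amino acid. The index-only rule is a design
choice — requiring the reference amino acid to match would be equivalent
on consistent annotations and stricter only on corrupt ones.

## Rule engine

Germline rules are evaluated in a fixed priority: loss-of-function,
canonical splice, hotspot missense, knowledge base (all pathogenic);
then the missense criterion dichotomy (likely pathogenic vs likely
benign); splice-region and in-frame deletions (uncertain); synonymous
(likely benign). Only the audit trail (`rules_fired`) is sensitive to
the priority order — the bin is not, because the four P rules are not
mutually exclusive but all map to P. CADD > 30 applies to the scaled
(phred-like) score and both score comparisons are strict, matching the
scheme's published thresholds.

A missense variant whose relevant scores are all missing is binned VUS,
not LB: absence of evidence is not evidence of benignity, and the
published bin structure contains a missense VUS that the threshold
dichotomy alone cannot produce. "Relevant" is criterion-scoped: under
the CADD criterion a missing CADD score makes the variant unscorable
even if metaSVM is present. Missing scores are a distinct sentinel
(`None`) from the file reader onward and are never imputed or defaulted
to zero.

The knowledge-base rule is exact-match on canonicalised HGVS (c. first,
then p.), with no positional or fuzzy matching: "credibly reported
pathogenic" is a curation act, so it enters the pipeline as a
user-supplied file, not as logic.

The somatic rule treats canonical-splice disruption as loss-of-function,
so the two-rule somatic convention (LOF or hotspot) covers it.

## Counting conventions

Unique-variant tabulation deduplicates by canonical identity (HGVS c.,
falling back to p., then raw coordinates). Carrier counts are distinct
subjects with ≥ 1 variant in the bin set. Allele counts are
carrier-level events: co-occurring same-bin variants within one subject
collapse to one event (so the collapsed AC of a bin equals its carrier
count), while distinct subjects sharing a variant each count; a
per-variant mode without collapsing is available but non-default. Both
published rounding conventions are implemented with half-up rounding:
nearest integer for tabular ratios (9,173/13 = 705.6 → 1:706) and
nearest hundred for narrative ones (9,173/2 = 4,586.5 → 1:4,600).
Zero carriers yields an explicit no-carriers result rather than a
division error. Cancer-type fractions use denominators from the subject
roster side (e.g. 3/524 uterine carcinomas → 0.6%), never from the
variant data, since carriers are a subset. No confidence intervals are
attached to the ratios by default, matching the source convention.

## Packaged fixtures

The adult-cohort fixture transcribes the published carrier roster: 19
germline observations, 18 subjects, 16 unique variants, 10 cancer types,
with demographics, the two somatic co-variants of one subject, and
population allele frequencies where printed. Per-variant in-silico flags
are not printed in the source; the packaged assignment is one
reconstruction consistent with every printed aggregate (9 unique metaSVM
missense with allele count 11 — forced to include both twice-carried
metaSVM variants — 5 CADD, 1 REVEL, all 13 covered by at least one).
The flags are data, editable, and documented as a reconstruction. The
pediatric fixture carries the published counts (175 subjects over two
tumour types, two LP carriers, both metaSVM-deleterious, one with
CADD > 30); its variant identities are synthetic stand-ins.

## Synthetic cohorts

The generator (`dicerclass.simulate`) emulates the variant universe the
classifier operates on. Per subject and per intended bin it draws a
Bernoulli carrier indicator (`bin_carrier_fractions`), then picks a
concrete class within the bin from the global class-proportion vector
renormalised over that bin's classes. Every variant is constructed
geometrically: splice-class variants are placed at a verified intronic
distance from a real junction, hotspot variants at a registry codon, and
coding variants at a computed cDNA offset, so recomputing geometry from
coordinates reproduces the intended class — a property the tests check
exhaustively per cohort.

Scores for likely-pathogenic-intent missense are drawn per predictor
(metaSVM 0.6, CADD 0.4, REVEL 0.15 satisfaction probabilities, resampled
until at least one holds) from two-component uniform distributions
straddling each threshold (CADD 30.5–45 vs 1–25; REVEL 0.76–0.99 vs
0–0.60); benign-intent missense draws only the benign components. These
distributions are test instruments designed to exercise both sides of
every decision boundary, not estimates of real score distributions (the
scheme defines thresholds, not distributions). Ground-truth bins are
written at generation time from the class and the realised scores using
the threshold definitions inline, keeping the truth an independent
construction rather than a call into the classifier.

Caller behaviour is modelled as per-caller detection sensitivity plus a
per-caller false-call rate producing single-caller benign observations,
which any ≥ 2-caller consensus removes. Default carrier fractions mirror
the analysed adult cohort (P 2/9,173 ≈ 2.2 × 10⁻⁴, LP 13/9,173 ≈
1.4 × 10⁻³); the uncertain, benign and out-of-scope fractions (0.004,
0.03, 0.01) are set once at levels realistic for a rare-disease gene
screened across a cohort, and subject demographics are uniform payload
never consulted by any rule. What passing synthetic tests shows is that
the pipeline's logic is exact on inputs whose annotations are internally
consistent; it does not validate annotation quality, caller error modes
beyond the simple sensitivity/false-call model, copy-number variation,
or mosaicism, none of which are modelled.

## Test design notes

Problem sizes were chosen to make the checks exhaustive where the domain
is finite (every base of multi-exon toy transcripts on both strands;
every generated variant's geometry) and statistically sound where they
are stochastic: end-to-end ground-truth recovery demands zero
discrepancies on ten independent 1,000-subject cohorts; consensus
merging is compared against a brute-force multiplicity tally on 10,000
random keys; and carrier-fraction recovery checks each 1,000-subject
cohort's carrier count against the exact central 95% binomial interval,
allowing at most two of ten cohorts outside it so the whole check has a
designed false-failure probability near 1% rather than the 40% a
10-way all-must-pass rule would carry.

## Known limitations

The pipeline classifies annotated observations; it does not call
variants, normalise representations beyond allele decomposition, or
re-derive consequences, and disagreements between an upstream
annotation and transcript geometry are resolved in favour of geometry
for splice classes only. Copy-number changes are invisible to it.
Single-transcript only, by design; the published "1:1,500 by CADD"
narrative figure is not reproducible from the printed per-criterion
aggregates under any flag assignment (the printed unique-variant counts
imply at least seven CADD-criterion carriers, i.e. at most 1:1,310) —
the package reports what it computes.
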