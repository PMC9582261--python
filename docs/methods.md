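# Methods

This note documents the models, conventions and numerical choices behind
`gcrep`, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinates and the germline reference

All coordinates are 0-based half-open on ungapped sequences.  V genes are
read in the IMGT-gapped dialect (gap character `.`); FR/CDR boundaries are
derived once at load time from IMGT unique numbering (FR1 codons 1–26,
CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104) by counting non-gap
characters up to each codon boundary.  A gapped V must be exactly 312 nt;
anything else is rejected as inconsistent with the numbering.  The
packaged mini-reference (6 V, 3 J, 7 CH1 segments) is synthetic — generated
once with a fixed seed, stop-codon-free in frame, with a conserved Cys
codon at IMGT 104 and IMGT-style gaps in two genes — because the real
germline database cannot be redistributed here.  All coordinate and region
logic is identical for real IMGT references supplied by the user.

Hotspot motifs RGYW and WRCY (R=A/G, Y=C/T, W=A/T) are scanned on the
given strand separately; *every* position of a motif occurrence counts as
inside that motif, and a position may satisfy both motifs (e.g. AGCT).
The same convention is used by the simulator's targeting model, the
neutral expectation and the pattern statistics, so the three are directly
comparable.

## Annotation

The aligner is deliberately self-contained and ungapped: k-mer seeds vote
for a diagonal per gene, the best diagonal is scored over the full overlap,
and ties are broken by lexicographically smallest gene name.  Reads under
150 nt, or without a V hit at ≥ 60% identity over ≥ 100 nt, are
unassignable and logged.  Indels are out of scope (the generator emits
substitutions only), which makes ungapped alignment exact for the data the
pipeline targets; pre-annotated AIRR TSV input bypasses discovery but
mutations are re-derived from `sequence` against the called V.

Mutation calling compares aligned V positions to the germline; N positions
are skipped and removed from the identity denominator.  For a codon
carrying more than one mutation, each mutation is classified against the
germline codon with the other read positions held at the read state — a
deterministic convention (the alternative, cumulative left-to-right
application, differs only on multi-hit codons, which are rare at GC-typical
loads).  `v_identity = 1 − mutations / non-N aligned length`, which makes
it invariant to appended constant-region sequence.

The junction is taken as the last V codon through the first aligned J
codon (CDR3 plus anchors).  CDR3 is excluded from SHM and selection
denominators throughout: junction diversity reflects V(D)J joining, not
SHM, and the germline there is unknowable without a D model.  Whether
published SHM denominators include primer-covered FR1 is typically
unstated; here the FR1 primer mask length is configurable and defaults to
0, and masked positions are excluded from both numerator and denominator.

Subclass assignment matches the read's 3′ constant segment against each
CH1; the call requires the best entry to beat the runner-up by ≥ 2
mismatches, otherwise only the class-level isotype is kept.  With ≥ 3
differences between any two CH1 entries this margin makes the call robust
to sequencing error (≥ 99% accuracy at 0.5%/base in recovery tests).

## Clones and the two filtering regimes

Clone definition: same V gene and J gene (gene level — allele calls are
unstable under SHM), same junction length, junction identity ≥ 0.85 with
single linkage, grouped jointly across a donor's populations.  The 0.85
threshold is the common AIRR convention and is exposed as a parameter;
grouping is verified against independent brute-force single-linkage
clustering in the test suite.

`CLONE_COLLAPSE` keeps, per clone per population × isotype stratum, the
member with minimal Hamming distance to the stratum's per-position
majority consensus (ties: highest duplicate count, then smallest read id) —
the choice least likely to carry sequencing error; "first" and
"most-mutated" selectors are available for sensitivity analysis.

`UNIQUE` first merges identical sequences within a stratum, summing
duplicate counts.  Records with summed count 1 are then treated as
unsupported: they are dropped if they sit within one mismatch of a
supported (count ≥ 2) record of the same stratum and length (a likely
error copy is absorbed), or if they are not within the clone-linkage
threshold of any supported record (an unsupported isolate); singletons
clonally linked to supported records are kept as genuine rare variants.
This error-suppression rule is this package's own explicit stand-in for
unpublished read-cleaning recipes and is labelled as such in reports.  Its
feasible operating regime follows from duplicate arithmetic: with
per-base error ε and read length L, the probability a read is error-free
is e^(−εL), so support-based suppression is informative only when εL ≲ 0.1
(most reads clean, error reads one mismatch away from their source); at
εL ≈ 1 or beyond, no identical duplicates exist and no support-based rule
can simultaneously remove error variants and retain true sequences.  Tests
therefore exercise the rule at ε = 2·10⁻⁴ with geometric duplication
(mean 3), where the analysis predicts roughly 60–85% error-unique removal
at ≈ 90% true-sequence retention.

Strata with fewer than 45 post-filter sequences are excluded from all
downstream summaries (threshold configurable).  The rule is applied per
population × isotype class; how published analyses resolved this
ambiguity (per class, per population, or per combination) is unstated, so
the combination — the strictest reading — was chosen and recorded in every
filter report.

## SHM profiles and the CB–CC comparison

Stratum summaries keep the full per-sequence SHM% distribution and its
median; pattern fractions are pooled over the stratum's mutations and are
undefined (flagged) for unmutated strata.  Pattern statistics computed:
fraction of mutations at G:C vs A:T germline pairs, transition fraction
within each, fraction inside RGYW and inside WRCY (each motif counted per
flag), and replacement fraction within CDR and within FWR.  The published
panel this mirrors is not fully enumerable from text; this set covers the
G:C/A:T lesion-processing logic and may be a superset.

CB vs CC SHM is compared with a two-sided unpaired t-test on per-sequence
values; the unequal-variance (Welch) form is the default since stratum
variances differ materially, with the Student form behind a flag.  The
pipeline reports the direction sign(mean CB − mean CC) alongside t and p.

## Selection analysis

The neutral model enumerates all 3L single-base substitutions of each
germline V, weighting each by hotspot weight (motif positions) and an
optional transition bias, and derives (a) the expected fraction of
mutations allocated to CDR and (b) the expected replacement fraction
within CDR and FWR.  Stratum expectations aggregate per-sequence gene
expectations weighted by mutation count, so heavily mutated sequences
dominate, matching the pooled observed counts.  Observed vs expected is
tested with the exact two-sided binomial test; the score is the log odds
ratio σ (zero exactly at the expectation, antisymmetric around a 0.5
expectation, ±∞ at empty cells, flagged when a stratum has no mutations).
Three results are reported per stratum: CDR allocation, CDR R/S, FWR R/S.
Selection is scored pooled per stratum; per-sequence scores would require
per-sequence mutation counts large enough for a binomial test and are left
as auxiliary use of the same helper.  This enumeration + exact-inference
design is a deliberate, fully testable reimplementation choice, not a
reproduction of any published selection framework (e.g. lineage-aware or
posterior-density methods are out of scope).

Calibration: with the generator's targeting matched (same hotspot weight,
no transition bias) and selection off, the pooled observed replacement
fraction is statistically indistinguishable from the enumerated
expectation, and the binomial p-value distribution is near-uniform.  The
uniformity check uses strata of ≈ 200 CDR mutations per replicate because
the exact binomial p-value is discrete: its largest atom is roughly
1/√(2πnpq), so resolution — not calibration — sets a floor on the
Kolmogorov distance for small strata.

## Clonality, overlap and clone reports

Clone size for clonality metrics is the number of distinct member
sequences in the stratum (unique-sequence regime).  Metrics: largest-clone
fraction, expanded fraction (clones of size ≥ 2), Gini coefficient, and
Shannon evenness H/ln K (defined as 0 for a single clone).  A clonality
plot of expanded fraction (x) against evenness (y) reproduces the
qualitative corners "little clonality" (top left), "one very large clone"
(bottom left), "many small clones" (bottom right); the published axes are
not defined in text, so this is a documented reconstruction.

A clone is shared in a population if it also contains ≥ 1 sequence from
another population; a clone spanning three populations contributes to all
three numerators.  Overlap percentages are invariant to duplicate counts
and member order, and the unique-sequence regime is the default
denominator (recorded in every output row).

Clone mutation reports partition mutated positions into shared (all
members), partial (≥ 2 but not all) and unique (exactly one) sets — these
are disjoint and their union is exactly the set of mutated positions — and
render a text alignment with R/S markers and CDR columns.  On simulated
lineages the shared set equals the mutations carried by the sampled
members' most recent common ancestor ("trunk" mutations) except in the
rare event that a member back-mutates a trunk position below the MRCA
(probability ≈ trunk × downstream mutations / 3L per clone); the
ground-truth API exposes both the trunk set and the exact member-sequence
oracle, and tests pin the report against the latter plus the trunk case on
a hand-built lineage.

## The synthetic generator: what it emulates, and what it does not

Emulated: clonally related reads from sorted populations with
lineage-structured SHM (shared trunks arise because sampled cells reuse
existing lineage paths with probability 1/2 per division), hotspot-biased
targeting, selection-biased acceptance of CDR replacements, irreversible
class switching along the locus, heavy-tailed clone sizes (Pareto weights
with tail exponent `alpha`), population sampling with per-population mean
division counts, PCR duplication (fixed or geometric) and per-base
substitution error.  Junctions are built from templated V/J ends plus a
random N-insert (total 30–60 nt, in frame) — realistic clone
discrimination without a D-gene model.

Key defaults and why: 200 clones and 150–300 molecules per population give
post-collapse strata comfortably above the 45-sequence rule, as in the
libraries the analysis expects; `mu = 1.5` candidate mutations per
division over ~10 divisions yields ~3% median SHM, a typical GC load;
`hotspot_weight = 3` produces a detectable but not caricatured targeting
excess; per-division switch probability 0.08 out of IgM (one quarter of
that onward) yields roughly 45/40/10 M/G/A class usage after 10 divisions;
sequencing error 0.002/base and geometric duplication mean 3 are in the
range of amplicon protocols after quality filtering.  `clone_span_prob`
(with an optional population restriction) controls how many clones span
populations: confining spanning to CB/CC reproduces a healthy-donor-like
overlap signature (PB 0% shared), spanning all GC populations a
recycling-like one.

The selection acceptance rule — CDR replacements accepted with
min(1, e^s), all other candidates with min(1, e^−s) — realises the
intended relative factor e^s between the two candidate classes in both
directions while staying neutral at s = 0; a one-sided cap alone would be
a no-op for s > 0.  Acceptance applies per candidate, so s ≠ 0 also thins
the realised mutation load slightly.

Not emulated (and hence not demonstrated by passing tests): affinity
landscapes and Tfh-help dynamics, dark/light-zone mechanics, indels,
homopolymer error modes, light chains, D genes, and selective death of
low-affinity CC — the last means the generator does not reproduce the
empirical CB > CC SHM gap attributed to antigen selection; populations
differ in SHM only through their mean division counts.  SHM is confined to
the V segment (junction, J and CH1 are never mutated), so J-region SHM and
junction-proximal effects are absent.  Naive populations
(mean divisions 0) are independent unmutated singleton founders, not
members of GC clones.

Determinism: one integer seed drives a single generator stream; identical
config + seed gives byte-identical FASTA/TSV output, and the pipeline
manifest records a config hash and an output hash.

## Degenerate inputs and tie-breaks

Empty strata raise typed errors rather than returning NaN rows; excluded
strata are refused with a reference to the filter report.  Consensus ties
break by base order, representative ties by duplicate count then read id,
gene-call ties lexicographically; clone ids are ordered by smallest member
read id.  Reads without junctions are skipped and logged in grouping;
records with N at a position never count it as mutation or denominator.

## Problem sizes used in validation

Recovery tests run at desk scale: strata of 40–200 molecules, 20 seeds for
paired comparisons, 500 replicates for null calibration, 100 random
instances for clustering equivalence — sizes chosen so each check has the
statistical resolution its tolerance needs (3 standard errors, binomial
CIs, or exactness).  Full-scale deposited datasets can be analysed through
the AIRR input path unchanged.
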