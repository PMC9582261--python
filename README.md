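# gcrep — germinal-center BCR repertoire analysis

`gcrep` analyses immunoglobulin heavy-chain (IGH) repertoires of sorted
germinal-center (GC) B-cell populations — naïve, centroblast (CB),
centrocyte (CC), memory (mem) and plasmablast (PB) — the way clinical
immunology studies of GC dysfunction do: it infers clones from junction
sequences, applies two complementary filtering regimes, and quantifies
somatic hypermutation (SHM), antigen selection, IGHG subclass usage,
clonality and cross-population clonal overlap.  A lineage-structured
synthetic repertoire generator provides complete ground truth for every
stage, so each statistic is validated by parameter recovery rather than by
eyeballing.  It is aimed at immunogenomics analysts working with bulk AIRR
data from sorted B-cell subsets, and at method developers who need a
ground-truthed GC simulator.

## The model and statistics

**Clones.** Two sequences belong to the same clone iff they use the same
IGHV and IGHJ gene (gene level), have the same junction length, and their
junction nucleotide identity is ≥ 0.85 under single-linkage clustering.
Clustering runs jointly across all populations of a donor, which is what
makes cross-population overlap measurable.

**Filtering regimes.** `CLONE_COLLAPSE` keeps one representative per clone
per population × isotype stratum (the member closest to the stratum
consensus), so SHM/selection/subclass summaries are not skewed by large
clones.  `UNIQUE` collapses identical sequences (summing duplicate counts)
and suppresses unsupported singletons as error control, and feeds the
clonality and overlap analyses.  Any stratum with fewer than 45 sequences
after filtering is excluded from downstream summaries.

**SHM.** Per sequence, SHM% = 100 · m / L where m is the number of mutated
positions of the aligned V region (CDR3/junction excluded, primer-masked
FR1 and N positions excluded) and L the corresponding denominator.  CB vs
CC levels are compared with a two-sided unpaired Welch t-test.  Pattern
statistics summarise AID biology: mutations at G:C vs A:T pairs,
transition fractions, RGYW/WRCY hotspot-motif targeting, replacement
fractions in CDR vs framework.

**Selection.** The neutral expectation enumerates every single-base
substitution of the germline V, weighted by the targeting model (hotspot
weight, optional transition bias), giving the expected CDR allocation and
the expected replacement fraction R/(R+S) per region.  Observed counts are
tested with an exact binomial test and summarised by the log odds ratio

    σ = log[ odds(observed fraction) / odds(expected fraction) ]

σ > 0 means replacement enrichment (positive selection), σ = 0 neutrality,
with a Clopper–Pearson 95% CI on the observed fraction.

**Clonal structure.** Per stratum: largest-clone fraction, expanded-clone
fraction, Gini coefficient of clone sizes, normalised Shannon evenness.  A
clone counts as *shared* in a population if it also contains a sequence
from another population; per-population shared percentages, the pairwise
overlap matrix and upset-style membership counts are reported.  Per-clone
reports partition mutated positions into shared / partial / unique sets
and render a text alignment with R/S markers and CDR highlighting.

**Simulator.** Each clone is a branching lineage: per division, a Poisson
number of candidate V-segment mutations with positions up-weighted by
`hotspot_weight` inside RGYW/WRCY motifs; a candidate CDR replacement is
accepted with probability min(1, e^s) and any other candidate with
min(1, e^−s), so `selection_s` tilts the replacement landscape; isotype
state follows an upper-triangular per-division transition matrix over the
locus order M, G3, G1, A1, G2, G4, A2.  Sampled molecules are
PCR-duplicated and read out with per-base substitution error, and the
ground truth records lineage trees, true mutations and error positions.

## Worked example

The numbered drivers under `analysis/` run a three-donor synthetic cohort
(healthy-like `HD`, impaired-SHM `P2like`, recycling-like `P3like`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_annotate_reads.py
python analysis/03_filter_regimes.py
python analysis/04_bcr_specification.py
python analysis/05_clonal_structure.py
```

`04_bcr_specification.py` prints, per donor (abridged):

```
HD:
  IGHM: median SHM CB 2.24% vs CC 2.24% (CB > CC, p=0.224)
  CC IGHM CDR selection sigma = 0.574 (p=0.0146)
  CC IGHG distal subclass index = 0.197
P2like:
  IGHM: median SHM CB 1.29% vs CC 1.45% (CB <= CC, p=0.113)
  CC IGHM CDR selection sigma = -0.038 (p=0.888)
  CC IGHG distal subclass index = 0.040
P3like:
  IGHM: median SHM CB 6.54% vs CC 5.45% (CB > CC, p=0.563)
  CC IGHM CDR selection sigma = 0.047 (p=0.859)
```

i.e. the healthy-like donor shows a clearly positive CDR selection score,
the impaired donor low SHM with no selection signal and near-absent distal
IGHG subclasses, and the recycling-like donor high SHM without selection.
`05_clonal_structure.py` prints the overlap signature:

```
HD:       PB  0.0% shared (0/27 clones)   CB 57.4%, CC 54.7%
P3like:   PB 85.3% shared (29/34 clones)  CB 87.2%, CC 80.4%
```

— overlap confined to the CB/CC axis in the healthy-like donor versus
broad sharing across all GC populations in the recycling-like donor.  All
tables land under `results/`.

The same pipeline runs from the shell: `gcrep simulate`, `gcrep annotate`,
`gcrep analyze --airr annotated.tsv`, or `gcrep run --config run.yaml`
(AIRR Rearrangement TSV in/out throughout).

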