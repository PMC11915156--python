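# Methods

## Redox classification model

The atomic unit of the analysis is the *cysteine site observation*: a
(protein accession, 1-based residue position, redox label, condition,
replicate) tuple.  Labels are assigned purely from the variable-modification
tokens of the search-engine export through a `ModificationMap`: NEM-type
tokens (+125.05 Da; the monoisotopic mass of the C₆H₇NO₂ adduct is computed
from standard atomic masses at import time) mean the thiol was free in vivo
(*reduced*); BPM-type tokens (+548.28 Da) mean it was reversibly oxidized;
an untagged cysteine is *unlabeled*.  Numeric tokens are matched to
registered delta masses within ±0.02 Da.

Peptides are located in their stated protein by exact substring search.  A
peptide that matches at several offsets is flagged ambiguous and excluded by
default (`include_ambiguous=True` retains it); a peptide absent from its
protein is skipped with a logged reason.  No razor-protein or shared-peptide
inference is attempted: the accession in the PSM row is taken as given.

Counting conventions, used everywhere downstream:

- duplicate observations (same site, label, condition, replicate from
  different PSMs) collapse to one;
- a site seen with *both* tags in one replicate (different PSMs) keeps one
  observation per label — the within-condition mixed-label states are
  exactly what the Venn regions M and N describe;
- a single residue carrying both tag classes in the *same* PSM is
  contradictory and is dropped with a log entry;
- percentage denominators are the distinct (site, label) observations of the
  replicate, so %ox + %red + %unlabeled = 100 per replicate.

Group comparisons use the equal-variance two-tailed Student's t test on
per-replicate percentages, reported as mean ± SEM (SEM with ddof = 1).

## Reproducibility and region algebra

A (site, condition, label) is *reproducible* when detected in at least
`min_replicates` (default 2) of `n_replicates` (default 3) replicates.
Unlabeled observations never become reproducible entries.  Each reproducible
site key then carries a pattern (S_RT, S_cold), S ⊆ {oxidized, reduced}, not
both empty: 15 realizable patterns, partitioning all reproducible sites.
Classes are defined set-theoretically — dynamic (both non-empty, unequal),
RT-/cold-exclusive (other side empty), stable (equal, non-empty), and
reactive = the three oxidation-shifted dynamic patterns
({red},{ox}), ({ox,red},{ox}), ({red},{ox,red}).

Letters L, M, N for the reactive patterns are fixed by their published
definitions, and A–C / I–K are the RT-/cold-exclusive blocks.  The letters of
the nine remaining regions are not recoverable from any public definition, so
this package fixes a canonical order (documented in `repro_regions`) and
treats letters as presentation labels; all tests assert class semantics, not
letter identity, except for L/M/N.  Protein-level Venn counts deduplicate by
accession within a region or class, so a protein with several sites in the
same category counts once.

## Motif statistic

Windows are 15-mers with the cysteine fixed at the center; flanks truncated
by a protein terminus are padded with `-`, and pads are excluded from both
foreground counts and background frequencies (numerator and denominator).
The background is, by default, the per-position residue frequency over *all*
cysteine-centered windows of the supplied proteome, with the foreground not
subtracted; a pooled-composition background is available as an option since
published pLogo runs do not state which convention was used.

The score is the signed −log10 exact binomial tail (enrichment:
P(X ≥ k); depletion: P(X ≤ k), negative sign), computed with scipy's exact
binomial distribution and cross-checked in the tests against brute-force
term summation to 1e-9.  The published cut-off 3.75 is reproduced as the
Bonferroni bound −log10(α / (20 residues × 14 positions)) at α = 0.05
(3.7482, printing as 3.75); any constant can be supplied directly instead.
By construction the per-logo family-wise probability of any false enrichment
call is ≤ α, which the acceptance suite verifies empirically over 200 null
logos.  Degenerate background cells (p exactly 0 or 1, possible with tiny
backgrounds) cannot carry a finite score: consistent cells (k = 0 with
p = 0; k = N with p = 1) score 0, inconsistent ones ±inf and are flagged.

The heatmap matrix is the score matrix with rows permuted into a
property-grouped order (charged, polar, special, hydrophobic); values are
never altered by reordering.

## Subcellular and abundance summaries

Sites are joined to a compartment table (controlled vocabulary of seven
compartments with a small alias map for UniProt term variants such as
"Mitochondria" vs "Mitochondrion").  A site on a protein annotated with m
compartments contributes one record to each — multi-localization inflates
compartment counts by design and never deflates them.  Percent oxidized per
compartment uses tagged sites only, computed per replicate and averaged
(mean ± SEM, Student's t between conditions); a pooled mode collapses
replicates first, since the per-replicate vs pooled denominator convention is
not externally fixed.

Abundance analysis: each sample column is scaled so its total equals the
mean raw column total (total-sum normalization); log2 fold change is
log2(mean_cold / mean_RT) of normalized intensities; the per-protein test is
an equal-variance two-tailed t on log2 intensities (the log scale is the
standard surrogate when the upstream software's internal test is
unspecified; a raw-scale option exists).  Significance is p < 0.05 with
|log2FC| > 0 and deliberately no multiple-testing correction, matching the
stated decision rule.  Proteins with a zero group mean have no defined fold
change and are excluded from testing.

## Synthetic data generator

The generator emulates a 2-condition × 3-replicate differential-alkylation
study at desk scale.  Defaults: 200 proteins of 250–450 residues drawn
i.i.d. from a mouse-like residue composition; 318 planted labeled sites
distributed over the 15 patterns in roughly the proportions of the study
design scaled to about a quarter (stable-reduced dominating, ~50 oxidized /
~240 reduced site-labels at RT, a small dynamic minority with 17 reactive
sites); 30 unlabeled filler sites; detection probability 0.9 per replicate
(1.0 and 2/3 are used by specific tests); lysine planted at −1 in 60 % of
reactive sites and aspartate at +1 in 50 % of exclusively reduced sites,
mirroring the positive-charge-near-thiolate chemistry the motif analysis is
meant to detect; a 6-sample log-normal abundance matrix (σ = 0.2 on the log2
scale) with 20 proteins shifted 2-fold in the cold.

Sites are planted at spaced positions; the local sequence is sanitized so
that each site lies on a fully tryptic peptide (cut after K/R, no missed
cleavage) that occurs exactly once in its protein — rare collisions are
resolved by swapping in a tryptophan away from planted positions.  Every
PSM is emitted independently per (condition, label, replicate) with the
detection probability, so the 2-of-3 pass rate under detection probability
p is exactly P(Binomial(3, p) ≥ 2).  An audit pass (`synthetic_data.audit`)
re-checks emitted files against the truth table after every generation.

What the generator does **not** emulate: spectral noise and FDR, missed
cleavages, shared peptides between proteins, correlated detection across
replicates, compartment-dependent redox bias, and real proteome sequence
structure (windows are i.i.d. given the planted motifs).  Passing recovery
tests therefore demonstrate correctness of the counting, algebra and
statistics under the stated sampling model, not robustness to search-engine
artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the Monte-Carlo
checks statistically decisive yet quick: 300 (site, condition, label)
trials for the binomial reproducibility check (3-SD band around 20/27),
100-window foregrounds against 4000-window backgrounds with 200 null
repetitions for the motif family-wise check, and 500–600 proteins for the
abundance false-positive and effect-recovery checks.  The binomial tails
use scipy's exact implementation (agreement with direct summation is
≤ 1e-14 over all N ≤ 30 grids tested).  Ties and degenerate inputs follow
these rules: empty replicate → excluded with a warning; zero-variance t
tests with equal means report t = 0, p = 1; empty compartments are omitted;
a both-empty redox pattern and a reproducibility threshold above the
replicate count are errors.

## Known limitations

- The letter assignment for the nine unnamed Venn regions is a package
  convention; only L/M/N (and the A–C / I–K blocks) are externally fixed.
- The pLogo statistic here is the signed −log10 binomial tail; the
  log-odds-of-binomial variant described in the original pLogo publication
  is isolated behind `plogo_score` and could be swapped in.
- Percentage and compartment denominators are per-replicate by default;
  pooled variants are provided because the original convention is ambiguous.
- Headline site counts of the motivating study derive from deposited LC-MS
  raw data and are not recomputable here; the packaged reactive-site table
  supports the published worked example only.
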