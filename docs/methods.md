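# Methods

`tcrrep` characterizes T-cell receptor β-chain (TCRβ) CDR3 repertoires:
it simulates V(D)J recombination under configurable group phenotypes,
annotates junctions against a germline segment reference, and computes the
diversity, composition, sharing, and cohort statistics used to compare
immunodeficiency patient groups with healthy controls. This note records
the models, conventions, and numerical choices behind each stage.

## Junction convention

The CDR3 junction runs from the conserved V-segment cysteine codon through
the conserved J-segment phenylalanine/tryptophan codon, both inclusive;
every length in the package is a junction length under this convention.
Coordinates are 0-based half-open internally. The reading frame of every
junction — including out-of-frame ones — is anchored at position 0, the
first base of the cysteine codon. A junction is `oof_frameshift` when its
length is not a multiple of three, else `oof_stop` when any in-frame codon
is a stop, else `in_frame`; the precedence makes the three classes
disjoint, so the two out-of-frame subtypes partition the non-productive
pool (whether a stop-containing frameshift should count in both panels is
genuinely ambiguous; we chose disjoint classes and state it here).

## Generative model (synthetic_data)

Each clone is assembled the way the locus assembles one:

1. V, D, J segments are drawn by configurable weights; an optional V–J
   mask removes forbidden pairings (the joint V×J weight matrix is zeroed
   and renormalized).
2. Each recombining edge — 3'V, 5'D, 3'D, 5'J — loses a
   truncated-geometric number of nucleotides. Geometric lengths were
   chosen because they are single-parameter, monotone, and heavy-tailed;
   nothing in the package depends on the exact family beyond its mean.
   V and J always retain at least 1 nt; the D segment may be deleted
   completely (5' deletion drawn first, capped at the D length; 3'
   deletion then capped at what remains).
3. The two non-templated insertions (V–D and D–J) have truncated-geometric
   lengths (cap 30 nt, far in the tail of every preset) with bases drawn
   i.i.d. from a nucleotide bias, default P(G)=P(C)=0.3, P(A)=P(T)=0.2.
   The GC excess reflects the dGTP/dCTP preference of terminal
   deoxynucleotidyl transferase (TdT); the exact magnitude is a package
   default, configurable.
4. Read counts follow a Zipf-like power law over clone ranks with
   exponent `clone_size_alpha`: every clone receives one read, and the
   remaining budget is apportioned by largest remainder, so the read sum
   is exact. Rank-to-clone assignment is a seeded permutation.
5. Clones that happen to produce an identical (junction, V, J) triple are
   merged rather than re-drawn — convergent recombination is the very
   phenomenon the sharing analysis measures.

Every simulation emits a truth ledger (one row per generated clone) from
which each junction reconstructs byte-for-byte; spiked rows (below) are
flagged and exempt from reconstruction.

### Group presets

No quantitative generative parameters exist for the real patient groups,
so the presets encode only the qualitative repertoire phenotypes reported
for them, with magnitudes chosen once as package defaults:

| preset | deletions (3'V,5'D,3'D,5'J) | insertions (V–D, D–J) | clone-size α | V–J mask |
|---|---|---|---|---|
| control | 3.5, 3.5, 3.5, 3.5 | 4.5, 4.5 | 0.5 | none |
| AT | 3.2, 3.2, 3.2, 3.2 | 3.0, 3.0 | 1.1 | none |
| ICF1 | 1.5, 3.5, 3.5, 3.5 | 4.5, 4.5 | 0.5 | none |
| ICF2 | 1.8, 3.5, 3.5, 3.5 | 4.5, 4.5 | 0.95 | none |
| atypical_SCID | 3.5, 3.5, 3.5, 3.5 | 3.8, 3.8 | 0.8 | fixed 40% of pairs |

The ataxia-telangiectasia (AT) preset removes 3.0 nt of total insertion
(its defining deficit, attributed to reduced TdT activity downstream of
ATM loss) and mildly shortens deletions — insertion loss dominates, so
mean CDR3 length falls — while raising clonal skew. The ICF presets
lengthen CDR3 through longer 3'V retention; ICF2 additionally restricts
diversity. The atypical-SCID preset forbids a fixed, deterministic 40% of
V–J pairs and moderately reduces insertions. Control insertion means of
4.5 nt per junction sit in the middle of the 2–5 bp-per-joint range
typical of human coding joints.

### paTCR spiking

`spike_patcr` replaces ⌊fraction × unique⌋ randomly chosen clonotypes
with back-translations of database CDR3s (most-frequent human codon per
residue, so back-translation is deterministic). Replacements that would
collide with an existing (junction, V, J) key take the next database
entry, so the unique clonotype count — and hence the spiked proportion —
is preserved exactly.

## Germline reference

The packaged reference (`germline_trb_synthetic.fasta`) is a synthetic
stand-in for a TRB locus: 12 V, 2 D, and 13 J segments with the header
grammar `>NAME|CLASS[|anchor=N]`, where the anchor is the 0-based offset
of the conserved Cys (V) or Phe (J) codon. V junction regions (anchor to
3' end) are 15 nt; J junction regions (5' end through the anchor codon)
are 15 nt; D cores are 12 and 16 nt and GC-rich like their natural
counterparts. V tails and J heads were generated with enforced pairwise
divergence (Hamming ≥ 7 over 12 nt, distinct anchor-adjacent triplets) so
that short retained stretches still discriminate genes — a property real
TRBV genes get from their length, which a 15-nt toy flank must get from
design. Any IMGT-style reference with the same header grammar can be
substituted.

## Annotation (vdj_annotation)

Segment calls use ungapped terminal alignment (match +1, mismatch −2):
the V candidate whose junction region has the maximal-scoring contiguous
prefix against the read wins, J symmetrically from its anchor backward,
with a coarse pass over genes followed by a refinement pass over the
winning gene's alleles. Calls require a terminal match of at least 5 nt
(configurable); junctions failing it are counted unassignable, not fatal.
D segments are searched only between the V and J blocks and require at
least `min_d_match = 3` contiguous exactly matching nucleotides. Ties
break to the longer match, then the lexicographically smaller name.

### Boundary ambiguity and the posterior decomposition

Maximal matching is the right rule for *calling* but a biased rule for
*decomposing*: whenever an inserted base coincidentally equals the
germline base it replaced, the maximal match absorbs it, so deletions are
understated and insertions shortened — under the control preset the
deficit is roughly 0.4 nt per junction, which would defeat any attempt to
read generative parameters back off annotated data. Two boundary modes
are therefore offered:

* `greedy` — deterministic maximal matching (deletion = available −
  matched length, using the longest *exact* terminal match; the scored
  match may bridge isolated mismatches and is used only for calling).
* `posterior` (default) — given the V and J calls, every consistent
  tiling of the junction is enumerated: the V block may hand back up to 4
  terminal bases (posterior mass decays ~4-fold per base, so deeper moves
  are negligible), symmetrically for J; the D block ranges over every
  exact germline-D run between the blocks, with up to 4 nt trimmed from
  either end but never below `min_d_match`; and a no-D tiling (retained D
  below the identification threshold, the whole region non-templated) is
  always included. Each tiling is weighted by its likelihood under
  geometric length priors for the four deletions and two insertions and
  an i.i.d. base model for insertions: bases claimed by a germline block
  contribute likelihood one, the same bases explained as insertion
  contribute their insertion base frequency. One tiling is sampled per
  junction (seeded), which keeps decompositions integral and
  length-conserving while removing the systematic bias of maximal
  matching in expectation.

The prior parameters are estimated from the data themselves, in two
passes: a greedy pass yields moment estimates (geometric odds recovered
by inverting the truncated-mean formula, since observed deletions live on
a bounded support; insertion base frequencies with a +1 pseudocount), a
first posterior pass refreshes them, and a second pass produces the final
decompositions. No generator internals are consulted.

Residual limitations: junctions whose true V or J retains fewer
nucleotides than the minimum terminal match are intrinsically
unidentifiable — on simulated data their "calls" are chance matches.
Accuracy is therefore reported over identifiable clonotypes (true
retained segment ≥ the minimum match), the same conditioning applied to
D-call accuracy. Per-junction insertion summaries remain very slightly
conservative (≈0.1 nt under the control preset) because miscalled clones
and same-name D misplacements are invisible to the boundary model.
D-ambiguous clonotypes never contribute to the four deletion or two
insertion distributions; their merged non-templated stretch feeds the
total-N-length statistic only.

## Per-sample metrics (repertoire_metrics)

Samples are first downsampled without replacement (multivariate
hypergeometric on clone read counts, seeded) to a common depth — default
10⁶ reads, the conventional normalization for repertoire sequencing;
tests and the demo pipeline use 10⁴ so the suite stays fast. On the
normalized sample:

* Shannon's H = −Σ pᵢ ln pᵢ over clone read fractions (natural log; the
  Pielou normalization H / ln n is base-free, so the choice is cosmetic
  but stated).
* The Gini coefficient uses the population pairwise-difference form,
  computed by the sorted O(n log n) identity; an O(n²) oracle guards it
  in the tests. The literature on repertoire evenness names both a "Gini
  evenness coefficient" and a "Gini skewing index"; we implement the one
  well-defined statistic (0 = even, 1 = skewed) and report evenness as
  1 − G wherever an evenness direction is wanted.
* Pielou's evenness is H / ln n, defined as 0 for the degenerate
  single-clone sample.
* V–J pairing skew is the Gini coefficient over the summed read counts of
  observed V–J cells (unobserved pairs excluded; a unique-clonotype-per-
  cell weighting is available by flag). Clone-size indices are computed
  on read counts; read counts versus unique-clone frequencies differ only
  by the scale the Gini is invariant to.
* The top-100 fraction is the read share of the 100 largest clones
  (ties at the boundary broken lexicographically by junction; all clones
  when fewer than 100).
* Frame-class percentages are read-weighted and sum to 100.
* Mean CDR3 lengths (in-frame and out-of-frame) are unique-weighted.

## Composition (junction_composition)

Length spectra are normalized histograms with unique (per-clonotype) or
total (read-weighted) mass. The tyrosine index is tyrosines over all
residues of translatable CDR3s; stop-containing (pre-selection)
clonotypes are included by default, with the `*` symbol excluded from
numerator and denominator, and a flag restricts to stop-free clones since
either denominator is defensible. Positional composition follows the
fixed-length convention: only in-frame 13-residue CDR3s qualify, and
positions are 1-based; the hydrophobic set {A, I, L, M, F, W, V, C} is
the positive Kyte–Doolittle range. Insertion GC content pools all
inserted bases, merged insertions included; a sample with no inserted
bases yields an absent value rather than an error.

## Sharing and paTCR matching (sharing_patcr)

Sharing identity is the amino-acid CDR3 string (public-clone and
pathology databases are amino-acid level; a nucleotide mode exists).
Unique-weighting divides the shared set size by the mean unique count of
the two samples — the numerator is bounded by the smaller count, so the
fraction stays in [0, 1]; total-weighting divides the read mass on shared
sequences by the combined read mass (the natural reading of "total"
sharing; the count-denominator variant is available by flag). Common
clonotypes are sequences present in at least 5 control samples.
Database matching is exact identity; CDR3s containing a stop never
match. Per-sample paTCR proportions divide matched unique clonotypes by
all unique clonotypes (matching the pre-selection-abundance
interpretation, and making a spiked fraction recoverable exactly);
read-weighted proportions are the total-repertoire analogue. Categories
are evaluated independently, so a CDR3 curated under two categories
counts toward both.

## Cohort statistics (group_comparison)

* Rank-sum contrasts use the Mann–Whitney U with exact null enumeration
  when the combined size is ≤ 20 and the pooled values carry no ties
  (cohort sizes of 3–14 make the exact test both feasible and necessary:
  printed p-values like 2/84 are exact-tail values) and mid-ranks with
  tie-corrected normal approximation otherwise. `scipy` provides the
  engine; a full-enumeration oracle verifies it in the tests.
* The bootstrap Kolmogorov–Smirnov test draws both groups with
  replacement from the pooled data at their original sizes, computes the
  ECDF sup-difference only at tie-run ends (resampling creates ties even
  from continuous data), and reports (1 + #exceedances)/(1 + n_boot);
  n_boot defaults to 1000 and every run is seeded. Empirical size at
  nominal 0.05 is within [0.03, 0.07] for both tests in the packaged
  calibration checks.
* Multiplicity control is Bonferroni (V-usage-style scans) or
  Benjamini–Hochberg (distribution families), via `statsmodels`; the
  pipeline adjusts within each metric family.
* Correlation defaults to Spearman, consistent with the nonparametric
  testing throughout; Pearson is a flag.
* The PCA takes exactly six per-sample variables — Pielou evenness, TCR
  Gini, V–J Gini, percent in-frame, mean out-of-frame CDR3 length, and
  unique-clone tyrosine index — standardized to zero mean and unit
  variance; group separation is the silhouette of labels in the
  (PC1, PC2) plane. Extra or missing columns are an error by design.

## What the simulations do and do not show

The generator reproduces the mechanistic skeleton of repertoire formation
— segment choice, exonucleolytic trimming, TdT insertions, clonal
expansion, convergent recombination — which is exactly what the
annotation-recovery, parameter-recovery, and group-contrast checks
exercise. It deliberately omits thymic selection, HLA-driven antigen
selection, sequencing error, and PCR amplification bias; somatic
hypermutation does not occur in TCRs and is not modeled. Passing tests
therefore demonstrate that the estimators are faithful to the stated
generative model at realistic parameter values, not that any particular
biological cohort satisfies that model. Problem sizes in the packaged
checks — 2000 clones for call accuracy, three repertoires of 5000 clones
for parameter recovery, cohorts of 20000-clone samples for sharing — were
chosen so each Monte-Carlo comparison is decided by its effect size
rather than by realization noise.

## Determinism

Every stochastic component (simulation, spiking, downsampling, posterior
boundary resampling, bootstrap) takes an explicit seed; the pipeline
derives named per-stage child seeds from one root seed and writes no
timestamps, so identical configurations produce byte-identical outputs.
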