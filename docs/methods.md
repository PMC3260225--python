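# Methods

This note records what the pipeline computes, the conventions it commits
to where the underlying definitions admit more than one reading, and what
the synthetic-data generator does and does not emulate.

## TE metrics

TE density is the fraction of the gene span (longest isoform, introns and
exons alike) covered by the union of TE fragments clipped to that span.
Union coverage — rather than summed fragment lengths — keeps density within
[0, 1] even though RepeatMasker fragments can abut or overlap. Coordinates
are 0-based half-open everywhere inside the package; GTF and RepeatMasker
`.out` inputs (1-based inclusive) are converted at parse time only.

Mean TE age is the fragment-length-weighted mean percent divergence,
`d̄ = Σ dᵢ·lᵢ / Σ lᵢ`, with `lᵢ` the clipped but **unmerged** fragment
length: the sum runs over fragments, not bases, so a base under two
fragments contributes to both fragments' weights. The merged alternative
would under-weight nested fragments; the unmerged choice is documented here
and exercised by a dedicated test. `d̄` is only defined when at least one
fragment overlaps the gene — an empty gene is a density-0 success but an
age *error*, so callers cannot silently average over nothing.

Class composition assigns each covered base to a single fragment (lowest
start wins; the longer fragment on a start tie, using pre-clipping
coordinates) and normalizes class bp by total TE bp, so the four fractions
sum to 1 whenever any TE bp exists. A per-base sweep oracle verifies both
coverage and composition on genes up to 50 kb.

G+C content is (G+C)/(A+C+G+T) over the gene span, case-insensitive, with
ambiguity codes excluded from numerator and denominator both. In the
synthetic pipeline G+C is supplied as a per-gene table; FASTA-backed
computation (via pyfaidx) exists for real data and is tested on a tiny
generated FASTA.

Non-TE RepeatMasker classes (simple repeats, low complexity, satellites,
structural RNAs, `Unknown`) are dropped with a logged count; any *other*
unrecognized class is a hard error so new inputs force an explicit mapping
decision rather than silent loss.

## Outlier detection

Only genes strictly larger than 10 kb are analyzed: below that size the
density distribution degenerates into a spike at zero because small genes
cannot hold much TE sequence.

Both gene size and exon density constrain attainable TE density, so
outliers are called within a 5×5 lattice: genes are sorted into size
quintiles, and each size quintile into exon-density quintiles (cut at order
statistics, ties broken by gene ID so the assignment is deterministic).
Cell occupancies differ by at most a rounding remainder. Exon density
defaults to exon **count** per kb of gene span; an exonic-bp-fraction
alternative is available via `exon_density(mode="bp")` for sensitivity
checks. Within each cell the `ceil(q·n)` highest and lowest densities
become upper and lower outliers (`q = 0.10` by default, grid 2.5%–25% in
2.5% steps for the cutoff scan); a cell too small to host both tails is an
error rather than a silent overlap. After merging cells, upper and lower
sets show no rank-sum difference in size or exon density on synthetic data,
which is the point of the stratification.

## Shared outliers and the null

A homology group qualifies for cross-species analysis only when it has
exactly one analyzed (>10 kb, metric-bearing) gene in every species; groups
with within-species paralogs are excluded to avoid double counting. A
shared upper/lower outlier (SUO/SLO) is such a group whose gene is an
outlier of the same side in all species. Under independent calling the
per-group probability is `q^S`; the observed proportion is tested against
that null with a one-sample equality-of-proportions test. The package
reports `q^S` and the empirical frequency; it does not attempt to
reconstruct any other null.

Composition and G+C correlations over shared sets use Pearson r on the
normalized class fractions (fraction of TE bp per class), reported as
undefined (NaN) on zero-variance input or fewer than three informative
pairs. "SINE-dominated" means a normalized SINE fraction strictly above
0.5.

## Conservation and TE age

Conservation levels come from the homology table alone: *ancient* = group
contains at least one configured outgroup species (zebrafish, fruit fly,
yeast) alongside a mammal; *mammalian-specific* = at least two of the focal
mammals; *species-specific* = everything else, including genes absent from
the table entirely. The definition is applied literally; a gene in
human+mouse only is mammalian-specific regardless of what other taxa might
contain it. TE-age comparisons between gene sets use the two-sided Wilcoxon
rank-sum test with group means reported. The random-control experiment
draws `n = 200` genes per conservation level (seeded, without replacement)
and repeats the same comparison, separating gene-age effects from TE-age
effects; it errors loudly, naming the deficit, when a level has too few
genes with defined TE age.

## Tissue specificity

Binding entropy is `H = −Σ p_t log₂ p_t` with `p_t` the per-gene normalized
binding strengths over five mouse tissues (ESC, brain, heart, kidney,
liver); zero-strength tissues contribute nothing (the `x log x → 0` limit).
`H ≤ 2` bits is tissue-specific ("high_TS"), `H > 2` ubiquitous: the
boundary is closed on the tissue-specific side. The strongest tissue
minimizes `Q_t = H − log₂ p_t` (equivalently maximizes `p_t`; ties broken
by tissue-name sort; `p_t = 0` gives `Q_t = +∞` and is never selected).
"Strong binding in only one tissue" is operationalized as: tissue-specific
**and** top-tissue fraction `p_max ≥ 0.5`; the floor is configurable since
no sharper definition is available from the data this emulates.

## Chromatin and expression

Promoter states derive from the two mark flags: K4-only (open), K27-only
(repressed), bivalent (poised), neither. The effect matrix restricts
shared lower outliers to the K4-only and bivalent columns (the K27-only
class is left out as too small to test), cross-classifies by the supplied
developmental flag, and tests the four conditional proportions A/T1, B/T2,
B/T3, D/T4 against caller-supplied background counts — counts, not rates,
because the background denominators are part of the evidence. A zero
margin yields a flagged, undefined comparison instead of a division error.

The expression split computes the median over **all** background genes
(> 10 kb), so the background is 50/50 by construction; a value counts as
"high" only when strictly greater than the median, which sends an all-tied
input entirely to "low" — the conservative direction.

## Statistical primitives

All enrichment p-values come from the chi-square equality-of-proportions
test on the 2×2 success/failure table with the capped Yates continuity
correction, on by default and toggleable (it visibly moves borderline
p-values, so every report records the setting, the method and the input
counts). One-sided variants take the signed square root of the statistic
against the normal tail. The Wilcoxon rank-sum test is exact (full
enumeration) when both samples have ≤ 8 untied observations and otherwise
uses the tie-corrected normal approximation with continuity correction.
Type-I error of the proportion test under a simulated null sits within
[0.03, 0.07] at α = 0.05, verified by simulation in the test suite.

## Synthetic-data generator

The generator produces, per species, BED12 gene models, rmsk-dialect TE
tables and a per-gene G+C table; one homology table spanning the three
mammals plus occasional outgroup members; and, for the binding species
(mouse), binding, mark, expression and developmental-flag tables — all in
exactly the dialects the readers accept, byte-identical under a fixed seed.

Its backbone is a latent per-group "openness" state `o_g`: a standard
normal group component mixed with per-species noise so orthologs correlate
at ρ (default 0.8). Per gene, TE fragment counts are negative-binomial with
log-mean `α + β·o_g` per kb (β = 0.6 by default), fragment classes follow a
mixture tied to the gene's G+C (SINE weight rising, LINE falling with G+C),
and divergences are Gamma-distributed per class with slightly younger TEs
in open genes. Binding profiles are Dirichlet draws — symmetric
concentration for the ~54% ubiquitous genes, sparse with a dominant tissue
otherwise, the dominant tissue skewed toward ESC with openness (skew 1.5) —
and marks, expression and the developmental flag are logistic/log-normal
functions of the same `o_g`. Gene sizes are log-normal (median 30 kb) with
Poisson exon counts placed one per equal-width slot; a few intergenic
fragments land in the upstream gap of each gene to exercise clipping.

Defaults were fixed once, after a power calibration of the
parameter-recovery design (openness effect detectable by rank-sum and the
ESC-excess proportion test at p < 0.01 at the default scale of 2000
ortholog groups), and define the package's study conditions.

What the generator does **not** emulate: real sequence (TE families are
labels, not sequences), insertion-site preference within genes (placement
is uniform), selection or fixation dynamics, inter-gene correlation along
chromosomes, assembly artifacts, and the heavy-tailed fragment-length and
divergence distributions of real RepeatMasker output. Green tests
therefore demonstrate that the machinery is correct and recovers planted
structure under the stated model — not that real genomes satisfy that
model.

## Problem sizes and numerical choices

The default simulation uses 2000 ortholog groups (+150 private genes per
species), chosen as the package's standard desk-scale study condition; the
test suite uses smaller bundles (40–500 groups) for unit-level checks and
the full default scale for parameter recovery. Tail counts use
`ceil(q·n − 1e−9)` to guard against floating-point noise in `q·n`.
Quintile and tail ties are always broken by identifier sort, making every
stage deterministic: identical inputs give identical outputs, and the run
manifest records input/output checksums per stage so reruns are auditable.

## Known limitations

- Shared-outlier counts at desk scale are small (tens, not hundreds), so
  downstream proportion tests on SUO/SLO sets are illustrative at default
  scale; the acceptance checks therefore target calibration and oracle
  equivalence rather than headline effect sizes.
- The homology-based conservation scheme cannot distinguish genuinely
  young genes from genes missing from the homology table.
- GO-style function assignment is out of scope: the developmental flag is
  a supplied input, generated by the simulator.
- No multiple-testing correction is applied anywhere; reported p-values
  are per-comparison.
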