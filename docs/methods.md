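# Methods

This note documents the models, conventions and numerical choices behind
`missplice`, and what the synthetic cohorts do and do not establish about
real data.

## Coordinates and junction classification

All interval logic is 0-based half-open on the intronic interval: `start` is
the first intronic base, `end` one past the last. STAR `SJ.out.tab` rows
(1-based first/last intronic base) are converted on read (`start−1`, `end`)
and back on write; the conversion is a bijection on valid records. The donor
of an intron sits at `start` on the plus strand and at `end` on the minus
strand; the acceptor is the opposite end.

A junction is *annotated* when interval and strand match an intron exactly;
*novel donor* when its acceptor coordinate matches an annotated acceptor
(strand-aware) while its donor coordinate matches no annotated donor;
*novel acceptor* symmetrically; everything else is *unassigned*. Junctions
whose two boundaries match sites of two different introns (candidate
exon-skipping products) are deliberately unassigned — the three-class scheme
has no category for them. QC filters (length < 25 bp, blacklist overlap,
unplaced contig, minor-spliceosome intron, undefined strand) are all
evaluated independently so attrition can be reported per filter; any flag
forces `unassigned`. The 25 bp minimum is the shortest interval excisable as
an intron without consuming flanking exon sequence.

**Unique assignment.** When several introns share the matched site, the
intron with the highest total annotated read support in the current batch
wins; ties go to the shortest intron, then the lexicographically smallest
id. Support-weighted choice reflects competitive splicing: a cryptic site is
most plausibly a failed attempt at the boundary that is actually used.
This rule is a declared convention — uniqueness is required but no published
rule exists to reconstruct.

## Mis-splicing ratio

`MSR_D = Σj / (Σj + Σs)` pools raw novel-donor (`j`) and annotated (`s`)
read counts over the samples of a group before forming the ratio; no
per-sample normalisation is applied, which makes the pooled MSR the maximum
likelihood estimate of the per-read error probability and keeps it invariant
to uniform count rescaling. `0/0` is reported as missing, never as zero: an
intron without junction reads at a site carries no evidence, which is
different from an intron observed to splice accurately. Unique-junction
percentages count distinct (chrom, start, end, strand) keys across a group's
samples; read percentages sum every count.

## Splice-site scoring

Sites are framed per the MaxEntScan convention: donors as 9-mers (3 exonic +
6 intronic, GT at intronic positions 1–2), acceptors as 23-mers (20 intronic
+ 3 exonic, AG at intronic positions 19–20); minus-strand sites are
reverse-complemented so motifs always read in transcript orientation. Two
interchangeable model kinds sit behind one `score` interface:

* `maxent_tables`: user-supplied k-mer → score lookup tables. Scores are
  self-contained and independent of any background composition.
* `logodds_pwm`: per-position log2 odds against a background composition
  (default: the pooled composition of the training sequences) with +1
  pseudocounts, trained from the annotated sites of the input annotation
  (minimum 50 sites per kind). `N` bases contribute zero log-odds.

All downstream claims use *delta* scores (annotated − novel) of paired
sites under a single model, never absolute scores, so conclusions are
model-consistent: a positive delta means the cryptic site is the weaker
motif under whichever model is in use. Note that PWM scores themselves shift
when the background changes, and the shift depends on sequence composition;
only within-model deltas are interpreted.

## Geometry

The raw distance is `gcIntron − gcNovel` (0-based coordinates); the
strand-adjusted distance flips the sign on the minus strand so mirrored
fixtures agree. With that convention, positive values point into the
upstream exon at donors and into the intron at acceptors — the latter being
the AG-exclusion-zone side, so the acceptor upstream/downstream count ratio
directly measures that depletion. Frame profiles use |distance| mod 3,
restricted to MANE-transcript introns (where RefSeq and Ensembl agree on
exon structure) and to |distance| < 100 bp (strict), keeping the novel
product confidently within the adjacent exon and intron. Both raw and
adjusted distances are emitted so either sign convention can be reproduced.

## Zero-inflated Poisson model

The response is `Y = round(MSR × 100,000)` (round-half-even). The count
component has a log link over nine covariates, uncentred: gene transcript
count, protein-coding transcript fraction, donor and acceptor motif scores,
mean conservation and mean constraint over the donor-proximal (first 100
intronic bases) and acceptor-proximal (last 100 intronic bases) windows, and
intron length in bp. Introns shorter than 200 bp are dropped so the two
windows cannot overlap. Track window means use available positions only and
become missing when more than half the window is missing — gapped
conservation tracks otherwise produce unstable means.

The structural-zero component is intercept-only by default: the count-model
formula is the scientific object here and nothing pins down a zero-model
formula; putting every covariate in both components (the common default of
reference implementations) is available via `zero_formula="full"`. Fitting
is maximum likelihood (statsmodels' ZIP likelihood) warm-started from a
GLM-Poisson fit and a logit of the observed zero excess, optimised with
BFGS and a Nelder–Mead fallback; non-convergence raises with the optimizer
trace rather than returning a silent partial fit. Standard errors are
sandwich (HC0) robust; p-values are two-sided Wald; q-values are BH within
the model. Exponentiated betas give the multiplicative effect on the scaled
MSR per covariate unit. Degenerate all-zero responses short-circuit to a
flagged, unidentifiable fit with zero-inflation mass 1.

## Group comparisons

Sample matching is greedy: all cross-group pairs ranked by absolute key
difference (RIN or log depth), accepted while both members are unused and
the difference is within tolerance (0.05 for RIN). Greedy pairing is
deterministic and order-free; it produces a maximal matching that can be up
to a factor 2 smaller than the true maximum (tests document the bound).
Intron expression matching keeps introns present in both groups with
|Δ log10 mean annotated support| ≤ 0.005.

Rank tests use the continuity-corrected Wilcoxon signed-rank (paired, zero
differences dropped) or Mann–Whitney (unpaired). Effect sizes are
probabilities of superiority: unpaired, the exact pair-counting
`(#{a>b} + ½#{a=b})/(n_a n_b)`; paired, the matched-pairs rank-biserial
correlation mapped to [0, 1] as `(r+1)/2`. The unpaired effect is invariant
under strictly monotone transforms; the paired one is not (it ranks
difference magnitudes), which is the standard price of the signed-rank
framework. Age stratification bins samples at 20–39 / 40–59 / 60–79 years
(≥ 25 per bin), RIN-matches the older bins to the youngest, restricts to
introns supported in all bins, and contrasts the extreme bins one-tailed
(old > young), paired by intron on group-pooled MSR — pairing by intron
matches the group-level definition of the MSR.

**Inverse-fold-change correction.** For a candidate factor, the fold change
`f = mean TPM(case)/mean TPM(control)` summarises its expression shift. The
default correction divides the case MSR by the inverse fold-change
(`corrected = MSR × f`, clipped to [0, 1)): when reduced factor expression
inflates mis-splicing in proportion, this restores the case MSR to the
control scale, and the re-run comparison should return to effect ≈ 0.5.
The reciprocal reading (`MSR / f`) is available via
`mode="divide_by_foldchange"`. Factor ranking scores each factor by the
drop in effect size its correction produces (uncorrected − corrected),
descending, ties by factor id. Binding-site enrichment uses Pearson
chi-square without continuity correction on the 2×2 table of MSR direction ×
binding within intron ± 100 bp; expected cells below 1 flag the result.

## Synthetic cohorts

The generator emits a complete input set — GTF, FASTA, bedGraph tracks, BED
masks, MANE list, STAR-dialect junction tables, metadata — with ground truth
for every novel read.

*Reference.* Genes with Poisson intron counts, log-normal intron lengths
(log-mean 7.57, log-sd 1.71, minimum 80 bp — echoing the genome-wide
landscape where the mode is far below the mean), exons around 120 bp, both
strands. Annotated boundaries carry consensus-derived donor/acceptor motifs
(mutation rate 0.10 outside the invariant GT/AG); cryptic sites carry
degraded motifs (rate 0.45) and a latent strength deficit drawn
Exp(scale 3), which drives read allocation among a intron's cryptic sites by
softmax (temperature 2). Cryptic distances respect a frame-preservation
weight `w0 = 0.374` for |d| mod 3 = 0 and an acceptor-upstream suppression
odds factor of 0.3 (emulating the AG exclusion zone); magnitudes are capped
at 60 bp and at the flanking exon/intron margins. Conservation tracks fall,
and constraint tracks rise, with an intron's planted error rate over its
proximal windows.

*Counts.* Per sample and intron, total junction flux is Poisson with a
per-sample gamma size factor (negative binomial marginally, dispersion 0.3)
around `depth_mean × expression`; the flux is split multinomially into
novel-donor / novel-acceptor / annotated reads. Group multipliers act on the
**MSR estimand** (`p_d/(1−p_a)` under that split), with channel
probabilities recovered by inverting the ratio equations — so a group effect
of `m` scales the measured MSR by exactly `m`, which is what the matched
contrasts and the fold-change correction assume. Defaults: `p_D = 0.002`,
`p_A = 0.005` (the acceptor-over-donor excess), 5,000 reads/intron/sample,
20 samples. Presets: `null` (two identical groups), `age` (multipliers
1.0/1.2/1.5 with ages drawn per bin), `knockdown` (multiplier 5 on a
targeted intron subset in cases), `disease` (24+24 samples, multiplier 2
driven by a causal factor's 2-fold TPM downregulation among five factors,
500 reads/intron — typical bulk polyA coverage; per-sample factor TPMs have
10% log-normal noise).

*What passing tests show — and don't.* The simulator plants exactly the
structure the estimators assume: multinomial read splits, independent
introns, group effects that are clean MSR multipliers, and expression noise
that is log-normal and unconfounded. Recovery and calibration on these
cohorts validate the arithmetic, the strand handling, the estimator
definitions and the inferential plumbing; they do not establish robustness
to mappability artefacts, correlated intron families, batch structure,
3'-bias, or regulated novel splicing misread as error — all real-data
phenomena outside the generator's scope. Two measured caveats: the
fold-change correction's per-replicate effect size carries ~0.07 sampling
noise from estimating `f` with 24 samples per group (its mean over
replicates is the stable quantity), and correcting by a scale factor leaves
a small (+0.01) residual asymmetry because scaling changes the sampling
variance of the corrected values.

## Validation experiment sizes

The bundled experiments (also run by `scripts/acceptance.py`) use: 1,000
junctions × 100 introns for the classification oracle; 3 cohorts of 200
introns × 20 samples for MSR coverage (Clopper–Pearson 95% intervals;
coverage is an unconditional rate, so it is averaged over cohorts); 50,000
rows for ZIP parameter recovery (20% structural zeros); 1,000 null label
shuffles spread over 5 cohorts (the rejection rate conditional on a single
cohort's counts swings by several percent); 50 ageing replicates at 26
samples/bin; 150-gene cohorts for geometry recovery with simultaneous
Bonferroni-adjusted binomial intervals on the mod-3 classes; and 100
disease replicates for correction/ranking. These sizes keep every
experiment well-powered while the whole suite completes in a few minutes.

## Known limitations

* Tandem/NAGNAG-like short-distance acceptors are not modelled or detected
  as a separate class; regulated novel events are indistinguishable from
  errors by construction.
* The log-odds PWM is a position-independent approximation; genuine
  maximum-entropy tables capture position dependencies and should be
  supplied when available.
* Greedy matching trades optimality for determinism (bounded factor-2 gap).
* The ZIP zero component defaults to intercept-only; covariate-driven
  structural zeros require `zero_formula="full"`.
* Reclassification-rate analysis requires the caller to supply both
  annotation versions; no Ensembl access is performed.
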