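# missplice

Quantifying the accuracy of pre-mRNA splicing from bulk RNA-seq split reads.

Most RNA-seq reads that span an exon–exon junction land exactly on annotated
intron boundaries, but a measurable minority use an unannotated donor (5'ss)
or acceptor (3'ss) a few bases away — the signature of imprecise spliceosome
site selection. `missplice` turns per-sample junction count tables into a
per-intron measure of that imprecision, characterises where and why it
happens, and tests how it shifts between matched sample groups (ageing,
splicing-factor knockdown, disease). It is aimed at transcriptomics
researchers with STAR/regtools-style junction output and an Ensembl GTF.

## The statistics at its core

**Junction classes.** Each observed split-read junction is compared
strand-aware against the intron set derived from the annotation:
*annotated* (both boundaries match one intron), *novel donor* (shares the
acceptor, uses an unannotated donor), *novel acceptor* (the mirror case), or
*unassigned*. Novel junctions are assigned uniquely to one annotated intron.

**Mis-splicing ratio (MSR).** For intron *X* pooled over the *N* samples of
a group *T*, with `j_i` novel donor reads and `s_i` annotated reads in
sample *i*:

    MSR_D = Σ j_i / (Σ j_i + Σ s_i),   MSR_D ∈ [0, 1)

and `MSR_A` analogously with novel acceptor reads. 0 means no evidence of
donor-side mis-splicing; values near 1 mean the annotated site is rarely
used precisely.

**Splice-site strength.** Donor 9-mers (3 exonic + 6 intronic bases) and
acceptor 23-mers (20 intronic + 3 exonic) are scored by a pluggable model —
precomputed MaxEntScan-style k-mer tables if supplied, otherwise a log-odds
position weight matrix trained on the annotated sites. For every novel
junction the *delta score* = annotated score − novel score; positive deltas
mean the cryptic site is the weaker motif.

**Geometry.** Signed distance between each novel site and its annotated
counterpart (`gcIntron − gcNovel`, strand-adjusted), the |distance| mod 3
frame profile restricted to MANE-transcript introns within 100 bp, and the
upstream/downstream positional asymmetry at acceptors (the AG exclusion
zone).

**Determinants of the MSR.** A zero-inflated Poisson regression of
`Y = round(MSR × 100,000)` on nine gene- and intron-level covariates
(transcript count, protein-coding fraction, donor/acceptor motif scores,
conservation and constraint in the 100-bp proximal intronic windows, intron
length), with sandwich (robust) standard errors and Benjamini–Hochberg
adjusted q-values. Introns shorter than 200 bp are excluded so the two
windows never overlap.

**Group contrasts.** Greedy RIN/depth matching of samples, log10 expression
matching of introns (|Δlog10| ≤ 0.005), one- or two-tailed (paired)
Wilcoxon tests with a probability-of-superiority effect size, BH/Bonferroni
correction, chi-square tests of binding-site enrichment, TPM computation,
and an inverse-fold-change correction that asks how much of a group's MSR
shift is attributable to the expression change of a given splicing factor.

A synthetic-data generator emits all of the above inputs (GTF, FASTA,
bedGraph tracks, BED masks, STAR `SJ.out.tab` junction tables, metadata)
with known ground truth, so the whole pipeline is testable end to end
without any downloads.

## Worked example

Simulate an ageing cohort (three age bins, 26 samples each, old-group
mis-splicing multiplier 1.5) and run the analysis:

```python
import numpy as np, missplice as mp
from pyfaidx import Fasta
from missplice import simulate as sim
from missplice.scoring import train_from_annotation, delta_scores
from missplice.junctions import read_junctions, merge_junctions

cfg = sim.preset_config("age", n_genes=40, n_samples_per_group=26)
ref = sim.generate_reference(cfg, seed=11, outdir="work")
metas, truth, paths = sim.simulate_junction_counts(ref, seed=12, outdir="work")

ann = mp.load_annotation("work/annotation.gtf",
                         mane_ids={l.strip() for l in open("work/mane.txt")})
junctions = merge_junctions(read_junctions(p, "star_sj", sample_id=s)
                            for s, p in paths.items() if s != "metadata")
classified = mp.classify_junctions(
    junctions, ann, minor_introns=mp.read_region_mask("work/minor_introns.bed"))

samples = [m.sample_id for m in metas]
records = mp.msr_table(classified, samples)
msr_d = np.array([r.msr_d for r in records])
msr_a = np.array([r.msr_a for r in records])
print(f"median MSR_D = {np.nanmedian(msr_d):.5f}, median MSR_A = {np.nanmedian(msr_a):.5f}")

genome = Fasta("work/genome.fa")
deltas = np.array([d.delta for d in delta_scores(
    train_from_annotation(ann, genome), classified, ann, genome)])
print(f"novel sites scored: {len(deltas)}, positive delta: {100*(deltas>0).mean():.1f}%")

mats = mp.msr_matrix_by_sample(classified, samples)
res = mp.age_stratified_comparison(
    {"donor": mats["novel_donor"], "acceptor": mats["novel_acceptor"]},
    mats["annotated"], metas)
for kind, r in res.items():
    print(f"{kind}: old > young one-tailed p = {r.p:.3g}, "
          f"probability of superiority = {r.effect_size:.3f} (n = {r.n} introns)")
```

Output:

```
median MSR_D = 0.00250, median MSR_A = 0.00625
novel sites scored: 409, positive delta: 92.9%
donor: old > young one-tailed p = 6.52e-19, probability of superiority = 1.000 (n = 103 introns)
acceptor: old > young one-tailed p = 6.33e-19, probability of superiority = 1.000 (n = 103 introns)
```

Reading it: acceptor-side mis-splicing runs ~2.5× higher than donor-side
(0.00625 vs 0.00250, the planted 2.5:1 ratio); 93% of cryptic sites score
weaker than the annotated site they compete with; and the old-versus-young
contrast detects the planted 1.5× multiplier with an effect size
(probability that a random intron's MSR is higher in the old group) near 1.

The same stages are available from the shell:

```bash
missplice simulate --preset age --seed 11 --outdir work
missplice run --config pipeline.cfg     # key = value config file
```

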