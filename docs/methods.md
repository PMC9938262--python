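# Methods

This note documents the models behind each stage, the choices made where a
design was genuinely open, and what the synthetic cohort does and does not
emulate.

## Synthetic cohort generator

The generator produces, per patient, a clone tree with per-region cancer-cell
prevalences and renders read-level observables from it. It works on a
desk-scale mini-genome: 22 autosomes of 10 Mb, arms split at 5 Mb,
coordinates 0-based half-open.

**Clone trees.** The truncal clone has prevalence 1 in every region. A single
child's per-region prevalence is the parent's times a factor drawn from
{0 (absent, p = 0.3), 1 (regionally fixed, p = 0.25), U(0.4, 0.8)}; sibling
subclones expand in *disjoint* region subsets. This construction guarantees
the two feasibility rules (cross rule: descendant ≤ ancestor per region;
pigeonhole: children sum ≤ parent per region) by design, makes branching
identifiable from prevalences alone (each branch owns a region where its
siblings are absent), and creates clonal-illusion clones (prevalence exactly
1 somewhere, 0 elsewhere) with a clean margin: subclone prevalences are
either an ancestor's value or ≤ 0.8, so the 0.9 illusion threshold never
sits on top of a planted value. Cohorts with ≥ 2 patients alternate forced
linear/branched topologies so both patterns always occur.

**Reads.** Per-site depth is Poisson (default mean 100, matching a
deep-coverage exome); alt counts are binomial at
VAF = CCF·m·ρ/(CN·ρ + 2(1 − ρ)) with multiplicity m = 1 — copies beyond one
carry the mutation on a single allele, the same assumption the CCF estimator
makes. The matched normal uses a 10⁻³ error rate. Purity is drawn
U(0.6, 0.9) per region (typical for macrodissected tumors).

**Copy number.** Non-doubled patients start at 1+1, genome-doubled patients
(default 30% of the cohort) at 2+2 with twice as many subclonal arm events —
doubling is deliberately coupled to instability so the cohort reproduces the
GD/subclonal-SCNA association directionally. MSAI patients (default 50%)
carry one arm where haplotype A is gained in one region and haplotype B in
another; phased SNP BAFs are rendered binomially from the haplotype copy
numbers.

**Methylome.** Each of 300 1-kb bins has a bimodal normal-tissue rate and a
tumor rate; planted DMR bins (10% of bins, half hyper half hypo) shift the
tumor rate by 0.40. A per-patient baseline shift (σ = 0.06) is applied to
tumor *and* matched normal — patients differ epigenetically without
perturbing tumor−normal contrasts. Regions add exchangeable jitter
(σ = 0.02), except 5% "variable" bins with region-specific rates. Observed
bulk counts are binomial at the purity/copy-weighted mixture of tumor and
normal rates — exactly the mixture the deconvolution formula inverts, so
deconvolution with true purity and copies recovers tumor rates to within
binomial error (a tested invariant). Epiallele loci draw a dominant 4-CpG
pattern; each read flips each CpG independently with probability
disorder/2, which sweeps entropy/epipolymorphism/PDR from 0 to their maxima
with one parameter; loci over copy-altered arms optionally get high
disorder (0.5 vs 0.1) to plant the SCNA/epiallele coupling.

**Expression.** log2 expression = gene baseline + patient offset + region
noise + 0.8·(CN − 2) (copy dosage) − 1.5 for regions with a planted
hypermethylated promoter, exported as TPM. The four quadrant classes are
planted by (within, between) SDs: I (1.5, 0.2), II (0.2, 0.2),
III (1.5, 1.5), IV (0.2, 1.5). Immune marker genes for 16 populations are
expressed at a high (6) or low (2) mean per region according to the planted
infiltration state.

**What it does not emulate:** raw reads, alignment or sequencing-error
profiles, mutation hotspots, subclonal copy number within an arm, epiallele
spatial autocorrelation, realistic gene-length/GC structure, or continuous
immune gradients. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not performance on
real sequencing artifacts.

## Variant clonality

- The CCF uses the standard mixture rearrangement
  CCF = VAF·(CN·ρ + 2(1 − ρ))/(m·ρ). An alternative algebra with the
  copy-number term in the denominator is available behind
  `printed_form=True` for comparison; it assigns CCF 0.25 to a clonal
  heterozygous mutation at purity 1 and CN 2 and is therefore not the
  default.
- Clone clustering is a finite binomial-mixture EM over per-region
  (alt, depth) counts with the linear link p = θ·c, c = ρ/(CN·ρ + 2(1 − ρ)).
  The M-step update θ = Σγ·alt / Σγ·depth·c is the exact MLE under this
  link. Components are selected by BIC over 1..10 (20 restarts, seeded);
  patients with < 5 mutations fall back to one cluster. This replaces
  Dirichlet-process MCMC with a deterministic, self-contained estimator of
  the same target.
- Illusion flags in the pipeline use clone-level CCFs (each mutation
  inherits its cluster's posterior-mean prevalence): pooling across a
  clone's mutations is what makes "appeared clonal in one region"
  decidable at realistic depths. The threshold (0.9) is exposed as a
  parameter; no cutoff is canonical in the literature.
- Tree building attaches each cluster (in decreasing total prevalence) to
  the feasible parent with the smallest prevalence — deterministic and
  maximally resolved. Feasibility tolerance ε = 0.05 absorbs CCF sampling
  noise; the pipeline widens ε stepwise (0.05, 0.1, 0.2) before declaring a
  patient tree infeasible.
- Signature refitting is NNLS on the 96-channel frequency spectrum with a
  user-supplied signature matrix (none ships); sets under 15 mutations are
  skipped.

## SCNA

- Calls are made on total copy number divided by sample mean ploidy, log2
  scale; thresholds log2(2.5/2)/log2(1.5/2)/log2(4/2). The wGII baseline is
  the *rounded sample ploidy* (so a doubled genome is not wholly
  "aberrant"); genome doubling is flagged at ploidy ≥ 3.
- Subclonal SCNA fractions partition the genome by the union of all region
  breakpoints (minimal intervals); an altered interval is clonal only when
  every region agrees in direction.
- MSAI: B-allele fractions use the conventional alt/(alt + ref), bounded in
  [0, 1]. Per arm and region, imbalance direction is the sign of the mean
  haplotype-A fraction minus 0.5, significant by one-sample t-test at
  α = 0.01; the arm-coverage requirement (≥ 75%) is evaluated over ten
  equal windows. An event needs ≥ 2 regions with significant opposite
  directions. SNPs need 10× coverage; arms with < 10 usable SNPs are
  skipped.

## Methylome

- DMRs: two-proportion z-test on pooled methylated/unmethylated counts per
  1-kb bin (≥ 3 CpGs), BH-corrected; hyper/hypo at q < 0.01 and |Δ| > 0.25.
  Counts are first deconvolved with per-region purity and local copies
  (bulk rates replaced by round(m_t·total)); without this correction the
  planted 0.40 shift attenuates below the 0.25 call threshold at purity
  ≲ 0.65. The count-based test on deconvolved rates slightly understates
  the null variance; the |Δ| > 0.25 requirement dominates the error
  control (measured null call rate ≤ 0.6% at q < 0.01).
- Bin levels are unweighted means of per-CpG levels (coverage weighting is
  a toss-up; unweighted is simpler and matches the tested examples).
- APITH uses Euclidean distances between region bin-level profiles over
  bins covered in all regions.
- Epiallele entropy is reported in bits, unnormalized; external epiallele
  tools differ in normalization and none is canonical. Metrics require
  ≥ 60 reads per locus.

## RNA

- intra(g) = mean over patients of the per-patient SD across regions;
  inter(g) = SD across patients of patient means; quadrants split both at
  their cohort means. These definitions are this package's normative ones
  (the external method they summarize publishes no formula).
- Concordance is the mean silhouette width of the patient partition on the
  single-gene value vector. Note the null is *negatively* biased (random
  small clusters score < 0); the meaningful comparison is relative
  (class IV ≫ class I), which the pipeline reproduces.
- RNA-ITH = median pairwise (1 − Spearman ρ); the median makes the score
  invariant to duplicating a region. Saturation curves use all region
  subsets up to 20, else 100 seeded random subsets.
- Promoter analysis: a promoter (TSS ± 2 kb) is differentially methylated
  between two regions when ≥ 1 CpG has Fisher p < 0.05 and |Δlevel| ≥ 0.2;
  expression differences are oriented hyper-minus-hypo and tested per
  element (promoter, first exon, gene body) with one-sample t-tests of the
  paired differences.

## Immune and neoantigens

- TIL classification: Ward linkage on Manhattan distances between region
  score vectors (equivalent to R's ward.D2 on a precomputed distance), cut
  at k = 2; the group with the higher mean total-TIL score is "high". The
  classification is invariant to region order and to uniform affine
  rescaling of scores.
- Marker lists are configuration; the generator ships synthetic markers for
  16 populations. Real marker registries plug in via `markers.yaml`.
- Neoantigen rules are monotone in the rank threshold; "equal or better
  affinity" is rank_mut ≤ rank_wt (percentile ranks, lower = stronger).
  Under subclonal HLA-LOH an epitope is excluded only when every clone
  carrying it lost the allele; the pipeline approximates a clone's regions
  by the regions where its mutations are genotyped present.

## Integration

- Cross-omics distances are Euclidean per layer; intra- vs inter-patient
  pairs are compared by two-sided Wilcoxon rank-sum. Hierarchical
  clustering for the cross-omics comparison uses complete linkage unless
  configured otherwise (the metric, not the linkage, is the specified
  part).
- MDS is classical Torgerson scaling (double-centering +
  eigendecomposition), matching R's `cmdscale` rather than SMACOF; exactly
  embeddable configurations are reproduced to numerical precision.
- Partial correlations regress both variables on the covariates (with
  intercept) and correlate residuals.

## Problem sizes and determinism

Default study conditions: 8–10 patients, 2–6 regions, 2–5 clones with 30
mutations each, depth 100×, purity 0.6–0.9, 300 CpG bins at 60×, 60
epiallele loci at 80× (≥ 60 reads), 400 genes. Benchmarks use 200
simulations for MSAI power, 1000 null arms for its false-positive rate, 10
cohorts for DMR recovery, and 500 replicates for the null type-I check —
sizes at which the measured rates have standard errors well inside the
asserted margins. Every random draw flows from an explicit integer seed
through `numpy.random.default_rng`; rendering uses a stream decoupled from
truth sampling so truth is stable under render-parameter changes, and the
pipeline summary JSON is byte-identical across runs at a fixed seed.

## Known limitations

- Multiplicity is fixed at 1; amplified mutations on several copies are
  neither simulated nor modeled, which understates CCF separability in
  genome-doubled tumors (a handful of individual mutations there are
  intrinsically ambiguous between clones).
- Arm-level segments only; no focal events or subclonal copy states within
  an arm, hence no subclonal-GD timing beyond the ploidy flag.
- The DMR test is marginal per bin; spatially correlated methylation would
  need window-level smoothing the generator does not produce.
- Phasing is taken from the simulator; for real data SNPs must be phased
  by tumor-informed co-segregation before MSAI calling.
- PMD (partial methylation domain) analysis, pathway enrichment, MSI and
  HLA typing are out of scope; their outputs enter, if at all, as plain
  input tables.
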