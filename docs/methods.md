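# Methods

## Problem setting

Clonally propagated turfgrass cultivars — notably the triploid hybrid
bermudagrasses (*Cynodon dactylon* × *C. transvaalensis*) used on golf
putting greens — accumulate off-type patches that differ visibly from the
planted cultivar. An off-type can be a somatic mutant of the cultivar
itself or an unrelated contaminant. This package implements the
computational side of a combined genotypic (genotyping-by-sequencing, GBS)
and phenotypic (morphometric) characterization of such samples, together
with a seeded synthetic-data generator so the whole workflow is testable
without any sequencing data.

## Genotype model

Genotypes are unphased biallelic dosage calls. A sample of ploidy *p*
carries a sorted allele tuple of length *p* (e.g. `0/0/1` for a triploid
with one alternate allele); the *dosage fraction* d/p maps every genotype
onto [0, 1] independently of ploidy. Calls collapse onto three classes —
homozygous-reference (d = 0), heterozygous (0 < d < p), homozygous-
alternate (d = p) — and an explicit missing state. Multi-allelic records
are outside the model: the class rules below are defined for two alleles
only, so the VCF reader skips such records and logs the count rather than
decomposing them.

Positions are 0-based internally and 1-based in VCF. Indel and
multi-nucleotide alleles are carried as opaque ref/alt strings with no
normalization. The model enforces `sum(AD) == DP`; files that violate it
have DP reset to the AD sum on read (logged), since all downstream
computation treats the allele depths as the evidence.

## Replicate pooling and dosage re-calling

Samples with fewer than one million raw reads are excluded (strictly
"less than": exactly one million is retained). Clonal replicates of one
cultivar are pooled by summing per-site (ref, alt) read depths. The pooled
genotype is re-called deterministically: alternate dosage
`round(p * alt / total)`, exact halves rounded away from zero, zero total
depth giving a missing call. This re-caller replaces a probabilistic
(haplotype-likelihood) caller on purpose: the downstream differentiating-
locus logic consumes only genotype classes and depths, and the
deterministic rule makes every oracle test exact. The rule is monotone in
the alternate depth and recovers the founder genotype exactly on
error-free clonal data whenever the pooled depth exceeds the ploidy.

## Differentiating loci

A locus differentiates a pair of cultivars when their collapsed classes
differ; two heterozygotes of different dosage (`0/0/1` vs `0/1/1`) never
differentiate. Without phased subgenome assignment — which GBS cannot
give — a dosage difference inside the heterozygote class is not reliable
evidence of cultivar divergence, hence the exemption; the rule is exactly
"class inequality", which is the only reading consistent with both the
flagged archetypes (hom-ref vs hom-alt, hom vs het) and the exemption.

Counts are restricted to loci inside a per-cultivar read-depth window,
default [40, 100): the lower bound guards against heterozygotes missed at
low coverage, the upper bound against collapsed repetitive loci. Both an
exclusive-high ("less than 100", the default) and an inclusive-high
("no more than 100") dialect are supported because the two phrasings occur
in practice; the switch is `--inclusive-high`. A site missing or
out-of-window in one cultivar is skipped for pairs involving that cultivar
only, not globally.

## Ploidy partition

"Variant present in a ploidy group" means at least one member sample
carries at least one alternate allele in a non-missing call of depth ≥ 1
(no extra filter by default). The three group sets are split into the
seven disjoint regions of a three-set Venn diagram by plain set algebra;
per-group region counts always sum to the group total. Cross-group locus
matching is assumed upstream (a shared site-id namespace).

## Distance, embedding and divergence screen

The pairwise distance is the mean absolute dosage-fraction difference over
co-called sites — an identity-by-state-type metric that is bounded in
[0, 1], reduces to standard IBS sharing for diploids and remains defined
across ploidies. It is an L1 mean of per-site metrics, hence symmetric,
zero on identical samples and triangle-inequality-satisfying. A pair with
no co-called sites is a hard error by default (masked under
`allow_missing_pairs`) rather than silently imputed.

Classical (Torgerson) MDS embeds the matrix: B = −½·J·D²·J with J the
centering projector, eigendecomposition, coordinates = top-k eigenvectors
scaled by the square root of their (positive) eigenvalues. The embedding
reproduces Euclidean configurations exactly; per-axis signs are fixed so
the largest-magnitude coordinate is positive, making output deterministic.

The divergence screen replaces a visual outlier call with a reproducible
statistic: each sample's score is its mean distance to the reference
standards (self excluded), the baseline is the references' own scores, and
z = (score − median) / (1.4826 · MAD), flagging z > 3.5 (the conventional
robust-outlier threshold, exposed as `--z-threshold`). A degenerate
baseline (MAD = 0) flags any score above the median, with a warning. The
screen is posed for putting-green samples against the triploid standard
cultivars; diploid and tetraploid progenitor accessions separate by ploidy
by construction and are excluded from the screened subset in the pipeline.

## Genome size

2C DNA content is the plain fluorescence ratio
(sample FL2-A / standard FL2-A) × 1.67 pg/2C, the genome size of the
*Sorghum bicolor* cv. BTx623 internal standard; no correction for the
standard's own CV is applied. Classification assigns the nearest reference
anchor by relative deviation, "unclassified" beyond 15% (configurable),
ties broken toward the lower ploidy. The shipped anchors carry only the
two published triploid values ('Tifway' 1.37, 'Tifgreen' 1.61 pg/2C);
anchors for other ploidies must be user-supplied — the package refuses to
invent biological constants.

## Morphology clustering

Replicate measurements (4 pots × 3 stolons × 2 dates = 24 records per
sample) are averaged per sample before clustering; the leaf length:width
ratio is computed from the aggregated leaf means rather than averaged per
record, which is stable under measurement noise. K-means
(k-means++ initialization, Lloyd iterations, 10 restarts, fixed seed)
comes from scikit-learn; the fit is summarized by R² = 1 − SSW/SST.
Standardization is off by default — consistent with clustering raw trait
values — and available as a flag because the traits have heterogeneous
scales (internode length dominates leaf width by an order of magnitude
when unstandardized).

The cubic clustering criterion follows Sarle's approximation: the data's
covariance eigenvalues are scaled to hypercube-equivalent axes u_j; the
effective dimensionality p* is the largest j whose scaled axis exceeds the
cluster-count-derived cell edge, found by fixed-point iteration (cap 100,
tolerance implicit in integer convergence); the null expectation E[R²]
follows from the u_j and n; and

    CCC = ln((1 − E[R²]) / (1 − R²)) · sqrt(n·p*/2) / (0.001 + E[R²])^1.2.

CCC is negative whenever R² < E[R²] and +inf (with a warning) at R² = 1;
it is undefined at k = 1 (R² ≡ 0 there, and the package refuses to compute
it rather than return a misleading number). The approximation's null
expectation assumes clusters that are near-cubical cells of the data's
hypercube: it is well calibrated (mean ≈ 0 under uniform data) when the
cluster count can tile the effective dimensions (e.g. k = 4 in 2
dimensions) and is biased negative when k is small relative to the
dimensionality — the regime in which strongly negative values on real
morphology fits should be read as "diffuse, overlapping clusters", not as
an arithmetic artifact.

Per-cluster trait summaries report mean and SD; two clusters are flagged
"different" on a trait when their mean ± SD intervals do not overlap
(singleton clusters report SD 0 with a warning).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale (default 2,000 loci):

* **Roster** (default): six triploid standard cultivars × 6 clonal
  replicates; two diploid and two tetraploid progenitor accessions × 3;
  47 putting-green samples of unknown status attributed to three of the
  cultivars, 5 of which are contaminants.
* **Genotypes**: a per-locus ancestral alternate-allele frequency
  f ~ U(0.05, 0.95) shared across ploidies; per-ploidy consensus dosage
  ~ Binomial(p, f); each cultivar founder redraws its dosage uniformly over
  the p+1 genotypes at loci chosen with probability
  `within_family_divergence` (default 0.02); contaminant founders use
  `contaminant_divergence` (default 0.5) instead. Each replicate is its
  founder plus somatic ±1-dosage steps at rate 1e-3 per locus — matching
  the view that most off-types arise from somatic mutation rather than
  wholesale genotype change.
* **Depths**: negative binomial (overdispersed, dispersion 2.0) with
  per-ploidy means 9.5 (2x), 4.9 (3x), 7.4 (4x); zero depth makes the call
  missing. Allele depths are binomial draws around the true dosage
  fraction perturbed by the sequencing error rate (default 0.005); with
  the error rate exactly 0 the split is deterministic and proportional, so
  "noise-free" runs admit exact founder recovery. Raw read totals are
  log-uniform over 1.3–13.9 million.
* **Morphology**: three clusters with trait means (internode 34.6 / 21.9 /
  24.7 mm; leaf length 14.9 / 9.9 / 29.8 mm; stolon diameter 0.8 / 0.7 /
  0.75 mm; leaf width 2.2 / 2.0 / 2.1 mm) and replicate-level SDs of
  4.0 / 0.08 / 2.5 / 0.2 mm; zero-truncated normals, 24 records per
  sample, cluster sizes in proportion 14:26:12.
* **Flow cytometry**: sample FL2-A = standard FL2-A × (2C size / 1.67) ×
  (1 + N(0, CV)) with CV 0.02; simulated 2C sizes 1.07 / 1.61 / 2.15 pg
  for 2x/3x/4x — the triploid value is the published 'Tifgreen' content,
  the others are synthetic stand-ins scaled linearly with ploidy.

Everything derives from one integer seed; identical configs produce
byte-identical outputs, and a `truth.json` sidecar records founder
genotypes, contaminant identities and true morphology clusters for
recovery tests.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genotype-call error at low depth (the stored
genotype is the true one; only allele depths and missingness are noisy),
linkage and allele-frequency structure between loci, aneuploidy and
copy-number variation, shared mutational lineage among cultivars (founders
diverge independently from one consensus), batch or date effects in
morphology, and flow-cytometry debris/gating artifacts. Divergence and
somatic rates are order-of-magnitude choices exposed in the config, not
fitted values.

## Numerical and testing choices

* Eigen-decompositions use symmetric solvers; MDS drops non-positive
  eigenvalues (warning when the requested dimensionality is reduced).
* Dosage re-calling uses integer arithmetic so the half-away-from-zero tie
  break is exact.
* Stochastic properties (contaminant recovery, cluster recovery, CCC null
  calibration) are tested over 50–100 fixed seeds at the generator's
  default conditions; problem sizes (2,000 loci, ~95 samples, 52
  morphology samples) keep the full suite fast while leaving every rate
  estimable.
* The acceptance script runs the entire pipeline on a fresh simulation at
  the given seed and reports only quantities computed in that run.

## Known limitations

* The differentiating-locus rule is defined for biallelic sites only;
  multi-allelic records are skipped, not decomposed.
* The dosage re-caller ignores base quality and genotype likelihoods.
* The divergence screen's median/MAD baseline is unstable when the
  references comprise very few distinct clonal lineages; with six
  cultivar lineages the false-flag tail among the standards themselves is
  non-negligible, which is why the pipeline reports flags for standards
  separately from the putting-green samples.
* CCC inherits the biases of the published approximation (see above); it
  is a diagnostic, not a test statistic.
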