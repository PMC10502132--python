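# Methods

This note documents the models, defaults, numerical choices and limitations
behind `rubuspanel`, in the order data flows through the pipeline.

## Genotype model

All analyses operate on a samples × loci matrix of ALT-allele dosages
{0, 1, 2} with NaN as the single missing sentinel. Parsing is phase-free
("0|1" and "1|0" are both dosage 1) because every statistic used is
phase-free. Half-called genotypes ("0/.") are treated as missing — the
conservative choice, since a half call cannot distinguish dosage 0 from 1.
Coordinates follow the VCF convention (1-based) throughout; locus
identifiers default to `seq:pos:ref:alt` when the VCF ID column is empty,
which is unique within a call set. Multi-allelic records are read (dosage =
count of non-REF alleles) but flagged and removed by the first QC stage.

A key invariant, asserted across the test suite: every downstream statistic
is invariant under allele recoding x → 2 − x (REF/ALT swap). This is what
makes the dual-reference machinery safe in the presence of coding flips.

## Synthetic testcross panels

The generator emulates a specific experimental design: one highly
heterozygous black-raspberry tester ("Jewel") crossed as female to three
red-raspberry donors, producing half-sib F1 families, with an unrelated
check cultivar added to the panel. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| family sizes (JG/JT/JS) | 43/38/35 | the panel the pipeline targets (116 hybrids) |
| chromosomes × length | 7 × 40 Mbp | black-raspberry genome layout |
| n_loci | 5000 | density ≈ 18 markers/Mbp, enough for every stage at desk scale |
| tester_het_rate | 0.77 | the tester's published observed heterozygosity |
| donor_het_rate | 0.58 | the donors' published mean observed heterozygosity |
| fixed_divergence_rate | 0.08 | calibrated from progeny Ho: E[Ho] = 0.5(1−d) + d = 0.54 ⇒ d = 0.08 |
| missing_rate / genotype_error_rate | 0.02 / 0.002 | typical post-calling GBS panel quality |
| dual_overlap_fraction | 0.40 | fraction of markers called against both assemblies |
| coding_flip_prob | 0.20 | REF/ALT disagreement rate between assemblies |
| n_scaffolds | 100 | gives the second call set its fragmented-assembly character |
| mean_depth (NB, dispersion 5) | 32× | published mean coverage; dispersion 5 gives the long right tail of GBS depth |

Offspring receive one uniformly random allele from each parent per locus;
missing parental genotypes propagate to missing offspring genotypes, never
imputed. At a `fixed_divergence_rate` fraction of loci the tester is hom-REF
and all donors hom-ALT — the interspecific signature that makes every
hybrid heterozygous there. The check is an unrelated genotype drawn from
the donors' allele frequencies (HWE draw), since no pedigree is assumed for
it. The second call set re-maps loci onto scaffolds (chromosomes split at
uniform random breakpoints), applies independent single-step genotype
errors (0↔1↔2, never 0↔2 at once — the allele-dropout-dominated error mode
of GBS), missingness, and coding flips; the cross-set pairing is recorded
as truth.

What the generator deliberately does **not** model: linkage and
recombination (loci segregate independently — no downstream statistic needs
genetic linkage, and LD-decay estimation is validated against a direct
r²(distance) generator instead, see below); coalescent ancestry, selection
and mutation; read-level sequencing. Consequently, passing tests certify
the estimators and the pipeline plumbing, not population-genetic realism of
linked variation, and windowed LD computed on a simulated panel is flat
noise near 1/n by construction.

Two algebraic notes on the design:

* **Mid-parent heterozygosity.** At non-divergent loci offspring
  heterozygosity has expectation 0.5 regardless of parental genotype
  frequencies, so with highly heterozygous parents (mean parental het m̄ >
  0.5) the panel's Ho exceeds the mid-parent Ho only when the divergent
  fraction d satisfies 0.5·d/(1−d) > m̄ − 0.5. The "hybrids more
  heterozygous than their parents" signature is therefore a statement about
  divergence, not about hybridization per se; the suite asserts it under
  equal parental rates (m̄ = 0.5), where the divergence term is isolated.
* **Identifiability of the pairing truth.** At fixed-divergent loci every
  hybrid is heterozygous, the parents are identical across such loci, and
  the check is driven to hom-ALT — the genotype columns are *identical*.
  Identical columns carry no pairing information: any cross-call-set
  matcher over-pairs them, and the greedy matching among them is arbitrary.
  This is not an implementation defect but an information-theoretic limit;
  it is pinned down by a dedicated test and is the likely mechanism behind
  inconsistent coincident/unique marker counts reported for real panels of
  this design. Matcher precision/recall is therefore validated on panels
  with the divergent class switched off.

## Marker QC

Filters run in a fixed order — biallelic, call rate, MAF, LD pruning — and
each removed locus is logged with the stage at which it died, so
input = survivors + removals always holds and the pipeline is idempotent.
Boundary semantics are inclusive (call rate ≥ 0.90, MAF ≥ 0.05) to avoid
knife-edge float exclusion; a strict (>) mode is a switch, and the report
records which was used. Monomorphic loci are always removed at the MAF
stage. LD pruning needs an order and a window that the filter thresholds
alone do not determine: a greedy left-to-right scan within 1 Mbp on the
same sequence (first kept wins, r² > 0.99 drops the later locus) was chosen
for determinism, using the same window as the decay analysis; on
scaffold-anchored sets the same rule applies per scaffold. Correlations use
pairwise-complete observations, and pairs with fewer than 20 shared calls
are never pruned (insufficient evidence). Within group-level analyses,
loci that become monomorphic in a subset are *not* removed; they simply
contribute their defined values (e.g. MAF 0) to group means, which is what
makes single-sample group rows arithmetically coherent.

## Dual-reference harmonization

All-pairs Pearson correlation between the two call sets' columns is
computed as standardized matrix products over observed entries —
O(M₁·M₂·n) in a handful of BLAS calls at panel scale. Candidates need
|r| ≥ 0.98 and ≥ 20 pairwise-complete samples; the absolute value is used
because REF/ALT assignment legitimately differs between assemblies (a
strict-signed mode exists for literal reproduction). Constant columns have
undefined r and are excluded. Candidates are resolved to a one-to-one
matching greedily by descending |r| (ties: larger overlap, then
lexicographic ids) — chosen over optimal assignment for determinism and
speed. The unique matrix keeps every chromosome-anchored column and the
unpaired scaffold-anchored columns, so |unique| = |MOC| + |MID| − |pairs|
by construction; a link table (chromosome, position, scaffold, position, r,
flip) is emitted for circos-style visualization.

Measured limits of the matcher under the generator's conditions (121
samples, error 0.002): a column accumulating ≥ 2 genotype errors — a
Poisson(0.24) tail event of ~2.5% — typically falls below the 0.98
threshold unless its dosage variance is high, bounding recall near
0.97; parental-homozygosity classes (all four parents homozygous,
~1.7% of loci at the default het rates) produce family-deterministic,
mutually identical columns, bounding precision near 0.98. Both bounds are
properties of the fixed matching rule at these conditions, not tunables.

## Diversity statistics

With p the within-group ALT frequency on non-missing calls and q = 1 − p:
MAF = min(p, q); PIC = 1 − (p² + q²) − 2p²q² (the biallelic
Botstein definition — the convention of SNP marker tooling, adopted because
the quantity is otherwise underdetermined); GD = 2pq (expected
heterozygosity); Ho = fraction of heterozygous calls (per locus and per
individual, each over its own callable entries, so S is
individual-specific). Group allele frequencies are recomputed within each
group — a group's GD is meaningless under panel-wide frequencies — and
group means are unweighted.

The molecular inbreeding coefficient sums the identity of an individual's
two alleles over its S callable SNPs, halves it, normalizes by S and
subtracts 1. Under the allele-identity reading a homozygous locus
contributes 2 and a heterozygous locus 1 to the double sum, so the
coefficient reduces exactly to F = (proportion of homozygous loci) = 1 −
Ho, bounded in [0, 1]; this is the default because it yields a coherent
Ne = 1/(2F̄). The alternative reading — scoring the heterozygosity
indicator (0 hom / 1 het) instead of allele identity — reduces to
F = 2·Ho − 1, can be negative, and is provided as an audit mode; the mode
used is recorded in every output. Note the estimator's behavior: for an
outbred, highly heterozygous panel (Ho ≈ 0.5) it gives F ≈ 0.5 and hence
Ne ≈ 1 — homozygosity-based F measures departure from complete
heterozygosity, not pedigree inbreeding, so large published Ne values
cannot be recovered from these definitions and are not asserted anywhere in
the suite. Non-positive mean F yields an infinite Ne with a warning, never
a crash.

## Relationship matrix and structure

VanRaden's G = ZZ′ / (2Σₖ pₖqₖ) with Z the 2p-centered dosage matrix;
missing dosages are mean-imputed (2p) for this computation only. Column
centering forces G's row sums to zero (tested at 1e−8), and symmetry is
enforced exactly. PCA is the eigendecomposition of G; numerically negative
eigenvalues are clipped to zero in scores and in the variance-explained
denominator, and each eigenvector's largest-magnitude loading is made
positive so exports are sign-reproducible. On complete data the scores
equal those of the centered-dosage SVD up to the 1/√denominator scale
(Gram duality, tested).

Ward clustering operates on the G-induced distances d²(i,j) = G_ii + G_jj −
2G_ij (numerically negative values clamped to zero), with the
squared-distance ("Ward.D2"-equivalent) update; the dendrogram is exported
as newick with edge length = parent merge height − child merge height, and
`cut(k)` yields hard assignments for any k.

DAPC: (1) PCA of the centered (mean-imputed) dosages, retaining n_pca = 45
score columns (capped at rank and n − 1); (2) k-means for each candidate
k ∈ 1..8 (10 restarts, seeded) with BIC(k) = n·ln(WSS_k/n) + k·ln(n); the
BIC form is one convention among several, so the full BIC curve is emitted
for users preferring elbow-style selection; (3) linear discriminants from
the generalized eigenproblem of between- vs within-group scatter on the
retained scores, ridge-stabilized (ε·tr(S_w)/d + ε on the diagonal,
ε = 1e−8, logged when it matters); (4) membership probabilities from
Gaussian densities with shared within-group covariance and equal priors in
discriminant space — the simplest model consistent with linear
discriminants. Assignments are the membership argmax. Same seed + input ⇒
identical result, asserted.

## LD decay

Pairwise r² is computed for all same-sequence locus pairs closer than 1 Mbp
(pairwise-complete dosages, pairs with < 20 shared calls skipped and
counted). Decay per chromosome fits the Hill–Weir sample-size-adjusted
expectation E[r²](C = ρd, n) by nonlinear least squares over ρ and reports
the smallest distance where the fitted curve crosses the target r² (0.20
default), searched up to 10× the window; a curve that never crosses is
reported as undefined with the reason, never fabricated. When the fit
fails, 10-kb bin means with linear interpolation of the first crossing are
the fallback; the method used is recorded per sequence. Since the panel
generator has no recombination, decay-estimation tests draw (distance, r²)
pairs directly around a known Hill–Weir curve with truncated Gaussian noise
(σ = 0.08) and compare the estimate to the analytic crossing; recovery
within 10% is the acceptance bar, and fit-vs-bin agreement within 15% is
asserted on low-noise data.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each statistical check has adequate power: 10⁴
offspring for Mendelian recovery, 50×200 matrices for oracle equivalence,
5000 loci / 121 samples for matching, 3000 loci for structure recovery,
5000 (distance, r²) pairs for decay. Every random draw flows from a single
`numpy.random.default_rng` seed; pipeline runs write a manifest with sha256
checksums of all outputs, and re-runs with the same seed are bit-identical.

## Known limitations

* The homozygosity-based F/Ne pair is internally consistent but not
  comparable to pedigree-based effective sizes (see above).
* Cross-call-set matching cannot disambiguate statistically identical
  columns (fixed interspecific divergence, all-homozygous parental
  classes); expect over-matching on real interspecific panels, visible as
  unique-matrix counts smaller than |MOC| + |MID| − |true shared|.
* Scaffold-anchored LD is computed on request but decay over scaffold
  coordinates has limited interpretation (warned).
* The generator's missing-data process is uniform; real GBS missingness is
  depth- and locus-correlated, so call-rate filter performance on real data
  may differ from the binomial oracle used in tests.
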