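# Methods

This note documents the statistical models, estimators, defaults and design
choices behind `piaoscan`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute themselves.

## Selection scan

**Per-site statistics.** For a biallelic site with `m` called alleles and
alt-allele frequency `p̂`, nucleotide diversity uses the unbiased
heterozygosity estimator

    π_site = m/(m−1) · 2 p̂ (1 − p̂),

which equals the mean number of differences over all C(m, 2) pairs of
sampled alleles. F<sub>ST</sub> defaults to Hudson's two-population
estimator,

    N = (p₁ − p₂)² − p₁(1−p₁)/(m₁−1) − p₂(1−p₂)/(m₂−1),
    D = p₁(1−p₂) + p₂(1−p₁),

chosen for its clean closed form and good behaviour in two-population scans;
the Weir–Cockerham (1984) variance-component form (a, a+b+c) is available by
flag. Window F<sub>ST</sub> is the **ratio of sums** ΣN/ΣD over in-window
sites — the standard variance-reducing aggregation — and per-window values
are not clamped to [0, 1]. Sites with fewer than two called alleles in a
population are excluded from that population's sums; sites callable in only
one population are excluded from F<sub>ST</sub>.

**Windows.** 40-kb windows stepped every 20 kb, 0-based half-open and
anchored at 0 per chromosome; a 1-based position P belongs to window
[start, start+40000) iff P−1 falls inside it. Pi per bp divides the summed
per-site diversity by the window width (not by the variant or callable site
count) — the common genome-scan convention; this makes Pi proportional to
variant density, which cancels in ΔPi comparisons across windows of equal
width. Terminal windows truncated by the chromosome end are kept, with the
true width as the per-bp denominator, only if at least half a window wide.
Windows with fewer than `min_sites = 10` usable sites are dropped (the
source protocol is silent on both; both are configurable).

**Candidates.** ΔPi = Pi(control) − Pi(case); positive values flag reduced
case diversity, the sweep signature. The top set for each statistic is the
top k = max(1, ⌈q·n⌉) windows at q = 0.01, with ties at the threshold
included; candidates are the intersection of the F<sub>ST</sub> and ΔPi top
sets. The ceiling form (rather than ⌊qn⌋) keeps the advertised 1% of
windows in the top set when q·n is fractional.

**Recovery ratio.** Each of `n_replicates = 1000` replicates draws 20
controls without replacement from the control pool (cases unchanged),
recomputes both windowed statistics and the top-set intersection, and
records membership. rr_fst and rr_dpi are per-statistic recovery fractions;
rr_joint is recovery by the intersection. The selection rule defaults to
rr_fst ≥ 0.95 AND rr_dpi ≥ 0.95 — the per-statistic reading — with the
joint-recovery rule available by flag, because the two readings are both
defensible from the source protocol. Replicate r derives its RNG from the
child seed (seed, r), so any replicate is reproducible in isolation.

**GF filter.** "Ratio with altered alleles" is interpreted as the
alt-**allele** frequency among called alleles, (het + 2·hom-alt)/(2·n_called);
a carrier-frequency mode (fraction of called individuals with ≥ 1 alt
allele) is available by flag since the phrase admits both readings.
Eligibility encodes the strict bounds: called in ≥ 16 of 20 cases (> 15) and
≥ 51 of 98 controls (> 50); the ratio bounds (> 0.8, < 0.06) are strict.
SNPs and indels pass through identically and are reported with their type.

## Genotype simulator

Sites are Poisson-spaced at `site_density` expected variants per bp. Each
site draws an ancestral frequency p₀ ~ U(0.05, 0.95) and, independently per
population, a Balding–Nichols frequency Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with
F = `background_fst` (default 0.05). Balding–Nichols was chosen over
coalescent machinery because it gives a tunable expected F<sub>ST</sub> with
a closed generative form usable as a Monte-Carlo oracle. Sweeps are modelled
as a frequency displacement: inside each sweep region the case frequency
moves by `sweep_shift` (default 0.6) toward the nearer of {0, 1},
truncated — enough to create the rank signal the scan detects, without
simulating linkage or demography (non-goals). Genotypes are
Binomial(2, p_pop) per individual; missingness is i.i.d. at `missing_rate`
(default 0.02). Defaults give 5 chromosomes × 2 Mb ≈ 500 windows with one
grid-aligned 40-kb sweep per chromosome, matching the 20-vs-98 design.

Planted highly differentiated sites (default 25, placed outside sweep
regions) are written as hom-alt in every case and hom-ref in every control
*before* missingness, so they pass the GF filter by construction whenever
enough calls survive (always at missing_rate = 0). Indels are realized as a
site-type flag with a one-base insertion allele — no sequence content — since
the downstream filter treats SNPs and indels identically. `write_vcf` emits
plain VCF 4.2 with GT fields; `read_vcf` (cyvcf2) maps 0/0→0, 0/1 or 1/0→1,
1/1→2, any missing allele→missing, ignores phasing, and drops multiallelic
records with a logged count.

What the simulator does **not** model: linkage disequilibrium, demographic
history, read-level error, allele-specific anything. Passing tests therefore
demonstrate that the scan recovers frequency-displacement signals of the
planted magnitude under independent-site sampling — not performance on real
chicken genomes.

## Expression pipeline

**FPKM** is computed exactly as counts·10⁹/(length·lib_size) with lib_size
defaulting to column sums. **Filtering** retains a gene iff, in ≥ 80% of the
case samples or ≥ 80% of the control samples, both counting models give
counts ≥ 10 and FPKM > 0 (fractional comparison, no rounding).

**Normalization** is log2(FPKM + offset), offset 1.0 by default (the filter
guarantees positivity only for retained genes in supporting samples). The
optional GC/length correction fits, per sample, a robust Huber regression of
the log2 value on (GC fraction, log10 length) and subtracts the centred fit,
preserving each sample's mean to numerical precision. This is a transparent
linear surrogate for spline-based conditional-quantile normalization
(deliberately *not* a re-implementation of it, which is a non-goal); it
removes linear trends only.

**Covariate adjustment** fits, per gene, OLS of the value on an intercept
plus numeric covariate encodings and subtracts Σ β̂_c·x_c, keeping intercept
and residual. Encodings: days D7/D8/D9 → 1/2/3; lanes one-hot against the
first level; breed as a **control-subtype contrast only** (Gushi vs Wuding,
cases at the reference level). A full breed factor would be perfectly
confounded with case/control in this design (all cases are one breed), so
the group contrast would be absorbed and unidentifiable; the group label is
never among the adjustment covariates. Collinear covariate sets (including
constants, which duplicate the intercept) are rejected with the offending
columns named via pivoted QR. Adjustment is idempotent because residuals are
orthogonal to the design.

**DEG test.** Per gene, OLS of the (normalized, unadjusted) value on
intercept + group indicator + covariates, vectorized across genes with the
shared design; two-sided t-test on the group coefficient with n − p residual
degrees of freedom; Benjamini–Hochberg step-up q values (the standard choice
where the protocol says only "FDR"), flagged at q < 0.05. Fold change on the
FPKM scale uses a pseudo-count of 0.01 in both numerator and denominator to
keep ratios finite for nearly undetectable genes, and is reported with the
higher group's label. External caller results (e.g. Cuffdiff or DESeq2 gene
lists) are consumed as one-id-per-line files and intersected; a built-in
Welch t-test caller exists purely to exercise the intersection machinery and
is explicitly not a count-model method.

## Expression simulator

The sample table mirrors the embryo design: 9 cases (3 per day D7–D9, breed
Piao) and 12 controls (Gushi and Wuding, 2 replicates per breed per day),
with lanes assigned in a Latin-square stagger so lane never aliases day.
Per gene, the log2 expected count is

    baseline + group effect + day slope·code + breed/lane effects
    + module signal + depth,

with baseline ~ N(5, 2), per-gene covariate coefficients ~ N(0, σ_c)
(defaults σ_day = 0.2, σ_breed = 0.3, σ_lane = 0.1 log2 units) and
idiosyncratic noise of sd 0.5. The generated breed effect is a contrast
between the two control breeds, matching the analysis encoding: a
whole-breed case effect would be indistinguishable from the group effect in
this design, so planting one would make the null uncalibratable rather than
more realistic. DE genes (default 100 of 2000) receive a ±`de_log2fc` group
shift (default 2, i.e. 4-fold). Module genes replace their idiosyncratic
noise with a shared latent program of amplitude 2.0 log2 units and loading
λ = `module_cor` (default 0.95, on the scale of the kME > 0.8 hub criterion
the network arm applies); pairwise latent correlation is λ².

Counts are NB(μ, α) with α = 0.05 (Var = μ + αμ²); whole-gene-model counts
add Poisson(0.05 μ) "intronic" reads on top of union-exon counts, so the
nesting counts_whole ≥ counts_union holds by construction. A per-sample
depth factor (sd 0.15 log2 around a nominal 10⁶ mapped fragments) scales
every gene's expected count and is recorded as lib_size, so FPKM division
removes it; lib_size is *not* the panel column sum because at desk scale a
handful of high-amplitude genes would dominate that sum and FPKM
normalization would partially cancel the planted module signal — in real
data the ~20k-gene transcriptome buffers this. Gene lengths are
LogUniform(200, 10⁵) bp, GC ~ U(0.3, 0.7), both independent of expression
(the GC-correction test plants its own trends explicitly).

## Co-expression network

Pearson correlation throughout (the WGCNA default). Signed adjacency
a_ij = ((1 + cor_ij)/2)^β with a_ii = 1; β defaults to 12. The scale-free
fit bins connectivity k into 10 equal-width bins and regresses
log10(frequency) on log10(mean k); the chosen power is the first with
R² > 0.8, else the argmax with a warning. (Equal-count binning is
unusable here: it forces a constant frequency per bin, leaving the
regression undefined.) At the desk-scale problem sizes the suite uses,
connectivity is module-dominated rather than scale-free, so the fit is
reported as a diagnostic while network construction fixes β = 12.

TOM follows the standard formula
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), TOM_ii = 1,
computed by matrix product and verified against a triple-loop oracle.

**Module detection** replaces the dynamic tree cut of the reference WGCNA
workflow with a deterministic static cut: average-linkage clustering on
1 − TOM, cut at an absolute dissimilarity height (default 0.85); clusters
with ≥ 30 genes become modules M1, M2, … by decreasing size, everything else
is M0. The absolute cut exploits the scale separation this dissimilarity
exhibits: tightly co-expressed blocks join below ≈ 0.8 while merges among
unrelated genes concentrate near 1 (a *quantile*-of-merge-heights cut would
place the threshold inside the noise continuum and return one giant
cluster on structureless data). Correctness is defined by planted-module
recovery and null behaviour, not by gene-for-gene agreement with any
particular tree-cut heuristic.

**Eigengenes and merging.** A module eigengene is the first right singular
vector of the module's per-gene-standardized submatrix, unit norm, signed to
correlate non-negatively with the module mean. Merging iteratively joins the
module pair with the highest eigengene correlation while it exceeds
1 − merge_height = 0.75, recomputing eigengenes after each merge (ties break
toward smaller module indices); final labels are reassigned by size. A
second pass at the same height merges nothing.

**Trait statistics and hubs.** The rumpless trait is coded case = 1,
control = 0. Module–trait association is the Pearson correlation of each
eigengene with the trait, p from t = r√((n−2)/(1−r²)) on n−2 df, flagged at
p < 0.05. GS is the gene–trait correlation on the raw trait (a day-adjusted
variant was considered and rejected: the adjusted matrix already removes day
effects). kME is the gene–eigengene correlation; kIM sums adjacency (not
TOM — the standard intramodular connectivity) to same-module members. Hubs
require |GS| > 0.2 AND |kME| > 0.8, strictly; per module they are ranked by
kIM descending (ties by gene id) and edges among the top 50 with TOM > 0.1
are exported as three-column TSV (source, target, weight) loadable by
standard network tools.

## Problem sizes and numerics

The test suite and acceptance script run everything at desk scale, chosen as
the smallest sizes at which the planted signals are statistically
identifiable: ~500 windows × ~50k sites × 118 individuals for the scan
(1000 RR replicates in the acceptance script, 200 in the repeated-seed
test), 2000 genes × 21 samples for the DEG arm, 300 genes (3 × 50-gene
modules + 150 noise) for the network arm. Exact oracles are held to 1e−12
(Pi), 1e−10 (TOM, idempotence) or 1e−8 (eigengene); stochastic recovery
criteria are evaluated over 10–20 seeds. Degenerate inputs follow explicit
conventions rather than erroring where a value is well-defined: monomorphic
sites contribute 0 to Pi, windows with zero F<sub>ST</sub> denominator
report 0, empty window lists yield empty candidate sets, and single-gene
modules use the gene's standardized profile as eigengene.

## Known limitations

- Independent sites: no LD, so RR variability across control subsamples is
  lower than in real data where windows share haplotypes.
- The GC/length correction is linear; curved GC biases are out of reach.
- The static module cut assumes the within/between dissimilarity gap that
  planted modules produce; diffuse real modules near the cut height will be
  split or absorbed where a dynamic cut might recover them.
- The Welch caller is a stand-in second method for intersection tests, not a
  substitute for count-based DEG callers.
- Module counts and trait-significant module counts from real data depend on
  tree-cut heuristics not reproduced here and are not a validation surface.
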