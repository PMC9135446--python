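# Methods

`keystonet` reimplements, as a tested library, the statistical pipeline used
to study how ammonia-oxidizing archaea (AOA) and bacteria (AOB) respond to
organic soil amendments: alpha/beta diversity, thresholded signed
co-occurrence networks, MCODE module detection, Zi–Pi keystone
classification, module eigengenes, natural-connectivity robustness, and the
nitrogen-function calculators (potential nitrification activity, its
1-octyne partition, nitrogen use efficiency, fold changes). A synthetic
community generator supplies data with known ground truth so every stage is
testable without sequencing data.

## Co-occurrence network inference

Input is a samples × OTUs count table with each OTU assigned a guild (AOA
or AOB) and a phylogenetic cluster. The pipeline:

1. **Prevalence filter.** Keep OTUs present (count > 0) in *strictly more
   than* a fraction `min_fraction` (default 3/4) of the samples. Amplicon
   tables carry a tail of rare, sporadically detected OTUs whose
   correlations are dominated by shared zeros; this step removes them.
2. **Correlation.** Spearman's rho on relative abundances (count / sample
   total), all OTU pairs. With the very small n of field trials the
   t-approximation for Spearman p-values is unreliable, so p-values are
   exact (full enumeration of the permutation null) for n ≤ 9 and
   t-approximated above. An ensemble mode requires Spearman *and* Pearson
   to pass the thresholds, reporting Spearman's rho as the edge weight.
   Zero-variance OTUs are excluded with a log entry. No zero replacement or
   log-ratio transform is applied; the pipeline deliberately works on plain
   relative abundances.
3. **Multiple testing.** Step-up Benjamini–Hochberg within the full set of
   pairs tested for that network (never pooled across networks).
4. **Thresholding.** An edge requires |r| > 0.7 (strict) and adjusted
   p < 0.01 (strict) by default; a flag switches the p-threshold to the raw
   p. Edge sign is the sign of rho. Isolated nodes are dropped.

Networks are built per condition subset (e.g. unamended treatments CK+N
versus amended NS+NSM+NB) on the pooled AOA+AOB table, so edges within and
between guilds are tabulated together (the `edge_composition` report splits
them into AOA–AOA / AOA–AOB / AOB–AOB × sign and gives the percentage of
negative correlations, PNC).

### Choice of p-threshold at small n

These two thresholds interact with sample size in a way worth being
explicit about. At n = 15 and ~10³ tested pairs, requiring a BH-adjusted
p < 0.01 corresponds to an effective cutoff of |r̂| ≈ 0.8. A block of OTUs
with latent correlation 0.9 has population Spearman ≈ 0.89, but its *sample*
correlations fluctuate together across a 15-sample draw (the block factor's
sample variance has CV ≈ √(2/14) ≈ 0.38), so in a sizeable fraction of
datasets the whole block lands below 0.8 and the module dissolves. The
planted-structure benchmark (`recover_planted_structure`) therefore uses
the raw-p flag, where the |r| > 0.7 threshold itself is the binding
constraint; `build_network`'s own default remains the adjusted p.

## Modules: MCODE

Implemented from the original algorithm description, on the unsigned
skeleton: (1) each vertex is weighted by k × density of the highest k-core
of its closed neighborhood; (2) complexes grow greedily from the
highest-weight unseen vertex, admitting neighbors whose weight is at least
`seed weight × (1 − node_score_cutoff)` (default cutoff 0.2); (3) the
haircut removes singly-connected vertices (iterated to a fixed point), and
complexes without a 2-core or smaller than 3 nodes are discarded. The
"fluff" stage is omitted (off by default in the reference implementation).
Modules are labeled I, II, … by descending size. Nodes outside every
complex are unassigned; an optional greedy-modularity fallback assigns an
unassigned node to the module that best overlaps its greedy-modularity
community, provided the node has at least two links into it (so pendant
noise nodes stay out). The full pipeline enables the fallback; the bare
`mcode_modules` default leaves it off.

## Node roles: Zi–Pi

Within-module degree z-score `Z_i = (κ_i − mean κ) / SD(κ)` uses the
*population* SD over the node's module (standard in the module-role
literature; ties are common in small modules) with the convention Z = 0
when the SD is zero. The participation coefficient
`P_i = 1 − Σ_s (k_is/k_i)²` counts edges to unassigned neighbors as one
pseudo-module so the shares always sum over the full degree. Roles:
module hub (Z > 2.5, P < 0.62 — the candidate keystone taxa), network hub
(Z > 2.5, P ≥ 0.62), connector (Z ≤ 2.5, P ≥ 0.62), else peripheral; all
inequalities strict as written. Role topology ignores edge signs.

## Module eigengenes

Each module member's relative abundance across the chosen sample subset is
z-scored (population SD; constant members are dropped with a log entry),
and the module eigengene is the leading left singular vector of the
samples × members matrix — unit-norm scores per sample — oriented to
correlate positively with the module's mean standardized profile. Variance
explained is the leading squared singular value over the total. Eigengenes
are computed per network condition subset, since each network's modules
summarize that subset's samples.

## Natural connectivity and robustness

Natural connectivity is `ln((1/n) Σ_i e^{λ_i})` over the eigenvalues of the
unweighted adjacency matrix, evaluated with a shift by λ_max so large
graphs do not overflow. An edgeless graph gives exactly 0; disconnected
graphs are handled by the full spectrum. Robustness curves remove a grid of
node fractions either uniformly at random (seeded replicates, mean ± SD) or
in descending intact-network degree (deterministic, ties broken by node
id), recomputing natural connectivity each time; fraction 0 reports the
intact value exactly.

## Nitrogen-function calculators

Potential nitrification activity (PNA) is the OLS slope of NO₂⁻-N
concentration against time over all assay time points (default grid 0, 8,
24, 30, 48, 60, 72 h); no lag-phase trimming is applied by default, and
negative slopes are returned as-is with a warning flag. 1-octyne
selectively inhibits bacterial ammonia oxidation, so PNA_AOA is the slope
with octyne, PNA_AOB the difference (without − with), and PNA_total is
*defined* as PNA_AOA + PNA_AOB so the additivity identity is exact in
floating point. NUE is 100 × (N uptake fertilized − unfertilized) / N
application rate. Group summaries are mean ± standard error over the three
field replicates, and AOA/AOB abundance ratios are computed per replicate
and then averaged (the mean of ratios, not the ratio of means). The PNA
unit is per gram dry soil, inferred from the 5-g slurry protocol.

## Diversity

Shannon entropy uses the natural log over positive counts; Chao1 is the
bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)) and requires integer
counts. No rarefaction is applied by default; an even-depth subsampler is
available behind a flag. Bray–Curtis dissimilarity Σ|x−y|/Σ(x+y) (scipy)
underlies both the compositional similarity (its complement) and NMDS
(Kruskal stress-1 via non-metric MDS, best of 20 random restarts,
seeded). Treatment effects on composition are tested with a seeded
PERMANOVA-style permutation test (999 permutations) on Bray–Curtis
distances.

## Tukey compact letters and association tables

Treatment comparisons use one-way ANOVA / Tukey HSD at α = 0.05
(statsmodels) followed by an insert-and-absorb compact letter display:
groups sharing no letter differ significantly. Association tables
(module eigengenes or cluster abundances versus soil chemistry, qPCR
abundances, productivity) use Spearman with the same exact-p machinery;
star labels mark raw p < 0.05 (*) and p < 0.01 (**) by default, with an
optional BH adjustment over the table.

## Synthetic community generator

The generator emulates the study design: 5 treatments (CK, N, NS, NSM, NB)
× 3 replicates, two guilds of OTUs, treatment-dependent abundance shifts,
and planted co-occurrence structure. Latent log-abundances are Gaussian
with a target correlation matrix (a Gaussian copula over log-normal
abundances), so the planted *rank* correlations survive the exponential
map; counts are multinomial at a fixed depth per sample (50,000 by
default), making the data compositional as amplicon data are. Ground truth
(memberships, hub ids, the realized latent correlation matrix, latent
abundances, true PNA slopes) is recorded exactly.

The community mixes four abundance classes: (i) *structured* OTUs carrying
the planted modules and hub groups — moderately abundant, log-SD 1.0;
(ii) *treatment responders* shifted ±0.8 log units under the amended
treatments, balanced up and down so the sample total is stable across
treatments; (iii) a few *dominant stable core* taxa per guild (log-SD 0.3)
holding most of the reads, as real ammonia-oxidizer communities do; and
(iv) a *sporadic rare tail* present in ~55% of samples, which the
prevalence filter removes. Classes (iii) and (iv) are not decoration: the
relative-abundance transform divides by the sample total, so any
fluctuation of that total is shared noise in every log relative abundance
and preferentially dilutes *negative* rank correlations. Anchoring the
total with stable dominants keeps the planted structure expressed in the
counts.

Planted modules are correlation blocks `signs_i × signs_j × rho` (default
rho 0.9). A hub is an OTU tied to every satellite at |rho| (default 0.85),
negative for a configurable fraction (default all). Correlation geometry
constrains this structure: if a hub is tied at |rho| to m satellites, the
satellites' mutual correlations are forced up to the
positive-semidefiniteness floor `(m·rho² − 1)/(m − 1)` (a λ_max bound —
strong correlations are quasi-transitive). The generator plants the
satellites exactly at that floor, the weakest mutual coupling the hub ties
allow, and validates every block before projecting the assembled matrix to
the nearest valid correlation matrix (Higham projection via statsmodels;
matrices already valid pass through unchanged, and an infeasible planted
block raises an error naming it).

### What the generator does and does not show

Passing recovery tests on this generator demonstrates that the inference
chain (filter → correlation → thresholds → MCODE → Zi–Pi) faithfully
recovers block-correlation structure expressed through compositional
counts at realistic depth and n. It does not emulate phylogeny, PCR or
chimera artifacts, overdispersion beyond the log-normal, or genuinely
non-Gaussian dependence. One consequence of the Gaussian model deserves
emphasis: the same λ_max bound above means a latent hub's satellites are
always themselves interconnected at ≈ rho² — a node with many strong
neighbors whose neighbors are mutually weak cannot exist in a Gaussian
copula. High within-module degree z-scores (Z > 2.5) in thresholded
correlation networks therefore arise mainly in noise-dominated, very-small-n
networks rather than from strong planted ties; at n = 15 the generator's
hubs are recovered as high-degree, negatively-signed module members, but
their Z typically falls between 1 and 2.5 (the satellite floor keeps
member degrees too even). The recovery report
(`evaluate_recovery`) exposes both the module Jaccard and the hub-role
flags so this behavior is measured, not assumed.

## Problem sizes and numerical choices

Default synthetic conditions: 30 + 30 OTUs, 15 samples, depth 5 × 10⁴,
two 6-OTU planted modules, one hub with 19 satellites; recovery is
evaluated over 20 consecutive seeds. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical configs and
seeds reproduce outputs byte-for-byte. Spearman exact nulls are cached per
n (n ≤ 9; 9! ≈ 3.6 × 10⁵ permutations enumerated once). Eigen-decompositions
use symmetric solvers; the nearest-correlation projection clips eigenvalues
at 10⁻¹⁰. Ties in MCODE seeding and targeted removal are broken by node id
for determinism.

## Known limitations

- Correlation-network "keystones" are statistical constructs; nothing here
  validates ecological keystoneness.
- The exact Spearman null assumes tie-free data; tied ranks fall back to
  the t-approximation at any n.
- CoNet's original "multiple correlations" ensemble is under-specified in
  the literature; the ensemble mode here is Spearman ∧ Pearson agreement.
- The PERMANOVA-style test and the NMDS restarts depend on the seeds
  provided; stress values from non-metric MDS are local optima.
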