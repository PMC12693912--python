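# Methods

## Confidence-interval standardization

Published QTLs rarely come with comparable interval estimates, so the
package re-expresses every QTL as a 95% positional interval. Reported
intervals are kept by default (`policy: prefer_reported`); missing ones
are filled from the empirical population-specific relations

| population class | CI width (cM) |
|---|---|
| F2, F2:3, BC | 530 / (N·R²) |
| RIL, BIL | 163 / (N·R²) |
| DH | 97.462 / (N·R²)^0.835 |

with N the mapping-population size and R² the phenotypic variance
explained (stored as a fraction; readers accept percent columns via a
dialect flag). The class↔formula assignment follows the conventional
population-specific CI calibrations; it is exposed in
`qtl_compendium.CI_FORMULAS` so users can remap it. Formula-derived
intervals are symmetric about the peak. Records without R² are rejected
because the standardization needs it; missing LOD is tolerated.

## Consensus map and projection

Per-study maps are merged chromosome by chromosome. The map with the most
markers anchors the frame; every other map is rescaled onto it by the line
through its terminal shared markers, so maps sharing anchors at identical
positions rescale by the identity, and a marker's consensus position is
the arithmetic mean of its rescaled positions. Marker-order conflicts are
resolved by majority: the conflicted marker is dropped from the smaller
map, with a warning. This deterministic rescaled-mean merge replaces
linear-programming map merging; the deviation is in mechanism, not in the
projection contract (consistent marker order, positions comparable across
studies). A map sharing fewer than two markers with the frame on some
chromosome contributes nothing there.

QTLs are projected through the linear transform defined by the nearest
shared markers bracketing the peak; the CI bounds go through the same
segment transform. Peaks up to 5 cM (configurable
`extrapolation_limit`) outside the shared span use the edge segment's
slope; beyond that the QTL is excluded with a warning, because silent
long-range extrapolation would corrupt the mixture input. The projected
interval yields the positional standard deviation s = width/3.92, the
two-sided Gaussian 95% convention. Genetic coordinates are
chromosome-local cM with the origin at the first marker.

## Meta-QTL mixture model

Projected peaks on one chromosome are modelled as draws from a K-component
Gaussian mixture with **known per-observation variances**:

    lnL = Σ_i ln Σ_k π_k φ(x_i; μ_k, s_i²)

Only the K means and K−1 free proportions are estimated (p = 2K−1). The
EM updates are closed-form: responsibilities r_ik ∝ π_k φ(x_i; μ_k, s_i²),
then μ_k as the r-weighted inverse-variance mean and π_k as the mean
responsibility. Defaults: 20 quantile-spread initializations (jittered
after the first), tolerance 1e−8 on the log-likelihood, at most 2000
iterations, responsibilities floored at 1e−300 against underflow. The EM
log-likelihood trajectory is retained on the fit and is non-decreasing;
for K = 1 the fixed point is the closed-form inverse-variance-weighted
mean. Log-densities and log-sum-exp are computed inline for speed; they
are the standard stable formulas.

Candidate K ranges follow the panel size: chromosomes with ≤ 10 QTLs
search K = 1..min(4, n) (the small-sample regime), larger ones
K = 1..min(⌈n/2⌉, 12). K is selected by the three-of-five rule over AIC,
AICc, AIC3, BIC and AWE (D = −2 lnL, p = 2K−1, n observations):

    AIC  = D + 2p                     AICc = AIC + 2p(p+1)/(n−p−1)
    AIC3 = D + 3p                     BIC  = D + p ln n
    AWE  = −2 lnL_c + 2p(3/2 + ln n), lnL_c = lnL + Σ r_ik ln r_ik (0·ln 0 = 0)

AICc is reported as +∞ (with a warning) when n ≤ p+1. Each criterion
votes for its argmin (smallest K on exact ties); a K with ≥ 3 votes wins,
otherwise the K with the most votes, with remaining ties resolved toward
the smallest K — parsimony is the deliberate bias.

A QTL joins component k only if r_ik > 0.60 strictly **and** its peak lies
inside the component's 95% interval. The interval comes from the
responsibility-weighted precision combination of the provisional members
(peak = Σ r x/s² / Σ r/s², var = 1/Σ r/s², CI = peak ± 1.96 sd), computed
once; members failing the peak-in-interval check move to the unassigned
list and the summary is recomputed from the survivors. Requiring both
rules is the stricter of the two plausible readings of the method, and
with many precise members the combined interval is narrow, so a
substantial share of QTLs can legitimately end up unassigned; they are
always reported, never dropped. MQTLs are named `MQTL<chr>.<rank>` by
position. The QTL-overview index integrates each QTL's Normal(x_i, s_i²)
positional mass over 0.5 cM bins and averages over QTLs, so total index
mass per chromosome is at most 1.

## GWAS validation

Marker physical coordinates are an input table (1-based, inclusive). An
MQTL is anchored on a flanking marker of its highest-membership member
QTL — the marker nearest the MQTL peak on the consensus map when genetic
positions are available — and windowed at anchor ± 0.5 Mb, clipped at
chromosome ends. Unanchorable MQTLs are excluded from validation with a
warning. A marker–trait association supports a window iff it is on the
same chromosome, inside the window (boundaries inclusive) and has
−log10(p) ≥ 5.0 (inclusive, matching the printed "≥"). The production
implementation uses per-chromosome sorted-position search and is tested
for exact equality against the brute-force double loop.

## Candidate-gene funnel

DEGs are |log2FC| ≥ 1 (inclusive) and FDR < 0.05 (strict), unioned over
contrasts; DE statistics are inputs — the package fits no DE model.
Gene–window overlap uses the any-overlap rule by default (≥ 1 bp;
`containment: full` available). Expression profiles are replicate-averaged
FPKM per genotype and timepoint; the two genotypes' profiles are
concatenated, standardized per gene to zero mean and unit variance
(zero-variance genes are excluded), and clustered by fuzzy c-means
(Bezdek updates, c = 9, fuzzifier m = 2, tolerance 1e−5 on memberships,
best of 5 k-means++-seeded starts by objective; a point coincident with a
center takes full membership in the first such center, which keeps
duplicated profiles together in degenerate noiseless data). Nine clusters
reflect the natural 3 × 3 structure of rising/falling/flat trends per
genotype. The signature cluster maximizes (mutant slope − wildtype slope)
with the mutant slope positive and the wildtype slope negative, slopes
being least-squares trends of the cluster-mean standardized profile over
days 0/3/6; genes belong to a cluster by maximum membership ≥ 0.5.

Promoters run from 2000 bp upstream of the ATG to the TSS, shrinking to
1500 bp upstream when the 5′UTR exceeds 100 bp so long UTRs do not dilute
the element scan; minus-strand genes are reverse-complemented and
out-of-sequence spans are clipped with a warning. Cis-regulatory elements
are matched as exact IUPAC-degenerate consensi on both strands
(reverse-strand hits reported at their plus-strand offset); N in the
sequence never matches. The shipped catalog (ABRE = ACGTG,
DRE core = RCCGAC, MBS = CAACTG, MYC = CANNTG, ARE = AAACCA,
W-box = TTGACC, as-1 = TGACG, G-box = CACGTG) follows standard plant CRE
compilations and is an editable data table, not hard-coded; only the
G-box core is fixed by the source material, the others are the package's
choices. Element enrichment is reported as presence counts plus a
one-sided binomial test against composition-preserving shuffled promoters
— a pragmatic screen, not a canonical test. A gene becomes a candidate
(DECG) iff it sits in the signature cluster and its promoter carries at
least one ABRE hit; the evidence trail (hosting MQTLs, contrasts, cluster,
hits) is attached.

## Synthetic data

The generator emulates the inputs' statistical structure at desk scale:

- **QTL panel.** Default 3 chromosomes of 120 cM with planted loci at
  20/60/100 cM (minimum separation 10 cM, enforced), 8 studies, 5–10 QTLs
  per locus, population mix F2 0.3 / BC 0.2 / RIL 0.4 / DH 0.1. Each QTL
  draws R² ∈ [0.05, 0.30] and a target positional sd in [0.5, 2] cM; N is
  back-solved from the class CI formula so the formula-derived interval
  implies that sd, and the peak is drawn Normal(locus, sd²). Study maps
  share a 2 cM marker grid jittered by 0.2 cM per study (order
  preserved); peaks, intervals and flanking markers are expressed in the
  study frame.
- **Physical coupling.** A fixed 250 kb/cM scale links genetic and
  physical coordinates, so windows and genes co-locate predictably;
  marker anchors derive from the same scale.
- **GWAS panels.** Seven panels; significant SNPs (−log10 p ∈ [5, 10])
  are planted within ±100 kb of a configurable fraction (default 0.3) of
  the true loci; background SNPs are sub-threshold.
- **Genome and expression.** Random-sequence chromosomes carry planted
  candidate genes (in-window, DEG, signature profile, ABRE planted in the
  promoter) and four decoy classes each violating exactly one funnel
  condition: in-window non-DEG; out-of-window DEG with signature and
  ABRE; in-window signature DEG with the promoter scrubbed of ABRE on
  both strands; in-window DEG with ABRE but a falling-mutant profile.
  Filler genes populate the remaining temporal archetypes (3 mutant × 3
  wildtype trends, slopes ±0.5 FPKM/day around a base of 4 FPKM, Gaussian
  replicate noise, default sd 0.3, values clipped at 0). Every generated
  file parses through the package's own readers, generation is
  byte-deterministic under a fixed seed, and a `truth.json` records the
  planted structure.

What the generator does **not** emulate: real linkage-map error
structure (only small order-preserving jitter), linkage disequilibrium
around GWAS SNPs, realistic genome composition or gene density,
count-based expression noise (Gaussian on FPKM instead), or correlated
fold-change/profile noise. Passing tests therefore demonstrate that the
pipeline recovers structure it is designed to detect under its own model
assumptions — not that those assumptions hold for any particular real
compendium.

## Numerical choices and degenerate inputs

- Degenerate projection segments (zero source length) map to the left
  marker; a collapsed projected interval receives a nominal 1e−6 cM sd
  rather than zero.
- Empty chromosomes produce empty results, not errors; a single QTL forces
  K = 1 and becomes its own MQTL.
- Fuzzy c-means guards empty clusters (mass captured by a coincident twin
  center) by freezing their center instead of dividing by zero.
- Exact criterion ties vote for the smallest K; exact distance ties in
  clustering resolve to the first zero-distance center.
- The acceptance scenarios in the test suite use one 120 cM chromosome
  with 60 QTLs for mixture recovery and the default 3-chromosome bundle
  for funnel recovery; these sizes keep the planted structure estimable
  while the suites stay quick to run.

## Known limitations

- The mixture assumes independent QTL observations; QTLs from the same
  study share a map and are not truly independent.
- The consensus merge is a rescaled mean, not a constrained optimization;
  with strongly inconsistent maps the majority-order rule can discard
  informative markers.
- The one-pass membership/interval check can leave many QTLs unassigned
  on dense chromosomes (see above); an iterative reassignment scheme is a
  possible extension.
- CRE "enrichment" against shuffled promoters ignores dinucleotide
  composition and positional bias.
- Validation counts SNP co-localization only; it does not model linkage
  disequilibrium decay around the association peak.
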