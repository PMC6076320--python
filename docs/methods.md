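# Methods

This note documents the models, conventions and numerical choices behind
nivimyx, and what the synthetic-data generator does and does not emulate.

## Pairwise identity

The package never trims or re-aligns barcodes globally; every similarity is
a pairwise global alignment with free terminal gaps under match +1,
mismatch 0, internal gap −1 per column. Identity = matches / aligned
columns, where aligned columns exclude the terminal overhangs and internal
gap columns count as non-matches — the convention of common greedy
clustering tools. Because several alignments can share the optimal score,
the reported pair is made well-defined (and symmetric in argument order) by
maximising the triple (score, matches, −columns) lexicographically; this is
computed by propagating the triple through the DP, so no traceback or
tie-break rule is needed. IUPAC ambiguity codes never count as matches,
even against themselves — conservative, and rare in Sanger barcodes. For
substitution-only pairs of equal length the definition reduces exactly to
1 − hamming/L. The kernel is a numba nested loop (O(L²), ~0.2 ms at
L = 350); results are memoised per sequence pair. An optional minimum-length
filter (default 250 bp) is available but off by default.

## Greedy centroid clustering

Deduplicated ribotypes are processed in decreasing abundance (ties by
lexicographic first-member id, enforced as a precondition) and each joins
the *first* centroid at identity ≥ threshold (default 0.991) rather than the
best one — the classic greedy-clustering rule, which makes the outcome a
deterministic function of the input order. Cluster labels are the
abundance-weighted majority morphospecies; minority members are reported as
conflicts but never deleted, since exclusion is a curation decision.
Suffixes -a, -b, … order a split morphospecies' clusters by decreasing
abundance.

## Tiered annotation and the bootstrap confidence

Species-rank assignment requires best identity ≥ 0.98 (inclusive) *and*
confidence > 0.90 (exclusive); identity in [0.95, 0.98) — or a failed
confidence at higher identity — yields a genus-rank call from the best
match; below 0.95 the OTU is unassigned but its best hit is retained. The
confidence score is a k-mer bootstrap: with k = 8 and 100 replicates, each
replicate resamples ⌈n_kmers/k⌉ of the query's k-mers with replacement and
re-scores every reference species by shared-k-mer count (species k-mer sets
are unions over their references; ties go to the lexicographically smaller
name); the score is the fraction of replicates whose winner equals the
full-data winner. This is a self-contained confidence measure with the
same contract as classifier bootstrap supports (a fraction in [0, 1]
thresholded at 0.90); near-threshold calls on real data will depend on the
chosen k and replicate count.

## Richness, coverage, accumulation

Chao1 is bias-corrected by default, S_obs + f₁(f₁−1)/(2(f₂+1)), which stays
finite at f₂ = 0; the classic f₁²/(2f₂) form is an option. The analytic
variance follows the standard formulation for each form and the 95% CI is
log-normal on the estimated excess T = Ŝ − S_obs. Sample coverage is the
abundance-based estimator 1 − (f₁/n)·(n−1)f₁/((n−1)f₁+2f₂). Because field
reports sometimes quote "coverage" as the observed/asymptotic richness
ratio, that ratio is computed as a secondary quantity alongside.
Accumulation curves interpolate with the exact hypergeometric expectation
E[S(m)] = S_obs − Σᵢ C(n−xᵢ, m)/C(n, m) (log-gamma arithmetic) and
extrapolate with S(n+m*) = S_obs + f̂₀[1 − (1 − f₁/(nf̂₀+f₁))^{m*}], where
f̂₀ is the Chao1 excess; the two branches agree exactly at m = n. The
default grid runs 1..2n (doubling rule); larger sizes are computed with a
logged warning. Confidence bands are a seeded multinomial bootstrap of the
abundance vector (default 1,000 replicates); the band is clipped to contain
the point estimate, which matters only in degenerate small-n corners.

## Elevational analysis

Belts are half-open 100 m intervals over 1,100–1,900 m; out-of-range
records are clamped into the first/last belt so no record is lost. The
belt-range convention follows the wider of the two descriptions in
circulation for such transects (eight belts from 1,100 m). Weighted mean
elevations use belt midpoints and raw (untransformed) abundances; the
square-root transform exists for display scaling only. The fruit-vs-soil
shift is tested across shared taxa with a two-sided paired t-test (the
headline p) plus a seeded sign-flip permutation test (10,000 flips, +1
smoothing) as a distribution-free alternative. Soil abundance uses raw
reads by default — read depth is treated as uninformative about elevation —
with a relative-abundance option available by normalising the observation
table before profiling. Pearson correlations (effort vs richness,
suitable days vs elevation) are plain product-moment r with two-sided
t-distribution p and no multiple-testing correction; zero-variance inputs
return an absent result rather than NaN.

## Winter suitability classification

Days are calendar days in the logger's local time over raw 30-min readings.
A day with fewer than 24 readings is `insufficient_data` and excluded from
all substantive counts. A day is `unsuitable` when max < −0.5 °C, `suitable`
when mean ∈ [−0.5, 2] °C and (max − min) < 3.0 °C strictly — a day at
exactly 3.0 °C fluctuation is `neither`, so the boundary choice is
auditable. Suitable and unsuitable are provably disjoint (a suitable mean
≥ −0.5 forces max ≥ −0.5) and this is asserted on every aggregation.
Winters run Oct 1–Jun 30 (configurable) and are labelled "YY/YY". Snow-cover
days: the ultrasonic sensor reads the vegetation during the snow-free
season, so the baseline is the July–September daily-median when summer
months exist, else the 10th percentile of daily medians; a day is covered
when its median exceeds baseline + 10 cm (the threshold is a package
default — no numeric definition of a snow-cover day is standard), and runs
may bridge short gaps without counting the bridged days.

## The synthetic generator

The generator emulates the *structure* of a snowbank-myxomycete study, not
its sequences. Study-scale defaults: 28 morphospecies in 7 genera (plus 2
soil-only, non-nivicolous species), 45 ribotype clusters carrying 70
ribotypes, 533 specimens over four survey years weighted (199, 194, 327,
12), 39 soil samples over 16 sites (8 belts × open/closed canopy) with
5,623–55,791 reads each, and one logged winter at 30-min cadence.

Sequences are built over disjoint mutated position blocks from a common
350 bp root: each cluster gets ⌈0.03·L/2⌉ = 6 private substitutions, each
extra ribotype one more. Planted identities are therefore exact by
arithmetic — intra-cluster ≥ 0.9943, inter-cluster ≤ 0.9657 — bracketing
the 0.991 threshold, which is what makes exact partition recovery a fair
test. Cluster/ribotype totals are fixed by rounding the configured means,
so the position budget cannot overflow for any seed. Soil overlap is
planted per cluster: *exact* clusters contribute all members verbatim,
*near* clusters a single 1-substitution variant of their ancestor
(identity to every member in [0.991, 1)), *unmatched* clusters nothing;
category probabilities default to 34/70, 19/70, 17/70. Genus-level OTUs
(9 substitutions from a reference, identity ≈ 0.974) and unknown OTUs
(≥ 18 substitutions from everything, identity < 0.95) are verified by
hamming distance after construction and resampled if a constraint fails.

Read counts: per-sample totals are uniform over the configured range; a
fraction θ (default 0.406) of each sample's reads goes to
species-tier-capable OTUs, the rest to genus/unknown OTUs, with lognormal
(σ = 1.2) per-OTU weights shaded by a Gaussian occupancy kernel around each
taxon's elevational optimum and a geometric genus-dominance factor (0.45
per genus rank, giving the two leading genera ~80% of specimens in
expectation). Fruit optima are N(1570, 90) m; soil optima are shifted by
−130 m (± 40 m per taxon). Unknown-OTU presence declines linearly with
elevation, planting the richness–elevation trend. Because per-sample totals
are fixed, read counts are compositional: with a wide occupancy kernel the
per-taxon read profiles are dominated by renormalisation noise, so the
planted shift is recovered cleanly with a kernel sd of ~120 m and washed
out above ~250 m — the shift-recovery fixture uses the sharper kernel, and
this sensitivity is a finding about compositional read data, not a bug.

Winter weather: air temperature is a seasonal Gaussian cold dip plus AR(1)
noise (φ = 0.98 per 30-min step, stationary sd 2.5 °C) and a damped diurnal
cycle; a site's snow cover runs from an elevation-dependent onset to an
elevation-dependent melt (earlier onset, later melt higher up), with an
optional snow-free gap at low elevations. Snow-covered soil sits at
N(0.5, 0.15) °C; snow-free soil is coupled air temperature (coefficient
0.5) and can freeze. Ground-truth day classes are *defined* by applying the
suitability rule to the generated readings, so truth and classifier are
self-consistent; what the thermal tests then verify is the aggregation and
bookkeeping (day grouping, windows, counts), plus planted constructions
(a 7-day snow-free frost spell must yield exactly 7 unsuitable days).

What the generator does not emulate: PCR chimeras, primer bias, Illumina
error profiles, length variation (substitution-only by default), spatial
autocorrelation between neighbouring sites, or amoebal population dynamics.
Green tests therefore show that the estimators and rules recover planted
structure under idealised noise, not that they are robust to artefacts of
real amplicon data.

## Problem sizes

The default test and acceptance runs use the study-scale defaults above
(~70-ribotype pool, ~130 soil OTUs, 39 samples, 16 winter logger series of
~13,000 readings each) and complete in well under a minute; accumulation
curves use 200 bootstrap replicates in the pipeline report and 1,000 by
default in the library.
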