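# nivimyx

Tools for comparing two inventories of nivicolous ("snowbank") myxomycetes:
macroscopic **fruit bodies** collected and barcoded along a mountain
transect, and the invisible **soil amoebal stage** detected by 18S rDNA
metabarcoding of soil. The package asks the questions such surveys ask —
do the fruit bodies reflect the amoebae in the soil, where on the
elevational gradient does each life stage live, and which winter soil
temperatures permit amoebal growth — and ships a synthetic-data generator
with planted ground truth so the whole pipeline is testable without any
field data.

## What it computes

- **Ribotypes and clusters.** Partial-SSU barcodes (~350 bp) are collapsed
  to unique ribotypes and clustered by greedy centroid clustering: scanning
  in decreasing abundance, a ribotype joins the first centroid with pairwise
  identity ≥ *t* (default *t* = 0.991, the threshold used for OTU picking
  in snowbank-myxomycete metabarcoding), otherwise it founds a new cluster.
  Identity is matches / aligned columns of an optimal free-end-gap global
  alignment (terminal gaps excluded, internal gaps count as mismatches).
  Clusters are labelled `<morphospecies>-a`, `-b`, … when a morphospecies
  splits into several putative biospecies.
- **Tiered annotation.** A soil OTU is assigned to a reference
  *morphospecies* when best identity ≥ 98.0% and a k-mer bootstrap
  confidence > 90%; to the best match's *genus* when identity ∈ [95%, 98%);
  otherwise it stays unassigned (its best hit is still reported).
- **Cross-inventory matching.** Each fruit ribotype is *exact* (identity
  1.0 to a soil OTU), *near* (≥ 99.1% but < 1.0) or *unmatched* (< 99.1%),
  with summary statistics for the unmatched tail and per-site
  shared/unique counts correlated with collection effort.
- **Richness and coverage.** Bias-corrected Chao1,
  S<sub>Chao1</sub> = S<sub>obs</sub> + f₁(f₁−1)/(2(f₂+1)), sample coverage
  Ĉ = 1 − (f₁/n)·(n−1)f₁/((n−1)f₁+2f₂), and individual-based
  rarefaction/extrapolation E[S(m)] with bootstrap confidence bands,
  extrapolated to double the collection size.
- **Elevational profiles.** Records binned into eight 100 m belts
  (1,100–1,900 m, out-of-range records clamped), per-taxon profiles scaled
  to the taxon maximum, and a paired test (t and sign-flip permutation) for
  the shift in abundance-weighted mean elevation between inventories.
- **Winter suitability.** From 30-min soil-temperature loggers, a day is
  *suitable* for amoebal growth when its mean is in [−0.5, 2] °C with
  diurnal fluctuation < 3 °C (insulating snowpack), *unsuitable* when the
  temperature never rises above −0.5 °C (soil frost); per-winter counts,
  their correlation with elevation, and snow-cover-day estimation from an
  ultrasonic height sensor.

## Worked example

Everything below is computed on a synthetic bundle whose defaults mirror a
four-year alpine survey (533 specimens, 39 soil samples of 5,623–55,791
reads, a 1,100–1,900 m transect, one logged winter):

```python
from nivimyx.pipeline import run_synthetic
from nivimyx.simulate import SimulationConfig

rep = run_synthetic(SimulationConfig(seed=1))
```

prints, when summarised:

```text
533 specimens -> 48 unique ribotypes -> 33 clusters at 99.1%
match partition: 19 exact / 11 near / 18 unmatched
annotated read fraction: 40.6%
mean elevation: fruit 1552 m -> soil 1446 m (shift -106 m, paired-t p = 1.8e-03)
suitable days vs elevation: Pearson r = 0.99
```

Read: about half the soil-detectable ribotype clusters were also planted
verbatim into the soil table and are recovered as exact matches; 40.6% of
soil reads are annotatable to a reference morphospecies (the planted
fraction); the soil amoebae sit ~100 m lower on the transect than the
fruit bodies (the generator plants a −130 m shift; a single bundle
recovers it with sampling noise); and sites higher on the transect — with
longer-lasting snow cover — offer more days suitable for amoebal growth.

The same pipeline is exposed as a CLI (`nivimyx simulate | dedup | cluster |
annotate | match | diversity | elevation | thermal | all`), e.g.

```sh
nivimyx all --seed 1 --out run/
```

which writes the fixture bundle, all stage reports (TSV/JSON) and a
manifest of the thresholds used into `run/`.

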