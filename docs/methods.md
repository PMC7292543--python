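# Methods

This note documents the models behind `fnlqtl`, the default parameters and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot tell you about real data.

## The simulated cross

The generator emulates a biparental cucumber F2 between a long-necked
parent (P alleles) and a short-necked parent (M alleles).

**Genome and recombination.** By default one 20-Mb chromosome carries 2000
evenly spaced markers at a uniform map density of 5 cM/Mb (≈100 cM, a
cucumber-like chromosome). Gametes are simulated under the Haldane model:
crossover counts are Poisson with no interference, so the recombination
fraction over `d` cM is `r = (1 − e^(−2d/100))/2`. Kosambi distances are
used only when *estimating* a map from genotypes, mirroring common
practice (maps are reported in Kosambi cM while simulators and HMMs assume
no interference). Genotypes are coded `PP`/`PM`/`MM` (`NN` missing), P
being the long-neck parent's allele; coordinates are 1-based and intervals
closed on both ends.

**Trait model.** A single major QTL with genotype class means
`mu_pp = 7.5`, `mu_pm = 4.6`, `mu_mm = 2.2` cm — the parental and F1 neck
lengths of the cross this package emulates — giving additive effect
`a = 2.65` cm and dominance `d = −0.25` cm. The residual SD defaults to
`sigma_e = 2.87` cm so the QTL explains ≈30% of single-plant F2 variance
(`Vg = a²/2 + d²/4 = 3.53`; `R² = Vg/(Vg + σ²) = 0.30`), the middle of the
27.9–32.7% band this design is meant to reproduce. Phenotypes are class
mean + Normal noise; the QTL genotype is read at the marker nearest the
configured position. No polygenic background or epistasis is simulated.

**Variance decomposition for F2:3 families.** Family means of ≥10 plants
would explain far more variance than single plants if the whole 2.87-cm
residual were within-family: averaging would shrink it by √m. Field
trials do not behave that way — a large share of the residual is
plot-level environment that all plants of a family share. The generator
therefore decomposes the single-plant residual into a family-shared
component `sigma_family = 2.7` cm and a within-family component
(`√(2.87² − 2.7²) ≈ 0.97` cm is the complementary value). With
`sigma_e = 2.87` per plant plus `sigma_family = 2.7` per family,
102-family mean phenotypes give scan R² ≈ 0.30 and peak LOD ≈ 5–9, the
band observed for this design on real multi-environment trials. The
fine-mapping progeny tests, whose 15–20 plants are grown together, use
only the within-family component (0.97 cm), which is what makes all-long /
all-short / segregating classification reliable.

**Bulks and read counts.** The long/short bulks take the 50 plants beyond
7.5 cm and below 2.5 cm respectively; when more plants qualify than fit,
the most extreme are taken, and when fewer qualify the bulk falls back to
rank-based extremes (the rule that fired is recorded — published designs
rarely state which was used). Read counts per site are Poisson depths
(means 61× and 52× for the long and short pools) with binomial allele
draws around the bulk's true P-allele frequency and a per-read allele-flip
error of 0.005 (a post-quality-filter Illumina-like rate; no rate is
standard, so this is a fixed package default).

**Accession panel.** Four founder haplotypes over 32 binary promoter
variants (25 SNP-like + 7 InDel-like), group sizes 62/71/21/4 with
geographies East Asia / Eurasia / India / India (wild and semi-wild),
within-group call-flip rate 0.02 and group FNL means 6.5/2.5/4.5/4.5 cm
(SD 1.5) so that long necks sort with the East Asian group and short necks
with the Eurasian group, as in the panel this emulates.

**qPCR.** The reference gene has constant expected Ct; the target's
expected Ct is `base − log2(fold)`; three technical replicates with
Normal(0, 0.1) cycle noise by default.

All operations draw from per-operation substreams derived from the master
seed, so any stage can be regenerated without replaying the others and
every result is bit-reproducible for a fixed (config, seed).

## QTL-seq statistics

**SNP-index convention.** Both bulk indices are the P-allele read
fraction; Δ is their difference. Some methods write-ups score the short
bulk by its M-allele fraction instead; that variant drives Δ toward 0 at a
true QTL and contradicts the stated ±1/0 limiting cases, so it is provided
only behind `convention="literal"`, never as the default.

**Smoothing.** Loess is a tricube-weighted local linear regression
(statsmodels lowess) with span 0.1 of each chromosome's sites, evaluated
on a 10-kb grid by interpolation and clamped to [−1, 1]; a sliding-window
mean (1-Mb window) is available as the simpler alternative. The 10-site
minimum per chromosome can be lowered via `min_sites` for deliberately
tiny inputs. Missing indices (zero-depth bulks) are excluded, not imputed.

**Null envelope.** Published scans often quote a fixed Δ threshold; such a
constant is not derivable from the design parameters alone, so the default
here is a simulated envelope: each bulk is a fresh draw of 50 F2 genotypes
from 1:2:1 at an unlinked locus (so the pooled P-allele count is
Binomial(2n, ½)), followed by binomial read sampling at the site's depths;
the bounds are empirical 0.5%/99.5% quantiles from 10 000 replicates.
Depths are binned to the nearest 5 and cached per (Ln, Sn) depth pair, and
an isotonic pass over total depth enforces that the envelope never widens
with depth (finite-simulation quantiles are only stochastically
monotone). A scalar-threshold mode remains for reproduction-style runs.

**Region calls.** Maximal runs of grid points above the upper (or below
the lower, reported with sign) bound; runs separated by at most
`merge_gap_bp` merge, runs shorter than `min_span_bp` drop, and region
summaries (mean bulk indices, site count) come from the underlying per-site
records. BED output is converted to 0-based half-open coordinates on
write.

## Linkage mapping

Marker order is fixed by physical position (de novo grouping/ordering is
out of scope). Adjacent recombination fractions come from an EM maximum
likelihood over the nine two-locus F2 genotype classes — only the double
heterozygote is phase-ambiguous, contributing an expected
`2r²/((1−r)² + r²)` recombinant gametes in the E-step — iterated to
|Δr| < 1e-6 (cap 200 iterations) and capped at 0.4999 before Kosambi
conversion.

The scan is Haley–Knott: QTL genotype probabilities conditional on the
nearest informative flanking markers use Kosambi-consistent recombination
fractions combined without interference
(`r12 = r1 + r2 − 2·r1·r2`); individuals missing a flank fall back to
one-sided conditioning, and to the 1:2:1 prior if no informative marker
exists on the chromosome. Phenotype is regressed on the expected additive
(`P(PP) − P(MM)`) and dominance (`P(PM)`) predictors. "Composite" interval
mapping is realised as optional marker cofactors (additive + dominance
columns, dropped within 10 cM of the scan position); the default is plain
interval mapping since cofactor choices are rarely published. LOD is
capped at 50 for zero-residual fits and peak ties break leftmost. The
per-QTL explained variance is reported as `R² = 1 − 10^(−2·LOD/n)`, the
standard single-QTL conversion, since no other definition is universal. A
permutation threshold routine (phenotype shuffling against per-position QR
bases) supplies genome-wide significance when wanted.

## Fine mapping

A crossover between adjacent markers makes the genotype inside that gap
ambiguous, so a gap segment is compatible with a recombinant's implied
causal genotype whenever either flanking marker is — which is exactly why
delimited intervals are quoted as "defined by" their two bounding markers.
The candidate interval is the intersection of all per-recombinant
constraints over the alternating marker/gap segments; recombinants whose
class contradicts their entire haplotype are reported as conflicts and
excluded rather than aborting the analysis (real screens contain
phenotyping errors), while a mutually exclusive constraint set raises an
error carrying a minimal conflicting subset. Progeny-test cuts default to
halfway between the midparent and each parental mean (6.175 / 3.525 cm
with the default trait), `segregating` requires ≥2 plants in each tail,
and families under 15 plants score `unknown`; all of this is configurable
because published screens rarely state their rule.

## Phylogeography

Distance is the allele-mismatch fraction over variants non-missing in both
accessions (p-distance with pairwise deletion), treating SNP and InDel
states identically as binary characters — the MEGA-comparable default when
no substitution model is justified. Neighbour joining follows Saitou–Nei
with the Studier–Keppler Q-criterion; for bit-reproducibility, Q ties
break at the smallest (row, column) pair and negative branch lengths clamp
to zero with the deficit shifted to the sister edge. Bootstrap resamples
variant columns with replacement and scores each internal bipartition of
the reference tree (1000 replicates by default). Because binary p-distances
are heavily tied, weakly supported parts of the topology can depend on
input order; the supported structure does not. Panel groups are produced
by cutting the k−1 longest internal edges (k = 4 by default) — a stand-in
for reading groups off a published figure. Long/short classification uses
the panel-mean threshold with a strict `>` for long.

## Expression

Technical replicates are averaged on the Ct scale (Livak convention), the
amplification efficiency is fixed at 2 (no standard-curve correction), and
replicate SDs propagate to ΔCt as `√(sd_t² + sd_r²)`. The calibrator's
fold change is exactly 1 by construction.

## Problem sizes used by the test suite

The acceptance tests run the full study design — 1231 F2 × 2000 markers
with 50/50 bulks at 61×/52× over 20 seeded replicates for the bulk-scan
power check, 102 families × 10 plants × 30 markers over 20 replicates for
the interval-mapping check, and 2000-replicate null envelopes — sizes
chosen so the whole suite completes in about a minute while keeping every
Monte-Carlo comparison inside its stated tolerance. The pipeline defaults
mirror the study design (10 000 envelope replicates, 1000 bootstrap
replicates).

## Limitations

* No sequence-level read simulation (no FASTQ, no mapping artefacts); read
  counts are ideal Poisson/binomial draws, so real-data depth
  overdispersion and allele-specific mapping bias are not represented.
* Single-QTL trait model only: no polygenic background, no epistasis, no
  genotype × environment interaction beyond the shared family effect.
* One phenotyping error model (Gaussian); heavy-tailed measurement error
  would loosen the progeny-test classification guarantees.
* The NJ group extraction by longest-edge cutting assumes groups are
  separated by long internal edges; admixed panels violate this.
* Passing tests demonstrate correctness of the statistics and calibration
  of the simulation — not that a particular real dataset meets the
  generator's assumptions.
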