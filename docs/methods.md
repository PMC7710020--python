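# Methods

`pioneerbind` asks how transcription factors that recognize similar DNA
motifs nonetheless bind different genomic sites, and quantifies one
mechanism: differential ability to engage chromatin that was
inaccessible before the factor was expressed ("pioneer-like" binding).
The package implements the full analysis chain — differential ChIP-seq
binding classification, prior-accessibility quantification, motif
scanning with empirically calibrated thresholds, and gene-set
association — and a synthetic-data generator with known ground truth on
which every step can be validated end to end.

## Binding-event calling

Reads are reduced at load time to stranded 5' positions ("tags");
every downstream quantity is defined on tags. The caller scores 200-bp
windows (50-bp step) of pooled replicate tag counts against an
expectation that is the larger of (a) the input-control count in a
5-kb local window, scaled by the signal/control total ratio and the
window-size ratio, and (b) the genome-wide average rate. Window
p-values come from the Poisson upper tail; Benjamini–Hochberg is
applied across all tested windows, significant windows (q < 10⁻³) are
merged, and the summit is the maximum of the boxcar-smoothed (41 bp)
tag density, ties broken leftward. This is a deliberately simple
point-source caller: it preserves the downstream contract (events with
summits and q-values) without a generative read-distribution mixture
model, and that simplification is a known fidelity limit — it has no
multi-condition joint model and no artifact-region handling.

Per-TF event lists are restricted to the top 10,000 sites by
(q ascending, normalized signal descending) before cross-TF
comparison, to limit depth-driven bias between experiments.

## Differential binding and category labels

Events from different TFs whose summits lie within 100 bp are merged
into one site (midpoint summit; the merge radius is a package choice —
no published value exists). At each site, counts are taken in ±100 bp
per replicate. A common dispersion φ is estimated by a pooled
method-of-moments ratio on library-size-normalized counts,
φ̂ = Σ(v−m)/Σm² floored at 0 (var = m + φm² parameterization), with a
configurable fallback (default 0.05) when no condition has replicates.

Two TFs are compared with the exact negative-binomial conditional
test: pooled counts are rescaled to a common library size and the
conditional distribution of one condition's pooled count given the
pooled total is enumerated, with per-condition dispersion φ/n (pooling
n replicates). Two-sided p doubles the smaller tail, capped at 1 (a
min-likelihood variant is available). With φ = 0 and equal library
sizes this reduces exactly to the two-sided Binomial(t, ½) test. BH is
applied per TF-pair family over sites significant in at least one
member of the pair. Under a 10,000-site null with φ = 0.1 the measured
type-I error at p < 0.05 is 5.2–5.3%.

Category labels use the closed vocabulary A=B=C / X>Y,Z / X,Y>Z:
shared requires significant binding (q < 10⁻³) in all TFs and no
differentially bound pair (q > 10⁻²); X>Y,Z requires a significant X
event and X significantly greater than both others with a larger
log-fold-change versus input (pseudocount 1 on per-million counts);
X,Y>Z additionally requires X≈Y. Every site gets exactly one label or
"unclassified/minor"; categories under 500 events (configurable) are
flagged as not retained.

## Accessibility

Accessible domains are contiguous runs of 50-bp bins whose pooled ATAC
tag count exceeds the Poisson upper tail (p < 10⁻³) of the
genome-average rate, merged across gaps ≤ 200 bp and filtered to
≥ 200 bp. These parameters are package defaults (the upstream domain
caller's settings are unpublished); they reproduce the binary
open/closed partition the overlap statistics need. Site-level
accessibility is tags per million in a 2-kb window around the summit,
normalized per replicate before averaging — the same convention as the
composite (metagene) profiles, which accumulate 100-bp-extended read
coverage at each offset in ±1 kb, scale by 10⁶/total and 1000/n_sites,
and then average replicates. Domain membership is judged by the summit
point (events are point sources); interval-overlap semantics would be
a one-line change and is deliberately not the default.

## Motif scanning and empirical FDR

Scanning uses log₂(p_motif/p_background) per column with background
mononucleotide frequencies, a 0.01 pseudocount per PWM cell, and
reverse-complement scoring of every window; windows containing N score
−∞. The score threshold is calibrated empirically: per-sequence
maximum scores are computed for a query set (sequences with a planted
consensus) and for null sequences drawn from an order-2 Markov model
of the genome (trained with pseudocount 1, N-containing windows
skipped), and the threshold is the smallest score s at which
null-rate(s)/query-rate(s) drops below the FDR target (default 0.1).
A one-sample variant (null quantile) is available behind a flag. For
short motifs (6–8 bp) this procedure necessarily lands near the
consensus score, because even the exact consensus of a 6-mer occurs in
a few percent of random 100-bp sequences — an intrinsic property of
empirical FDR control with short motifs, not an implementation
artifact. Peak-set enrichment compares the fraction of peaks with a
hit within ±50 bp of the summit against uniformly sampled genomic
windows (Fisher's exact test on the 2×2 table; the test choice is a
package decision).

## Gene sets and association

Gene sets are built from LFC / adjusted-p summary tables with fixed
rules (thresholds LFC > 2, padj < 0.01): shared-up requires
up-regulation versus baseline in every TF and no between-TF contrast
with |LFC| > 2 (the "not differentially expressed" condition is
implemented as |LFC| ≤ 2; the source convention is ambiguous and this
is the only self-consistent reading); TF-specific sets require the TF
significantly above both others pairwise; two-of-three sets require
both members above the third and ≈ between themselves. Peaks are
assigned to the gene with the nearest TSS (ties to the
lexicographically smaller id). Association is a logistic regression of
the per-gene bound indicator on set membership with a log₁₀(mappable
length) covariate — a linear length term rather than a smoothing
spline, the minimal version of length control — fit by IRLS to 10⁻⁸,
Wald-tested, BH-corrected across all category×set pairs. Perfect
separation is flagged and excluded from the p-value family.

## Profiles and reporting

Binding-profile PCA treats experiments (replicates) as observations
over the site union (per-TF top lists merged within 50 bp), on
log₂(count+1)-transformed, site-centered window counts; component
signs are fixed by making each component's largest-magnitude loading
positive. Heatmap matrices count 100-bp-extended reads per 100-bp bin
over ±500 bp, rows ordered by binding significance, color ceiling at
the 85th-percentile bin count (ordered-bin convention, lower order
statistic) with a fixed floor of 5 applied to the color scale only.

## The synthetic scenario

The default scenario plants five binding categories of 800 sites each,
plus 800 unbound control sites, on a 10-Mb four-chromosome i.i.d.
background genome (GC 42%), with three TFs: A binds a TAAT-core
anterior motif, B and C a TTTAT-core posterior motif, and all three a
bipartite cofactor+posterior motif. Pioneer indices π (occupancy
multiplier at inaccessible sites) are A 0.5, B 0.9, C 0.1. Categories:
shared (bipartite, accessible), A-specific (anterior, accessible),
B-specific (posterior, fully inaccessible — only the strong pioneer B
occupies it), A,B>C (bipartite, accessible, C occupancy ×0.05
emulating a missing cofactor), B,C>A (posterior, accessible). Expected
occupancy is λ = affinity × category multiplier × (1 or π), scaled to
100 expected tags per replicate at λ = 1.

ChIP replicates draw NB counts (var = m + φm², φ = 0.05) per site,
place each signal tag at the summit plus a Normal(0, 35 bp) offset,
and fill with uniform background to a fixed 4×10⁵-tag total so that
library totals — the normalization denominator — match across TFs.
The genome/depth combination keeps background density near 0.02
tags/bp, the regime in which point-source calling is meaningful; a
smaller genome at the same depth would bury signal under ~1 tag/bp of
background. ATAC libraries (2×10⁶ tags) draw from a rate field 10×
higher inside truth domains (built around accessible sites, 450–700 bp
half-width) than outside; post-induction libraries add per-site gain
mass opener_strength×λ (A/B/C = 30/80/30 expected tags) and are
sampled at the same fixed depth, so gains redistribute density as they
do in libraries sequenced to a set depth. Planted motif instances are
the consensus (strand-randomized): detection at planted sites is then
a property of the threshold calibration, not of instance sampling
noise.

What the generator does not emulate — and what passing tests therefore
do not establish about real data: GC/mappability bias, artifact
regions, fragment-size structure and Tn5 sequence bias, PCR
duplicates, graded (rather than binary) accessibility, correlated
replicate noise, and motif-affinity-dependent occupancy. The generator
validates the statistical machinery, not platform noise models.

## Numerical choices and degenerate inputs

Quantiles use linear interpolation between order statistics; the
heatmap percentile uses the ordered-bin lower-order-statistic
convention. Summit ties break leftward; nearest-TSS ties break to the
smaller gene id; rank ties break by (q, signal, coordinate). Zero-tag
libraries yield empty event/domain lists, not errors; a zero-length
interval, constant PCA matrix, or unvaried bound indicator raises.
All stochastic components take explicit seeds and the pipeline writes
byte-identical outputs on rerun with the same config and seed.

## Known limitations

The caller's Poisson window test ignores replicate overdispersion at
the calling stage (it enters at the differential stage); dispersion is
common rather than tagwise; normalization is total-count ratio (no
trimmed-mean factors); the length covariate is linear; composite
profiles count both mates of a pair as independent tags. Each of these
is the simplest contract-faithful choice and is isolated behind the
corresponding module boundary.
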