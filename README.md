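# pioneerbind

Transcription factors (TFs) with nearly identical DNA-binding domains
— homeodomain paralogs are the canonical case — can occupy very
different genomic site sets in the same cells. One resolving mechanism
is chromatin: factors differ in their ability to bind motifs lying in
chromatin that was inaccessible before they were expressed.
`pioneerbind` is a toolkit for quantifying that mechanism from
ChIP-seq and ATAC-seq tag data: it classifies sites by which TFs bind
them equivalently versus preferentially, measures the prior
accessibility of each class, calibrates motif-scanning thresholds
empirically, and tests whether binding classes predict
differential-expression gene sets. A first-class synthetic-data
generator produces genomes, binding landscapes and tag libraries with
known ground truth, so the entire pipeline is validated end to end.

It is written for computational biologists analyzing induced-TF
ChIP/ATAC experiments, and for methods work that needs a
ground-truth-calibrated differential-binding stack.

## The statistics at the core

* **Binding events**: 200-bp sliding windows of pooled replicate 5'
  tag counts are tested against max(scaled local input control,
  genome-average rate) with a Poisson upper tail; BH across windows,
  merge, summit at maximum smoothed tag density. Events with
  q < 10⁻³ are kept; analyses use the top 10,000 per TF.
* **Differential binding**: the exact negative-binomial conditional
  test. With pooled counts (y_A, y_B) rescaled to a common library
  size and common dispersion φ (var = m + φm², method-of-moments), the
  two-sided p-value enumerates P(Y_A = k | Y_A + Y_B = t) with
  per-condition dispersion φ/n and doubles the smaller tail. Sites are
  labeled A=B=C, X>Y,Z, or X,Y>Z from binding significance
  (q < 10⁻³), pairwise differential significance (q < 10⁻²), and
  log-fold-change vs input; categories under 500 events are not
  retained.
* **Accessibility**: domains are Poisson-significant 50-bp bin runs
  (merged ≤ 200 bp, ≥ 200 bp long); site accessibility is tags per
  million in ±1 kb, per-replicate normalized then averaged; composite
  profiles are tags per million per 1000 sites at each offset.
* **Motifs**: log₂ likelihood-ratio PWM scanning on both strands; the
  hit threshold is the smallest score at which the null hit rate
  (order-2 Markov sequences) is ≤ 0.1 of the query hit rate;
  enrichment vs 10,000 random genomic windows by Fisher's exact test.
* **Gene-set association**: peaks map to the nearest TSS; logistic
  regression P(bound) ~ set membership + log₁₀(gene length), Wald
  test, BH across all category×set pairs.

## Worked example

Run the built-in scenario — three TFs sharing motifs, one of them
(B, π = 0.9) a strong pioneer, one (C, π = 0.1) accessibility-bound —
end to end:

```bash
pioneerbind run-all --seed 1 --outdir runs/demo
```

which prints (abridged):

```json
{
  "n_sites": 4800,
  "n_classified": 4000,
  "category_recovery": 0.99525,
  "dispersion": 0.04678
}
```

meaning: of 4,800 planted sites (4,000 bound + 800 unbound controls),
the classified site union recovers the planted multi-way label at
99.5% of planted sites, with an estimated common dispersion of 0.047
(truth: 0.05). The output directory contains the event tables,
category assignments, called domains, per-category prior-accessibility
summaries (`prior_density.tsv`, `domain_overlap.tsv`),
accessibility-change summaries per induced TF, motif-enrichment and
gene-set-association tables, and the binding PCA. For example,
`domain_overlap.tsv` shows the pioneer signature — B-specific sites
sit outside accessible chromatin while every shared site is inside:

```
label   fraction_in_domains
A,B>C   1
A=B=C   1
A>B,C   1
B,C>A   1
B>A,C   0.00497512
```

(plus a two-site spurious C>A,B class that falls below the 500-event
retention rule).

and `motif_enrichment.tsv` shows that sequence cannot explain the
difference: the posterior motif is equally over-represented at
B-specific and at B,C-shared sites (rate ratios ≈ 11.3 vs 11.3),
exactly the situation in which accessibility, not motif preference,
separates the factors.

The same analyses are available as library calls
(`pioneerbind.events.classify_multiway`,
`pioneerbind.accessibility.site_density`, …); see `docs/methods.md`
for the model details and parameter defaults.

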