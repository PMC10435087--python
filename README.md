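# mutaset

Are disease-associated gene sets mutated by environmental mutagens more
than you would expect by chance?  `mutaset` is an analysis pipeline for
single-nucleotide substitution catalogs from mutagen-exposed clonal cell
lines (one catalog per subclone, grouped into exposure classes such as
polycyclic aromatic hydrocarbons or radiation).  It answers that question
with a random-gene-set empirical null and exact binomial tests, and probes
*why* gene sets differ in vulnerability with sequence-property regression
and local-context analyses.

## What it computes

**Gene-set burden.** For an exposure class with $S$ treated subclones, the
expected mutation rate is estimated by sampling $N$ random sets of $m$
genes from the annotation and averaging the mutations-per-gene-per-subclone
rate; its mean is the null rate $p_0$.  A disease set of $G$ genes with
$k$ observed mutations is tested against $\mathrm{Binomial}(n = G \times S,\ p_0)$
with a two-sided exact test (minimum-likelihood tail), with table-wide
Bonferroni correction across all set × class cells, and optionally against
a size-matched Monte-Carlo null,
$p = 2\min(\Pr[T \ge k], \Pr[T \le k])$ over random-set totals $T$.

**Sequence-property mutability.** Per-gene counts (pooled over subclones)
are modelled with quasi-Poisson regression,
$\log \mu_g = \beta_0 + \beta_1\,\mathrm{length}_g + \beta_2\,\mathrm{expression}_g + \beta_3\,\mathrm{GC}_g$,
with dispersion $\hat\varphi = \chi^2_{\mathrm{Pearson}}/(n-p)$ inflating the
standard errors; effects are reported as rate ratios per interquartile-range
increase, $\exp(\hat\beta_j \cdot \mathrm{IQR}_j)$, and as centred
rate-ratio curves.  Separate models are fitted for whole genes and for
per-gene merged coding sequence.

**Local context.** 7-mers centred on each mutation (reference strand)
versus 7-mers sampled uniformly from the genome, and the 96-channel
pyrimidine-centred single-base-substitution spectrum with cosine similarity
to reference signatures.

**DNA-damage enrichment.** Base-pair-weighted mean of a depth-normalised
damage signal track (e.g. excision-repair sequencing coverage) per gene or
CDS, compared across gene sets with one-way ANOVA plus pooled-variance
pairwise contrasts under Benjamini–Hochberg FDR (genes) and
Kruskal–Wallis plus Dunn's test (CDS).

A synthetic-data generator (`mutaset.simulate`) produces a complete toy
study — genome, annotation, subclone manifests, rate-model mutation
catalogs, expression table, damage track — with known ground truth, so the
entire pipeline is testable offline.

## Worked example

Run the full pipeline on the default synthetic study (400 genes on 4 toy
chromosomes, 3 exposure classes × 10 subclones, one length-biased disease
set with a 2× rate excess):

```python
from mutaset.pipeline import run_pipeline

res = run_pipeline({"seed": 17, "enrichment": {"n_sets": 500, "set_size": 300}},
                   "results_demo")
print(res["enrichment"]["gene"].to_frame()[
    ["gene_set", "exposure_class", "observed", "expected",
     "obs_minus_exp", "p_binomial", "significant_bonferroni"]].round(3))
```

```
    gene_set  exposure_class  observed  expected  obs_minus_exp  p_binomial  significant_bonferroni
    NDD_like       radiation        87    42.857         44.143       0.000                    True
control_like       radiation        23    42.857        -19.857       0.001                    True
    NDD_like             PAH        74    33.401         40.599       0.000                    True
control_like             PAH        29    33.401         -4.401       0.470                   False
    NDD_like aromatic_amines        74    29.135         44.865       0.000                    True
control_like aromatic_amines        30    29.135          0.865       0.847                   False
```

The enriched disease-like set is mutated roughly twice its null expectation
in every class and is table-wide Bonferroni significant; the neutral
control set hovers around its expectation.  (At this desk scale the
enriched set is 10% of the gene universe, so it inflates the random-set
null slightly and a neutral set can dip below expectation — at genome
scale this contamination is negligible.)  The gene-level quasi-Poisson fit
on the same run reports

```
                rr  ci_low  ci_high        iqr
length      1.3950  1.3392   1.4532  2597.2500
expression  1.0136  0.9801   1.0481     3.7235
gc_percent  1.0714  0.9814   1.1697    19.1575
```

i.e. an IQR increase in gene length multiplies the mutation rate by ≈1.40
(the generator's truth: rates log-linear in length), while expression and
GC effects are near their generated values.  The run directory also
contains the set-size sweep, composition matrices, spectrum, damage tests,
per-figure TSV twins, rendered figures, and a `MANIFEST.json` recording
seeds and analysis decisions.

The same stages are exposed on the command line:

```bash
mutaset simulate --seed 3 --out fixtures/
mutaset run --config config.yaml --out results/
mutaset enrich --mutations m.tsv --manifest mani.tsv --gtf a.gtf \
               --genome g.fa --sets sets/ --seed 17 --out results/
```

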