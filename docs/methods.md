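# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know.  No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates and gene covariates

Internally every interval is 0-based half-open; GTF is read as 1-based
inclusive and mutation positions (TSV/VCF) as 1-based.  Two deliberate
conventions:

- **Gene length** is GTF `end − start`, one nucleotide less than the
  inclusive span.  This is the covariate definition used in the burden
  literature this pipeline follows; the 1-nt discrepancy is immaterial but
  is applied consistently (readers, generator, regression).
- **CDS length** is the summed width of the per-gene *union* of all
  transcripts' CDS intervals, and CDS GC is computed on that union — one
  value per gene, not per segment.

GC content is (G+C)/(A+C+G+T) with ambiguous bases excluded from both
numerator and denominator; an all-ambiguous sequence yields a missing
value rather than a number.  Expression joins by exact case-sensitive
symbol match; unmatched genes keep a missing expression and are dropped
only by analyses that need it.

Mutation-to-gene assignment is pure coordinate overlap: a substitution at
1-based position p belongs to every gene whose half-open span contains
p−1, and to the CDS level when a merged CDS interval contains it.
Overlapping genes each receive the count (set-level tallies treat genes
independently, so no arbitration is defensible), genes may contribute
multiple mutations, strand is ignored for counting, and intergenic
mutations land in an unassigned bucket.  Using CDS-interval overlap in
place of transcript-consequence annotation is an approximation: it counts
intronic-splice-boundary and mixed-isoform cases purely by coordinates.

## Random-set null and burden tests

For an exposure class with S subclones, N random sets of m genes are
drawn uniformly without replacement (within a set; independently across
sets) from the whole annotated gene universe.  Each set's rate is
(total mutations in its genes among the class's subclones)/(m·S); the
null rate p0 is the mean over sets.  Defaults N = 1000, m = 300.  Because
the unit is mutations *per gene per subclone*, m need not match the
disease set's size; the set-size sweep (sizes 10…300, step 10) exists to
demonstrate exactly that: the per-gene-per-subclone curve is flat while
the per-subclone curve grows linearly with slope equal to the per-gene
rate.

A disease set of G genes with k observed mutations is tested against
Binomial(n = G·S, p0).  The binomial n is a modelling choice: "per gene
per subclone" makes gene×subclone the natural trial.  Since a single gene
can carry several mutations, k can in principle exceed n; in that case the
test falls back to an exact Poisson test with mean p0·n and warns (the
binomial family cannot represent that multiplicity).  The two-sided
p-value uses the minimum-likelihood tail — the sum of probabilities of all
outcomes whose point probability is ≤ that of the observed outcome, with
relative tolerance 1e−7 for floating-point ties.  A central (doubled
one-tail) alternative was considered and rejected as the default because
the minimum-likelihood definition is the convention of the statistical
environments this analysis style comes from.

The Monte-Carlo sensitivity test draws N random sets *matched to the
disease set's size*, takes their total counts T, and reports
p = 2·min(#{T ≥ k}, #{T ≤ k})/N, truncated at 1, ties counted in both
tails, no pseudo-count.  With no pseudo-count p can be exactly 0 when k
falls outside the null range; such values are flagged as below the 2/N
resolution rather than silently clamped.

Multiplicity is controlled table-wide: one heatmap's m = (#sets)×(#classes)
cells share a Bonferroni threshold 0.05/m, gene-level and CDS-level tables
corrected separately.  Length-quartile stratification orders a set's genes
longest-first (ties by symbol) and splits into four groups whose sizes
differ by at most one, extras going to the longest-gene groups.

Known desk-scale caveat: when an enriched set is a non-negligible fraction
of the gene universe (10% in the default synthetic study), it contaminates
the random-set null upward, deflating neutral sets' expected-vs-observed
comparison.  At genome scale (hundreds of disease genes among ~20k) the
effect is negligible, which is why the null deliberately does not exclude
disease-set genes.

## Quasi-Poisson mutability regression

Response: per-gene total mutation count pooled over all subclones and
classes (one gene-level and one CDS-level model; CDS models use only genes
with non-empty CDS).  No exposure offset is used — the pooled count is the
modelled quantity, and the intercept absorbs the subclone total.
Covariates enter on raw scales (length in nt, expression in RPKM, GC in
percent); a log-expression transform is available but off by default since
the raw scale is what makes the near-null gene-level expression effect
reproducible.  Rows with any missing covariate are dropped before
fitting.

The mean model log μ = Xβ is estimated by IRLS (statsmodels GLM, Poisson
family; convergence tol 1e−8, cap 100 iterations; non-convergence and
rank deficiency are hard errors).  Dispersion is Pearson:
φ = Σ(y−μ̂)²/μ̂ / (n−p); quasi standard errors are Poisson SEs × √φ.  A
φ numerically at 0 (perfectly fitted counts) is flagged degenerate.
Effects are reported as RR = exp(β_j·IQR_j) with Wald 95% intervals
exp((β_j ± 1.96·SE_j)·IQR_j); RR per IQR is invariant to linear rescaling
of a covariate.  Zero-IQR covariates return RR = 1 with a warning.
Centred curves report RR(x) = exp(β_j(x − x̄_j)) with the band from SE_j;
below the mean the ± band flips, so the interval takes elementwise
min/max.

## Local sequence context

7-mer composition matrices are built from the reference strand as-is (no
pyrimidine orientation — the composition view shows raw A/C/G/T content);
windows crossing a chromosome edge or containing ambiguous bases are
skipped and tallied, and records whose ref allele disagrees with the
genome are excluded as reference mismatches.  The random comparator
samples k-mer windows uniformly over all edge-safe, ambiguity-free
positions of the whole genome (not genic regions), default 50,000.

The 96-channel spectrum uses the standard pyrimidine-centred convention:
purine-centred substitutions are reverse-complemented, channels ordered
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) then 5' and 3' base.
Every eligible SNV lands in exactly one channel, so the spectrum total
equals the eligible count; reverse-complementing the whole dataset leaves
the spectrum invariant.  Only spectra and cosine similarity to supplied
reference matrices are computed — no de-novo signature extraction.

The random-mutation length model samples n positions (default 100,000)
uniformly over the concatenation of all gene (or CDS) sequences and
returns the lengths of the hit sequences, making a sequence's hit
probability proportional to its length — the comparator line for length
distributions.

## Damage enrichment

Per-region enrichment is the bp-weighted mean of the signal over the
region (uncovered bases count 0): Σ value×overlap / region width.  For a
piecewise-constant track this equals a scaled-region (length-normalised)
average, and unlike binned interpolation it is exactly invariant to
splitting track intervals — which is why it is computed this way.  CDS
enrichment averages over the gene's merged CDS union.  Zero-width regions
are errors.

Gene-level comparisons: one-way ANOVA, then all pairwise contrasts with
the pooled ANOVA error variance (t on N−k df) under Benjamini–Hochberg.
CDS-level (non-normal) comparisons: tie-corrected Kruskal–Wallis, then
Dunn's z on mean ranks with tie-corrected variance,
z = (R̄_i−R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i+1/n_j)),
Benjamini–Hochberg by default (Bonferroni or none selectable) — Dunn's
test is implemented in-package since no installed library provides it.
All-tied data make H undefined and raise.

## Synthetic generator

The generator encodes the minimal structure the analyses assume, not
realistic genome biology:

- genome: per-chromosome i.i.d. bases at a background GC (default 0.5);
- genes: non-overlapping, lengths LogNormal(meanlog ln 3000, sdlog 0.6)
  floored at 300 nt, each rewritten with its own GC drawn from
  Beta(6, 6) so the GC covariate varies; 1–3 disjoint CDS sub-intervals
  per gene (~quarter of each segment);
- expression: LogNormal(1, 1) RPKM;
- rate model: per gene per subclone
  λ_g = class multiplier × δ^{member} × exp(β0 + βl·len + βgc·gc + βe·expr)
  with defaults β0 = −3.5, βl = 1e−4, βgc = 0.5, βe = 0.002, giving base
  rates ≈0.05–0.08 — the order of magnitude of strong mutagen classes;
  class multipliers 1.5/1.2/1.0 for radiation/PAH/aromatic amines,
  3 classes × 10 subclones;
- sets: a 40-gene length-biased disease-like set with δ = 2 and a 40-gene
  neutral control set;
- counts: Poisson, or gamma-Poisson (negative binomial, configurable size)
  for overdispersion; positions uniform within the gene, ref read from
  the genome, alt uniform over the other three bases;
- damage: per-gene-constant signal = set mean (1.5 enriched / 1.0
  otherwise) + N(0, 0.3) truncated at 0.

Default scale (4 × 1 Mb chromosomes, 400 genes) runs the whole pipeline in
seconds.  What it does *not* emulate — and hence what passing tests do not
demonstrate about real data: chromatin/replication-timing structure,
trinucleotide-biased substitution types, transcript isoform diversity,
overlapping genes, assembly gaps, sample-level contamination, and the
scale of a real genome (so null-contamination by enriched sets is visible
here and negligible there).

## Verification strategy and problem sizes

The acceptance suite checks, at these sizes (chosen to make Monte-Carlo
bands tight while the suite stays fast): exactness of the binomial
machinery against full pmf enumeration (all n ≤ 50 × 4 null rates);
type-I calibration on 500 homogeneous-null cells (2000 genes, rate 0.05,
10 subclones); binomial/Monte-Carlo rejection agreement on 200+ null
cells; power of detecting the generator's δ = 2 set over 100 seeded
studies; quasi-Poisson recovery at n = 5000 genes with Wald coverage over
200 seeds and Pearson-dispersion response to negative-binomial counts
(pooled response, mean counts O(1)); sweep flatness/linearity; spectrum
and composition conservation laws; the closed-form ANOVA (F = 3) and
Kruskal–Wallis (H = 4.5714) fixtures plus a permutation-size check; and
the two-gene length-model expectation (mean hit length 250).
`scripts/acceptance.py` recomputes the same families of quantities from
scratch under a single user seed.

## Known limitations

- CDS assignment is coordinate overlap, not consequence annotation.
- The binomial trial definition (gene × subclone) understates multiplicity
  when single genes accumulate many mutations in one subclone; the Poisson
  fallback covers the extreme case only.
- The Monte-Carlo p has resolution 2/N and no continuity correction.
- Pairwise contrasts assume a common error variance across sets.
- The generator's alt-allele draw is uniform; spectra from synthetic data
  are flat by construction and only conservation laws are meaningful.
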