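# Methods

`epimutkit` analyses count data from mutation-accumulation (MA) experiments:
several lineages descended from one founder population, propagated at minimal
population size so drift dominates selection, and assayed at the founder
("PMA", generation 0) and at alternate generations thereafter. Its goal is to
detect *epimutations* — heritable changes in chromatin accessibility, small-RNA
levels or gene expression without DNA sequence change — and to quantify their
rate, inheritance, duration and cross-channel coupling.

## Epimutation calling

Counts for one (lineage, assay) are a loci × generations matrix. Each
generation column is depth-corrected with median-of-ratios size factors:
`factor_g = median_i count_ig / geomean_i`, where the median is taken on the
ratio scale over reference loci (loci nonzero in every column). Only size
factors are used downstream; no dispersion estimation or Wald testing is
performed.

For each generation *g* > 0 versus the founder, an MA-plot linear model is
fitted by ordinary least squares:

    y_i = log2((c_ig + pc) / (c_i0 + pc))        # fold change
    x_i = log2((c_i0 + c_ig)/2 + pc)             # pairwise mean (default)
    y   = a + b·x + r

The fit removes the systematic dependence of fold-change variability on
abundance. Residuals are standardized with the population SD,
`Z_i = (r_i − mean(r)) / sd(r)`, so every non-degenerate comparison has mean 0
and SD 1 over the fitted loci. Calls are made at a symmetric threshold *t*
(default 2.25): `Z > t` is an Up epimutation (+1), `Z < −t` a Down epimutation
(−1), boundaries are strict. "Less than *t*" for Down is read as "less than
−*t*" — the threshold is symmetric by construction.

Tunables (with units and defaults):

| parameter | default | meaning |
|---|---|---|
| `z_threshold` | 2.25 (SD units) | symmetric call cutoff; the default is where the inheritance excess over the reassortment null peaks |
| `pseudocount` | 1.0 (counts) | added before every log2 to avoid log-of-zero |
| `min_mean` | 1.0 (normalized counts) | loci below this in **both** compared samples are excluded from the fit and set Z = 0 |
| `subset_chromosome` | none | restrict fit and standardization to one chromosome's loci (e.g. X-specific Z-scores, where dosage compensation gives the X a distinct chromatin environment) |
| `ma_mean_mode` | `pairwise` | `x` uses the two compared samples (MA convention); `all_samples` uses the across-generation mean |

One OLS fit is made per (lineage, generation) comparison; normalization is per
(lineage, assay). Both choices reflect that each generation is compared to its
own founder; pooled alternatives are reachable through the API but are not the
default.

Two intrinsic ceilings of Z-standardized calling are worth knowing. First,
because calls are defined on standardized residuals, a large *fraction* of
truly changed loci inflates `sd(r)` and (through the fold-change/mean
correlation of symmetric effects) tilts the fitted slope, absorbing part of
the signal: per-cell recall is essentially 1 only while the active fraction
per column stays below roughly 5%. Second, the pseudocount caps the observable
Down fold change at ~log2(c_0 + 1), so very strong losses at low-abundance
loci saturate. Both effects are visible in the generator-recovery tests.

## Runs, inheritance and duration

Lineages are observed only at even generations, and occasional even
generations are missing entirely. A *run* is a maximal stretch of consecutive
measured generations carrying the same nonzero call at one locus; unmeasured
generations between two same-direction measured calls are imputed as
epimutated, and missing even generations are treated exactly like odd ones
(the imputation is about unobserved time points generally). Run length counts
the imputed generations: `length = offset − onset + 1`. A measured zero or a
sign flip terminates a run — the processes establishing and dismantling a
chromatin state are antagonistic, so direction is part of a run's identity. A
run is *inherited* when it spans at least two measured generations
(conservative: transmission was seen at least once) and *censored* when still
active at the last measured generation. "Percentage inherited" counts runs
(episodes) by default; cell-level counting is available via `unit="cells"`.

Duration is summarized per group with Kaplan–Meier estimates (lifelines),
censored runs entering as right-censored at their observed length, plus a
log-rank test across groups. The reported median is the smallest time with
S(t) ≤ 0.5. For rate bookkeeping (not survival), censored runs keep their
observed length.

### Reassortment null and threshold choice

Whether epimutations are truly transmitted is tested by destroying
across-generation memory: each generation column's calls (with signs) are
redistributed uniformly without replacement among *epimutable* loci, exactly
preserving per-column call counts and sign multisets. The observed inherited
percentage minus the null's mean is the *inheritance excess*; the empirical p
uses the add-one permutation convention, `p = (1 + #{sim ≥ obs})/(1 + n_sim)`.
Scanning a cutoff grid (default 1–3, step 0.25, so the conventional 2.25 sits
on the lattice) and maximizing the excess selects the calling threshold.

The epimutable universe is a parameter. On real data the operational proxy —
loci with at least one call — guards against structurally never-epimutable
loci diluting the null. That proxy, however, conditions on having a call: for
sparse tables it concentrates the redistributed calls into a small subset and
*inflates* the null's coincidence rate, biasing the excess downward (the
detection is conservative, never anti-conservative). When the whole universe
is known to be epimutable — as in calibration simulations — `epimutable="all"`
makes column reassortment the exact conditional law of independent data, and
the excess is unbiased at zero. Defaults: `n_sim=1000` for the excess scan,
`n_sim=10000` for the fixed-rate null used in class-level comparisons of the
inherited proportion (each cell independently called with a fixed rate,
random sign; note that with random per-cell signs the inherited proportion at
rate *r* over two generations is exactly r/(4 − r) by enumeration of the nine
two-cell states — sign flips split runs).

### Environmental exclusion

Even with controlled conditions, a shared external stimulus (temperature, UV)
would induce the *same* change in all lineages at the same time, since the
lineages are handled in parallel. Runs with identical locus, direction, onset
generation and duration in **all** lineages are therefore erased from every
lineage and logged. Direction is part of the signature: a sign-flipped
coincidence is not the same induced event.

## Longevity classes

Each locus with runs receives a duration estimate: the mean of its run
durations pooled across lineages (the OLS solution of `duration ~ locus`),
optionally shrunk toward the grand mean with a ridge weight λ
(`estimate = (Σ durations + λ·grand_mean)/(n + λ)`), standing in for a
random-intercept fit. λ = 0 (no shrinkage) is the default; the knob exists
because the appropriate pooling across lineages is genuinely open and the
downstream consumer is only a one-dimensional clustering.

Estimates are split with 1-D K-means (k = 2, 25 restarts, seeded): among loci
with at least one inherited run, the larger-centroid cluster is *long-lived*,
the rest *short-lived*; loci with only single-generation runs are
*non-inherited* regardless of clustering, so long-lived and non-inherited can
never intersect. A two-component Gaussian mixture fitted by EM (tolerance
1e-8, ≤500 iterations, random restarts on degenerate fits) provides an
independent cross-check; the Jaccard overlap of the two long-lived sets is
reported.

## Association analyses

Integration is gene-centric, per (gene, lineage) — epimutations are lineage
events, so lineages are not collapsed by default. Expression runs at a gene
are matched with partner runs: chromatin runs at any regulatory element
annotated to the gene (genes may own several promoters/enhancers) or
antisense 22G small-RNA runs at the gene itself. A partner is *simultaneous*
when it shares ≥1 measured epimutated generation with an expression run —
durations need not match, because an established epigenetic state may persist
after its initiating signal — and *concordant* when directions agree at the
earliest shared generation (a gene with several simultaneous pairs is
concordant if any pair matches; a strict all-pairs flag exists).

The stepwise Fisher battery (2×2 exact tests, two-sided) narrows the
background in four steps: (1) expression change × partner epimutation over
all genes (the chromatin channel restricted to genes with annotated
elements); (2) inherited expression change × partner epimutation, same
background; (3) inherited change × simultaneous partner among genes with
expression changes; (4) the same among genes with both change types. Odds
ratios are reported in both conventions — the sample cross-product
(a·d)/(b·c) and the conditional-MLE estimate that R's `fisher.test` prints —
since they differ away from 1. Concordant and discordant simultaneous
partners get separate arms against genes with no simultaneous partner.

Domain enrichment crosses longevity classes with chromatin-domain labels
(Active/H3K36me3, Regulated/H3K27me3, X, piRNA clusters, …) in a Fisher grid
with Bonferroni correction over the grid; enrichments are flagged at the
reporting cutoff p ≤ 0.1. Ontology enrichment takes a user-supplied gene→term
table (no web service): with a large background (≥ `sample_size`, default
6000) it draws `n_samples` (default 50) background samples and scores each
term by the mean Pearson chi-squared (no continuity correction) of its 2×2
membership table; smaller backgrounds get direct Fisher tests with
Bonferroni. Terms with fewer than `min_genes` (default 5) members in both
lists are excluded.

## Synthetic data

The generator emulates the study design: 3 lineages, founder plus even
generations 2–20, three channels (expression and 22G per gene, accessibility
per regulatory element; every gene owns at least one element, extras are
assigned at random). Baselines are log-normal (default median 100 counts,
log-SD 1); counts are negative-binomial with the RNA-seq-like trend
`var = μ + φ(μ)·μ²`, `φ(μ) = a + b/μ` (a = 0.01, b = 1), plus a per-column
log-normal depth factor (SD 0.2) so normalization is genuinely exercised.

Events arise on the full generation lattice 1–20 — onset Bernoulli(ρ = 0.01
per channel per generation, the ~1%-per-generation regime typical of
regulatory loci in these experiments), geometric duration with continuation
π = 0.8 (median 4 generations, matching the 3–5-generation persistence of
small-RNA epimutations), multiplying the mean by 2^{±δ} (δ default 3; the
real effect-size distribution is unknown, so δ is a knob, not an estimate).
Observation only at measured generations means some true events are invisible
or truncated — intended, so the imputation logic is genuinely tested.
Optional couplings: an expression event spawns a partner chromatin/22G event
with probability `coupling_prob` (same onset, independent duration, sign
concordant with probability `concordance_prob`); `environmental_events`
events are injected with identical locus/direction/onset/duration in every
lineage, with onsets on even generations.

Every event is recorded in a truth ledger. To keep per-event recovery
well-defined, events at one locus are separated by at least two silent
generations (each event then projects to exactly one called run on the
measured grid) and environmental loci carry no other events; overlapping
same-locus events would have no unambiguous per-event precision/recall.

What the generator does **not** emulate: real chromosome geometry (domains
are labels), locus-specific epimutability, correlated noise between channels,
batch structure beyond per-column depth, or the real effect-size spectrum.
Passing recovery tests therefore shows the pipeline's rules are implemented
correctly and calibrated under NB noise — not that real data meet these
assumptions.

## Numerical choices and problem sizes

All stochastic operations take explicit seeds (`numpy.random.default_rng`);
identical seeds give byte-identical outputs. Degenerate MA fits (residual
SD < 1e-12, or fewer than 3 loci passing `min_mean`) raise an error naming
the generation. K-means ties break toward the lower centroid via the library
assignment; EM degeneracy (component SD < 1e-6) triggers jittered restarts
(≤10). Empirical p-values are never 0 by the add-one convention. The test
suite and the acceptance script use 10⁴ loci × 10 generations × 3 lineages
for null calibration, 5000 loci (2000 genes + 3000 elements) for
generator-recovery checks, and 50–1000 simulations per null; these sizes give
Monte-Carlo errors comfortably inside the asserted tolerances.

## Known limitations

- The "observed" epimutable proxy makes the inheritance excess conservative
  on sparse data (see above); excess values near zero should not be read as
  evidence against inheritance when call rates are low.
- Recall degrades when the per-column active fraction exceeds ~5% or when
  strong Down events hit low-abundance loci (pseudocount saturation).
- The duration model ignores censoring when estimating per-locus effects
  (censored runs contribute observed length), biasing long-lived estimates
  downward; the survival analysis, not the class split, is the calibrated
  duration summary.
- Coordinates in annotations are bookkeeping only; no positional analysis is
  performed.
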