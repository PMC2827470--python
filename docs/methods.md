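# Methods

## The model

The pipeline addresses a two-condition, small-replicate expression study:
intensities for ~28k probes measured in biological triplicate under a
treated (splice-switched) and a control condition. Analysis proceeds in
five stages — significance filtering, weighted pathway overrepresentation,
pathway-pair interconnectivity, cross-platform signature comparison, and
qPCR concordance validation — each exposed as library functions and a CLI
subcommand, and each testable against synthetic data with planted truth.

### Differential expression

Per-probe log₂ fold change is the difference of group means of log₂
intensities (treated minus control). The test statistic is the two-sided
Welch *t*-test on log₂ intensities: with only three replicates per group a
minimal-assumption unequal-variance test is the defensible default, and the
statistic sits behind a single function so a moderated alternative could be
slotted in. Degenerate probes with zero variance in both groups get
*P* = 1 when the group means are equal and the smallest positive float when
they differ (the data admit no other answer under the model).

The signature filter keeps probes with raw *P* < α (default 0.05), the
convention of the signature studies this pipeline serves. No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available behind a flag. Consequences of the raw filter are quantified
rather than hidden: on an array where ~90% of probes are null, a
nominal-level filter admits roughly 3–5% of the null probes (Welch on
triplicates runs somewhat conservative), which (a) inflates the signature
beyond the planted size, (b) dilutes the overall up/down split toward 50/50
— the planted split is therefore recovered on the truth-restricted subset —
and (c) caps the Jaccard overlap between recovered and planted sets around
sens/(1 + 9·fp) ≈ 0.75 regardless of sensitivity. Sensitivity (≥ 95% at the
default effect sizes) and the null call rate (5% ± 2 points) are the
quantities the tests pin down.

Probe-to-gene collapsing keeps, per gene, the entry with the smallest
*P*-value (ties: largest |log₂FC|, then probe id); it is idempotent. All
orderings in the package use this deterministic tie-break, so outputs are
bit-stable.

### Normalization

`normalize` offers `median` (shift each sample's log₂ values to the global
median), `quantile` (equalize empirical distributions via the mean sorted
profile) and `none`. Median is the CLI default for real data, where
between-sample offsets are expected. The synthetic generator plants no such
offsets, and on synthetic data global normalization is actively harmful: a
direction-asymmetric signature (90.5% up at 10% prevalence) genuinely
raises the treated samples' medians, so re-centering them pushes every null
probe slightly down and produces direction-biased false calls. The demo and
the recovery analyses therefore run with `none`; this is the reason trimmed
or reference-based normalizations exist for real asymmetric-response data,
and a pluggable normalization hook is the honest substitute here.

### Weighted overrepresentation

Genes annotated to *k* pathways weigh 1/*k* in each, so each annotated gene
distributes exactly unit weight over the annotation (weight conservation is
asserted by a property test). Per pathway the observed count is the weighted
sum over signature genes, the expected count is |S|·S_P/|B|, and the
*P*-value is the one-sided binomial upper tail with success probability
S_P/|B|. The null is "a random gene set of the same size drawn from the
array background"; the binomial is an approximation to the exact
hypergeometric draw, and a calibration test checks the empirical rejection
rate at 0.05 stays within a deliberately loose [0.01, 0.08] band.

Weighted counts are non-integer. The tail Pr(X ≥ w) is evaluated by the
continuous extension I_p(w, n−w+1) (regularized incomplete beta), which
coincides with the exact pmf summation at every integer w (checked to
1e-12 over 10,000 random cases). A `ceiling` mode evaluates
Pr(X ≥ ⌈w⌉) instead — the literal tail of the integer-valued null, which is
never larger than the continuous value.

The default background is the whole array (annotated or not), matching the
"all genes on the platform" universe convention; an annotated-only
background is a flag. Signatures are collapsed to genes before enrichment,
since pathway annotations are gene-level objects.

### Interconnectivity

For every unordered pair of selected pathways, the count of shared genes
that are also in the signature is tested against the pair's shared
background genes using the same binomial tail (n = |S|, p = shared
background / |B|). Shared-gene counts are unweighted by default — the pair
statistic counts genes, not memberships — with a 1/k-weighted mode
available since the weighting convention for pairs is genuinely ambiguous.
Pairs sharing fewer than two regulated genes are reported but flagged
unassessed. Tiers: P < 0.05 highly significant (red), P < 0.10 significant
(orange), otherwise low (gray). The network export writes significant
pathways as Pajek vertices colored by their strongest assessed link and
edges weighted by the shared regulated-gene count.

### Signature comparison

Cross-platform comparison happens strictly in a shared non-redundant
gene-id namespace: `map_signature` translates probe ids through a probe map,
drops genes outside the target universe, resolves multi-probe genes by
smallest *P*, and reports the mapped fraction. Venn partitioning produces
the exact disjoint region decomposition for 2 or 3 labeled sets (disjoint
and exhaustive by property test). Concordance classifies genes significant
in both signatures by fold-change sign, with an `inverted` orientation flag
for depletion-vs-induction designs read in the opposite sense; the default
compares signatures as measured. Crosstalk partitions report only-A /
only-B / both classes as percentages of the union or of condition 1. The
fold-change matrix masks absent gene×signature cells; nothing is imputed.

### qPCR validation

−ΔΔCt with replicate Cts averaged before differencing, a single reference
gene, and the standard 100%-efficiency assumption (fold = 2^−ΔΔCt). The
result is invariant to adding any constant to all Cts. Agreement with the
array is the Pearson R² over genes present in both (≥ 3 required, constant
vectors rejected).

## The synthetic-data generator

Defaults are the emulated study's conditions: 27,868 probes, biological
triplicates, a 961-probe signature with a 90.5%/9.5% up/down split, 131
overlapping pathways, ~87.9% cross-platform mapping coverage, an 80%
same-direction fraction between paired signatures, and 14-gene qPCR panels.
Scaled-down runs (5,000 probes / 500-probe signature) are used by the demo
and the recovery analyses; those sizes are stated where used.

Choices the emulated study does not pin down, fixed here once:

- **Baseline intensities** log-normal with log₂ mean 8, sd 1.5 — a plausible
  microarray scale.
- **Noise** i.i.d. Gaussian on the log₂ scale per probe × sample
  (sd 0.25 by default); no probe-specific variance structure, the simplest
  model supporting the *t*-statistic. Within-group variance of the platform
  is a convention, not an estimate.
- **Effects** |N(2, 0.5)| log₂ units with signs assigned by an exact
  up-quota (`frac_up`), so the planted split is a construction.
- **Multi-probe genes**: by default 1% of genes carry a second probe,
  mirroring the small probe/gene excess of the emulated signature.
- **Pathways**: sizes uniform on [10, 60]; built in two passes — disjoint
  draws, then an exact quota of genes each inserted into one extra pathway
  (displacing a singleton member) so the multi-membership fraction equals
  `multi_membership_rate` exactly and overlap is spread evenly. A planted
  pathway receives a deterministic quota of signature genes equal to
  `multiplier` × the signature's background share of its size; quota genes
  are protected from displacement. An earlier sequential-reuse design
  concentrated overlap on the earliest pathways and silently eroded planted
  1/k weights — the two-pass form removes that artifact. Multi-member genes
  have k = 2 by construction; heavier-tailed membership distributions of
  real ontologies are not modeled.
- **Paired signatures**: mapping coverage and the same-direction fraction
  are exact quotas, not samples, so downstream recovery checks compare
  against constructed truth. Platform B effects are half the magnitude of
  A's, reflecting the attenuation seen when mapping across platforms.
- **qPCR**: Ct values are constructed so −ΔΔCt equals the planted log₂ fold
  change; Gaussian noise of sd `ct_noise_sd` is added per Ct value, so the
  recovered fold change carries sd ct_noise_sd·√(2/r_t + 2/r_c). Whether
  replication noise lives at the Ct or the fold-change level is a modeling
  choice; Ct-level is used. Zero noise recovers truth exactly.
- **Randomness**: one global seed; all generators derive substreams from
  `numpy.random.SeedSequence(seed).spawn` in a fixed order, so identical
  (config, seed) reproduce outputs bit for bit.

What passing on synthetic data does *not* show: the generator has no array
spatial artifacts, dye bias, probe cross-hybridization, probe-specific
variance, between-sample offsets, or correlated genes; real-data
performance of the raw-*P* filter and the binomial null will be worse than
the planted-truth recovery numbers, in ways the calibration bands above are
designed to bound rather than hide.

### Study-scale stand-in tables

`synthetic_data.synthetic_reference_tables` constructs synthetic stand-ins
for the study's published supplementary signature tables at their printed
scale: 961 probes over 955 genes (six two-probe genes) on a 27,868-probe
background with 870 up / 91 down (90.5%/9.5%), 803 genes mappable to the
partner platform, and 140/114 partner-regulated genes with 50 shared
(204 = 50 + 90 + 64). The acceptance script and tests run the actual
counting pipeline (filter, collapse, direction summary, mapping, Venn
partition) over these tables; the builder fixes the input scale, the
pipeline computes every reported number.

## Numerical choices

- Ties broken deterministically everywhere: ascending *P*, then descending
  |log₂FC|, then lexicographic id.
- `binomial_tail(w ≤ 0) = 1` exactly; `p = 0 → 0`, `p = 1 → 1`.
- Percentages reported to one decimal; fractions kept at full precision
  internally.
- Readers reject malformed numerics with line numbers rather than coercing;
  all text I/O is UTF-8 with "." decimals.

## Known limitations

- The binomial null ignores the finite-population correction of the exact
  hypergeometric draw; its rejection rate is only bounded, not calibrated.
- Raw-*P* filtering at a 9:1 null:signal ratio necessarily admits enough
  false positives that whole-signature summaries (size, split, Jaccard) mix
  signal and noise; truth-restricted metrics are reported alongside.
- No moderated variance estimation; with triplicates the Welch test is
  conservative and weak effects (≲ 1 log₂ unit) are unreliable.
- Interconnectivity weighting for pathway pairs is convention, not fact;
  both modes are implemented and the unweighted default is a choice.
- Heat-map rendering and graph layout are out of scope; matrices,
  partitions and Pajek files are exported for external tools.
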