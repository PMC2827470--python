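# sigtome

Analysis pipeline for two-condition transcriptome signature studies of the
kind used to characterise the inducible pro-apoptotic TAF6δ splice isoform:
a treated-vs-control replicate expression study is filtered to a significant
signature, the signature is tested for pathway overrepresentation with
inverse-membership gene weighting and a binomial null, overrepresented
pathways are tested pairwise for interconnectivity, signatures from
different platforms or conditions are mapped, partitioned and checked for
direction concordance, and array fold changes are validated against qPCR
ΔΔCt measurements. A synthetic-data module generates studies with planted
truth so every stage is testable against a known answer.

## Who it is for

Anyone analysing small-replicate (typically triplicate) two-condition
expression studies who wants the classic signature workflow — raw *P* < α
filtering, probe→gene collapsing, weighted gene-set overrepresentation,
pathway networks, cross-platform comparison, qPCR concordance — as a tested,
scriptable library rather than a chain of one-off spreadsheets.

## The statistics at the core

**Differential expression.** Per probe, log₂FC = mean(log₂ treated) −
mean(log₂ control); the *P*-value is a two-sided Welch (unequal-variance)
*t*-test on log₂ intensities. The signature keeps probes with raw
*P* < α (default 0.05); Benjamini–Hochberg is an opt-in flag.

**Weighted overrepresentation.** A gene annotated to *k* pathways carries
weight 1/*k* in each, so every annotated gene contributes total weight 1.
For a pathway *P*, a signature *S* and array background *B*:

    count(P)  = Σ_{g ∈ P∩S} 1/k_g
    S_P       = Σ_{g ∈ P∩B} 1/k_g
    expect(P) = |S| · S_P / |B|
    p(P)      = Pr[ X ≥ count(P) ],   X ~ Binomial(|S|, S_P/|B|)

Weighted counts are non-integer, so the upper tail is evaluated by its
continuous extension, the regularized incomplete beta function
I_p(w, n−w+1), which equals the exact pmf summation at every integer w.

**Interconnectivity.** For each pair of selected pathways, the number of
shared genes that are also regulated is compared to the pair's shared
background genes with the same binomial null; links are tiered
*highly significant* (P < 0.05), *significant* (P < 0.10) or *low*, and
pairs sharing ≥ 2 regulated genes are exported as a Pajek `.net` network.

**Comparison and validation.** Signatures are mapped to a shared
non-redundant gene namespace, partitioned by 2-/3-way Venn decomposition or
condition crosstalk, and classified by fold-change sign concordance. qPCR
agreement uses −ΔΔCt = −[(Ct_tgt − Ct_ref)_treated − (Ct_tgt − Ct_ref)_control]
as log₂ fold change and reports the Pearson R² against the array values.

## Worked example

Run the end-to-end demo on synthetic data with planted truth (5,000 probes,
a 500-probe signature that is 90.5% upregulated, biological triplicates,
131 overlapping pathways with `PW000` planted at 5× enrichment, an 80%
same-direction paired signature, and a 14-gene qPCR panel):

```bash
sigtome demo --seed 1 --out demo_out
```

which logs

```
INFO sigtome: signature=659 (80.9% up), top pathway PW000 (p=7.27e-06),
concordance=0.800, qPCR R^2=0.929
```

and writes `demo_out/summary.json` containing, among others:

```json
{
  "signature_size": 659,
  "pct_up": 80.9,
  "pct_up_planted_recovered": 90.3,
  "sensitivity": 0.994,
  "top_pathway": "PW000",
  "top_pathway_p": 7.268562561857488e-06,
  "concordant_fraction": 0.8,
  "qpcr_r_squared": 0.9287
}
```

Reading these numbers: 99.4% of the 500 planted probes are recovered at
*P* < 0.05 and their direction split (90.3% up) matches the planted 90.5%;
the raw signature is larger (659) and its overall split lower (80.9%)
because a nominal-level filter also admits ≈3.5% of the 4,500 null probes,
whose directions are symmetric — the expected behaviour of raw-*P*
filtering, quantified rather than hidden. The planted pathway tops the
enrichment table, the paired-signature concordance recovers the planted
80% exactly (it is constructed by quota), and the qPCR panel agrees with
the array at R² ≈ 0.93 under 0.25-cycle Ct noise.

The first lines of `demo_out/enrichment.csv`:

```
pathway,count,expect,p_value,significant
PW000,10.5,1.7945454545454547,7.268562561857488e-06,True
PW123,8.0,3.3896969696969697,0.022397702140014592,True
```

All stage outputs (signature CSV, GMT, links CSV, Pajek network, Venn CSV,
Ct table, validation CSV) land in `demo_out/`; identical seeds reproduce
them byte for byte. Each stage is also available as its own subcommand
(`simulate`, `signature`, `enrich`, `links`, `compare`, `qpcr`) or as
library functions under `sigtome.*`.

## Layout

- `src/sigtome/synthetic_data.py` — generators with planted truth
- `src/sigtome/io_formats.py` — signature CSV, GMT, Pajek, probe maps, Ct tables
- `src/sigtome/diffexpr.py` — normalization, Welch statistics, filtering, collapsing
- `src/sigtome/enrichment.py` — weighted overrepresentation and interconnectivity
- `src/sigtome/signature_compare.py` — mapping, Venn, concordance, crosstalk
- `src/sigtome/qpcr_validate.py` — ΔΔCt and Pearson validation
- `src/sigtome/cli.py` — subcommands and the end-to-end demo
- `docs/methods.md` — models, assumptions, parameter choices, limitations
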