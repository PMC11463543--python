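# endolyso

Organelle-immunoprecipitation (organelle-IP) proteomics of the endolysosomal
system: differential enrichment of tagged endosome (Endo-IP) and lysosome
(Lyso-IP) captures versus untagged controls, compartment/overlap analysis,
abundance-trajectory clustering across neuronal differentiation, candidate
endocytic-cargo classification, and SNX27/SNX17 sorting-motif discovery with
complex-prediction (ipTM) score triage.

The package is aimed at proteomics analysts working with tagged-vs-control
multiplexed (TMT-style) organelle IP designs — for example EEA1-tagged
endosomes and TMEM192-tagged lysosomes captured from stem cells and induced
neurons — and at method developers who need a fully ground-truthed synthetic
test bed for such pipelines.

## The model

Enrichment calling is a moderated two-group comparison in log2 space.  Per
protein *g* (n_t tagged, n_c control channels), the pooled residual variance
s²_g (d_g df) is shrunk toward an empirical-Bayes prior (d0, s0²) fitted by
moment-matching log s²_g against its scaled-F sampling distribution:

    s²_post = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t_g     = log2FC_g / sqrt(s²_post·(1/n_t + 1/n_c)) ~ t(d0 + d_g)

with Benjamini–Hochberg q-values and the call rule
`enriched ⇔ log2FC ≥ 1.0 and q ≤ 0.01`.  Downstream stages apply the
candidate-cargo rule (enriched ∧ ≥1 transmembrane segment ∧ cell-membrane
annotation), hypergeometric gene-set over-representation, k-means/silhouette
trajectory clustering, and the sorting-motif grammars
`[S/T]-x-Φ` (C-terminal, SNX27/PDZ) and `Φ-x-N-x-x-[Y/F]` (SNX17/FERM) with
a strict ipTM > 0.6 screening threshold.  See `docs/methods.md` for the full
account.

## Worked example

```python
import endolyso as el

# a ground-truthed synthetic dual-IP experiment (12 channels, triplicate)
cfg = el.SimConfig(n_proteins=300, seed=1)
matrix, design, truth = el.simulate_ip_experiment(cfg)

res = el.EnrichmentModel(matrix, design, stratum=("endo", "iNeuron")).fit()
print(res.summary())
```

```
Moderated organelle-IP enrichment
==============================================
stratum:           endo-IP, iNeuron
proteins:          300 (300 tested)
prior df (d0):     25.60
prior var (s0^2):  0.1132
call thresholds:   log2FC >= 1.0, q <= 0.01
enriched:          47
```

All 300 proteins had enough observations to test; per-protein variances are
shrunk toward the prior s0² ≈ 0.11 (log2 units²) with 25.6 prior degrees of
freedom.  The 47 called proteins are exactly the planted truth of this
simulation — 42 target-compartment/cargo proteins at +2.5 log2 units and 5
cross-captured endolysosomal-core proteins at +1.5 — which can be verified
against `truth`:

```python
ann = el.simulate_annotations(truth)
calls = el.select_candidate_cargo(set(res.enriched), ann)
print(calls.summary())
```

```
candidate cargo: 15 (0 enriched proteins unannotated)
PM/TM proteins in IP: 15/61 (24.6% -> 25%)
```

Of the 61 plasma-membrane/transmembrane proteins in this simulated
proteome, 15 were captured and enriched in the Endo-IP, i.e. ~25% are
candidate endocytic cargo in this run.  Applying the same arithmetic to the
study's printed counts:

```python
el.cargo_fraction(152, 504)   # -> (30.158..., 30)   % of PM/TM proteins in Endo-IP
el.cargo_fraction(70, 347)    # -> (20.172..., 20)   % of synaptic PM/TM proteins
```

A command-line layer mirrors the library
(`endolyso simulate|enrich|annotate|cluster-profiles|cargo|scan|peptides|screen|logos`).

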