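# Methods

`endolyso` re-implements, as a tested library, the computational analysis of an
organelle-immunoprecipitation (organelle-IP) proteomics study of the
endolysosomal system in stem-cell-derived induced neurons (iNeurons): tagged
endosomes (EEA1 handle, "Endo-IP") and lysosomes (TMEM192 handle, "Lyso-IP")
are captured from tagged and untagged (control) cultures, quantified by
multiplexed reporter-ion mass spectrometry, and analysed for enrichment,
candidate endocytic cargo, and SNX27/SNX17 sorting motifs.  Because the
study's raw proteomics is not publicly retrievable, every stage is driven and
validated by a ground-truthed synthetic-data generator.

## Differential enrichment model

The core statistic is a moderated two-group comparison in log2 space,
analysed independently per stratum (ip_type × cell_state).

**Normalization.** Intensities are log2-transformed and each channel is
median-centred.  By default the reference is the grand median of channel
medians *within each (ip_type, cell_state, condition) group*: this removes
per-channel loading and labelling-efficiency offsets while preserving the
tagged-vs-control contrast exactly.  Centring every channel to one global
grand median (available as `scope="global"`) is the more common convention
but shrinks true enrichment whenever the enriched minority shifts a tagged
channel's median — with ~15–20% of proteins enriched at +2.5 log2 units, the
bias is several tenths of a log2 unit, which is why the group-wise default
was chosen.  No imputation is performed; proteins with fewer than two finite
values in either group are reported untested (`enriched = False`, missing
statistics).

**Empirical-Bayes variance moderation.** For protein *g* with pooled
two-group residual variance s²_g on d_g = n_t + n_c − 2 degrees of freedom,
the prior (d0, s0²) is estimated across proteins by moment-matching
log s²_g against its scaled-F sampling distribution: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2),

    E[e]   = log s0² − ψ(d0/2) + log(d0/2)
    Var[e] = ψ′(d_g/2) + ψ′(d0/2),

d0 is obtained by Newton inversion of the trigamma function on the excess
variance of e, and s0² from the corrected mean.  When the observed spread of
e does not exceed its sampling component the prior is degenerate (d0 = ∞);
when the variances have literally zero spread the observed common value is
taken as s0² directly.  With fewer than 20 usable proteins the fit falls
back to d0 = ∞ with s0² = median(s²) and logs a warning.  The moderated
statistic

    t_g = log2FC_g / sqrt(s²_post,g (1/n_t + 1/n_c)),
    s²_post,g = (d0 s0² + d_g s²_g) / (d0 + d_g)

is referred to t(d0 + d_g) (standard normal when d0 = ∞); it reduces exactly
to the ordinary pooled-variance t at d0 = 0, which is asserted as a limit
test.  Two-sided p-values are Benjamini–Hochberg adjusted (step-up, with
missing p propagated and excluded from the test count), and a protein is
called enriched when log2FC ≥ 1.0 and q ≤ 0.01 — the thresholds drawn in the
study's volcano plots, exposed in `RunConfig`.  The upstream publication
names only a statistics package (MSstats) without its settings; the
moderated model here is this package's own, equivalent in role, and whether
the study's q-values were BH-adjusted is likewise an assumption, flagged
here.

## Overlap, selectivity, and gene-set analysis

Venn-style overlap reports enumerate the disjoint regions of 2–3 named
protein sets.  State-selective proteins are classified by a log2
abundance-ratio threshold τ = 1.0 (higher / equal / lower), a rule the study
reports only as proportions; τ mirrors the fold-change convention used
elsewhere in the analysis and is a parameter.  Gene-set
over-representation uses the one-sided hypergeometric tail P[X ≥ k] with BH
adjustment across sets; the universe defaults to the proteins quantified in
the stratum rather than the whole proteome, to avoid detection-bias
inflation.  Gene sets are flat; no ontology-graph propagation is done.

## Trajectory clustering

Differentiation profiles (proteins × sampling days) are linearly
interpolated within rows, z-scored (population sd; zero-variance rows
dropped with a report), and clustered by k-means (20 restarts, fixed seed)
over k = 2..10, choosing k by maximum mean silhouette.  Clusters are
renumbered by the day of their centroid maximum so labels are reproducible
and row-order-independent.  The publication never names its clustering
method; k-means with silhouette selection is this package's documented
stand-in, chosen for determinism and testability.

## Candidate-cargo rule and fractions

A candidate endocytic cargo is an Endo-IP-enriched protein with tm_count ≥ 1
that carries a cell-membrane annotation — the rule exactly as printed, over
a boolean annotation column so upstream vocabulary mapping stays the data
producer's responsibility.  Headline fractions (captured / universe) are
reported unrounded and rounded half-up to integer percent; from the study's
printed counts, 152/504 plasma-membrane proteins → 30% and 70/347 synaptic
ones → 20%.  Domain/family classification partitions candidates into
both / exactly-one / neither annotation categories.

## Motif grammars and screening

* SNX27 (PDZ): C-terminal [S/T]-x-Φ; serine/threonine at −3 and a
  hydrophobic residue as the last residue.  Acidic context (D/E count at
  −4..−8) is reported because upstream acidity enhances PDZ binding, but it
  never filters hits.
* SNX17 (FERM): Φ-x-N-x-x-[Y/F] at every start position (overlapping starts
  all reported), optionally restricted to the cytosolic tail downstream of
  the last transmembrane span.  "Related motifs" looser than the literal
  grammar are deliberately not expanded — grammar creep would silently
  change counts.

Φ = {A, V, L, I, M, F, W, Y} (the Kyte–Doolittle-positive set), exposed as a
parameter since "hydrophobic" is not further specified in the source
analysis.  Peptide windows are 15-mers: the C-terminal 15-mer for SNX27
(whole sequence, flagged short, for shorter proteins); for SNX17, 4 residues
upstream + motif + 5 downstream, shifted inward at termini — the SNX17
window length is not stated anywhere and mirrors the stated SNX27 window.
Controls for the SNX27 screen are C-termini of proteins with an SNX17 motif
but no SNX27 motif, reproducing the study's control design.

Screening scores each query with an interface-confidence (ipTM) value from
either an ingested table of externally computed predictions or the built-in
truth-informed mock (planted windows ~N(0.8, 0.1), background ~N(0.3, 0.1),
clamped to [0,1], deterministic per query and seed).  A query passes only
with score strictly greater than the 0.6 cutoff, matching the repeated
">0.6" phrasing; a protein passes if any of its windows passes, because the
source tallies motifs and proteins separately (its own motif-vs-protein
counts cannot be fully reconciled from the text, so both levels are always
reported here).  Logos are position-frequency matrices with pseudocount 0.5
against a uniform 20-letter background; information content per position is
log2(20) − H in bits.  No structure prediction is performed; the predictor
interface is score ingestion plus the mock.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's *designs* with known truth, from one
seed with independent named substreams per generator:

* **IP experiment** — 12-plex-style tagged/control channels in triplicate
  for both IPs; log2 intensity = baseline (N(20, 2)) + effect + N(0, 0.35)
  noise, exponentiated to intensity scale.  Effects: +2.5 log2 units for
  target-compartment proteins (endosomal proteins and the endocytosed 30% of
  plasma-membrane proteins in Endo-IP; lysosomal proteins in Lyso-IP), +1.5
  cross-capture for a shared endolysosomal-core class (20% of
  endosomal/lysosomal proteins) so the Endo∩Lyso overlap has planted truth,
  0 otherwise.  Effect sizes are set so volcano separation at the 1.0
  fold-change cutoff is achievable but not trivial at the default noise.
  A separate noise seed re-measures the same truth, for replicate-dataset
  reproducibility analyses.
* **Annotations** — compartments/TM counts copied from truth (cell-membrane
  proteins always ≥1 TM), a "synaptic" gene set enriched among
  plasma-membrane proteins with a configurable odds ratio (odds 1 gives an
  exact null for calibration), and domain/family labels for cargo-eligible
  proteins.
* **Sequences** — i.i.d. uniform residues (keeping grammar background rates
  closed-form: SNX27 per-sequence rate (2/20)·(8/20) = 0.04) with motifs
  planted at known sites; accidental background matches are found by
  post-hoc exhaustive scan and recorded, so scanner sensitivity/specificity
  are measured against complete truth.
* **Time-course** — three template shapes (monotone up/down, transient) over
  days 0–12 sampled every 2 days, unit amplitude, Gaussian noise.

Not modelled, by design: reporter-ion ratio compression, isotopic impurity,
batch/plex effects, peptide-level roll-up, proteome-weighted residue
frequencies, and compositional loading differences between tagged and
control IPs.  Passing tests therefore demonstrate correctness of the
statistics and rules under clean protein-level data, not robustness to
those real-data artefacts.

## Numerical choices and problem sizes

Calibration checks use 50 null runs × 200 proteins and 5 planted-effect
runs × 200 proteins (sensitivity ≥ 0.95 at q ≤ 0.05 against truth); oracle
equivalences use 1,000 random p-vectors / sequences and exhaustive
enumeration for hypergeometric universes N ≤ 12; the background-rate check
uses 10,000 random 20-mers.  These sizes give Monte-Carlo error comfortably
inside the asserted bounds while keeping the full suite fast.  Ties in
top/bottom-N selection break on protein identifier; k-means ties on
silhouette break toward smaller k; BH ties resolve by stable sort.  d0 is
treated as infinite above 1e12.

## Known limitations

Real Uniprot/SynGO annotation joins, plex bridging, and GPU-scale structure
prediction are out of scope; the study's absolute headline counts
(611/566/236 enriched, 241 cargo, 19/34 screen passes) depend on its
unreleased raw data and predictor runs and are not reproducible here — the
package instead reproduces the printed arithmetic (30%/20%) and validates
every procedure against planted truth.
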