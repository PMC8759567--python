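# Methods

This note documents the models, numerical choices and limitations behind
`tadomics`, in the order the pipeline runs.

## Coordinates and overlap

All interval work is done in 0-based half-open coordinates.  Omics tables
and the TAD/segment BED are taken to be 0-based half-open as supplied; GTF
records (1-based closed) are converted on load.  Two intervals overlap when
their half-open intersection has length ≥ 1; zero-length touching does not
count.  Strand is ignored everywhere except promoter-sequence extraction
for motif analysis.  Only autosomes (`chr1`–`chr22`) are retained by
default (`allowed_chromosomes`); events elsewhere are dropped at load time
with a logged count.

## Scaling onto the common [0, 100] scale

Frequency layers (methylation beta × 100, mutation VAF × 100) are already
on the target scale; stray values are clamped with a warning, and a layer
whose maximum is ≤ 1 is treated as raw beta values and multiplied by 100
(`beta_autoscale`, on by default — the heuristic cannot misfire on
percent-scale data unless every value in the layer is ≤ 1).

Count layers are mapped per sample column *j* as

    v_ij = ln(1 + E_ij) · 100 / max_i ln(1 + E_ij)

A plain `ln(E)` is undefined at zero counts, which are pervasive in
expression matrices, so `ln(1+E)` is used instead: it is the package's one
deliberate change to the textbook column-max log scaling, keeps zeros at 0,
and agrees with `ln(E)` to < 2 % for counts above ~50.  An all-zero column
stays zero.  Division happens before the multiplication by 100 so the
column maximum maps to exactly 100 in floating point.  Note the per-column
maximum makes the transform sample-wise: a sample's values are comparable
across events, and group *differences* are unaffected in expectation, but
absolute values are not calibrated across samples with very different
sequencing depth.

## Gene and TAD annotation

Gene features are read from the GTF into per-chromosome interval trees.
Each gene contributes its span (labelled `intron`, the weakest gene-body
class), its exon/CDS/UTR records, and a promoter window around the TSS
([TSS−1000, TSS+200) on the annotated strand; both distances are
configurable — there is no universal promoter definition, and 1 kb
upstream / 200 bp downstream is a common compromise).  An event overlapping
several features of one gene receives the highest-precedence class
(cds > exon > UTR > intron > promoter); an event overlapping several genes
lists all gene IDs joined with `;` (sorted).  No overlap ⇒ `intergenic`.

TAD assignment is single-valued: an event overlapping several segments is
assigned to the one with maximal overlap length, ties broken by the
lexicographically smallest segment name — boundary-spanning events have no
canonical home, and a deterministic tie-break keeps runs reproducible.
Unassigned events stay in the integrated table but are excluded from the
TAD universe in the domain-level test (both N and K), since an event that
cannot belong to any domain carries no evidence about domains.

## Methylation inversion

`reverse_methylation` maps `v → 100 − v` for methylation rows whose gene
feature is in `reverse_features` (default promoter and intergenic): low
methylation at regulatory sites usually marks an accessible, active locus,
and inverting makes "high = active" uniform across layers before events
are compared within a TAD.  The operation is an involution and is applied
only when explicitly requested (`--methnorm`).

## Event-level model

For a binary contrast the per-event statistics are the classical pooled
two-sample quantities computed with pairwise missing-cell exclusion:
`logFC = mean₁ − mean₀` on the [0, 100] scale, pooled variance `s²_g` on
`df_g = n₀+n₁−2` degrees of freedom.  Events with fewer than two observed
samples in either group are flagged and excluded.

Variances are then shrunk with the standard empirical-Bayes hierarchical
model: `s²_g | σ²_g ~ σ²_g χ²_{df}/df` with prior
`σ²_g ~ s₀² d₀ / χ²_{d₀}`.  The prior is estimated by moment matching on
`e_g = ln s²_g − ψ(df_g/2) + ln(df_g/2)`: the excess of the empirical
dispersion of `e` over its sampling component identifies `ψ′(d₀/2)`, solved
by Newton iteration on the inverse trigamma (tolerance 1e-8, ≤ 50
iterations; closed-form asymptotes for arguments below 1e-6 and above
1e7).  A non-positive excess means no detectable variance heterogeneity:
`d₀ = ∞` and `s₀² = exp(ē)`.  Zero-variance events are excluded from the
prior fit with a warning; at least 10 informative events are required.
The posterior variance `s̃²_g = (d₀ s₀² + df_g s²_g)/(d₀ + df_g)` gives
the moderated `t` on `d₀ + df_g` degrees of freedom (standard normal when
infinite), two-sided p-values, and Benjamini–Hochberg adjustment across
events.  Default event call: `adj_p < 0.01` **and** `|logFC| ≥ 2` — both
exposed (`alpha_event`, `lfc_min`) since the adjusted-p-only variant is
also in common use; the logFC cut is only meaningful because all layers
share one scale.

Contrasts are strictly two-group; metadata columns that are not binary are
dropped with a warning, as are binary markers present in fewer than
`min_marker_n = 5` samples or lacking two samples per group.

## TAD-level model

With N TAD-assigned tested events of which K are significant, a TAD
holding n events with k significant gets the upper-tail hypergeometric
p-value `P(X ≥ k)`, X ~ Hypergeom(N, K, n) — the chance of seeing k or
more significant events in the domain if significance were scattered at
random.  The companion criterion is *activation*: the mean |logFC| over
the TAD's expression-source events, requiring the domain's phenotypic
readout (transcription) to move, not just its CpGs.  TADs with no
expression events have activation 0 and can never be called — treated as
"no phenotypic evidence" rather than exempt.  Default call:
`hyper_p < 0.01` and `activation ≥ 2`.  The raw (not adjusted)
hypergeometric p is used for the call, keeping the criterion a descriptive
enrichment cut; a BH column (`hyper_adj_p`) is emitted for information.

`tad_sample_means` (TAD × sample means) and `tad_abs_diff_means` (per-TAD
mean |group difference|) support the PCA/heatmap-style convenience views.

## Functional analysis

All enrichment runs offline from user-supplied files.  Gene-set
over-representation uses the upper-tail hypergeometric on
(N = genes in the aggregated table, K = term genes in that universe,
n = query genes, k = overlap), BH across terms.  The per-(term, TAD) test
asks whether an enriched term's genes concentrate in particular domains:
same tail with n = genes in the TAD, BH within term.

Motif analysis extracts sequences (point events ± 50 bp flank; expression
events replaced by their gene's promoter window), merges overlapping
intervals per chromosome, and scans both strands with JASPAR PWMs using
log₂-odds after pseudocount (0.01) renormalisation against a uniform
background; windows containing N are skipped.  A sequence is a hit when
its best score reaches `pwm_hit_fraction = 0.8` of the motif's maximum
achievable score — a scale-free threshold that behaves comparably across
motif widths.  Per motif, a one-sided Fisher exact test compares hit
frequencies between foreground (significant events) and background
(tested, non-significant events), BH across motifs.  Numerical parity with
web-service enrichment stacks is not claimed; the statistical content
(over-representation + per-TAD localisation) is what is preserved.

## Synthetic bundles

The generator emulates a two-layer same-sample study at desk scale:
200 TADs × 20 events and 20 samples per group by default (the test and
acceptance problem size).  Non-overlapping domains of 0.2–1.5 Mb are laid
cyclically across the autosomes with 10–100 kb gaps; each domain gets toy
two-exon genes (~1 per 3 events), expression events at gene positions and
methylation events at random positions.  Methylation: per-event baseline
beta from a bimodal Beta(2,5)/Beta(5,2) mixture (clipped to [0.05, 0.95]),
per-sample Beta noise whose variance is drawn from a scaled inverse-χ²
prior (d₀ = 10, s₀² = 36 on the 0–100 scale, i.e. sd ≈ 6 units) — so the
event-level model downstream is well specified and variances are
realistically heterogeneous.  Expression: negative binomial with
dispersion 0.2 around log-normal means (ln-mean 4, ln-sd 1.5).  A planted
TAD shifts group-1 means by `effect` scale units on every event — directly
for methylation (sign flipped, mimicking inverse promoter-methylation /
expression coupling) and via a count multiplier `exp(effect·L/100)` with
L = 10 (the typical log1p column span) for expression.  Everything derives
from one seed; bundles are byte-identical across runs.

What the generator does *not* emulate: co-methylation correlation between
neighbouring CpGs, sample-specific library-size or batch effects, copy
number, and realistic TAD nesting.  Passing the planted-recovery and
type-I suites therefore shows the statistics behave correctly under the
stated model, not that the pipeline is robust to those real-data artefacts.

## Determinism and outputs

All randomness flows through explicit seeds; reruns of any stage on the
same inputs produce byte-identical outputs.  The integrated tables,
per-contrast event/TAD result files, summaries, enrichment CSVs and
figure sidecars follow the file layout described in the README; every
figure has a CSV sidecar carrying exactly the plotted numbers.

## Known limitations

- Two-group contrasts only; no covariates, pairing or count-specific
  variance modelling (the count layer is treated as continuous after
  scaling, which is mildly anti-conservative for very low counts).
- The hypergeometric TAD test treats events as exchangeable; correlated
  events (neighbouring CpGs) make it optimistic on real data.
- Single-TAD assignment discards the ambiguity of boundary-spanning
  events.
- GO term relationships (DAG propagation) and motif-affinity models
  beyond best-hit thresholding are out of scope.
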