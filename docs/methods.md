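# Methods

This note documents the models and procedures implemented in `edura`, the
parameters that matter, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Coordinate system

The chromosome is a circle of `g` base pairs (default 4,641,652 bp, the
*E. coli* K-12 chromosome). Coordinates are 0-based with inclusive
start/end; all arithmetic is mod `g`. A gene is reduced to its centre, the
average of its start and end positions; genes wrapping through the origin
(start > end) take the midpoint of the forward arc. Centres are kept as
reals (x.5 is allowed) and distances are compared without rounding. The
genome length is supplied in configuration rather than inferred from the
largest coordinate, which would be fragile under truncated inputs.

Two graphs live on this circle:

* **TRN** — directed gene-to-gene regulation, parallel edges collapsed,
  self-loops retained at load time (each analysis states its own exclusion
  rule).
* **GPN** — undirected proximity graph: edge iff the circular centre
  distance is ≤ `T_GPN` (inclusive; default 20,000 bp).

## Axis rotation (EDURA)

A candidate Ori–Ter axis at coordinate `a` splits the circle into a right
arm (the increasing-coordinate semicircle from Ori — either chirality is
internally consistent; this one is fixed and documented) and a left arm.
Each directed edge falls into one of six categories r+, r−, l+, l−, rl, lr
(away/toward Ori on each arm, or across arms in either direction).
Conventions for measure-zero cases: centres exactly at Ori or Ter belong to
the right arm; same-arm edges whose endpoints are equidistant from Ori
count as "+"; self-loops have no category and are tallied separately.

Two asymmetries summarise the counts:

    A_pm_r = (n(r+) − n(r−)) / (n(r+) + n(r−) + n(rl))        (left arm mirrored, with n(lr))
    A_x    = (n(lr) + n(rl) − Σ along) / (Σ all six)

Zero denominators are recorded as 0 with an explicit flag so per-position
curves stay aligned.

**Scan grid.** Categorisation is piecewise constant in `a` between
breakpoints (gene centres and their antipodes), so the scan evaluates one
position per segment — the segment midpoints — which represents the full
continuum exactly. A uniform-step grid is available for plotting. The grid
is symmetric under a half turn, which makes the category-swap identities
(n_r+(a) = n_l−(a+g/2) etc.) hold exactly on it.

**Baseline.** Raw asymmetries reflect gene density and hubs as much as any
axis systematics, so the mean asymmetry over `n_random` (default 100)
switch-randomized graphs — gene positions fixed, 5000 accepted
degree-preserving double-edge swaps each — is subtracted per position.

**Detection.** Because an edge migrates through a fixed cycle of categories
under rotation, the two arm asymmetries are strongly correlated at generic
positions; the statistic is their Pearson correlation in a centred circular
window, and the detected axis is the position minimising that curve. The
window defaults to the smallest odd integer ≥ 10% of scan positions
(minimum 11). The fraction was fixed by calibration on planted-axis
systematic networks (N = 400, counts 120/30/120/30/20/20, 40 seeds):
recovery of the planted axis within g/50 was 0.95 at 10% versus 0.925 at
5%, the wider window suppressing spurious local dips. The correlation can
be computed from raw or baseline-subtracted asymmetries; the default is
baseline-subtracted.

The correlation curve is analytically symmetric under a half turn, so
global minima come in antipodal pairs whose values differ only by rounding.
`detect_axis` treats curve values within 1e-9 of the minimum as ties and
selects the smallest coordinate, making the outcome deterministic rather
than a coin flip between antipodes. By default the reported axis is then
refined to the weighted circular centroid of the correlation trough around
that minimum (weights = local maximum minus curve, over one correlation
window): the raw argmin jitters by roughly a quarter window inside the
wide trough, and on the planted-axis calibration the centroid cut the
maximum recovery error from 23.8 to 16.8 kbp (on g = 1 Mbp) and raised the
40-seed recovery rate from 0.95 to 1.0. `refine=False` returns the grid
minimiser itself.

## Null models

**Switch randomization** performs `n_steps` *accepted* double-edge swaps
(a→b, c→d) ⇒ (a→d, c→b); swaps creating self-loops or duplicate edges are
rejected and do not count, so mixing is independent of the rejection rate.
Attempts are capped at 100 × `n_steps`; exceeding the cap raises an error
rather than returning an under-mixed graph.

**Systematic random networks** plant an axis: N/2 genes per arm at distinct
integer positions strictly inside each arm (the genome length must be even
so the arm boundary is a valid coordinate), then exactly the requested
number of edges per category, drawn uniformly without replacement among the
ordered pairs realising that category. Recounting categories at the planted
axis reproduces the request exactly; this round-trip is a hard
postcondition and the basis for calibrating the detector.

## Control strengths

For one contrast, genes with |logFC| > `T_FC` (strict; default 2.5; or
one-sided for up/down modes, missing values never called) induce an
*effective network* in the TRN or GPN. Its control ratio is

    R = N_connected / max(N_isolated, 1)

with N_connected the subgraph nodes of non-zero degree. The clamp handles
fully connected subgraphs, for which no rule is otherwise defined; a
`statistic="connected"` variant uses N_connected itself. The control type
confidence (CTC) is the z-score of R against `n_null` (default 10,000)
random gene sets of the same size — drawn from the TRN node set for the
digital CTC and from the genome gene set for the analog CTC. Resampling
existing gene positions preserves the empirical gene density; an
alternative analog null drawing fresh uniform circle positions is
available. A zero-variance null yields CTC 0 with a degenerate flag.

Operon-level calls lift gene calls by "any member called"; an operon mixing
up- and down-calls in a one-sided mode (not expected in curated data) is
resolved by its largest-|logFC| member, with a warning.

Null ensembles are evaluated with chunked sparse matrix products
(membership matrix × adjacency), so 10,000-draw ensembles cost fractions of
a second on desk-scale graphs.

## Decision trees and corrected importances

Each gene carries nine features: `pos_oric` (unsigned circular distance to
Ori; a signed variant exists), three binding-site densities (sites within
±50,000 bp, boundary inclusive), `gpn_cont` (called GPN neighbours),
`trn_cont` (called direct TRN regulators), and three binary flags for being
a direct target of hns/fis/crp. `trn_cont` uses direct predecessors,
consistent with the dig-cont flags; an `ancestors=True` switch counts the
transitive closure instead, as the two readings of "affected regulators"
differ. Genes absent from a graph take 0 for its features.

The tree is grown to purity with binary splits at midpoints of consecutive
distinct feature values, maximising the impurity gain S − G (entropy
S = −(p₁ ln p₁ + p₀ ln p₀) by default, Gini p₁(1−p₁)+p₀(1−p₀) as the
alternative). Tie-breaks are deterministic: lowest feature index, then
lowest threshold. Nodes holding contradictory duplicates (identical
features, mixed labels) become impure leaves. No train/test split is used:
the object of interest is which features the tree employs, not predictive
accuracy. The tree is implemented in-package because the analysis requires
these exact deterministic tie-breaks and growth rules; scikit-learn's tree
(whose best-splitter visits features in randomized order) serves as an
independent cross-check in the test suite on tie-free data.

Importance is mean decrease in impurity: each internal node contributes
n·(S − G) to its split feature; the vector is normalised to sum to 1. MDI
is biased toward high-cardinality features, so the labels are permuted
`n_shuffles` times (default 100, preserving class counts), the tree refit,
and the mean shuffled importance subtracted. The corrected importance of a
feature is only centred on zero when the labels carry no signal at all; if
the labels are strongly predicted by one feature, all other features'
corrected importances are systematically negative (small real tree versus
broad shuffled trees) — a property of the statistic, not an artefact.

Per-feature Spearman correlations (average ranks on ties) between the
corrected-importance columns and the analog/digital CTC across contrasts
summarise which feature class each control strength recruits.

## Synthetic data

The generators emulate: a circular genome at ~1 gene/kbp (the real
chromosome's density — 2000 genes on 2 Mbp by default), optionally with
clustered gene density from a mixture of wrapped normals; a hub-dominated
disassortative TRN (20 hubs carrying weight 100:1 when edge sources are
drawn; 5000 edges); binding sites uniform or jittered (sd 5 kbp) around a
factor's targets; and contrast matrices from a two-mechanism mixture. Each
contrast receives `n_seed_events` (default 2) events: digital with
probability λ — a regulator with out-degree ≥ 10 (a "global regulator",
keeping event sizes homogeneous and comparable between mechanisms) is
perturbed and each of its targets called with p_d = 0.5 — otherwise analog:
genes within a circular ±15 kbp window of a uniform focal position are
called with p_a = 0.5. Background calls occur at rate ρ = 0.001. Called
genes receive |logFC| ~ N(4, 0.5) truncated above T_FC and random sign;
uncalled genes N(0, 0.5) truncated to |logFC| ≤ T_FC — so threshold calls
recover the ground truth exactly by construction (a `noisy` mode relaxes
this). Call sets are therefore ~20–60 genes of 2000, the relative scale of
real effective networks.

The gene density matters: at double the real density the GPN becomes so
dense that random null sets are almost always fully connected and the ratio
R inverts the analog signal. The defaults were chosen to keep the relative
density (mean GPN degree / node count) near the real chromosome's.

What the generators do **not** emulate: transcription biophysics,
supercoiling, operon structure in the synthetic genome, correlated
contrasts from shared experimental designs, platform noise, and missing
values. Passing tests on synthetic data therefore demonstrate that the
statistics recover planted structure under the stated mixture model, not
that real data contain such structure.

## Problem sizes used in the validation suite

The property checks run at desk scale, chosen to exercise every code path
with comfortable statistical margins: axis recovery on N = 400 planted
networks over 20 seeds (baseline ensemble 100 × 5000 swaps); generator
round-trips over 100 random specifications; CTC null calibration with 200
repetitions of 10,000-draw ensembles of 30-gene sets on a 500-node,
1000-edge hub-free random graph (mean total degree 4, the real TRN's
regime — hub-dominated graphs give the ratio statistic a heavy tail whose
sample SD over 200 repetitions is unstable and would measure the graph
rather than the calibration); the mechanism sweep over λ ∈ {0, 0.25, 0.5, 0.75, 1}
with 40 contrasts per value at 2000-null ensembles; and tree-importance
medians over 40 pure-analog and 40 pure-digital contrasts on 400-gene
genomes with 40 shuffles (the label-independence check uses 100 shuffles on
dedicated 60-sample datasets).

## Known limitations

* The axis detector reports the correlation-curve minimum even when no
  axis systematics exist; judge the minimum's depth against the curve.
* The ratio R is unstable when effective networks approach the size where
  random sets are fully connected; the `connected` statistic variant is
  preferable there.
* Operon-level feature aggregation (means over member genes) is an
  extension beyond the control-strength operon analysis and is flagged as
  such.
* Multi-replicon genomes, strand information, and GFF3/GenBank inputs are
  out of scope.
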