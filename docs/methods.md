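# Methods

## Scope and model

`mrnet` builds signed gene co-expression networks from a TPM expression
matrix and the downstream layers a functional-genomics database needs:
a GO-calibrated edge threshold, an interolog-projected PPI network, a
differential-expression overlay, and a KEGG-based enzyme-family screen.
Everything operates on plain TSV tables; a seeded simulator generates
all of them with planted ground truth, so the whole stack is testable
offline.

### Co-expression scoring

For genes A and B with TPM profiles X, Y over n samples the edge score
is the Pearson correlation

    PCC(A,B) = Σ(X−X̄)(Y−Ȳ) / ( √Σ(Xᵢ−X̄)² · √Σ(Yᵢ−Ȳ)² ),

computed on the TPM scale. Correlation alone is a poor edge criterion in
compendia where a few dominant expression programs make whole blocks of
genes inter-correlated, so the pair score actually thresholded is the
Mutual Rank

    MR(A,B) = √( Rank(AB) · Rank(BA) ),

the geometric mean of B's position in A's correlation-sorted partner
list and vice versa. MR is the standard condition-independent
co-expression score of the ATTED-style literature: reciprocal best
partners get MR = 1, and a pair that is merely swept along inside a
large correlated block gets a large MR even when its PCC is high.

Conventions (the mutual-rank literature is not fully standardized; these
are deliberate choices):

* **Self-exclusion.** A gene is not its own partner; rank 1 is the best
  non-self partner, so MR spans [1, G−1] and reciprocal best pairs hit
  exactly 1.
* **Ties** receive average ranks (keeps row rank-sums exact and MR
  unbiased under relabeling).
* **Constant genes.** A zero-variance profile has undefined PCC
  (division by zero); such genes are flagged, excluded from ranking and
  from networks, and reported, rather than being imputed a correlation.
* **Two ranking directions.** The positive network ranks partners by
  descending PCC; the negative network ranks by ascending PCC (rank 1 =
  most negative). A single descending ranking would give strongly
  anti-correlated pairs enormous ranks in a large genome and empty the
  negative network, so each sign gets the ranking that makes "MR small =
  strong for that sign" true.
* **Memory contract.** Matrices are dense genes × genes; above a
  30,000-gene cap the call refuses with an explicit error rather than
  silently thrashing. Sub-setting (e.g. expressed genes only) is the
  intended workaround at larger scale.

### Threshold calibration against GO priors

The network is read as a binary classifier of unordered gene pairs:
*predicted linked* iff PCC passes the sign-appropriate cutoff (strictly
`> c` or `< −c`) **and** MR < m. Ground truth is co-annotation:
biological-process GO terms whose gene count inside the expression
universe lies in [4, 20] are kept as *prior gene sets*, and a pair is a
true link iff the two genes share at least one such term. The size
window matters — tiny terms carry no pair signal, large generic terms
("metabolic process") would label essentially random pairs positive.

Only genes carrying at least one retained prior term enter the
calibration universe; unannotated genes cannot be labelled and would
otherwise be counted as (unknowable) negatives. The final network is
built over all genes regardless.

Sweeping m over a grid (default 5, 10, …, 100) at fixed PCC cutoff
(default 0.7) yields TPR/FPR per cutoff. "The AUC at one MR cutoff" is
taken to be the area of the one-knot ROC through (0,0), (FPR,TPR),
(1,1):

    AUC(m) = (1 + TPR(m) − FPR(m)) / 2,

which makes a per-cutoff AUC well defined; the trapezoidal area over
the whole sweep is also reported as a diagnostic (the two agree on how
good the sweep is, but only the former attaches a number to each
cutoff). The selected cutoff is the grid argmax, ties broken toward the
smaller cutoff (the sparser, more conservative network). Calibration is
deterministic; it is threshold selection, not hypothesis testing, so no
multiple-testing correction applies.

### Network construction and queries

Edges are exactly the pairs passing both strict inequalities; boundary
pairs (PCC = cutoff or MR = cutoff) are excluded. Networks are
undirected, stored once per pair in lexicographic order with pcc/mr as
edge attributes, and the positive and negative networks are edge-disjoint
for any positive PCC cutoff. Neighborhood queries return the induced
subnetwork within a given graph distance of a query gene (the typical
"show me everything co-expressed with my enzyme" use case).

### Interolog PPI transfer

A reference-species PPI edge (a1, a2) is projected to every target pair
(b1, b2) with b1, b2 orthologous to a1, a2 respectively. Many-to-many
ortholog relations expand as a full cartesian product by default —
orthogroup-derived maps rarely come one-to-one and dropping the
expansion silently would bias the projected network toward single-copy
genes; a `one_to_one` switch restricts to uniquely mapped genes in both
directions when a conservative network is wanted. Pairs collapsing onto
one target gene are dropped as self-loops and counted. Each projected
edge retains its source reference edge in a provenance table.

### Differential expression and overlay

The DEG caller works on the TPM matrix directly and is deliberately
transparent rather than count-model based (a TPM-level resource has no
raw counts to feed a negative-binomial model):

* log2 fold change: `log2((mean_a + 1)/(mean_b + 1))` — pseudocount 1
  TPM stabilises ratios of weakly expressed genes;
* p-value: Welch's unequal-variance t-test on `log2(TPM + 1)`;
* multiplicity: Benjamini–Hochberg across tested genes;
* gate: `up` iff log2FC ≥ 1 and adjusted p < 0.05 (both configurable),
  symmetrically `down`, else `ns`;
* floor: genes with mean TPM < 1 in both groups are reported `ns` with
  p = 1 and excluded from the BH pool, keeping tables aligned with the
  matrix instead of dropping rows.

Overlay is a pure join: each network node gets the DEG direction of its
gene (`up`/`down`, the red/blue display convention) or `absent` when
the gene is missing from the table.

### Pathway-family screen and tissue-elevated flags

A family map (label → KO identifiers + description keywords) assigns
genes from a KEGG annotation table to enzyme families; keyword matches
are case-insensitive whole-word. The shipped default covers the 18
enzyme families of L-ascorbate biosynthesis (HK, PGI, PMI, PMM, GMP,
GME, GGP, GPP, GDH, GLDH, MDHAR, DHAR, APX, GalUR, GulLO, ALase, GulDH,
MIOX) with canonical KEGG orthologies where they exist and keyword
rules otherwise; "DHA" is aliased to DHAR (the same reductase appears
under both abbreviations in the literature). The map is a plain YAML
config meant to be edited per genome.

"Elevated in tissue T" combines a dominance rule with a significance
rule: mean TPM in T at least `fold` (default 2) times the largest other
tissue mean, **and** an `up` call for T vs the pooled other tissues
under the DEG defaults. Either rule alone misfires (dominance alone is
noise-prone at low replication; the pooled test alone flags genes high
in two tissues).

## Synthetic data: what it emulates and what it does not

The generator plants co-expression modules with a one-factor model per
module on the log scale:

    log2(TPM_i + 1) = baseline_i + s_i·λ·f_m(sample) + shift_i(group) + ε,

with f_m ~ N(0,1) per sample, ε ~ N(0, σ), s_i = −1 for the
anti-correlated fraction of each module, and back-transformation to
TPM ≥ 0. Two same-sign module genes then have log-scale correlation
ρ = λ²/(λ² + σ²); the config states ρ directly (default 0.9) and λ is
solved from it.

Because the pipeline correlates **TPM**, not log-TPM, the exponential
back-transform shrinks correlations toward 0 (the classic lognormal
attenuation), and more strongly for negative ones. The default per-gene
dispersion is therefore modest — σ = 0.2 log2 units of replicate noise,
total per-gene sd ≈ 0.63 — so the planted log-scale ρ survives the
transform to within a few hundredths and the closed form above remains
the calibration of record. With a large dispersion the same planted
ρ = 0.9 would surface as TPM-scale correlation ≈ 0.65 and the planted
modules would straddle the 0.7 edge threshold by construction.

Default study conditions: 300 genes, 10 modules of 10, 30 samples in 5
tissue groups of 6 (a multi-tissue compendium in miniature), module 0
shifted +3 log2 (8×) in mature fruit as a planted fruit-ripening
program. Module genes carry their module's GO term, so truth terms have
exactly module-sized prior sets; background genes share 6 large generic
terms that the 4–20 window excludes — mimicking how real annotation
splits into informative small terms and uninformative large ones. The
interolog fixture draws an Erdős–Rényi reference PPI and a random
many-to-many ortholog map, and returns the exhaustively expanded target
network as an independent oracle. All generators are pure functions of
(config, seed).

What the simulator does **not** emulate: count-level sequencing noise
(no negative-binomial reads), library-size artifacts, correlated
background structure, GO term overlap/hierarchy, and ortholog-map
errors. Passing recovery tests therefore shows the pipeline is correct
and well-calibrated under its own model assumptions — not that a real
compendium will yield networks of any particular quality.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and symmetrised after
  `numpy.corrcoef` to absorb last-bit asymmetry; diagonals are exactly 1.
* Rank ties use `scipy.stats.rankdata` average ranks; NaN (self,
  undefined) entries are omitted from the ranking.
* `call_degs` p-values that come back NaN (identical values in both
  groups) are reported as 1.
* Fewer than 3 samples, fewer than 3 variable genes, an all-constant
  matrix, empty prior-term selections, and one-class pair labels are
  hard errors, never silent defaults.
* Thresholds are strict inequalities everywhere; the tie-break in
  calibration goes to the smaller MR cutoff.

## Problem sizes used in tests and the acceptance script

Formula-level checks run on 10–20-gene instances against scalar-loop
oracles at 1e-12; recovery checks run on the default 300-gene
conditions; the permutation-null check uses 1,000 label shuffles on a
60-gene instance; the DEG recovery fixture is 500 genes with 50 planted
4× shifts at 5 vs 5 replicates. These sizes keep the full suite in the
seconds range while leaving each statistic enough resolution for its
stated tolerance.

## Known limitations

* The dense correlation path is quadratic in gene count; the 30,000-gene
  cap is a refusal, not a sparse fallback.
* MR is only defined relative to the gene universe supplied: removing
  genes changes ranks, hence MR, hence the network. Calibrate and build
  on the same universe.
* The single-point AUC treats each MR cutoff as one operating point; it
  is not an ROC over sub-threshold orderings, and the two notions can
  rank cutoffs differently on pathological label structures.
* The DEG caller is a location test on log-TPM; it will be conservative
  relative to count-based models at very low expression.
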