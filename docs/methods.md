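# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `matncycle`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design emulated by the synthetic generator

The generator reproduces the *design* of a millimeter-resolution mat
study: seven 1-mm layers cut from each of three replicate cores, assayed
for nine qPCR/RT-qPCR markers (Bacteria-16S, Archaea-16S, nifH,
Archaeal-amoA, Bacterial-amoA, Nitrospira-nxrB, nosZ, nirS,
Planctomycetes-16S) on DNA and cDNA templates — 378 records per panel —
plus a four-layer metagenome gene catalog and HAO-family protein sequences
of known class.

**Noise model.** Copy numbers and coverages span many orders of magnitude,
so noise is lognormal: values are drawn as 10^(μ + ε), ε ~ N(0, σ) with
σ = `noise_sd_log10` on the log10 scale. The default σ = 0.15 is a
moderate qPCR replicate spread chosen as realistic for environmental
assays; replicate variance is a free parameter of the generator, not a
published value.

**Depth profiles.** Each marker's true mean log10 DNA copies per g follows
a Gaussian bump over depth, `lo + (hi − lo)·exp(−(layer − peak)²/(2·1.5²))`,
with the (lo, hi) decades and peak layer set from the published per-g
ranges and peak layers (e.g. nifH 10⁸–10¹⁰·⁵ peaking in Layer 2, nosZ
peaking in Layer 3 with expression peaking in Layer 4). cDNA means are the
DNA means plus log10 of a marker-specific expression-ratio profile that
peaks in Layer 3 or 4. The Gaussian-bump shape is a modeling convenience;
only magnitudes, peak positions, and trend signs are meaningful.

**Gene catalog.** Default per-category gene counts equal the published
inventory (60 fixation, 15 assimilatory, 38 DNRA, 52 *hao*, 121 *hcp*, 69
denitrification) plus 300 out-of-vocabulary background genes so that
nitrogen filtering is nontrivial. Coverage follows a per-category log10
slope per mm (fixation −0.144, i.e. 2.7-fold over layers 1→4;
assimilatory −0.16; DNRA +0.20; *hao* +0.12; *hcp* +0.10; denitrification
+0.08; background 0), with lognormal noise. Every generated record traces
to a `GroundTruth` entry.

**RNG discipline.** Each output table has its own stream, seeded as
`default_rng([seed, offset])` with a stable per-table offset, so adding a
table never perturbs the others; identical configurations reproduce
byte-identical outputs.

**What the generator does not emulate.** Read-level sequencing (no FASTQ,
error models, assembly or annotation noise), extraction-efficiency biases
between layers, real between-marker covariance of expression, below-LOD
censoring mechanisms beyond a fixed threshold, and real HAO sequence
divergence (see below). Tests that pass on synthetic data demonstrate the
*statistics and accounting* are correct, not that biological conclusions
would replicate on raw reads.

## qPCR statistics

Copies are normalized both per g of mat and per ng of nucleic acid
(extraction efficiency differs between the bases; both are carried and the
basis is an explicit option everywhere). Below-detection-limit records are
flagged, never dropped at generation; statistics exclude them rather than
substituting LOD/2.

The cDNA/DNA ratio aggregates replicates *before* the quotient (ratio of
means, default `mean`) — robust when a replicate DNA value is near zero;
median aggregation is the alternative. Layers whose DNA aggregate is below
LOD or zero yield no ratio, with a reason code instead of an infinity.

Kruskal–Wallis uses midranks with tie correction and the χ²ₖ₋₁
approximation (via `scipy.stats.kruskal`); all-identical data is a defined
no-separation case (H = 0, p = 1), not an error. The χ² p-value is
conservative at very small group sizes (with 3 replicates per layer the
empirical type-I error is ≈ 2% at α = 0.05, rising to the nominal 5% by
~10 per group); the suite asserts calibration at sizes where the
asymptotic approximation is the operative claim. Conover–Iman pairwise
p-values are reported unadjusted by default, matching long-standing
PRIMER-era practice for this assay family; a Holm option exists. The
compact letter display uses insert-and-absorb (split every letter
containing a significant pair, then absorb subsets), giving the minimal
letter set with letters ordered by descending group mean, ties by layer
index.

## Nitrogen accounting

The packaged KO vocabulary covers the nitrogen-metabolism KOs of the six
pathway categories (nifDHK; nirA/narB/NRT; nrfA/nrfH; hao K10535; hcp
K05601; napAB, narGZH Y, narIV, nirKS, norBC, nosZ). Subunits that share a
KO model keep the combined symbol (K00370 = narG/narZ/nxrA, K00371 =
narH/narY/nxrB) because the annotation cannot separate them.

N-CPM divides by the summed coverage of *nitrogen* genes only (an
all-genes denominator is a config option); the defining invariant — layer
sums exactly 10⁶ — is asserted on random tables. FDIC is computed on N-CPM
values by default. The two bases do not give identical FDIC when layer
totals differ; the defining identity (per-gene depth shares summing to 1)
holds on either basis and is what the suite asserts. narI/narV genes act
in both denitrification and DNRA; they are counted once, under
denitrification, so categories partition the catalog, and the summary
carries a shared-genes note. Coverage input is taken as already
length-normalized per gene; no length correction is applied.

Fold changes between layers are means over the selected genes,
`fold = mean(layer_a) / mean(layer_b)`; with `layer_a` the shallower
layer, fold > 1 is labeled "decreasing" with depth (flat within a
configurable tolerance, default 5%). A zero denominator reports an
infinite fold, still "decreasing" under the same semantics.

## Community statistics

Similarities use the PRIMER 0–100 convention; clustering and ordination
convert to dissimilarity (100 − S)/100 internally. Sample-total
standardization (rows to percentages) precedes Bray–Curtis by default in
the pipeline. An all-zero sample pair has undefined similarity; the
configurable convention defaults to 0 with a warning.

Group-average (unweighted) clustering computes inter-cluster distances as
means of the original pairwise dissimilarities, with deterministic
lexicographic tie-breaking on member-id tuples; heights are monotone and
match SciPy's average linkage exactly on random matrices.

SIMPROF tests each node root-down, stopping below non-significant nodes;
nodes with < 3 samples are untested (p = 1). The observed profile is the
ordered vector of pairwise Bray–Curtis similarities; one batch of
permutations (values shuffled independently within each variable across
the node's samples) estimates the mean null profile, a second batch gives
the null distribution of π = Σ|profile − mean profile|, and p is the plain
proportion of π* ≥ π. Defaults: 999 + 999 permutations, α = 0.05, seed
recorded in output. Empirical null rejection at the root is within ±2% of
α in the suite's 200-simulation check.

NMDS wraps scikit-learn's SMACOF non-metric MDS (isotonic regression of
distances on dissimilarities, Kruskal stress-1 reported), run as
independent single-init fits under explicitly seeded restarts so the
returned configuration provably has the best stress among restarts.
Defaults: k = 2, 50 restarts, 300 iterations, convergence 10⁻⁶,
coordinates centered. Vector overlays are Spearman correlations of each
variable with each axis, rescaled so the longest vector touches the unit
circle; constant variables are skipped.

The Spearman pair table (markers × markers and markers × environment)
drops incomplete pairs below 3 observations with a warning; p-values use
the t approximation.

## HAO classification

The packaged reference alignment is **synthetic** (so named in its
filename and sidecar): nine rows in four labeled classes (2 AOB-HAO, 1
anammox-HAO, 4 εHao, 2 nitrate-reductase-like) generated from a common
ancestral sequence with class-level divergence, an AOB/anammox-specific
4-column insert, the anchor tyrosine in the AOB/anammox rows, and the
tryptophan + Met−8 motif in the εHao and nitrate-reductase-like rows. It
reproduces the *motif and clade structure* of the real reference set, not
real sequences; for real analyses load an alignment plus YAML sidecar
(`anchor_ref`, `anchor_pos`, `class_labels`). The anchor position is data,
never hard-coded: the packaged default is ungapped position 63 of the
synthetic anchor row.

Queries are aligned to the frozen reference profile: position-specific
scores are BLOSUM62 averaged over column residue frequencies (gaps
excluded), with affine gaps costing 11 + k·1 for length k — terminal gaps
included. Reference columns are immutable; query insertions are recorded
separately and excluded from column indexing. X or nonstandard residues
score 0 (neutral) and produce an `ambiguous` call if at the anchor column.
"Eight residues upstream" is evaluated in the query's own ungapped
coordinates.

Trees use p-distance (mismatches over columns with no gap in either row)
and Saitou–Nei neighbor joining with deterministic lexicographic
tie-breaking; negative branch lengths are clamped to zero with the deficit
moved to the sibling so the pair sum is preserved; the final three
clusters join at a trifurcation. For clade reading the tree is midpoint
rooted (longest leaf-to-leaf path, ties lexicographic) — nested clades on
an unrooted NJ tree are otherwise ill-defined — and each query takes the
class of the first rootward ancestor containing a reference, `unresolved`
if that clade mixes classes. No alignment/tree method is claimed optimal;
the choice (profile alignment + p-distance + NJ) is deterministic,
dependency-light, and sufficient for clade-level statements, which is all
the classifier asserts.

## Pipeline and reproducibility

Tables are tab-delimited UTF-8 with '.' decimals; layers are 1-based 1-mm
slices from the surface. Floats are serialized at 17 significant digits
and read back with round-trip parsing, so rerunning a configuration
reproduces every numeric output byte-for-byte (the report timestamp is the
only difference). Every random operation's seed appears in the config echo
of `report.json`. Stages are isolated: a failure is recorded without
corrupting completed outputs.

Problem sizes in the test suite and acceptance script (e.g. 6 × 10 null
matrices with 999 permutations and 200 simulations for SIMPROF
calibration, 50 random trees for NJ recovery, 20 synthetic proteins for
motif recovery) are chosen to make the statistical claims testable at desk
scale while keeping the default run short.

## Known limitations

* The N-CPM denominator definition (nitrogen-only) is fixed by its
  layer-sum invariant; an all-genes variant is available but changes the
  scale of every value.
* The Conover–Iman implementation reports unadjusted p-values by default;
  multiplicity control is opt-in.
* SIMPROF p-values are plain permutation proportions; with B = 999 the
  smallest attainable p is 0 rather than 1/(B+1).
* The profile aligner is O(L·q) per query in pure Python — fine for
  hundreds of sequences, not for proteome-scale input.
* Clade assignment depends on midpoint rooting; a pathological tree whose
  diameter lies within one class could misroot. Reference classes well
  separated from each other (as in the packaged set) avoid this.
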