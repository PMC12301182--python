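# Methods

This note documents the models, conventions and parameter choices behind
`hgtbench`, and what the synthetic benchmark does and does not show about
real genomic data.

## Frame of reference

All analyses live on a rooted species tree whose branches are named by their
child node; the root has no branch. Gains are events (family, recipient
branch, optional donor branch, confidence). Gene positions are the 0-based
indices of each chromosome's ordered gene list; "intervening genes" between
positions p < q is q − p − 1; chromosomes are linear (no wraparound
neighbors, consistent with the null model's boundary approximation, below).
Gain-event tables group into an `InferenceSet`: a map from a stringency
value (confidence threshold, penalty ratio, or MAD multiple, depending on
the method) to an event collection.

## Co-acquisition evaluation

Only gains on terminal branches are evaluable, because gene positions exist
only in extant genomes. Each gained family is expanded to all of its member
genes in the recipient; all unordered cross-family gene pairs on the same
chromosome count as co-acquisitions (the simplest faithful reading of "pair
of genes" for multi-copy families). Two small-number guards are applied:
chromosomes with fewer than 1,000 genes are dropped, and stringency levels
with fewer than 20 pairs are marked excluded.

The null expectation for the neighbor fraction is
2·Σᵢ(t+1)(cᵢ/gᵢ) / Σᵢcᵢ with cᵢ = pairs and gᵢ = genes on chromosome i. Two
conventions deserve note. First, cᵢ counts *pairs* (not gained genes); this
is declared, not derived. Second, the per-gene neighbor probability
2(t+1)/gᵢ ignores chromosome ends; the formula is exact when positions are
drawn independently and uniformly with circular distance, and the package's
Monte-Carlo oracle tests it under exactly that geometry (the linear-geometry
bias is O(t/g), negligible at g ≥ 1000 but larger than Monte-Carlo noise at
10⁵ replicates, so the oracle must match the formula's own geometry to be a
fair test of the algebra). For multi-chromosome inputs the formula divides
the summed per-chromosome *rates* rather than the summed expected *counts*
(which would carry a second factor of cᵢ); the implementation follows the
stated formula, and the distinction vanishes for the single-chromosome
simulations used throughout.

Co-transfer flags are tri-state: a pair is a co-transfer if both families'
gain events carry donors and the donor sets intersect; not a co-transfer if
both carry donors that differ; unknown if either is donorless. Both
co-transfer percentages (co-transfers, neighboring co-transfers) use all
co-acquisitions as the denominator, so their ratio is the share of
co-transferred pairs that are neighbors.

## Genome-evolution simulator

The species tree is Yule (pure birth, rate 1 per lineage), ultrametric,
depth-normalized to 1. Genomes evolve in one preorder pass. Per branch of
length L: (1) each gene is lost independently with probability `p_loss`
(neighbors close ranks); (2) Poisson(`hgt_rate`·L) segmental transfers; (3)
Poisson(`rearr_rate`·L) translocations of geometric-length segments. A
transfer picks a donor branch uniformly among branches off the recipient's
root path, a uniform segment start in the donor genome, and a
Geometric(`p_seg`) length truncated at the donor's end; with probability
`p_novel` the segment's families are replaced by brand-new ones
(taxon-restricted influx). Because the simulation is a single preorder pass,
an unvisited donor has no genome yet; the segment is then read from the
nearest already-evolved ancestor of the donor. Donor choice is not
time-consistent — acceptable because the evaluation never consults donor
timing, only donor identity.

Defaults (chosen once as a realistic desk-scale regime; the benchmark's
logic does not depend on them): root genome 1,200 families on one chromosome
(comfortably above the 1,000-gene chromosome filter after losses),
`p_loss` = 0.01, `hgt_rate` = 8 per unit branch length, `p_seg` = 0.4 (mean
segment 2.5 genes, 40 % single-gene transfers), `rearr_rate` = 0.5,
`p_novel` = 0.1. Under these settings a 30-taxon simulation yields roughly
1–3·10³ co-acquisition pairs with a neighbor fraction an order of magnitude
or more above the null.

`corrupt_inference` degrades a truth set for parameter-recovery studies:
true events are dropped with probability `fnr`; false events — uniform
(family, terminal branch) pairs outside the truth — are added at
fpr/(1−fpr) times the retained count, so `fpr` is the expected false
fraction. Confidences are Beta(8,2) for true and Beta(2,8) for false events;
the deciles of the pooled confidences define a nested stringency sweep in
which raising the threshold raises precision.

Sequences are order-0: each taxon draws a GC content uniform in
[0.35, 0.65]; native genes are i.i.d. from it; genes of families gained on
the terminal branch get GC displaced by ±`shift` (sign per transfer event,
clamped to [0.05, 0.95]), default gene length 500 nt. There is no
substitution model, no codon structure, and no amelioration of transferred
genes over time.

## Asymmetric Wagner parsimony

Per family, a Sankoff DP over states {0, 1} with costs gain = r, loss = 1
finds the minimum-cost labeling of the binary presence profile on the tree;
r is the stringency. Conventions the underlying tools leave unstated, fixed
here: the root's state is chosen to minimize total cost *including* a stem
charge of r if the root is present (reported as a gain with the root label
as recipient, so every present family is gained somewhere); traceback ties
prefer absence, the conservative choice. Copy numbers are reduced to
presence/absence — the evaluation consumes (family, branch) gains only. As r
exceeds the leaf count the reconstruction becomes Dollo-like (exactly one
gain per family). The DP is verified exact against exhaustive enumeration on
all instances with ≤ 6 leaves in the test suite.

## Wn typicality detector

Per taxon, the background is the pooled k-mer count vector of all gene
sequences plus their reverse complements (strand symmetry), with a
pseudocount of 0.5; k defaults to 8 as in large-genome practice, but tests
and desk-scale runs use k = 3–4, where k-mers are not undersampled on 500-nt
genes. A gene's typicality is the per-window log-likelihood ratio
(1/W)·Σ_w c_w·log₂(f_genome(w)/f_gene(w)) — the negative KL divergence of
the gene's k-mer composition from the background, in bits. It is 0 for a
background-identical gene and decreases for deviation in *either* direction;
a plain log-probability under the background was rejected because it is
maximized by low-entropy sequences concentrated on the background's modal
k-mers and therefore ranks some compositionally shifted genes *above* native
ones.

Detection: scores are sorted ascending; the curve is smoothed with a
Savitzky–Golay filter (order 3). The window length is selected
automatically: candidate windows (5, 7, …, 101) are tried in ascending
order, and the RMSE between successive smoothed curves is tracked — while it
decreases, longer windows are still removing noise; when it stops decreasing
(two candidates' patience), further lengthening distorts the signal, and the
last improving window is returned. An exactly polynomial curve returns the
smallest window; a curve shorter than the smallest candidate is left
unsmoothed. This operationalizes "the longest filter whose RMSE stops
decreasing"; note that the naive reading (RMSE of smoothed vs. original)
cannot select long windows, because that RMSE grows monotonically with
window length.

The flagging rule compares the smoothed curve's double derivative (two
applications of `numpy.gradient`) against s·MAD₀, where MAD₀ is the median
absolute double derivative of the *raw* curve — the noise scale of the
double derivative around zero. Using the smoothed curve's own MAD instead
makes the threshold scale-free in the wrong sense: under a pure null the
smooth quantile curve's tail curvature always exceeds a few times its own
(tiny) median curvature, and ~15–25 % of genes get flagged regardless of
signal. Against the raw-noise scale, the null flags ~2–4 % at s = 4 while a
0.3 GC-shift knee is detected with recall ≈ 1. The cut index is the largest
lower-half position exceeding the threshold; genes ranked below it are
flagged; the flag set shrinks monotonically in s (sweep 4–13). MAD₀ = 0
(perfectly smooth curve) flags nothing. Taxa with fewer than 30 genes are
skipped.

## Method comparison

Events are keyed by (family, recipient branch), ignoring donors, so
implicit, explicit and parametric methods are mutually comparable. Method
similarity is the Overlap Coefficient |A∩B|/min(|A|,|B|) maximized over the
full Cartesian product of the two methods' stringency levels (empty levels
skipped); 1 − maxOC is the distance; UPGMA (size-weighted average linkage,
merge height = distance/2) clusters the methods, with ties broken
lexicographically for reproducibility.

## What the synthetic benchmark does and does not show

The simulator realizes the premise the evaluation tests — segmental
transfers produce neighboring co-acquisitions — so passing tests demonstrate
that the *statistics and machinery* behave as designed (the neighbor
fraction tracks the false-positive rate; stringency sweeps act as intended;
the null model is exact for random placement). They do not certify
biological realism: real genomes have operon structure and rearrangement
hotspots that correlate gene order with function, amelioration erodes
compositional signal over time, and gene families are fuzzier than the
simulator's labels. Absolute neighbor percentages from the simulator are
therefore not comparable to empirical values; only orderings and
null-relative enrichments are meaningful. Problem sizes throughout (tens of
taxa, ~10³-gene genomes, 10–20 replicate seeds, k = 3–4) were chosen so the
full suite runs on a laptop-class machine while every statistical check
retains comfortable margins.
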