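# Methods

`devconn` analyzes structural brain networks built from diffusion-MRI
tractography in a developmental case-control setting: preterm-born children
with intrauterine growth restriction (IUGR) versus preterm controls, observed
cross-sectionally around 1, 6 and 10 years of age. This note records the
models, conventions, and numerical choices the package commits to, and what
its synthetic cohorts do and do not emulate.

## Connectome construction

Nodes are anatomical parcels. The default inventory follows the AAL scheme:
90 cortical parcels plus a 16-parcel cerebellar inventory that is merged by
laterality into left cerebellum, right cerebellum and vermis, giving 93
network nodes. Merging is name-driven (`_L`/`_R` suffix, `Vermis` prefix)
and configurable, so other cerebellar inventories work unchanged; missing
cerebellar labels produce a warning and an identity merge (or an error in
strict mode).

Two regions are connected if at least one streamline has one endpoint in
each (self-loops excluded). Endpoint assignment uses the containing voxel's
label, with a nearest-labeled-voxel fallback within a 2-voxel Euclidean
radius (lowest label on ties): deterministic tractography stops near the
grey-white interface, so endpoints frequently sit in thin unlabeled white
matter next to the target parcel. Streamlines with an endpoint outside the
grid or unassignable, and self-loops, are counted in a discard log.

Three variants are produced per subject:

* **binary** — 1 iff any accepted streamline links the pair;
* **FA-weighted** — the unweighted arithmetic mean of the per-streamline
  mean-FA values over the streamlines linking the pair (streamline length is
  not used as a weight);
* **FA-normalized** — the FA-weighted matrix divided by its total network
  strength *S*, the sum of weights over undirected edges, each edge counted
  once. The output's total strength is exactly 1 (floating tolerance 1e-12)
  and weight ratios are preserved; normalization is invariant to uniform
  rescaling of the input. An all-zero matrix cannot be normalized and raises.

Group-average networks are entrywise means with absent edges counted as 0.
High-FA display edge lists use a strict threshold (weight > tau, default
tau = 0.3).

## Graph metrics

All metrics follow the Rubinov–Sporns conventions. Degree and strength are
node means of neighbor counts and incident-weight sums. Both "average nodal
strength" and "strength/(n-1)" normalizations appear in the connectomics
literature; the package reports nodal strength and exposes
`mean_edge_weight` for the other convention.

Path length is hop count (binary) or the minimal sum of step lengths with
length = 1/weight (weighted); stronger connections are shorter. Global
efficiency is the mean of 1/d over ordered pairs, disconnected pairs
contributing 0; under uniform weight scaling w -> c·w it scales exactly as
c·E. Local efficiency is the node-mean of the efficiency of each node's
neighbor-induced subgraph (node excluded, original weights retained, no
per-subgraph renormalization); nodes with < 2 neighbors contribute 0.
Binary clustering is the standard triangle fraction; weighted clustering is
the Onnela geometric-mean triangle intensity computed on the **raw** weights,
which are assumed to lie in [0, 1] — true for FA and for normalized weights.
No per-graph maximum-weight rescaling is applied: this matches the Brain
Connectivity Toolbox convention, keeps "all weights = 1" exactly equal to
the binary metrics, and (unlike a scale-invariant rescaled form) lets the
normalized variant's clustering carry the 1/S factor, which is what makes
its group direction opposite to the FA-weighted variant's. networkx's
rescaled Onnela value times the maximum weight reproduces our value exactly,
which the test suite uses as an external cross-check.

No thresholding or density matching precedes metric computation; raw
networks are compared. Shortest-path kernels are exact Floyd–Warshall
implementations JIT-compiled with numba; the test suite verifies them to
1e-9 against naive pure-Python oracles on graphs up to 20 nodes.

The 11-entry per-subject metric table is: binary degree / global efficiency
/ local efficiency / clustering; FA-weighted strength / global efficiency /
local efficiency / clustering; FA-normalized global efficiency / local
efficiency / clustering.

## Statistics

Case-control comparisons are OLS general linear models with gender (0/1) and
maternal education (3-level ordinal, single numeric column) as cofactors and
gestational age at birth (weeks) as a covariate; metric responses add age at
scan, score responses age at test. The reported effect is the IUGR-indicator
coefficient with a two-sided t-test; with no covariates this reduces exactly
to the pooled-variance two-sample t-test. Significance is declared at
p < 0.05 and a trend at p < 0.1; no multiple-comparison correction is
applied, and raw p-values are always emitted so users can correct
themselves. Missing covariates trigger logged listwise deletion.

Metric-score association: scores are residualized on age at test, metrics on
age at scan, then the Pearson correlation of the residuals is computed after
removing gender, GA, maternal education and group (partial correlation on
the pooled sample; per-group correlations are out of scope). The p-value
uses t = rho·sqrt(df/(1-rho²)) with df = n - 2 - #confounders; whether one
should subtract the confounder count is convention-dependent, so both df and
n are reported.

Developmental trajectories are per-group least-squares quadratics in age
(years, continuous). The default fits subject-level points; fitting to
per-age means is available, in which case 3 distinct ages are interpolated
exactly. Trajectories are descriptive; no between-group coefficient test is
offered.

## Synthetic cohorts

The generator exists so the full pipeline can be exercised end-to-end with
known ground truth. It emulates the *statistical* structure of the study
cohorts, not anatomy.

**Connectomes.** Each subject's binary topology comes from a latent ring
model: nodes get positions on a circle; a pair's connection propensity mixes
ring proximity with uniform noise; the E pairs with highest propensity are
realized, E being set by the subject's degree target (Gaussian between-
subject jitter). One *structure* parameter in [0, 2] interpolates from
Erdős–Rényi (clustering ≈ density, ~0.65 here) through a windowed ring graph
(clustering ≈ 0.75) to a regime where nodes are progressively relocated into
five tight random clumps (clustering up to ~0.9). Structure is calibrated
once per design cell by bisection (32 Monte-Carlo replicates with common
random numbers per evaluation, cached) against the cell's binary clustering
target. Because these dense graphs have diameter 2, binary global efficiency
is pinned by density (E ≈ (1+p)/2) and local efficiency by clustering
(≈ (1+C)/2), so matching degree and clustering reproduces the published
efficiency levels without separate tuning — the published values are in fact
mutually consistent with exactly these diameter-2 identities, which is what
makes this low-dimensional calibration possible.

Edge FA values are Gaussian around a per-subject mean (clipped to
[0.1, 1.0]; the 0.1 floor encodes the tractography FA stop threshold, its
only role in the package). The per-subject FA mean carries the
between-subject strength variance; the within-subject SD defaults to 0.045,
the value at which weighted shortest paths exploit strong edges just enough
to reproduce the published FA-weighted global-efficiency level given the
degree and mean-FA targets. Cell defaults encode the published group
means/SDs: sample sizes (7/8, 8/10, 8/8 per age), GA and age distributions,
binary degree and clustering, and mean edge FA derived from the strength
values (at 1 year strength is average nodal strength; at 6/10 years the
printed values are two orders smaller and are interpreted as
strength/(n-1)).

**Direction of group differences.** Nothing about the normalized variant is
injected: dividing by total strength S makes its efficiencies scale as 1/S,
so the IUGR cells' lower degree and FA produce *higher* normalized
efficiencies automatically — the same mechanism the normalization is
designed to expose in the real data.

**Scores.** Each score is mean + confounder contributions (fixed small
effects for age, GA, gender, education, and a -3-point IUGR effect) + a term
linear in one named network metric + Gaussian noise, with the loading and
noise variance solved from the target age-residualized partial correlation
and a 100/15 standardized scale. Default models inject the reported
significant 1-year associations (e.g. rho = 0.9001 between a socio-emotional
scale and FA-weighted strength); recovery is checked empirically at n = 500.

**Known limitations.** (i) Metrics across subjects are independent given the
cell targets; no covariance model beyond the shared latent structure is
imposed. (ii) The emergent FA-weighted local efficiency runs ~5% below the
published level (~0.286 vs 0.301 at 1 year, about 1 generated SD): the
published local/global efficiency ratio implies FA-topology covariance
(locally elevated FA within modules) that this latent family does not
express; a distance-coupled FA variant was evaluated and rejected because it
only lowers global efficiency without raising local. (iii) Normalized-variant
magnitudes are ~1/S ≈ 3e-4, far below the published ~0.15: the published
normalized efficiencies are not reproducible from unit total strength spread
over ~2800 edges under the inverse-weight distance convention, so the
package implements the stated normalization rule and matches only the
direction of the group differences. (iv) Cohorts are cross-sectional;
longitudinal within-subject correlation is not modeled. Passing tests
therefore demonstrate correct mechanics and faithful first- and
second-moment structure, not anatomical realism.

## Problem sizes and tolerances

Exactness claims (normalization total, round-trips) are asserted at 1e-12;
metric-vs-oracle agreement at 1e-9 on 50 random graphs up to 20 nodes;
GLM-vs-t-test equivalence at 1e-10. Type-I error of the group test is
checked over 1000 direct-GLM replicates and 500 full generator-to-test
replicates (24-30-node networks keep these fast), with acceptance bands
[0.03, 0.07] and [0.02, 0.08] at nominal 0.05. Calibration checks generate
50 subjects per 1-year cell at the full 93 nodes; directional reproduction
runs 100 seeded cohorts of 50 + 50 subjects at 93 nodes on the 1-year
design, the cell where all six required sign differences are present and the
binary differences are reported significant. Generator self-calibration
(degree-to-density and clustering bisection) is deterministic and cached per
design cell. Score-recovery checks use 30-node networks with degree targets
rescaled by 30/93, which leaves the injected partial-correlation machinery
unchanged while keeping runtimes in seconds.
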