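# Methods

## Individual morphological covariance networks

A subject's structural MRI, after tissue segmentation, spatial normalization
and modulation (outside this package's scope — the pipeline consumes the
resulting gray-matter maps), assigns every voxel a modulated gray-matter
(GM) value. Partitioning the brain with a 90-region parcellation
(AAL cerebrum convention; the region table ships with the package) turns
each region into an empirical distribution of GM values. The individual
morphological covariance network treats regions as nodes and the similarity
between two regions' GM value *distributions* as the edge weight:

1. each region's distribution is estimated by a Gaussian-kernel KDE with
   Silverman's rule-of-thumb bandwidth
   `h = 0.9 min(sd, IQR/1.34) n^(-1/5)` (a configurable scalar multiplier
   is exposed);
2. for a region pair, both densities are evaluated on one shared uniform
   grid of 128 points spanning the union of the two sample ranges, padded
   by 3 times the larger of the two bandwidths so the kernel tails are
   captured;
3. densities are floored at 1e-10 and renormalized (trapezoid) to integrate
   to 1, which keeps the divergence finite where one density underflows;
4. the symmetrized Kullback–Leibler divergence
   `D = KL(p‖q) + KL(q‖p)` is computed by discrete summation
   (density × grid spacing) and mapped to the edge weight
   `S = exp(−D) ∈ (0, 1]`.

`S = 1` iff the two distributions coincide on the grid, and `S` decays
monotonically as distributions separate (a property test verifies this on
Gaussian pairs). The exponential-of-negative-divergence form is the
standard choice for this construction: symmetric, bounded, and divergence 0
maps to similarity 1.

The KDE grid size, bandwidth multiplier, padding and the density floor are
configuration, not science: defaults were fixed once on numerical grounds
(grid resolution well below any bandwidth; floor far below attainable
density values) and the discrete divergence is validated against the
closed-form Gaussian result `(μ₁−μ₂)²/σ²` to within 2%.

Binarization keeps the top `K = floor(s·R(R−1)/2)` off-diagonal weights at
sparsity `s`, with ties broken by ascending (row, column) order so the edge
set is identical across platforms. Note `floor` means no `s < 1` yields the
complete graph — at `s = 0.05` and `R = 90`, `K = 200` exactly. The
analysis grid is `s = 0.05 … 0.39` in steps of `0.02` (18 levels), and
per-metric summaries over the grid use the trapezoidal area under the curve.

## Graph measures

All measures operate on undirected simple binary graphs:

- **Cp** — mean triangle-based clustering; nodes of degree < 2 contribute 0.
- **Lp** — mean shortest-path length over *connected* ordered pairs; the
  number of disconnected pairs is reported alongside. An edgeless graph has
  no Lp and is flagged NaN rather than raising.
- **Eg** — mean of 1/d over all ordered pairs with 1/∞ = 0; **Eloc** — mean
  over nodes of Eg of the neighborhood subgraph. These are the usual
  connectome conventions for possibly disconnected graphs.
- **assortativity** — Pearson correlation of endpoint degrees over edges
  (both orientations); NaN for regular graphs (zero variance).
- **modularity** — best Louvain partition quality over 10 seeded restarts.
- **nodal degree** and **betweenness** — betweenness is reported as raw
  source–target pair counts (each unordered pair once); a normalized
  option divides by (R−1)(R−2)/2.

Distances come from breadth-first search (scipy.sparse.csgraph); degree,
clustering, efficiency and assortativity are direct array computations, and
betweenness uses networkx's Brandes implementation. All five are
cross-checked in the test suite against independent brute-force oracles
(Floyd–Warshall; exhaustive shortest-path enumeration) to 1e-12 on random
small graphs.

**Small-worldness.** gamma = Cp/⟨Cp_null⟩ and lambda = Lp/⟨Lp_null⟩ over an
ensemble of degree-preserving rewired graphs (default 100 nulls, 10 swap
attempts per edge), sigma = gamma/lambda. The null model is the standard
double-edge-swap randomization — (a–b),(c–d) → (a–d),(c–b) when no
self-loop or duplicate arises — implemented as a numba-compiled kernel and
seeded, so ensembles are reproducible. A graph that admits no legal swap is
returned unchanged with a warning. Small-world organization means
gamma ≫ 1, lambda ≈ 1, sigma > 1; Watts–Strogatz graphs in the canonical
regime satisfy this and Erdős–Rényi graphs (their own null) give
sigma ≈ 1, both verified as stochastic acceptance properties.

## Voxelwise morphometry statistics

The group comparison at each voxel is a general linear model
`[intercept | group indicators | covariates]` with a partial F for the
group factor against the covariate-only reduced model,
df = (G−1, N−G−C). All voxels share one design, so the model is solved for
every in-mask voxel in a single vectorized pass. Maps are smoothed first
with a normalized Gaussian kernel specified as FWHM in mm
(sigma = FWHM/2.3548 per axis, divided by the voxel size; constant-zero
boundary, kernel support 6 sigma), and the analysis mask is "GM > 0.1 in at
least 90% of subjects" (both configurable — the mask convention is a
package choice, as is the nearest-neighbor rule for resampling label images,
which must never be interpolated continuously).

Thresholding is Benjamini–Hochberg FDR over all in-mask p-values at
q = 0.05, followed by a cluster-extent filter keeping connected components
*strictly larger* than 30 voxels (the literal reading of a ">30" rule)
under 18-connectivity (faces + edges, the common SPM convention;
6/26 available). Surviving clusters report size, peak statistic and peak
world-mm coordinates; post-hoc comparisons are pooled-variance two-sample
t-tests on per-subject cluster mean GM, Bonferroni-corrected over the three
group pairs, without covariates.

**Covariate policy.** Symptom severity (PANSS) and illness duration exist
only for patients, so a three-group model literally "adjusted" for them is
not estimable. The default policy drops any covariate with missing values
from the model (reporting which); mean-imputation and strict-error modes
are provided. Patient-only contrasts can use the covariates in full.

## Group and clinical statistics

Demographic tables are reproduced from summary statistics alone: one-way F
from between/within sums of squares reconstructed from per-group
means/SDs/ns, and two-sample t with pooled variance. Pooled (Student)
rather than Welch t is the default because it is what such tables report —
from the printed patient summaries it gives t(duration) = 2.88,
t(PANSS) = 6.13, t(MOAS) = 12.00, where Welch would give ≈ 2.65 for
duration. Values recomputed from a rounded printed table carry the input
rounding: ±0.005 on means/SDs propagates to about one unit in the last
printed digit of t or F, which is the agreement the tests require.

Clinical correlations are Pearson by default (Spearman available), computed
over patients only, with BH-FDR across the entire family of
(measure × score) pairs in one call; constant vectors are flagged and
excluded from the family. Calibration is verified by simulation: the group
partial F rejects at the nominal rate under the null ([0.035, 0.065] band
at α = 0.05 over 1000 replicates), and the mean false-discovery proportion
of BH stays at or below q. The FDR simulation plants 4 strong effects in
each family of 8: under a fully null family BH attains FDR = q *exactly*
(independent continuous p-values), so an all-null design cannot
distinguish control from failure — with planted effects the expected FDP
is q·m₀/m = 0.025 and the bound is informative. The all-null case is kept
as a separate two-sided calibration test (mean FDP in [0.03, 0.07]).

## Synthetic cohorts and what they do (not) show

The generator emulates the three-group case-control design this pipeline
targets — 22 HC / 23 NSZ / 18 VSZ males, matching the study whose
demographic table calibrates the clinical scores — with one latent severity
per subject (0/1/2 group means, within-group SD 0.3) driving all planted
effects:

- **Images**: a Voronoi parcellation of a spherical "brain" (32³ grid, 2 mm
  voxels, 90 regions, every region ≥ 20 voxels); region means uniform in
  [0.4, 0.7]; voxel noise SD 0.1; the planted (largest) region's mean is
  scaled by `1 − 0.10·severity`, so group means fall ≈ 1 : 0.9 : 0.8
  there and nowhere else. Values are truncated at 0 (rate recorded).
- **Networks**: per-subject Watts–Strogatz graphs (90 nodes, degree 8)
  with rewiring probability 0.05/0.15/0.30 per group plus
  0.10·(severity − group mean), so efficiency rises and path length falls
  from HC to VSZ; one designated node loses `round(1.5·severity)` edges
  (re-inserted elsewhere, preserving the 360-edge count), planting a
  nodal-degree deficit.
- **Clinical scores**: PANSS/MOAS/duration per patient group are
  mean + SD × (group-standardized mix of severity and noise, coupling 0.7),
  so group means and SDs match the demographic table exactly while scores
  track severity; HC scores stay missing; durations truncate at 0.

Image-level and network-level generators are separate (topology of
KDE-built networks is only indirectly controlled by the image generator),
but share the severity vector, so cross-domain correlation tests have
coherent ground truth: GM and the planted node's degree correlate
negatively, and Eg positively, with symptom/aggression scores — the sign
pattern the pipeline must recover.

The effect sizes above are deliberately strong relative to the noise
(planted-region Cohen's d ≈ 2–3 at the group level): passing recovery
tests demonstrates the pipeline's correctness — that each stage finds what
is planted, with the right direction, at better than 90% over 20 seeds —
not that effects of this magnitude exist in real MRI data. The phantoms
also lack cortical anatomy, registration error, scanner artifacts and
spatially correlated noise, so detection rates here say nothing about
real-data sensitivity; the real study's peak coordinates and metric values
are not reproducible without its MRI data and are covered only by these
qualitative analogues.

## Numerical and reproducibility choices

- All randomness flows through explicit seeds (numpy `SeedSequence`
  internally, salted per stage); identical cohort specs give byte-identical
  outputs, and the pipeline manifest records the config hash and SHA-256 of
  every artifact.
- Negative GM values (possible after upstream interpolation) are clipped to
  0 at load and counted; non-finite voxels are an error naming the count.
- Degenerate regions (all-identical values) make the KDE bandwidth
  undefined; an optional uniform jitter of 1e-6 (off by default) resolves
  them, and errors name the offending region.
- Problem sizes in tests and the acceptance runs — 32³ grids, 20-null
  ensembles for small-world checks, 20 seeds per recovery rate — were
  chosen as the smallest sizes at which the statistical checks are stable;
  the library defaults (100 nulls) remain larger.

## Known limitations

- Lp on badly fragmented graphs averages over few pairs and can be
  non-monotone across sparsity; the disconnected-pair count is reported so
  downstream analyses can filter.
- Whether group inference should run per sparsity level or on AUC summaries
  is a genuine design fork; the pipeline computes AUC-based tests by
  default and writes the per-sparsity long table so either is possible.
- The modularity optimizer (Louvain, 10 restarts) is a heuristic; reported
  modularity is a lower bound on the optimum.
- The three-group covariate policy (drop covariates undefined for a group)
  is one of several defensible resolutions of an inherently ambiguous
  design; alternatives are implemented and selectable.
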