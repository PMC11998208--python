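# Methods

## Data model

The unit of analysis is the **branch segment**: the stretch of airway
between two bifurcations, or between a bifurcation and the root (hilum) or
a terminal end. Trees are stored as parent-pointer maps (node = segment,
children derived), one rooted tree per subject; single-child chains are
legal — trimming a conducting tree at the terminal bronchioles can leave
pass-through segments, and every algorithm here handles them explicitly.
All lengths are micrometres; the package performs no unit inference.

Input tables are delimited text with a header; because no standard format
exists for airway segment tables, column names are resolved through a
user-supplied dialect map. Raw tables carry one row per (segment, image)
with inner and outer diameters; wall thickness is `(Ø_outer − Ø_inner)/2`
per image and per-image values are averaged per segment (averaging the
per-image wall values or applying the formula to averaged diameters is
identical by linearity; the former is what is implemented and tested).
Pre-averaged tables (lumen + wall columns) are accepted directly and
round-trip bit-exactly (`float_precision="round_trip"` on read).

Epithelium profiles — nucleus counts per cell category along a digital
ruler (100 µm default), epithelial height, cilium length measured along
the cilium's spine — are optional per row; which rows carry them encodes
any subsampling done at measurement time (e.g. center slides only). The
package stores values as given. Summaries are linear nucleus density
(counts/ruler, reported per mm) and per-category percentages of observed
nuclei; when zero nuclei were observed the percentages are *absent*, never
0/0.

## Branching-based groupings

* generations: root 0; +1 below every branch point (≥ 2 children);
* orders: terminals 1; +1 above every junction of ≥ 2 branches;
* Strahler orders: like orders, but +1 only where ≥ 2 children share the
  highest order.

Single-child segments inherit without increment in all three schemes (the
definitions are stated on branch points); junctions of three or more
branches count as a single branch point. The root generation is 0 (the
trachea-equals-zero convention; the base index only shifts label names,
not group structure). All three labelings are verified exactly against an
independently written naive recursion on hundreds of random trees, plus
closed forms (perfect binary tree of depth d → root Strahler d + 1;
caterpillar trunks → Strahler 2 along the entire trunk while generations
grow linearly — the monopodial failure mode in one line).

## Gaussian mixture clustering

Clustering operates on the two measured morphological features, lumen
diameter and wall thickness, **pooled over all trees of all subjects**;
labels map back to trees afterwards and per-tree refits are never
performed. Features enter on the raw µm scale by default (a standardize
flag exists for other data); the component geometry is then interpretable
directly in µm.

The EM implementation supports five covariance families — spherical or
diagonal or full, shared across components or free per component (the
classical model-based-clustering ladder; "full-free" is the ellipsoidal
variable-volume/shape/orientation family). Model selection scans
k = 1…9 × all five families and keeps the highest
`BIC = 2·log L − m·ln n`; ties break toward smaller k, then the simpler
family. k = 1…9 is a default, not a dogma, and is overridable.

Numerics: EM is initialized from a seeded k-means hard assignment;
`fit_gmm` runs 10 restarts by default, while the model-selection scan uses
4 restarts per (k, family) pair — with k-means initialization the scan is
insensitive to further restarts and this keeps a full 45-pair scan around
five seconds for ~1400 segments. Every covariance receives a floor of
1e-6 × the mean feature variance so duplicated measurements cannot produce
singular components; empty components are guarded by a mass floor. The
per-iteration log-likelihood trace is exposed on the fitted model and is
asserted non-decreasing in tests; convergence is declared when the
relative increase falls below 1e-7, and non-convergence within 200
iterations returns the best iterate with a warning. A same-data fit is
cross-checked against scikit-learn's `GaussianMixture` in the test suite;
scikit-learn is never the implementation (it lacks the shared-spherical
family and the trace).

Selected clusters are renamed CL1…CLk by strictly descending component
mean lumen; exact ties fall back to descending mean wall, then component
index. CL1 is therefore always the large central compartment and CLk the
smallest, most distal one. Hard labels are argmax posterior
responsibilities; full responsibilities are kept alongside.

Both treatment groups are pooled into one fit by default (the fitted
compartments are then comparable across groups by construction); per-group
fitting is possible by passing per-group cohorts but is not the default.

## Validity indices and the scheme comparison

Davies-Bouldin uses the classical q = 1, p = 2 form: dispersion = mean
Euclidean distance to the group centroid, similarity
`(S_i + S_j)/d(c_i, c_j)`, index = mean over groups of the worst-case
similarity. Coincident centroids raise an explicit error; singleton groups
contribute dispersion 0 rather than being dropped. Dunn uses
single-linkage between-group distance over maximum complete-linkage
diameter; an all-singleton labeling (diameter 0) raises an explicit error.
Both agree with brute-force double-loop recomputation on random instances
to 1e-9, and the expected invariances (rigid motions for DB, global
scaling for Dunn) hold to the same tolerance.

Protocol of the scheme comparison: the pooled mixture is scored **once**
on the pooled feature matrix (no SD); branching-based labelings only exist
per tree, so they are scored tree by tree on that tree's feature rows and
reported as mean ± SD across trees. Indices are computed on the same two
features for every scheme. A tree on which a scheme yields fewer than two
groups is excluded from that scheme's mean with a warning.

## Two-group statistics

Observations are per-segment values; comparisons run once globally and
once per cluster. The test is Mann-Whitney U, two-sided, α = 0.05: exact
(via full enumeration semantics) when both samples have ≤ 8 tie-free
observations, otherwise the tie-corrected normal approximation with
continuity correction for the p-value. The effect size is
`r = |Z|/√N` with `Z = (U − μ)/σ` from the tie-corrected approximation
*without* continuity correction, so r is defined in both regimes and
matches the usual hand calculation (U = 0 at 3 vs 3 → |Z| = 1.964,
r = 0.802); the discrepancy against exact-p inversion is bounded in tests.
Cohen's benchmarks are applied as half-open intervals
(r < 0.1 none, [0.1, 0.3) small, [0.3, 0.5) medium, ≥ 0.5 large; boundary
membership upward is a documented decision), and the effect category is
reported only for significant rows — non-significant rows print "-".
Stars follow `ns > 0.05 ≥ * > 0.01 ≥ ** > 0.001 ≥ *** > 0.0001 ≥ ****`
with inclusive boundaries. There is no outlier removal and no default
multiple-testing correction (raw per-scope p-values are reported; a Holm
helper exists, off by default). Segments lacking a parameter are skipped
with logged counts; a scope where either group is empty is returned
flagged not-computable instead of silently dropped. Mean, SD, median and
n per group are always emitted, since tables conventionally report
mean (SD) while boxplots display medians.

Per-segment observations are treated as independent even though they are
nested within a small number of animals; this mirrors common practice in
such designs and is a limitation, not a claim — mixed-effects modeling is
out of scope.

## Synthetic cohorts

The generator is the package's test bed standing in for an unreleased
small-animal dataset; its defaults define the study conditions and were
tuned once, then frozen.

**Topology.** Each subject carries one tree of two lobes joined at a
main-bronchus root; each lobe is a trunk caterpillar (default length 15)
whose nodes each bear one lateral daughter and end in a terminal tip.
Laterals recurse medium → small-a → small-b (binary branching with
probability 0.6 at the first two levels) and finish in a single-child
chain of 1–3 small-terminal segments. Two lobes are the default because a
single lobe makes every trunk order a singleton group, collapsing the
Davies-Bouldin of `orders` to near zero — an artifact of degenerate
topology, not of the scheme; real left lungs are multi-lobed. The
single-child terminal chains bound each lobe's Strahler order at 4 and the
tree's at 5 regardless of seed, while generations grow linearly with trunk
length: the structural contrast the benchmark exists to show. Defaults
yield ≈ 600–750 segments per group (two subjects per group), the scale of
a real cohort.

**Morphology.** Each archetype is a bivariate Gaussian over (lumen, wall)
with positive lumen-wall correlation (so the full-free family is the true
model): trunk (900, 42), medium (420, 24), small-a (190, 9), small-b
(110, 14), small-terminal (55, 12) µm, SDs chosen so adjacent archetypes
are ≥ 4 SD apart in lumen. Small-a is the thin-walled small compartment,
small-terminal the smallest with the widest wall spread. Draws violating
positivity are resampled. Epithelium: nucleus totals are Poisson
(density × ruler length), category counts multinomial with goblet
probability nonzero only in the two large-airway archetypes; heights and
cilium lengths are positive-truncated Gaussians with control-group means
descending from trunk (9.6 µm height, 7.2 µm cilium, 136 nuclei/mm) to
the distal archetypes (≈ 7.4–7.8 µm, ≈ 5.2–5.6 µm, ≈ 108–116 nuclei/mm).

**Treatment effects** multiply distribution parameters of the treated
group *before* sampling, so recovery tests have analytic targets. The
default effect is null; `GroupEffect.hyx_preset()` encodes the
hyperoxia-style pattern: lumen × 0.8 and wall × 1.2 in trunk and medium
only, epithelium height × 1.3, cilium length × 0.85, density × 0.9
globally.

**Determinism.** A mandatory integer seed drives a `SeedSequence` tree;
identical (config, seed) yields byte-identical cohorts and tables.

**What passing tests do and do not show.** The generator's archetypes are
well-separated Gaussians with near-fixed per-tree composition. Real
airway morphology is a continuum: clusters overlap, composition varies,
measurements carry operator noise and within-animal correlation. Recovery
of k = 5 with ARI ≥ 0.9 here demonstrates the machinery is correct under
conditions where the answer is known — not that five compartments exist
in any particular species. Two consequences of the idealization are worth
knowing. First, a *global* rank test is nearly blind to effects confined
to well-separated upper compartments (shifting trunk means by 20% flips
only within-compartment rank pairs, ~2% of all pairs), so global
significance of localized effects — observable in real, overlapping
data — does not reproduce here; per-compartment tests detect those
effects at full power, which is precisely the argument for compartment
analysis. Second, because per-tree archetype composition is nearly fixed
(stratified rather than iid-mixture sampling), the pooled global test is
conservative under the null (rejection ≈ 0.2% at α = 5% versus 4.6–6.2%
in the compartment scopes); conservatism, not anti-conservatism.

## Pipeline and reproducibility

`run_pipeline` chains ingest/simulate → branching labels → BIC selection →
canonical relabel → validity report → comparisons for all ten parameters
(lumen, wall, height, cilium, density, five cell percentages) at Global +
CL1…CLk → export. Tables are CSV with a three-line stamp (package
version, config hash, seed) and fixed float formatting, so a rerun with
the same config is byte-identical; the model and config echo are JSON;
figures are a cluster scatter with 2σ ellipses and per-parameter grouped
boxplots (1.5 × IQR whiskers, star annotations). Stage-level logging
records row counts (read, skipped, excluded) so exclusions are auditable.
The CLI (`simulate` / `analyze` / `report`) is a thin layer over this
function; a YAML config file can set any option, flags override.

## Problem sizes used in the test suite

Acceptance-style checks run at the generator's default scale (~1350
pooled segments): 50 seeded selection runs for cluster-number recovery
and scheme ranking, 50 effect-injection runs, and 500 null cohorts for
type-I calibration; the oracle-equivalence suites use 100–200 random
instances of ≤ 50 segments or ≤ 100 points. The full suite completes in
about six minutes on one CPU; `scripts/acceptance.py` (20 selection
repeats, 20 effect runs, 100 null cohorts) in about two.

## Known limitations

- Features are the two measured dimensions only; no covariate-adjusted or
  density-based clustering alternatives.
- No stereological counting corrections for the epithelium profiles;
  counts are used as collected.
- Independence across segments is assumed in the statistics (see above);
  no mixed-effects modeling, no power analysis.
- Whether a real left lung is best analyzed as one rooted tree or per
  lobe is study-specific; the package treats each subject's table as one
  rooted tree and accepts per-lobe subtables.
- Epithelium aggregation from multi-image raw rows keeps the first
  profile-bearing row per segment (profiles are measured once per segment
  in the intended protocol).
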