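# Methods

`fctopo` implements a whole-brain functional network topology analysis
of the kind used in large multi-site resting-state fMRI case-control
studies, together with a synthetic cohort generator that reproduces the
statistical structure such an analysis assumes. This note records the
models, the conventions chosen where the field's practice is not unique,
and what the synthetic world does and does not establish.

## Connectome construction

Nodes are points in MNI space (e.g. the Dosenbach 160-coordinate set),
each carrying a functional-network label from a fixed vocabulary: six
cortical networks of the Yeo parcellation (SMN, VAN, VN, DAN, DMN, FPN)
plus a subcortical network. When a 4D image is the input, a node's
signal is the unweighted mean of all voxels whose centers lie within a
5 mm radius (Euclidean, millimeter space, inclusive boundary) of the
node coordinate; a node with no in-sphere voxel is an error, mirroring
coverage-based subject exclusion. Partial-volume weighting is not
applied — the simplest reproducible convention.

Edges are Pearson correlations between node signals, Fisher transformed
(z = arctanh r). |r| is clipped at 1 − 1e−7 before the transform so
degenerate perfect correlations stay finite; the clip has no measurable
effect elsewhere. Optional motion scrubbing removes time points whose
framewise displacement is *strictly* greater than the threshold
(default 0.2 mm; a point exactly at the threshold is kept), and fails
if fewer than 3 points survive. "Overall connectivity strength" is the
signed mean of the upper-triangular z values (a positive-only mean is
available behind a flag); it exists as an optional covariate for
robustness models.

## Thresholding and graph metrics

Each subject's z matrix is reduced to weighted graphs by proportional
thresholding over a density grid, by default κ = 0.10 … 0.34 in steps of
0.01 (25 levels; the grid step is not dictated by the emulated analyses
and is configurable). At density κ, negative and zero z values are
discarded (an absolute-value mode exists) and the
K = round(κ·N(N−1)/2) largest remaining upper-triangular weights are
kept, ties broken by lexicographic (i, j) order so the retained set is
deterministic. If fewer than K positive edges exist, all are kept and a
warning is recorded.

Weighted metrics follow the connectivity-toolbox conventions, with edge
weight w mapped to length 1/w for path-based quantities:

- **Global efficiency** E_glob = mean over ordered pairs of 1/d_ij
  (1/∞ = 0).
- **Nodal efficiency** E_nodal(i) = mean over j≠i of 1/d_ij.
- **Local efficiency** E_loc: for each node, shortest paths are computed
  within its neighborhood subgraph on cube-root lengths, and
  (w_ua·w_ub)^{1/3}/d_ab is summed over ordered neighbor pairs and
  divided by k(k−1); nodes with fewer than two neighbors contribute 0.
- **Characteristic path length** L_p = mean of finite d_ij; the count of
  disconnected ordered pairs is reported alongside (disconnected pairs
  contribute 0 to the efficiencies — both conventions explicit).
- **Clustering coefficient** C_p: Onnela-style cube-root geometric mean
  of max-normalized triangle weights over k(k−1), averaged over nodes.
- **Degree** is the binary count of suprathreshold edges (weighted
  strength is exposed separately).
- **Betweenness** is Brandes' algorithm on the length matrix, with
  equal-length path multiplicity shared fractionally and normalization
  by (N−1)(N−2) ordered pairs. Floating-point tie detection uses a
  1e−12 absolute tolerance: exact-arithmetic ties (binary graphs) are
  shared, while ties in continuous weights are measure-zero.

All inner loops are numba-jitted; a pure-python brute-force suite
(Floyd–Warshall, exhaustive triangle and shortest-path enumeration) and
scipy/networkx serve as independent cross-checks in the tests.

**Weight normalization.** Metrics run on the raw retained Fisher-z
weights by default. Per-subject max-normalization to (0, 1] — the
pure-topology convention — is available (`normalize=True`) but is not
the default, for a reason verified empirically: max-normalization
removes exactly the overall-strength differences a multiplicative
connectivity attenuation produces, and with finite scan lengths the
*lower* signal-to-noise of attenuated subjects flattens their retained
weights toward uniformity, *raising* their normalized global efficiency.
Under the raw-weight convention, attenuated connectivity propagates
monotonically to lower efficiency, which is the behavior a strength
attenuation should induce and the behavior the test suite pins down.

Each metric's curve over the grid is summarized by its trapezoidal area
under the curve (AUC) — exact for the constant and linear test cases —
giving one outcome per subject per metric (per node for nodal metrics)
and avoiding commitment to any single threshold.

## Group inference

Each outcome is fit with the linear mixed-effects model

    y ~ 1 + group + age + sex + education + head motion
        + (1 | site) + (group | site)

with NC as the reference level (group coded 0/1), sex coded as a male
indicator, education in years, and head motion as mean framewise
displacement. Estimation is REML via statsmodels `MixedLM`; the group
effect is tested by a Wald statistic with normal-approximation p-values
(df recorded as ∞; the OLS fallback uses residual-df t). The outcome is
standardized to unit SD internally for optimizer stability and the
coefficient mapped back.

Small per-site samples make random slopes fragile, so the fit degrades
deterministically and transparently: if the random-slope fit does not
converge or its random-effects covariance is singular (smallest
eigenvalue < 1e−6 × residual variance), the model is refit with a
random intercept only, then with ordinary least squares plus site
fixed effects; the structure actually used is recorded in every result
row. Boundary-of-parameter-space warnings alone do not trigger the
fallback — the eigenvalue criterion decides.

Sites contribute only if they retain at least `min_per_group` subjects
in *each* group (default 10, boundary inclusive); subgroup contrasts
(FEDN vs NC, recurrent vs NC, recurrent vs FEDN) re-apply the filter
within the subset and refit with a fresh binary contrast. The symptom
model replaces the group term (fixed and random slope) with the HAMD
score and is restricted to patients, who alone carry meaningful scores;
a flag lifts the restriction.

FDR families follow the reporting convention of the emulated analyses:
each nodal metric is one Benjamini–Hochberg family across its nodes;
global metrics are reported with raw p-values (q set equal to p).
Significant nodes are tallied per functional network with direction
counts (patient-below vs patient-above reference).

## Synthetic cohort generator

The generator emulates the structure the inference stage assumes, at
desk scale, with known ground truth:

- **Covariance template**: block-modular correlation matrix, unit
  diagonal, `within_module_r` (default 0.4) inside modules and
  `between_module_r` (default 0.05) across (7 modules by default,
  remainder nodes in the last block), repaired to the nearest
  unit-diagonal PSD matrix by deterministic eigenvalue clipping when
  needed.
- **Subject connectivity scale**:
  scale = δ_subject · exp(b_site + s_site·patient + Σ β_c x_c), with δ
  the multiplicative patient attenuation (1 = null; per-subtype
  overrides allow effects confined to, e.g., recurrent patients),
  b_site ~ N(0, 0.1²) and s_site ~ N(0, 0.05²) per site on the
  log-connectivity scale, and optional covariate slopes. For
  0 ≤ scale ≤ 1 the scaled template is a convex combination with the
  identity and provably PSD; larger scales are clipped and repaired.
- **Time series**: i.i.d. multivariate normal draws from the subject
  covariance. Temporal autocorrelation is deliberately not modeled: the
  pipeline consumes only static Pearson correlations, so
  autocorrelation would change estimator variance, not the identity of
  any pipeline step. This is the generator's main departure from real
  BOLD data, along with the absence of scanner artifacts and
  missing-data mechanisms.
- **Covariates** (documented defaults, not derived from any specific
  sample): age ~ U(18, 60) years, education ~ U(6, 20) years,
  mean FD ~ |N(0.10, 0.05)| mm, P(female) = 0.64 in patients / 0.5 in
  controls (female preponderance typical of depression samples).
  Patient subtypes FEDN/recurrent/unknown default to fractions
  0.42/0.32/0.26; HAMD = 21 + slope·(1 − scale) + N(0, 4), rounded and
  floored at 0 (slope defaults to 0 so symptom-association power is
  opt-in); medication is Bernoulli(0.42).
- **Default scale**: 16 sites × 50 per group per site, 160 nodes, 200
  time points — consortium-like; simulations in the tests override the
  size parameters explicitly and say so.
- A shortcut generator draws outcomes directly at the AUC level from
  the same site-effect structure (group shift log δ, residual sd 1.0),
  for calibration studies where simulating time series adds cost but no
  information.

Determinism: a cohort is a pure function of its spec (one integer seed;
a single random stream consumed in fixed order), and the pipeline
manifest plus all delimited-text outputs are byte-identical across
re-runs of the same config.

A green simulation-based test therefore establishes that the pipeline
recovers known multiplicative connectivity effects with correct
direction and calibrated type-I error under the generator's Gaussian,
temporally white world — not that any particular clinical finding is
true, nor that the pipeline is robust to artifacts the generator does
not model.

## Numerical choices and degenerate inputs

- r→z clipping at 1 − 1e−7; correlation requires ≥ 3 time points and
  nonzero per-node variance (flat nodes are named in the error).
- Thresholding with K = 0 is an error; shortfall of positive edges is a
  recorded warning, not an error.
- CSV round-trips use 17-significant-digit floats and round-trip float
  parsing, so serialized matrices reload bit-exactly.
- Mixed-model listwise deletion counts are recorded (`n_used`);
  constant outcomes and single-group cohorts are errors.
- Symmetry is enforced at 1e−12; matrices read from disk are
  re-symmetrized by averaging before validation.

## Known limitations

- The generator's attenuation acts uniformly on all edges; it does not
  create focal, network-specific lesions, so nodal-level spatial
  patterns in synthetic data reflect module geometry, not pathology.
- Wald/normal inference for mixed fits is approximate with few sites;
  the calibration test pins the realized type-I error only for the
  tested design (4 sites × 20/group).
- Weighted local efficiency and clustering exist in several variants;
  the implemented forms are stated above and isolated behind single
  functions, but no claim is made that other variants would give
  identical group-level conclusions.
- No image preprocessing (registration, nuisance regression, FD
  computation) is included; time series and FD are consumed as given.
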