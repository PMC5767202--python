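# Methods

## Model and assumptions

`lieflow` implements the end-point LIE estimate of binding affinity for a
multi-pose simulation protocol. The inputs are ensemble-averaged
ligand–surrounding van der Waals and electrostatic interaction energies for
N independent bound-state simulations of one compound (different docking
poses, each typically run in duplicate) and for the unbound, solvated
ligand. Each simulation i contributes

    ΔG_i = α ΔV_i^vdw + β ΔV_i^ele + γ,

and simulations are combined with Boltzmann weights
W_i ∝ exp(−ΔG_i / RT), so that poses predicting stronger binding dominate.
The final estimate is the convex combination ΔG_pred = Σ W_i ΔG_i. Implicit
assumptions: linear response holds within a ligand class (α, β, γ are
class-specific empirical constants), the simulated poses enumerate the
thermodynamically relevant binding modes, and replicate runs of the same
pose are exchangeable with runs of distinct poses (each run enters the
weighting as an independent simulation; a flag to pre-average replicates per
pose was considered and rejected as the less literal reading of
"independent simulations", but `delta_interactions` operates per record, so
callers can pre-average if desired).

All energies are molar (kJ/mol); k_B T is represented as RT with
R = 0.0083145 kJ·mol⁻¹·K⁻¹. The default temperature is 300 K and is carried
inside `LIEParameters`, so the weighting temperature is always the one the
model was calibrated at. Trace averaging uses all frames by default
(burn-in 0 ps, configurable): production trajectories are assumed to start
after thermal pre-equilibration.

## Calibration

The parameters appear both linearly (in the regression) and nonlinearly (in
the weights), so calibration alternates:

1. compute per-compound weighted regressors (Σ W_i ΔV_i^vdw, Σ W_i ΔV_i^ele)
   under the current parameters (uniform weights at the start),
2. refit (α, β[, γ]) by ordinary least squares (numpy `lstsq` on the 2–3
   column design; rank deficiency is reported naming the collinear column).

Convergence is declared when the largest parameter change falls below
`tol = 1e-6` (cap 100 iterations). The update is a plain fixed-point step;
if the parameter change grows between iterations (oscillation) the step is
halved, repeatedly if necessary, and each damping event is recorded in
`CalibrationResult.notes`. The self-consistent sum of squared residuals is
not forced to decrease monotonically — the OLS step minimizes the residual
at frozen weights, and near the fixed point the self-consistent objective
can rise by a relative ~1e-4 — but a net increase over the whole run is
flagged in the notes. On synthetic data generated by the same forward model
the scheme recovers the generating parameters to <1e-6 without noise and
without detectable bias at 2 kJ/mol observation noise.

γ may be fixed to zero (`include_offset=False`); both modes are supported
because the offset is optional in this model family.

IC50 values are converted with the Cheng–Prusoff estimate
ΔG_obs = RT ln(IC50 in M). No substrate/Km correction term is applied: the
correction requires assay-specific quantities that are generally not
published alongside the IC50, and for rank-preserving calibration within one
assay it contributes only an offset absorbed by γ.

Model quality is reported as RMSE (training fit), SDEP (same
root-mean-square formula on held-out predictions), and Pearson r /
Spearman ρ (average ranks on ties; undefined correlations on constant
vectors are reported as NaN). `loo_sdep` re-runs the entire iterative
calibration n times, so the held-out compound never influences weights or
parameters of the fold predicting it.

## Applicability domain

Five criteria, each a binary violation flag; the confidence index is their
sum (0 = best, 5 = worst). All reference statistics are frozen at training
time in `ADReference`, so scoring is a pure function of (reference, query).

1. **Range.** ΔG_pred must lie within [min, max] of the *calculated*
   training predictions (not the experimental values), inclusive at the
   boundaries.
2. **Similarity.** The query's best Tanimoto score against the training
   fingerprints must be *strictly greater* than the cutoff, defined as the
   lowest nearest-neighbour Tanimoto within the training set. Fingerprints
   are boolean bit-vectors; a hashed Morgan/circular fingerprint generator
   (RDKit, radius 2, 2048 bits, configurable) is provided for SMILES input,
   and any fixed-length bit-vector works.
3. **Energy.** The Boltzmann-weighted (ΔV_vdw, ΔV_ele) pair must fall within
   the empirical 95th percentile of training Mahalanobis distances from the
   training centroid. Weighted (rather than plain) averages keep the
   coordinates consistent with the quantities entering the prediction. The
   2×2 covariance gets a +1e-8·I ridge when near-singular. Percentiles are
   empirical (numpy linear interpolation), not χ² quantiles, so the
   training-set self-coverage is 95 % by construction regardless of the true
   energy distribution.
4. / 5. **Decomposition (vdW / electrostatic).** Per-residue energy
   decomposition vectors are projected onto a PCA of the training
   decompositions. Components are retained while each adds ≥ 5 % of
   explained variance (the same increment rule used for pose clustering; at
   least one component). The score distance (eigenvalue-scaled Mahalanobis
   in score space) and the orthogonal distance (residual norm) must both be
   within their empirical training 95th percentiles; exceeding either flags
   the criterion. Criteria 3–5 are inclusive at the threshold; criterion 2
   is strict, following the respective wordings of the rules.

Expected behaviour on in-distribution data: criterion 3 flags ~5 % of the
training set itself, criteria 4–5 up to ~10 % each (union of two 95 %
conditions), so CI 0 is the norm but single-flag scores occur by design.

## Pose clustering

Heavy-atom coordinates of all docking poses (poses × 3·atoms) are
mean-centered and decomposed by SVD. No superposition is applied by default:
docking poses share the receptor frame. Components are retained while each
adds ≥ 5 % of explained variance. k-means (scikit-learn, 10 restarts, seed
42 by default) is run on the retained scores; k grows from 1 while an added
cluster raises the between-cluster fraction of score variance by at least
5 percentage points, stopping at the first failure. Cluster medoids (the
member minimizing summed within-cluster distance; ties broken by lowest pose
index) are returned as representative poses, in their original coordinates.

Degenerate inputs: a single pose or an all-identical pose set yields k = 1,
retained components 0, medoid index 0. Note that the increment rule is a
variance-partition criterion, not a cluster-validity test: on an isotropic
single cloud in few retained dimensions, a second cluster can legitimately
explain > 5 points of score variance, so k > 1 there is expected behaviour,
not a defect. `max_k` and `min_increment` are exposed for stricter use.

## Interaction profiles

Per frame, ligand–residue contacts are typed by explicit geometric rules
(defaults: hydrogen bond — donor-heavy to acceptor distance ≤ 0.35 nm and
donor-H⋯acceptor angle ≥ 120°, checked in both directions; hydrophobic —
annotated apolar carbons within 0.40 nm). These thresholds are common
practice defaults, fully overridable via a YAML rules file; donor/acceptor/
hydrophobe roles are input metadata (annotation sidecar CSV), not perceived
here. A residue scores at most once per type per frame; the profile is the
per-residue, per-type fraction of frames with a contact. For display,
hydrophobic frequencies are conventionally divided by 10 (configurable) so
the rarer directional interactions remain visible in stacked bars.

## Synthetic data

The generator emulates the post-simulation outputs of a docking + MD
campaign for a congeneric series, with known ground truth:

- interaction energies: per-compound ΔV drawn from a correlated bivariate
  Gaussian (mean (−60, −25) kJ/mol, SDs 12/8, correlation ~0.3), pose
  offsets SD 4 kJ/mol, replicate jitter SD 0.8 kJ/mol; unbound means drawn
  separately and bound means constructed as unbound + ΔV;
- observed affinities: the forward Boltzmann-weighted model under the true
  parameters (defaults α=0.33, β=0.12, γ=−13.0, 300 K — a published
  parameter set for one congeneric ligand class) plus Gaussian noise
  (σ = 2 kJ/mol default);
- decompositions: a base residue profile (rows scale with each compound's
  total) plus zero-sum low-rank structure and zero-sum noise, so each row
  sums exactly to the compound's weighted total for that energy type;
- fingerprints: per-family bit templates with per-compound random flips;
- pose clouds: Gaussian clusters around separated template conformations.

One global seed drives everything; per-component sub-generators are derived
deterministically from it. Default problem sizes (30 compounds, 3 poses × 2
replicates, 24 residues, 128-bit fingerprints, 20-compound sets for AD
references, 2000 points for percentile checks) keep the full test suite and
the acceptance script in the seconds-to-a-minute range.

What the generator does **not** emulate: force-field physics (energies are
statistical stand-ins, not molecular mechanics), conformational
autocorrelation within traces, systematic docking errors (wrong poses with
deceptively good energies), inter-class chemistry shifts, or assay
heterogeneity in the affinities. Passing tests therefore demonstrate the
correctness of the estimator, calibration, and domain logic — not the
physical accuracy of LIE predictions on real protein–ligand systems, which
depends on the simulation data fed in.

## Known limitations

- The AD similarity criterion depends on the fingerprint type; defaults are
  a choice, and cutoffs from tiny training sets are fragile (a single
  outlier compound can drive the cutoff to ~0, making criterion 2
  unfailable).
- Criterion 1's range check inherits any calibration bias: a badly fitted
  model produces a shifted range.
- The interaction typing covers hydrogen bonds and hydrophobic contacts
  only; π-stacking, salt bridges and water-mediated contacts are outside
  the default rule vocabulary.
- Energy tables are the package's canonical long-form CSV/TSV; engine-native
  energy files (GROMACS .edr/.xvg, Amber output) must be exported upstream.
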