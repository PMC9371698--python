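# Methods

This note documents the models, defaults, and numerical choices behind
`cadforce`, and what the synthetic-data experiments do and do not show.

## Force-curve model and generators

A synthetic retract trace is built by parametrising the tether in extension
*x*: the force follows the Marko–Siggia worm-like chain
F(x) = (kB·T/Lp)·[¼(1−x/Lc)⁻² − ¼ + x/Lc], the piezo position is
z = x + F/k (cantilever deflection correction with spring constant k), and
the curve is resampled on a uniform piezo grid. The rupture is
instantaneous — force returns to baseline within one sample — because the
drop shape carries no information used downstream. The approach segment is
pure baseline noise and supplies the zero-force reference.

Generator defaults (all configurable in `CurveGenSpec`): spring constant
80 pN/nm (a soft AFM cantilever, ~0.08 N/m), pulling velocity 1 µm/s,
10 samples per nm, Gaussian force noise of 5 pN, temperature 298 K
(kB·T = 4.114 pN·nm), tether Lp 0.38 nm (PEG in aqueous buffer) and Lc
40 nm. The contour length sits above the 30 nm acceptance cutoff by a
margin comparable to several SDs of the fitted-Lc noise, so clean events
are not clipped by the contour filter; a tether at exactly the cutoff
would lose half its events to fit noise.

Contaminants emulate the two failure modes the acceptance filters target:
short-tether events (Lc drawn uniformly from 5–25 nm → contour rule) and
high-noise events (noise SD ×5 → rmse outlier rule). The default
contaminant fraction used in the filtering experiments is 20%. Real
instrument data additionally contain multiple tethers, drift, and
hydrodynamic artefacts that these generators do not emulate; passing the
recovery tests therefore validates the analysis chain, not instrument
physics.

Rupture forces are drawn from the condition's Gaussian mixture
*untruncated*. A `truncate_negative` flag redraws the rare negative values
(< 0.5% of mass at the study parameters), but it is off by default: the
recovery experiments fit an untruncated Gaussian mixture, and for strongly
overlapping components even sub-percent truncation shifts the
maximum-likelihood solution several pN along the near-flat likelihood
ridge, so a truncated generator would measure that model mismatch rather
than estimator performance.

## Event detection and readout

Detection is deliberately simple plumbing around the physics: a moving
average (window 5) smooths the retract force; a candidate ends where the
smoothed force falls by the drop threshold (default 20 pN) within one
smoothing-window lookahead, stays that far down over the following ~10
samples (ruptures return to baseline; noise excursions do not), and the
drop also clears 6× the smoothed noise level estimated robustly (MAD) from
the approach segment, so noisy curves do not spray spurious candidates
into the rmse statistics. The window start walks back through the rising
stretch tolerating wiggles of a quarter threshold; the pre-drop sample is
refined on the raw signal as the largest single-sample fall, and the
rupture force is that sample minus the median approach force. On noiseless
curves this readout equals the generating rupture force to within one
sample of discretisation; over noisy replicates its mean bias is below
σ/√(smoothing window).

WLC fits use bounded least squares (scipy, trust-region reflective) with
Lp ∈ [0.1, 1] nm, Lc greater than the window's maximal extension, and a
deterministic 12-point multi-start grid; non-convergence flags the event
rather than raising. The rmse filter population is all successfully fitted
events of one condition (fit failures excluded); with fewer than two fitted
events the SD is undefined and the rule is skipped. Note an intrinsic
property of a mean + 1·SD rule: on a homogeneous population it trims the
upper ~16% tail of fit errors. It earns its keep when contaminants are
present — they inflate the threshold far above the clean cluster, so
essentially no clean events are lost while high-noise events are removed.

## Mixture modelling and reporting

Component-count selection: maximum-likelihood EM on the raw sample for
k = 1..3 (five quantile-spread starts, the first deterministic; tolerance
1e-6 on the log-likelihood; 500 iterations; component SDs floored at
1e-3 of the sample SD to prevent variance collapse), compared by
BIC = (3k−1)·ln n − 2·ln L with ties toward smaller k.

Parameter reporting: the chosen model is refined by least squares against
the Freedman–Diaconis-binned probability density, starting from the EM
solution. This mirrors how peak forces are reported from experimental
histograms, and it matters quantitatively: for the strongly overlapping
two-component conditions the EM likelihood surface has a long flat ridge,
and at n = 2000 the raw EM estimate drifts along it (high-component mean
biased upward ~3 pN, its weight downward ~6 points, 25-seed medians). The
binned-density fit is anchored to the observable density shape and recovers
the generating parameters within the acceptance tolerances. `refine="em"`
switches the reporting back to pure EM.

The Freedman–Diaconis width uses linear-interpolation quantiles; bins are
anchored at the sample minimum, the maximum falls in the interior of the
last (right-closed) bin, and zero-IQR data raise an error suggesting an
explicit width.

## Trajectory statistics

* **Superposition**: Kabsch via SVD with a determinant correction so the
  rotation is always proper; collinear point sets are rejected.
* **RMSF**: frames are superposed on their mean structure, iterating
  superpose → re-average until the mean converges (≤ 20 passes, 1e-10 Å),
  which makes the result invariant to rigid motion of the input frames to
  1e-6. RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ — the SD of the atomic position; a
  residue fluctuating isotropically with per-axis SD σ has RMSF σ√3.
  Defaults: α-carbons of residues 1–100, final sixth of the frames (the
  equilibrated tail, e.g. the last 10 ns of a 60 ns run). With fewer than
  three selected atoms superposition is skipped.
* **Salt bridges**: per frame, the minimum distance over all charged-atom
  pairs of the two residues (Glu OE1/OE2, Asp OD1/OD2, Lys NZ, Arg
  NH1/NH2/NE by default; configurable); the bridge is formed iff the
  median over frames is strictly below 4.0 Å, so a median of exactly
  4.0 Å is not formed.
* **SASA**: Shrake–Rupley with a golden-spiral quadrature (default 960
  points, probe 1.4 Å, Bondi radii). A test point is buried if strictly
  inside a neighbour's expanded sphere; exact-boundary points are assigned
  to the lower-indexed atom so that pathological coincident spheres count
  their shared surface once. Quadrature accuracy: ≤1% on an isolated
  sphere, ≤2% against the analytic two-sphere cap formula, ≤0.5% change
  when refining 960 → 3840 points. Because the grid is fixed in space,
  SASA is rotation-invariant only to quadrature accuracy — an inherent
  property of fixed-grid quadratures, documented rather than hidden.
* **ΔSASA and rupture**: ΔSASA = SASA(A) + SASA(B) − SASA(A∪B) ≥ 0; the
  rupture frame is the first (1-based) frame with ΔSASA at or below a
  1 Å² tolerance (the quadrature noise floor).
* **Centre-of-mass distances**: mass-weighted by default with standard
  atomic masses; the W2-pocket selection (residues 22–28, 36, 78–80,
  89–92) ships as a preset.

The fluctuation generator displaces every atom of a listed residue
independently and isotropically per frame — no covariance between atoms,
residues, or frames — so it validates the RMSF/RMSD estimators, not
protein dynamics. The separating-dimer generator translates body B rigidly
along the centre axis on a linear schedule scaled (by bisection on the
ΔSASA–displacement curve) so that the interface first reaches the
tolerance exactly at the requested frame, and verifies the construction.

## Pipelines and determinism

`RunConfig` centralises the analysis constants (30 nm contour cutoff,
0.1–1 nm persistence bounds, mean + 1·SD rmse rule, 20 pN drop threshold,
4.0 Å salt-bridge cutoff, probe 1.4 Å, k_max 3, final-sixth window); a
regression test asserts the defaults. A flat key=value file can override
any of them; every override is logged. Reports carry a manifest (package
version, seed, config snapshot, SHA-256 digests of the inputs, per-stage
record counts); identical configuration and inputs produce byte-identical
reports, since every stochastic stage consumes an explicit seed.

## Problem sizes

The recovery analyses use 25 replicate samples per condition at the
experimental sample sizes (n = 2000 wild-type conditions, n = 1500 mutant
conditions) and report medians; the filtering experiment uses 500 curves
at 20% contamination; RMSF recovery uses 10⁴ frames; SASA convergence uses
50-atom random structures. These sizes make the statistical checks sharp
while keeping a full run of the suite and the acceptance script in the
minutes range on a single CPU.

## Known limitations

* Thermal cantilever calibration uses plain equipartition without the
  optical-lever geometry factor (~0.8 for rectangular levers); calibrated
  values are therefore systematically high by that factor on real
  instruments.
* Single pulling velocity only: no loading-rate (Bell–Evans) analysis, no
  bond-lifetime estimation, no multi-tether deconvolution.
* The PDB reader rejects insertion codes (integer residue numbering only)
  and takes the first-listed altloc.
* No MD/SMD engine: trajectories are read (multi-frame XYZ plus a PDB
  topology) or synthesised; force fields, thermostats, and electrostatics
  are out of scope.
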