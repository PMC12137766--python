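# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic phantom does and does not emulate.

## Bloch model of the two-inversion cycle

The sequence is modeled at the level of longitudinal magnetization only.
One inversion-recovery (IR) period of length `tr_ir` contains, in order:
an instantaneous inversion Mz → −β·Mz (efficiency β, default 1.0 — an
ideal adiabatic pulse; incomplete inversion is supported but no value is
assumed), free T1 relaxation between events using the exact exponential
solution, and two blocks of `shots_per_ti_block` excitations spaced
`tr_shot`, centered on `ti1` and `ti2`, with block-specific flip angles
α1 and α2.  Each excitation produces transverse signal Mz·sin α and
leaves Mz·cos α; transverse magnetization is assumed perfectly spoiled
between shots, so no T2/T2* decay, off-resonance precession within a
shot, slice-profile or magnetization-transfer effects are modeled.  `te`
is carried as protocol metadata only.

The recursion is event-driven (closed-form exponential segments), not an
ODE integration; a fixed-step forward-Euler integrator (Δt = 0.01 ms)
exists in the test suite and acceptance script purely as an independent
oracle, and agrees with the event-driven path to < 1e−4 relative.

Steady state is reached by chaining cycles (default cap 50) until
consecutive cycles agree to 1e−9, relative to M0 so the criterion is
amplitude-invariant.  Iteration was chosen over solving the linear fixed
point directly: it is simpler, equally exact at this tolerance, and the
transient cycles are themselves useful output.

**Timing conventions.** The TI of each block refers to the *center* of
the shot block, which under linear segment ordering is when the k-space
center is acquired; the reported signals s1, s2 are those of the middle
shot (index `n//2`).  The block must fit between the inversion and the
end of the cycle — this is enforced by the protocol validator.  The
number of shots per block is an explicit protocol parameter (default 27
for the shipped whole-brain protocol, which reproduces the ~3.5 min
four-polarity duration; 3 for the acquisition-matched protocol): the
looping of a real multi-shot acquisition across kz planes and IR cycles
is more intricate than any simple closed form, so total scan time is a
plausibility quantity, not an exact claim.

**B1.** A relative transmit scale b1 multiplies both flip angles.
Scaling flip angles and scaling B1 are the same operation, which the
vectorized grid path exploits: signals over a B1 axis are computed as
signals over a flip-angle axis in one pass.

## Contrast and CNR

Contrast between two tissue signals is the bounded relative difference
C = (a − b)/(|a| + |b|).  Noise of SD σ per signal propagates to first
order (delta method) with analytic partials evaluated away from sign
changes, and CNR = C/σ_C.  Two non-obvious consequences:

* When a and b have **opposite signs**, C is locally constant at ±1 and
  its first-order noise is exactly zero; the delta method is then
  uninformative (CNR → ∞).  The scalar API returns signed infinity (and
  Monte-Carlo sampling confirms an SD of numerically zero at small σ);
  the grid optimizer marks such nodes NaN and excludes them from the
  argmax, since an infinite-CNR plateau at a signal zero-crossing is a
  model artifact, not an acquisition optimum.
* With the (GM − WM) ordering and signed signals, the longer-T1 tissue
  recovers *less* at TI1, so the TI1 contrast of a GM/WM pair is
  negative; optimization therefore maximizes |CNR|.

The default objective is the TI1 image (the T1-weighted image used for
segmentation); the TI2 image and the combined s1/s2 ratio (noise
propagated through the quotient per tissue first) are selectable.
Optimization is an exhaustive grid search — the surface is smooth but
can host several basins, and 900 nodes cost well under a second in the
vectorized path.  Ties resolve to the smallest α1, then α2.  Default
tissue T1 values are GM 1900 ms and WM 1200 ms (typical 7 T values);
both are parameters everywhere.

## Lookup-table T1 quantification

The table maps T1 → s1/s2 on a 600–3000 ms axis in 10 ms steps
(defaults; both configurable).  The signed ratio is used — the pipeline
averages complex data, so the TI1 image retains its sign; a
magnitude-ratio variant would fold the curve and lose monotonicity below
the TI1 zero-crossing.  Inversion is piecewise-linear on the largest
strictly monotonic run of the table; out-of-range ratios and voxels with
|s2| below a floor (default 1e−8, in image units) become NaN rather than
being clamped, so downstream consumers see failures.

B1 enters through a family of tables at bin centers spanning the
supplied B1 map's range, with nearest-bin assignment — a first-order
treatment of transmit inhomogeneity.  The default is **50 bins**: over a
0.7–1.3 relative-B1 range, the recovered-T1 sensitivity to a B1 offset
is roughly 8 ms per 0.01, so 20 bins (bin half-width 0.015) would leave
a discretization error comparable to the 10 ms lookup grid step, while
50 bins push it to ~4 ms at negligible cost (table construction is
vectorized over the T1 axis).

## Digital phantom and forward simulator

The phantom is a nested anisotropic ellipsoid: WM core, GM ribbon (≥ 3
voxels thick at 64³), CSF shell, air background; compartment T1/M0
defaults are CSF 2800/1.0, GM 1900/0.8, WM 1200/0.7.  Nuisance fields:
a low-order polynomial B0 (±~15 Hz) plus one Gaussian off-resonance blob
(default 30 Hz, emulating air-cavity inhomogeneity), and a smooth radial
transmit profile spanning 0.7–1.3.  Cortical depth is the normalized
radial coordinate through the ribbon (0 = WM surface, 1 = pial).  The
seed jitters geometry, polynomial coefficients and blob position, so
seeds give distinct but statistically comparable phantoms;
everything is bit-reproducible given (seed, settings).

The forward simulator composes, in order: (i) the ideal steady-state
signal image (Bloch signals tabulated per compartment over 400 fine B1
bins — effectively a continuous transmit field, deliberately finer than
the analysis-side binning); (ii) geometric distortion, a pull-resampling
along the phase-encode axis by d = B0[Hz]·esp_eff[s]·N_pe voxels, sign
set by the PE polarity, with Jacobian intensity modulation (mass
conserved to < 0.5%); (iii) an N/2 ghost: a half-FOV-rolled copy added
with pure-imaginary weight whose sign flips with read polarity — the
minimal model under which complex read-averaging cancels it exactly;
(iv) an additive low-spatial-frequency sinusoidal ripple, also
read-polarity–flipping, scaled to the WM signal (defaults: ghost 5%,
ripple 3% — arbitrary fixture amplitudes, no quantitative artifact model
is claimed); (v) complex Gaussian noise, seeded per volume.

What the phantom does **not** emulate: realistic anatomy and partial
volume at tissue borders beyond linear resampling, T2*-blurring of the
echo train, motion, parallel-imaging noise amplification and ghosting
beyond the two-parameter sign-flip model, and physiological noise.
Passing tests therefore validate the *computational* pipeline —
signal model, inversion, cancellation algebra, field estimation and
scaling — not robustness to in-vivo confounds.

## Polarity combination

Complex read-polarity averaging is a plain unweighted mean; magnitude is
root-sum-of-squares of real and imaginary parts.  Inputs are assumed
registered (motion correction is upstream and out of scope); a guard
compares the centers of mass of smoothed, low-value-suppressed
magnitudes and rejects pairs shifted by more than 0.25 voxels.  The
quarter-voxel tolerance reflects that the sign-flipping artifacts the
pair legitimately carries already displace the apparent center of mass
by up to ~0.1 voxel at the default amplitudes, while genuine
misregistration shows up at half a voxel and above.  Temporal SNR is
mean/SD (ddof = 1) over a volume series, NaN where the SD is zero.

## Displacement-field estimation and scaling

The estimator is a deliberately minimal 1-D variational method — a
functional stand-in for general reverse-PE tools (TOPUP-style), not a
re-implementation of any of them; only the displacement component along
the phase-encode axis is estimated, which is all the scaling logic
needs.  The field d (voxels, positive toward increasing index, defined
as the acquisition displacement of the +PE image under the pull
convention `out(x) = img(x + d(x))`) is parameterized by trilinear
interpolation of a node grid and found by minimizing

    mean[(warp(I+, −d) − warp(I−, +d))²] + λ · mean[(Δ²c / h²)²]

— each image corrected with its full field (the relative displacement of
the pair is 2d), with Jacobian modulation, plus a bending penalty on the
node grid expressed as curvature (second differences over h²) so that λ
(default 0.1) means the same thing at every pyramid level.  Coarse-to-fine:
node spacings 4×, 2×, 1× the final knot spacing (default 4 voxels) with
Gaussian image smoothing σ = 2, 1, 0.  Optimization is gradient descent
with a backtracking line search that only accepts steps decreasing the
penalized objective without increasing the data term, so the SSD history
is non-increasing within each level by construction.  The gradient drops
the Jacobian-derivative coupling terms; the line search guarantees
monotonicity regardless.  Everything is deterministic.

Scaling a field multiplies displacements and the echo-spacing tag by the
same factor: 0 gives the distortion-free target, negative factors invert
the field, `target/source` synthesizes a matched dataset.  Warping uses
linear interpolation with edge padding; Jacobian modulation is on by
default.  On 64³ phantoms with 10–50 Hz blobs the estimator recovers
fields of up to ~3 voxels with RMSE ≈ 0.02–0.1 voxels inside the brain.

## Depth profiles

Scalar maps are pooled into equal-width depth bins (default 21) over a
supplied depth map and mask; the landmark detector returns the most
prominent interior local minimum (boundary bins excluded to avoid
partial-volume edges), with a prominence threshold in map units (default
50 ms for T1).  Layering itself (surfaces, equivolume depths) is out of
scope — the phantom supplies the depth map, as external tools do for
in-vivo data.

## Workflows and problem sizes

The retrospective workflow chains: four-polarity session → complex
read-averaging per PE polarity → field estimation from the TI2 magnitude
pair (TI2 has stable positive signal; TI1 can cross zero) → full
correction of both PE polarities and averaging → distortion-free and
distortion-matched syntheses → T1 maps → GM depth profile → JSON report
with per-compartment recovery errors.  The acquisition-matched workflow
instead chooses the segmentation factor to hit the target effective echo
spacing and maps T1 directly from the read-averaged +PE volumes.

Simulated problem sizes are 64³ voxel phantoms, 10 ms lookup grids,
30×30 flip-angle grids, 1e6 Monte-Carlo draws, and ten phantom seeds for
field-recovery statistics; these sizes make the full test suite and the
acceptance script each run in a few minutes on one CPU while keeping
every estimate's sampling error far below its acceptance margin.

## Known limitations

* The Mz model ignores T2* decay and magnetization transfer during the
  echo train; quantitative T1 inherits whatever bias those cause in a
  real acquisition.
* B1 handling is first-order (binned lookup tables); strong transmit
  gradients within a voxel are not modeled.
* The field estimator assumes smooth, moderate fields (|∂d/∂x| < ~0.5);
  signal-void regions and fold-overs are out of its design range.
* The alignment guard detects bulk shifts only; it is not a substitute
  for motion correction.
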