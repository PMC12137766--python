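# t1234

Tools for a **T1-weighted two-inversion segmented 3D-EPI** structural
mapping method: forward Bloch simulation of the inversion-recovery
Look-Locker cycle, CNR-optimal flip-angle selection, lookup-table T1
quantification with transmit-field (B1) correction, artifact
cancellation by dual-polarity complex averaging, and reverse-phase-encode
distortion-field estimation and scaling — exercised end-to-end on a
synthetic digital brain phantom.

## The problem

High-resolution fMRI at 7 T reads out with EPI, which geometrically
distorts the image along the phase-encode axis in proportion to the local
B0 off-resonance and the *effective echo spacing* of the readout.
Conventional structural references (e.g. MP2RAGE) are distortion-free, so
registering them to distorted functional data is the hard step that
limits laminar analyses.  The approach implemented here acquires the
structural reference itself with a segmented 3D-EPI readout whose
distortion is **adjustable**: either matched to the functional data at
acquisition time (same effective echo spacing), or acquired almost
distortion-free with high segmentation and then *retrospectively* warped
by a scaled displacement field to any desired distortion level,
including zero.

## The model

Each inversion-recovery cycle of duration TR_IR starts with an adiabatic
inversion, Mz → −β·Mz (efficiency β), followed by two blocks of
excitation pulses centered on the inversion times TI1 and TI2 with
block-specific flip angles α1, α2.  Between events Mz relaxes as

    Mz(t+Δ) = M0 + (Mz(t) − M0) · exp(−Δ/T1),

and each pulse of angle α produces transverse signal Mz·sin α, leaving
Mz·cos α (spoiled readout).  The excitation train accelerates the
apparent recovery (Look-Locker): a constant train of period τ converges
to M0(1−E)/(1−E·cos α) with rate 1/T1* = 1/T1 − ln(cos α)/τ, E =
exp(−τ/T1).  Cycles are chained to their periodic steady state; the
signed ratio s1/s2 of the k-space-center signals at the two inversion
times is strictly monotonic in T1 over 600–3000 ms and is inverted per
voxel through B1-specific lookup tables.

GM–WM contrast is C = (S_GM − S_WM)/(|S_GM| + |S_WM|) ∈ [−1, 1];
first-order Gaussian propagation of per-image noise σ gives σ_C and
CNR = C/σ_C, maximized by exhaustive search over the (α1, α2) grid.

Geometric distortion is a 1-D voxel displacement along the phase-encode
axis, d = ΔB0[Hz] · esp_eff[s] · N_pe, with sign set by the phase-encode
polarity; the N/2 ghost flips sign with the *read* polarity, so averaging
the complex volumes of opposite read polarities cancels it exactly.  A
displacement field estimated from the opposite-PE pair scales linearly
with effective echo spacing: multiplying it by `target/source` synthesizes
any distortion level from one acquisition.

## Worked example

```bash
python examples/04_t1_mapping_phantom.py
```

```
lookup table: 241 T1 nodes, ratio +0.655 -> -0.049 over 600-3000 ms (monotonic)
CSF: true 2800 ms, recovered median 2801.7 ms, median |error| 11.4 ms
GM: true 1900 ms, recovered median 1900.6 ms, median |error| 4.0 ms
WM: true 1200 ms, recovered median 1200.1 ms, median |error| 1.9 ms
```

The table maps the TI1/TI2 signal ratio to T1; on a noise-free 64³
phantom with a smooth 0.7–1.3 transmit field, voxelwise inversion with
50 B1-binned tables recovers the compartment T1 values to a few
milliseconds (the residual is B1-bin discretization, not the 10 ms
lookup grid).  The other examples cover protocol arithmetic
(`01`), the Bloch trajectory (`02`), flip-angle optimization (`03` —
optimum at α1/α2 = 20°/9° for the shipped whole-brain protocol),
distortion-field estimation and synthesis (`05`), and cortical-depth
landmark detection (`06`).

The same functionality is exposed as a thin CLI:

```bash
t1234 protocol validate retrospective
t1234 cnr optimize --protocol retrospective --grid 1:30:1 --out surface.csv
t1234 workflow retrospective_matched --seed 7 --out run/
```

Two protocol parameter sets ship with the package
(`retrospective`: TI1/TI2/TE/TR_shot/TR_IR = 930/2368/8/23/3097 ms,
14-fold segmented; `acquisition_matched`: 1378/3793/26/78/5050 ms,
effective echo spacing 0.35 ms).

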