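# Whole-brain 0.8 mm protocol intended for retrospective distortion matching.
# Highly segmented EPI readout -> very small effective echo spacing, so the
# acquired images are nearly distortion-free; any desired distortion level is
# synthesized afterwards by scaling the estimated displacement field.
name: retrospective
ti1: 930.0        # ms
ti2: 2368.0       # ms
te: 8.0           # ms (metadata only)
tr_shot: 23.0     # ms
tr_ir: 3097.0     # ms
fa1: 10.0         # degrees, TI1 block excitation
fa2: 10.0         # degrees, TI2 block excitation
n_segments: 14    # EPI segmentation factor
matrix: [232, 232, 186]
partial_fourier: 6/8
caipi_dz: 3       # skipped-CAIPI 1x3z1
r_inplane: 1
echo_spacing: 1.05        # ms, actual per-line; effective = 1.05/14 = 0.075 ms
inversion_efficiency: 1.0
shots_per_ti_block: 27
voxel_size: [0.8, 0.8, 0.8]
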