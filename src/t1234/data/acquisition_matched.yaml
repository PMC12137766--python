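# Whole-brain 0.8 mm protocol whose effective echo spacing (0.35 ms) equals
# that of a standard 7 T functional EPI protocol, so the structural images
# carry the same geometric distortion as the functional data by construction.
name: acquisition_matched
ti1: 1378.0       # ms
ti2: 3793.0       # ms
te: 26.0          # ms (metadata only)
tr_shot: 78.0     # ms
tr_ir: 5050.0     # ms
fa1: 10.0
fa2: 10.0
n_segments: 1
matrix: [232, 232, 186]
partial_fourier: 6/8
caipi_dz: 3
r_inplane: 3
echo_spacing: 1.05        # ms; effective = 1.05/(1*3) = 0.35 ms
inversion_efficiency: 1.0
shots_per_ti_block: 3
voxel_size: [0.8, 0.8, 0.8]
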