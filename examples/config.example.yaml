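# Example pipeline configuration for `dcfseg extract --config ...`.
# Command-line flags override these values; the effective configuration is
# echoed into every result and report.

roi: [150, 180, 650, 430]     # x0, y0, x1, y1 (half-open box)
pixel_spacing: [0.01, 0.01]   # cm per pixel (sx, sy); omit to use DICOM PixelSpacing

alpha_cut: 0.5                # fuzzy membership cut
connectivity: 8               # blob labeling connectivity (4 or 8)
noise_size_frac: 0.085        # object dropped below this fraction of ROI area
left_margin_frac: 0.1         # left-skew clause: object starts left of this fraction...
min_width_frac: 0.5           # ...and is narrower than this fraction of ROI width
bridge_iterations: 1          # gap-bridging passes after boundary filling
expand_radius: 1              # dilation radius in the vertebra stage
restore_divisor: 1000.0       # distance-weight divisor of the restoration boost
offset_cm: 1.0                # lateral offset of the two side measuring columns
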