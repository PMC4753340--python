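"""Extract the DCF from one synthetic sonogram and measure its thickness.

Generates a phantom with known ground truth, runs the full pipeline and
prints the measured thickness next to the true value.  The three chords are
the vertical distances between the superficial fascial echo and the
vertebral echo line at the key column and 1 cm to either side.
"""

from dcfseg import PhantomParams, PipelineConfig, generate_phantom, run_pipeline

img, truth = generate_phantom(PhantomParams(seed=1))
result = run_pipeline(img, PipelineConfig(roi=truth.roi))

print(f"success:            {result.success}")
print(f"vertebrae found:    {result.vertebrae.n_objects}")
print(f"key point (ROI):    {result.key_point}   truth: {truth.key_point_roi()}")
for c in result.chords:
    print(f"  chord at x={c['x']:3d}: {c['length']:.3f} cm")
print(f"measured thickness: {result.thickness_cm:.3f} cm")
print(f"true thickness:     {truth.thickness_cm:.3f} cm")
print(f"absolute error:     {abs(result.thickness_cm - truth.thickness_cm):.3f} cm")
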