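# dcfseg

Automatic extraction and thickness measurement of the **deep cervical flexor
(DCF)** muscle group (longus capitis/colli) in B-mode cervical ultrasound.

Ultrasonographic assessment of the DCF — a deep neck muscle central to
craniocervical stability and neck-pain rehabilitation — is normally done by
hand: a sonographer identifies the muscle band between its superficial fascia
and the cervical vertebrae and measures its thickness with calipers. That
judgment is subjective, and the DCF's neighborhood is a particularly
low-contrast one: muscle, fascia and vertebral echoes have similar
brightness. `dcfseg` implements a fully automatic computer-vision chain for
this measurement, aimed at physiotherapy/ultrasound researchers who want an
operator-independent thickness readout, plus a synthetic sonogram *phantom*
generator with exact ground truth so the whole chain can be validated without
clinical data.

## Method

Given an 8-bit grayscale sonogram and a rectangular region of interest (ROI)
containing the DCF band and the vertebrae below it:

1. **Ends-in search stretching.** Contrast normalization
   `P = 255·(G − Min)/(Max − Min)`, clamped to 0 below `Min` and 255 above
   `Max`; preserves intensity ordering, unlike speckle filtering.
2. **Candidate band.** Average binarization (threshold = mean), connected
   component ("blob") labeling, and object-level noise removal: an object `O`
   in a `W × H` ROI is dropped iff
   `S(O) < 0.085·S(ROI)` **or** (`O.left < 0.1·W` **and** `Width(O) < 0.5·W`).
   Each column is then filled between its top and bottom surviving boundary
   pixels, one-pixel gaps are bridged, contours are traced by 4-directional
   search, and the band's upper/lower boundary curves are completed with a
   natural cubic spline (`S″ = 0` at both end knots).
3. **Vertebral echoes.** *Fuzzy sigma binarization*: from the image min/mid/max
   a sigma-shaped membership ramp is derived (support `[P_mid − β, P_mid + β]`,
   `u = 0` at the lower end rising linearly to `1` at `P_mid`), cut at
   α = 0.5. This keeps the dim deep portions of the bone echoes that a mean
   or Otsu threshold clips. After blob labeling, noise removal and one
   dilation, candidate vertebrae lying strictly above the band's lower line
   are rejected as subcutaneous fat; if the leftmost surviving vertebra sits
   in the right half of the ROI, the grayscale is boosted by the distance
   weight `α = 1 + ((x−x₁)² + (y−y₁)²)/1000` (clamped at 255) and
   re-thresholded once.
4. **Thickness.** The key point is the rightmost pixel of the leftmost
   vertebral object. Thickness is the mean of the three vertical chords
   between the band's upper boundary and the vertebral echo line (gaps
   DDA-interpolated, `y = round(m(x−x₁)+y₁)`) at the key column and ±1 cm.

Calibration comes from DICOM `PixelSpacing` or a user-supplied cm/px value.

## Worked example

```sh
python examples/extract_from_phantom.py
```

```
success:            True
vertebrae found:    3
key point (ROI):    (191, 115)   truth: (189, 114)
  chord at x= 91: 1.010 cm
  chord at x=191: 1.040 cm
  chord at x=291: 1.010 cm
measured thickness: 1.020 cm
true thickness:     1.010 cm
absolute error:     0.010 cm
```

The phantom (seed 1) drew a DCF thickness of 1.010 cm; the pipeline located
the three vertebral echoes, anchored the key point within 2 px of truth and
measured 1.020 cm — a 0.01 cm error, well inside the 0.3 cm band clinically
regarded as a faithful measurement. `examples/compare_binarizers.py` shows
why the fuzzy binarizer is used (it recovers 99.5% of vertebral-echo pixels
vs 99.1% for average and 95.4% for Otsu thresholding on the default
phantoms), and `examples/batch_error_histogram.py` reproduces the batch
error-histogram report.

The same pipeline is scriptable from the shell:

```sh
dcfseg phantom --n 5 --seed 1 --out scratch/phantoms
dcfseg extract scratch/phantoms/phantom_0001.png \
    --roi 150,180,650,430 --pixel-spacing 0.01 \
    --out scratch/result.json --overlay scratch/overlay.png
dcfseg batch scratch/phantoms --roi 150,180,650,430 \
    --pixel-spacing 0.01 --report scratch/report
```

## Layout

- `src/dcfseg/` — `imgio` (DICOM/PNG/TIFF, ROI), `enhance` (stretching),
  `binarize` (average/Otsu/fuzzy sigma), `morph` (blobs, noise rule, filling,
  dilation, contour tracing), `curves` (splines, DDA), `pipeline`
  (orchestration, key point, thickness), `phantom` (synthetic data),
  `cli`/`report`/`overlay` (tooling).
- `examples/` — one narrative script per capability.
- `docs/methods.md` — modelling notes, parameter table and limitations.
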