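# stain3d

Quantitative image computation for whole-mount 3D immunostaining of mouse
brain tissue. When intact specimens are stained with commercial antibodies
and imaged by optical projection tomography (OPT) or serial two-photon
tomography, four computational problems stand between the raw channels and
a biological readout:

1. **How far did the label penetrate?** Antibody/tracer penetration is
   quantified from slice images by sampling intensity along lines normal to
   the tissue edge. For free diffusion the profile is
   `C(x, t) = C0 · erfc(x / (2√(Dt)))`, so curves taken at different
   incubation times *t* collapse onto a single curve when depth is plotted
   as `x/√t`. Each curve's amplitude is normalized by the edge value from a
   third-order polynomial fit, and equivalent curves are averaged with a
   pointwise 90% Student-t confidence band.
2. **What part of the stain channel is real?** Endogenous autofluorescence,
   imaged in its own channel, bleeds into the stain channel at an unknown
   scale α. The scale is estimated by robust linear regression of the stain
   on the autofluorescence over background pixels and subtracted
   (`stain − α·auto`, clipped at 0). Smooth multiplicative non-uniformity
   (edge brightening from light scatter) is removed by dividing out a
   low-order polynomial surface fit to log intensity.
3. **Which bright pixels are artifacts?** Unreacted antibody leaves isolated
   high-intensity pixels. They are found by a median-filter high-pass,
   normalization by a local robust SD, and thresholding (default 5 SD);
   the high-pass value is subtracted only at flagged pixels, so everything
   else is preserved bit-exactly.
4. **How are the cells distributed?** Detected cell centroids (Gaussian
   blur → intensity threshold ∧ local rank filter → 8-connected clusters →
   mean pixel location) are converted to an area-density map on a coarse
   grid: at each node the `k = 8` nearest cells give
   `λ̂ = k / (π · mean(dᵢ²))` cells/mm², displayed on a linear gray scale
   between 30 (black) and 1200 (white) cells/mm².

Because public reference data do not exist for this workflow, the package
ships a first-class synthetic module: seeded two-channel phantoms with
known bleed-through, bias field, punctate artifacts and noise; analytic
diffusion fronts; inhomogeneous Poisson cell patterns; and a parallel-beam
projector/FBP pair so the whole chain can run on reconstructed images. The
generators return their ground truth, so every stage is tested against
known answers.

Intended users: imaging scientists and image-analysis developers who need a
tested, reproducible implementation of these procedures, or a ground-truth
harness for their own variants.

## Worked example

`examples/channel_corrections.py` generates a 256×256 two-channel phantom
(bleed-through scale 0.7, 50 punctate artifacts, 20% bias field, noise SD 5)
and runs the correction chain against its ground truth:

```
punctate artifacts injected:  50
pixels flagged:               50 (recall 100%, 0 false positives)
bleed-through scale:          0.7003 (truth 0.7)
clipping fraction:            0.4799
bias field max rel error:     0.23%
```

Every injected hot pixel is flagged with no false alarms; the regression
recovers the generating bleed-through scale to 0.05%; the polynomial
surface matches the known bias field to a quarter percent. (The clipping
fraction is the share of pixels that went negative on subtraction — large
here because the phantom background is pure bleed-through plus zero-mean
noise, half of which clips.)

The other examples each print one capability end to end:

| script | shows |
|---|---|
| `examples/penetration_profiles.py` | √t collapse, amplitude normalization, 90% band |
| `examples/density_mapping.py` | point pattern → detection → kNN density map with a density step |
| `examples/tomography_roundtrip.py` | 360-view projection and FBP (r = 0.9997) |
| `examples/full_pipeline.py` | seeded end-to-end run with provenance record |

A thin CLI exposes the same stages
(`stain3d simulate | diffuse-profile | correct | detect | density |
reconstruct | run`); run `stain3d --help`.

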