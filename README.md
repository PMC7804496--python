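# radialcontrast

Radially generalized contrast energy for visual crowding stimuli.

Visual crowding — the failure to *identify* a peripheral target when
flanking objects sit nearby, even though the target alone is perfectly
legible — has accumulated a thicket of specialised models.  This package
implements a much simpler account: a contrast-energy metric built from the
centre-surround receptive fields of the early visual stream, plus a
one-parameter mapping from that metric to behavioural accuracy.  It is
aimed at visual psychophysicists and computational neuroscientists who
want to check how much of a crowding result is carried by image contrast
alone, before invoking pooling, grouping or attentional machinery.

## The metric

An image `i` is filtered with a difference-of-Gaussians kernel

```
ς = M_σF − M_σB,    M_σ(p, q) = (2πσ²)⁻¹ exp(−(p² + q²) / 2σ²)
```

where the foreground (centre) scale σ_F follows midget ganglion cell
dendritic-field diameters at the stimulus eccentricity (power law
`y = 8.64·x^1.04` µm at `x` retinal mm) and the surround is a fixed
multiple σ_B = K·σ_F (K = 5).  The radially generalized contrast energy is
the per-pixel Euclidean semi-norm of the filtered image,

```
C(v) = sqrt( mean( (ς ∗ i)² ) )
```

It is nonnegative, absolutely homogeneous and subadditive, and with the
degenerate mask (impulse foreground, uniform background) it reduces
exactly to ordinary RMS contrast.  Unlike pixelwise contrast measures, it
is sensitive to the *neighbourhood* of each pixel, so flankers change it.

## From contrast to behaviour

Two Gaussians in contrast-energy space share the target-alone mean μ_τ:
`G_τ` (width σ_τ, fixed by the calibration that a 10 % contrast change
yields a 1 % identification rate, σ_τ = 0.1·μ_τ/√(−h) with h = 2 ln 0.01)
and `G_ϕ` (width k_ϕ·σ_τ, set by the single experiment-derived parameter
E_α, the contrast energy at which flankers first impede identification).
Predicted proportion correct is

```
p = 0.85 · [ G_τ(C) + 1 − G_ϕ(C) ]
```

with 0.85 the empirical performance ceiling of the modelled experiments.

## Worked example

Reproduce the annulus-plus-flanking-bars acuity experiment (condition
`KA`: Landolt C at 5° eccentricity viewed from 23 m, flanking bars at
0.06–4 arcmin, σ_F = 10.88 px):

```python
import radialcontrast as rc

config = rc.experiment_config("KA")
points = rc.run_experiment(config)
print(rc.curve_frame(points)[["flank_distance_arcmin", "contrast_energy",
                              "contrast_ratio", "proportion_correct"]]
      .round(4).to_string(index=False))
```

```
 flank_distance_arcmin  contrast_energy  contrast_ratio  proportion_correct
                  0.06           0.0562          1.3739              0.4076
                  0.12           0.0553          1.3520              0.3735
                  0.18           0.0536          1.3114              0.3096
                  0.24           0.0528          1.2928              0.2805
                  0.30           0.0515          1.2595              0.2294
                  0.60           0.0485          1.1874              0.1286
                  0.90           0.0481          1.1764              0.1150
                  1.20           0.0491          1.2017              0.1471
                  1.80           0.0522          1.2778              0.2573
                  2.40           0.0547          1.3387              0.3526
                  3.00           0.0564          1.3800              0.4171
                  4.00           0.0576          1.4082              0.4597
```

`contrast_ratio` is contrast energy relative to the isolated target.  The
curve shows the signature crowding profile: bars touching the C leave
contrast comparatively high (~41 % predicted correct at 0.06′), contrast
then *falls* into a worst-case "sweet spot" as the bars move into the
surround of the receptive field, and recovers monotonically once they
clear it, flattening toward an asymptote by a few arcminutes.

The same pipeline drives the other shipped conditions: `PL`/`PS` (letter
with letter flankers across 5–20° eccentricity), `HE` (vernier with 2–16
flanking lines of three heights) and `PA1`/`PA5` (Landolt C inside one or
five concentric flanking Cs or rings).  `rc.reproduce_table1()` recomputes
every derived column of the shipped condition table and flags the
internally inconsistent `PL`/`PS` width-ratio entries, which match the
defining formula only when their two E_α values are exchanged.

A CLI mirrors the library:

```
radial-contrast run KA --out out/         # curve CSV (+ optional maps)
radial-contrast table1                    # derived-column comparison
radial-contrast stimgen PA5 --out stim/   # stimulus PNGs + manifest
radial-contrast metric img.png --sigma 2  # metric on a user image
```

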