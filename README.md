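# sargassum

Quantification of pelagic *Sargassum* from satellite ocean-colour imagery,
together with the in-situ neuston-tow density analysis used to validate it.

Holopelagic *Sargassum* (the morphotypes *S. natans* var. *natans*,
*S. fluitans* and *S. natans* var. *wingei*) forms floating rafts whose
basin-scale abundance is monitored from space: rafts have a strong red-edge
reflectance signal that an ocean-colour band-ratio index picks up even when
they cover a small fraction of a 1-km pixel. This package implements the
full quantification chain from Rayleigh-corrected reflectance (Rrc) scenes
to regional wet-biomass time series, the weighted-density analysis of net
tows, and the two-sample statistics used to test abundance changes between
eras — plus a synthetic-data generator with known ground truth so the whole
pipeline is testable end to end without any satellite download.

## The method

**Index.** For each pixel the Alternate Floating Algae Index is the 748-nm
reflectance excess above a linear baseline between 667 and 869 nm:

```
AFAI = Rrc(748) − [Rrc(667) + (Rrc(869) − Rrc(667)) · (748−667)/(869−667)]
```

**Masking.** Pixels flagged LAND or CLDICE are excluded, as is everything
within 10 km of land or 2 km of cloud (centre-to-centre on the projected
1-km grid).

**Detection and unmixing.** *Sargassum*-containing pixels (default: a tiled
median-threshold detector; any segmentation model can be plugged in) are
grouped into 8-connected patches, discarding patches smaller than 3 pixels.
Each patch pixel's ΔAFAI is its AFAI minus the median AFAI of valid
non-*Sargassum* pixels within a 13-pixel dilation of the patch, and the
sub-pixel fractional coverage is the linear unmixing
`f = clamp(ΔAFAI / 4.41×10⁻², 0, 1)`, where 4.41×10⁻² is the AFAI excess of
a fully covered pixel.

**Biomass.** Fractional coverages are averaged into monthly/annual
0.5° × 0.5° composites (non-detected valid pixels count as 0), converted to
wet biomass with 3.34 kg m⁻², summed over region polygons, and organised by
ecological year (March–February; January/February belong to the previous
year) and season (MAM/JJA/SON/DJF).

**In situ.** Neuston tows (1.0-m net mouth, ~2 kn × 30 min ≈ 1 nm) yield
wet mass per morphotype. The density statistic is the weighted arithmetic
mean — total mass over total swept area for all tows in a region/period,
scaled to kg km⁻² — a ratio of sums, never a mean of per-tow ratios.

**Change statistics.** Annual biomass of two eras is compared with a
two-sample variance-ratio F-test followed by a Student's t-test (pooled
flavour when the F-test accepts equal variances, Welch otherwise), and
seasonality is described with per-month Tukey box statistics (type-7
quartiles, 1.5 × IQR whiskers).

## Worked example

```python
import sargassum as sg
from shapely.geometry import box

cfg = sg.SceneConfig(
    grid_rows=128, grid_cols=128,
    patch_spec=[sg.PatchSpec(row=40, col=40, footprint=3, fraction=0.6),
                sg.PatchSpec(row=80, col=90, footprint=2, fraction=0.25)],
    band_noise_sd=1e-4, seed=7)
scene, truth = sg.generate_scene(cfg)

grid = sg.compute_afai(scene)
mask = sg.build_valid_mask(scene)
patches, fraction = sg.quantify_scene(grid, mask, threshold=5e-4)
print(f"patches detected: {len(patches)}")
for i, p in enumerate(patches):
    print(f"  patch {i}: {len(p)} px, mean fraction {p.fraction.mean():.3f}, "
          f"background median AFAI {p.background_median:.6f}")

ras = sg.FractionRaster(fraction=fraction,
                        geotransform=scene.geotransform, date=scene.date)
comp = sg.composite_period([ras], period="month")[0]
biomass = sg.to_biomass(comp, sg.RegionSpec("scene", box(-61, -2, -55, 3)))
print(f"regional biomass: {biomass:.1f} t "
      f"(truth {truth.total_truth_biomass_kg/1000:.1f} t)")
```

prints

```
patches detected: 2
  patch 0: 9 px, mean fraction 0.599, background median AFAI -0.000202
  patch 1: 4 px, mean fraction 0.250, background median AFAI -0.000204
regional biomass: 21044.9 t (truth 21069.8 t)
```

The two injected rafts come back at their injected coverages (0.6 and 0.25,
blurred only by the 10⁻⁴ band noise), and the regional biomass from the
0.5° composite agrees with the known injected biomass to ~0.1%.

A console script exposes the same steps as subcommands
(`sargassum simulate-scene / simulate-tows / afai / detect / composite /
series / insitu-summarize / stats-compare`); run `sargassum --help`.

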