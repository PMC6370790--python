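# melanomap

Colour lightness of butterfly assemblages across climate gradients — a
tested, reusable implementation of the full analysis chain from specimen
images to spatial regression, exercised end-to-end on seeded synthetic
continents with known ground truth.

## The scientific problem

Melanin-based dark colouration helps ectothermic insects absorb solar
energy (the *thermal melanism hypothesis*) and is also implicated in
pathogen defence and UV protection. At macroecological scale these
hypotheses predict that butterfly *assemblages* — the sets of species
co-occurring in grid cells — should be darker in colder, more humid
regions and lighter in warmer, sunnier ones. Testing this requires
combining three data streams:

1. **Trait extraction.** Per species, *colour lightness* is the mean of
   the red, green and blue channel values (0 = black, 255 = white) over
   the body and the third of each wing closest to the body — the region
   most relevant for thermoregulation. Dorsal and ventral sides are scored
   separately; only females and monomorphic species are used, morphs are
   averaged, and species lacking either side are excluded. Taxonomically
   unstable species complexes are collapsed to single units with averaged
   traits and unioned ranges.
2. **Assemblage building.** Species range polygons are rasterized onto an
   equal-area grid (50 km × 50 km cells; presence = positive-area
   overlap). The assemblage trait of a cell is the unweighted mean
   lightness of the species present; cells with fewer than five species
   are dropped to stabilize the estimate.
3. **Environment & models.** Monthly insolation (INS, W m⁻²), air
   temperature (TMP, °C) and relative humidity (HUM, %) rasters are
   averaged to annual fields and aggregated per cell (area-weighted). For
   every continent × family scope × side × variable combination the model
   battery fits y ~ x and y ~ x + x² by OLS and classifies the shape:
   *n.s.* if neither model has overall-F p < 0.001; quadratic (*U* or
   *hump* by the sign of the x² coefficient) if Δr² = r²_quad − r²_lin
   is strictly greater than 0.1; otherwise *linear* with the slope's
   sign. A generalized least-squares model with Gaussian spatial error
   correlation, corr(i,j) = exp(−(d_ij/ρ)²) on Manhattan distances,
   checks that spatial autocorrelation does not distort inference, and
   Tukey HSD contrasts compare dorsal vs ventral lightness across
   families.

Because this kind of study hinges on scanned atlas images, digitized
expert range maps and a microclimate raster archive — inputs that are not
shippable — the package includes a first-class synthetic-data generator:
latitudinally structured climate, a species pool whose thermal optima are
coupled to true lightness through a configurable slope, climate-threshold
range polygons, and rendered specimen images whose distal wing carries a
deliberately different grayscale so region-of-interest errors are
detectable. Everything is reproducible from one seed.

## Worked example

```python
from melanomap import SynthConfig, gen_world, compute_lightness, render_specimen

cfg = SynthConfig(seed=1)
world = gen_world(cfg)
sp = world.pool[0]
print(sp.species_id, sp.family, sp.true_lightness_dorsal)
rend = render_specimen(sp, "dorsal", cfg)
print(round(compute_lightness(rend.image), 3))
```

prints

```
sp0000 Lycaenidae 87.0
86.939
```

— species `sp0000` was generated with a true dorsal lightness of 87; the
rendered specimen (Gaussian pixel noise, sd 3) is scored at 86.939 by the
channel-mean extractor, i.e. the image pipeline recovers the trait to
within the noise floor of a ~19,000-pixel region of interest.

The numbered drivers under `analysis/` run the whole study on two
synthetic continents and narrate what they find:

```bash
python analysis/01_simulate_worlds.py    # climate + species pools
python analysis/02_extract_traits.py     # image scoring + cross-source check
python analysis/03_build_assemblages.py  # grids, presence, environment
python analysis/04_fit_models.py         # OLS battery, GLS, Tukey HSD
python analysis/05_render_maps.py        # quantile choropleths
```

A typical `04_fit_models.py` run reports 60 model records with positive
lightness–insolation and lightness–temperature slopes and negative
lightness–humidity slopes on both continents (linear shapes, as
generated), GLS temperature slopes agreeing in sign with OLS, and a
dorsal−ventral contrast of ≈ −30 lightness units (dorsal darker), the
countershading offset the generator embeds.

The same pipeline is scriptable through a CLI
(`melanomap synth|lightness|grid|env|stats|report|all`), each stage
reading and writing open formats (TIFF + JSON sidecar rasters, GeoJSON
ranges, PNG specimens and masks, CSV tables with provenance headers).

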