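# goldendose

Biophysical modelling of gold-nanoparticle (GNP) radiosensitization, for
radiation biophysicists studying why measured DNA-damage enhancement does
not follow the macroscopic dose-enhancement prediction.

GNPs taken up by tumour cells sit in the cytoplasm, concentrated in a
perinuclear band just outside the nuclear envelope. Their photoelectric
cross-section boosts local energy deposition, but the short-range Auger
electrons that dominate dose near a particle cannot reach nuclear DNA from
there — only the long-range photoelectron can. This package implements
that idea quantitatively, together with the image analysis that measures
where the gold actually is:

* **Dose model** — nucleus as a sphere of radius `R`; gold as a
  homogeneous shell between `d1` and `d2` from the nucleus centre; an
  electron of energy `E_e` deposits uniformly in a sphere of radius
  `r = A E_e^B` (water penetration power law), and the nuclear energy
  fraction is the sphere-sphere intersection volume ratio averaged over
  the shell. Per open gold shell `s`,

      term_s(E) = w * tau_s(Au)/mu(water) * (E_e/E) * F(r(E_e)) * V_norm,
      enhancement(E) = 1 + sum_s term_s(E),       E_e = E - E_B(s),

  with `w` the gold weight fraction (default 0.007). The curve peaks at
  40 keV for the default geometry — far above the gold L edges, because
  just-liberated photoelectrons are too slow to cross the cytoplasm.
* **Image analysis** — Otsu segmentation of the nucleus channel, signed
  Euclidean distance from the boundary, gold intensity binned by distance
  (negative = intranuclear), and extraction of the model's `(d1, d2)`
  from the extranuclear signal quantiles.
* **Synthetic data** — mid-plane cell images with a planted perinuclear
  gold distribution, Gaussian PSF and exact Poisson counting noise, plus
  filtered Kramers bremsstrahlung spectra, so the whole pipeline is
  testable end to end with known ground truth.

Packaged physical constants (gold shell binding energies and jump ratios,
gold/water/aluminum attenuation coefficients on 1-160 keV grids) make the
package fully self-contained; see `src/goldendose/data/README.md` and
`docs/methods.md` for provenance, model assumptions and limitations.

## Worked example

```python
import numpy as np
from goldendose.enhancement import EnhancementConfig, enhancement_curve
from goldendose.imaging import gold_distance_profile, segment_nucleus
from goldendose.synthetic import SyntheticCellSpec, make_cell_image

# image round trip: where is the gold relative to the nuclear membrane?
image, truth = make_cell_image(SyntheticCellSpec(seed=0))
mask = segment_nucleus(image, "automatic")
profile = gold_distance_profile(image, mask, bin_width=0.25)
peak = profile.bin_centers[np.argmax(profile.intensity)]
print(f"gold peak at {peak:+.2f} um from the membrane")

# dose model with the default geometry (R = 7 um, shell 7-17 um, w = 0.007)
curve = enhancement_curve(EnhancementConfig(energy_grid=np.arange(10.0, 61.0, 1.0)))
print(f"enhancement peak {curve.enhancement.max():.3f} at {curve.argmax_energy():g} keV")
```

prints

```
gold peak at +0.50 um from the membrane
enhancement peak 1.147 at 40 keV
```

i.e. the pipeline recovers the planted perinuclear ring half a micron
outside the membrane, and the model predicts maximal DNA-damage
enhancement at 40 keV with a ~15% peak enhancement at 0.7% wt/wt gold.
The same numbers drive the narrative scripts under `analysis/`
(`01_simulate_cell.py` ... `04_broadband_fold.py`), which write their
tables to `results/`.

The command line mirrors the library:

```bash
goldendose enhance --grid 10 60 1 --out curve.csv      # peak at 40 keV
goldendose simulate spectrum --kvp 160 --filtration-mm 11.47 --out spectrum.csv
goldendose fold --curve curve.csv --spectrum spectrum.csv
goldendose run --out rundir                            # full pipeline
```

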