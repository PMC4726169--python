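# Methods

## The physical model

Gold nanoparticles taken up by a cell accumulate in the cytoplasm,
predominantly in a perinuclear band just outside the nuclear envelope.
When the cell is irradiated with keV X-rays, photoelectric absorption in
gold is far stronger than in tissue, and each ionisation launches a
photoelectron of energy `E_e = E_hv - E_B` (photon energy minus the shell
binding energy). The model asks a single geometric question: how much of
that photoelectron energy lands in the nucleus?

The nucleus is a sphere of radius `R` (default 7 um) of unit density. The
gold is a homogeneous spherical shell of emitters between radii `d1` and
`d2` from the nucleus centre (default 7-17 um, i.e. a 10 um cytoplasmic
band starting at the membrane). An electron born at distance `d` deposits
its energy uniformly in a sphere of radius `r(E_e)`, its maximum water
penetration. The fraction reaching the nucleus is the two-sphere
intersection volume over the electron sphere volume,

    f(r, R, d) = V_i(r, R, d) / (4/3 pi r^3),

with the three analytic branches (no overlap, full containment, lens),
and the shell-averaged factor is the d^2-weighted mean

    F(r) = Int_{d1}^{d2} f(r, R, d) d^2 dd / Int_{d1}^{d2} d^2 dd.

`F` is computed by adaptive Gauss-Kronrod quadrature with explicit split
points at the branch boundaries `d = |r - R|` and `d = r + R`
(`epsabs = 1e-12`, `epsrel = 1e-10`); a Monte-Carlo point-sampling oracle
(uniform emitters in the shell, uniform deposition points in the r-sphere)
guards the quadrature in the test suite at 4 standard errors.

### Range-energy relation

Electron penetration in water is a two-parameter power law
`r = A * E^B` (r in um, E in keV) fitted by least squares in log-log
space to three published checkpoints: 2 keV -> 0.1 um, 10 keV -> 1.5 um,
50 keV -> 20 um. The fit gives `A = 0.0326`, `B = 1.646` and reproduces
each anchor within 5%. Validity is 1-100 keV; ~100 eV electrons (ranges
of tens of nm) are outside the law and are excluded — in the enhancement
model any channel whose electron falls below 1 keV contributes zero,
which is also the physically right answer at these geometries (such
electrons cannot cross micrometres of cytoplasm).

### Enhancement factor

For each open shell `s` (K, L1, L2, L3, merged M) the extra dose to the
nucleus relative to the water dose is

    term_s(E) = w * [tau_s(Au)/rho](E) / [mu(water)/rho](E)
                * (E_e / E) * F(r(E_e)) * (d2^3 - d1^3) / R^3,

and the enhancement factor is `1 + sum_s term_s(E)`. Ingredients:

* `w` — gold weight fraction, default 0.007 (500 ug/ml dosing x 14-fold
  cellular concentration at unit density = 0.7% wt/wt).
* `tau_s(Au)/rho` — the gold photoelectric coefficient times the shell's
  partition weight, derived from edge jump ratios (crossing below an edge
  divides the coefficient by that shell's jump ratio; the merged M group
  absorbs the residual, so weights of open shells sum to one).
* `mu(water)/rho` — the **total** mass attenuation of water. The
  denominator is deliberately an energy-*transfer* reference, matching
  the numerator `tau_s * E_e/E` (energy transferred to photoelectrons),
  rather than the energy-absorption coefficient used for the macroscopic
  baseline. With this pairing the model reproduces its characteristic
  interior maximum at 40 keV for the default geometry; with
  `mu_en(water)` instead, the maximum would drift to ~48 keV because the
  denominator collapses too fast once Compton interactions dominate
  water attenuation.
* The volume factor `(d2^3 - d1^3)/R^3` refers energy released across the
  whole gold shell to the nucleus mass, with the cell modelled as the
  d2-sphere at unit density. It fixes the curve's absolute scale; the
  model's claims live in the curve's *shape* and peak location.

The curve is linear in `w`, equals 1 everywhere when `w = 0`, and peaks
at 40 keV on a 1 keV grid for the default geometry (factor ~1.15 at
`w = 0.007`). The low-energy behaviour is the model's main qualitative
point: the gold L edges (11.92, 13.73, 14.35 keV) open large photoelectric
channels, but the just-liberated photoelectrons are too slow to bridge the
gap to the nucleus, so the damage enhancement stays near 1 while the
macroscopic mixture rule `1 + w (mu_en(Au)/mu_en(water) - 1)` jumps at
every edge.

Auger emission is off by default: the Auger spectrum is independent of
photon energy above the edges and its 2 and 10 keV lines have ranges
(0.1 and 1.5 um) that barely reach past the membrane, so their
contribution is small and flat. The optional `include_auger` mode adds
one 2 keV and one 10 keV electron per ionisation, restricted to shells
bound deeply enough to emit them.

### Energy grid and edges

Attenuation tables are interpolated log-log between grid points, with
absorption edges stored as doubled grid energies so interpolation never
bridges an edge; queries exactly at an edge must state a side. The
default curve grid is 0.5 keV over 10-60 keV with doubled points at the
L edges; curve argmax is reported as the grid energy of the maximum,
ties broken to the lower energy.

## Image analysis

Mid-plane two-channel images are segmented with a global Otsu threshold
on the nucleus channel (the ImageJ-style automatic default), followed by
hole filling and largest-component selection. `low`/`high` variants scale
the automatic threshold by 0.7 / 1.3 to probe sensitivity; lower
thresholds give strictly nested, larger masks. The signed Euclidean
distance to the boundary pixels (negative inside, zero on the boundary)
bins the gold channel into 0.25 um bins — half the PSF width, so a ring
at 0.5 um lands in a unique bin. Bins are *centred* on integer multiples
of the bin width. Per-bin intensity is signal sum over pixel count, and
multi-cell pooling accumulates sums and counts before dividing, so the
binned totals conserve the gold signal exactly.

Shell parameters are extracted from the profile by weighted quantiles of
the extranuclear distance mass (intranuclear signal is clamped to the
membrane: it is PSF leakage, not gold). With quantiles (0, ~1) and the
default synthetic cell this returns d1 = 7.0, d2 = 17.1 for R = 7; the
pipeline default uses an upper quantile of 0.995 so single stray blurred
counts cannot inflate d2.

The PSF is interpreted as Gaussian with FWHM 0.5 um (sigma = 0.212 um),
the usual microscopy convention; the alternative (sigma = 0.5 um) is a
one-line config change. Analysis is strictly 2D mid-plane, with the
model's assumption that the imaged distribution is uniform in 3D around
the nucleus.

## Synthetic data

The generator emulates what the analysis assumes and nothing more: a
disk nucleus (blurred, Poisson-counted, on a small background), and gold
photons drawn from a radial density relative to the true boundary —
default a Gaussian ring at +0.5 um (sigma 0.5 um, truncated at the
membrane) carrying 60% of the gold on top of a uniform cytoplasmic band
out to 10 um, 2e5 expected photons, 0.1 um pixels, 384x384 field.
Photon radii include the circumference factor so the *per-pixel*
intensity profile peaks exactly at the planted offset; each photon is
jittered by the PSF and binned, making Poisson statistics exact. Fixed
seeds give bit-identical images.

What it does not emulate: non-circular nuclei, cytoplasm thickness
variation (3D), nanoparticle clumping into vesicles, channel
mis-registration, detector noise beyond counting statistics, or
neighbouring cells. Passing round-trip tests therefore show the pipeline
is correct and unbiased under its own assumptions, not that segmentation
is robust to real-world image pathology.

The spectrum generator is Kramers bremsstrahlung `phi(E) ~ (kVp - E)/E`
with aluminum filtration (beam hardening via the packaged Al attenuation
table); a 160 kVp beam needs ~11.5 mm Al equivalent for a 75 keV mean.
It is a stand-in family for a real cabinet source's spectrum, adequate
because only the mean energy and broad shape matter here.

## Problem sizes and numerical choices

The default test/analysis sizes — 384x384 images with ~2e5 photons,
0.5-1 keV curve grids, 4e4-1e6 Monte-Carlo samples — were chosen so every
result is statistically comfortable (profile peak recovery and the
leakage bound hold across arbitrary seeds) while the whole suite runs in
seconds. Degenerate inputs fail loudly: empty masks, all-zero profiles
and spectra, shells inside the nucleus, energies outside table ranges,
and sub-validity electron energies all raise typed errors rather than
returning numbers.

## Known limitations

* The gold photoelectric table is a constructed edge model anchored at
  standard reference values (see `src/goldendose/data/README.md`), not a
  direct database transcription; its few-percent accuracy is ample for
  the curve's shape and peak but the absolute coefficients should not be
  quoted as reference data.
* The enhancement scale is fixed by a simple cell-mass convention; only
  curve shape and peak location are meaningful observables.
* Electron transport through the emitting and neighbouring nanoparticles
  is ignored (negligible for the high-energy electrons that drive the
  model), dose within the electron sphere is uniform by assumption, and
  cross-cell dose is out of scope.
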