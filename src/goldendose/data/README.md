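# Packaged physical-constant tables

## `gold_shells.csv`

Gold atomic shells used by the photoelectron model: K, L1, L2, L3 and a
merged M group. Binding energies for K and the L subshells are the
standard spectroscopic edge energies (keV). The M group carries the
occupancy-weighted mean binding energy of M1-M5 (2.58 keV) and, in the
attenuation table, a single merged M edge at that energy. `jump_ratio` is
the absorption-edge jump (coefficient just above / just below the edge);
it both shapes the photoelectric table and partitions the total
photoelectric coefficient among open shells (the deepest group absorbs the
residual, so open-shell weights always sum to 1).

## `attenuation.csv`

Columns: `material, kind, energy_keV, value_cm2_per_g`, 1-160 keV.
Absorption edges appear as doubled grid energies (below-edge row first) so
log-log interpolation never bridges an edge.

* **gold / photoelectric** — built from a piecewise log-log model (one
  power law or log-log quadratic per inter-edge interval, joined by the
  jump ratios above), anchored at standard reference values for gold:
  NIST/XCOM-class coefficients in the 20-80 keV band, the well-known
  ~2 um attenuation length at Cu K-alpha (8.04 keV), and the 1 keV
  coefficient. Regenerate with `scripts/build_tables.py`. Expected
  accuracy is a few percent in the 10-80 keV band the model uses, and
  ~10-20% at the sub-4 keV end, where the true M sub-edge structure is
  smoothed into the single merged edge.
* **gold / energy-absorption** — derived, not transcribed: the
  photoelectric coefficient minus the fluorescence-photon escape fraction
  (K and mean-L yields), plus a small flat Compton energy-transfer term.
  Used only for the macroscopic mixture-rule baseline.
* **water / energy-absorption**, **water / total**, **aluminum / total**
  — transcribed from the NIST (Hubbell & Seltzer) X-ray mass attenuation
  tables; soft tissue is treated as liquid water throughout.
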