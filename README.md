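# melphasor

Fit-free FLIM and spectral-emission phasor analysis of melanins.

Melanocytes store two chemically distinct pigments: eumelanin (dark, short
fluorescence lifetime, red-shifted emission) and pheomelanin (light, longer
lifetime, blue-shifted emission). Their autofluorescence decays are complex
and unfittable per pixel, but the *phasor transform* sidesteps fitting
entirely: each pixel's decay I(t) (or emission spectrum I(λ)) maps to a
point

    g = Σ I(t_k) cos(hωt_k) / Σ I(t_k),    s = Σ I(t_k) sin(hωt_k) / Σ I(t_k)

with ω = 2πf the angular repetition frequency (80 MHz). Single-exponential
species land on the universal circle (g − ½)² + s² = ¼; a eumelanin /
pheomelanin mixture lands on the chord between the two pure-species phasors,
at the position given by its intensity fractions f₁, f₂. Segmenting the
phasor plane with circular cursors and mapping them back to the image yields
a quantitative melanin profile — the *ratio fraction* of each cluster,
labeled pixels over total image pixels — without ever assuming a decay
model.

The package is aimed at microscopists and image analysts working with
TCSPC FLIM and 32-channel lambda stacks of pigmented cells or tissue. It
provides:

- `synthetic_data` — a melanocyte scene simulator (perinuclear + peripheral
  melanosome granules, per-pixel eumelanin fraction, optional NADH/ECM/heme
  confounders, Poisson noise, periodic-wrapped decays, known ground truth);
- `flim_phasor` — transform, analytic references, ATTO 488-style
  calibration, median E-filter, two-component fraction decomposition, and a
  conventional biexponential fit for intensity-averaged lifetimes;
- `spectral_phasor` — spectral transform, phase/modulus, and phase →
  peak-wavelength inversion;
- `segmentation` — cursor assignment, ratio fractions, ordered melanin
  profiles, programmatic seven-cursor placement on the endmember chord;
- `phasor_stats` — region average points, SDs, s-value t tests, linearity
  scoring, and the shot-noise (SD ∝ 1/√N) check;
- `io_cli` — TIFF + JSON sidecar readers/writers and the `melphasor` CLI.

## Worked example

Run the bundled demo — four heterogeneously pigmented melanocytes on an
NADH-like background, imaged in both modalities, segmented with seven
cursors on the eumelanin→pheomelanin chord:

```sh
melphasor run --config examples/demo_config.json --out demo_out/
```

`demo_out/profile_flim.csv` then contains the melanin histogram profile:

```
cursor_id,ratio_fraction,mean_g,mean_s
0,0.002387152777777778,0.7055707826093678,0.3417518867149197
1,0.014431423611111112,0.6954801003711767,0.3489680417193899
2,0.038411458333333336,0.6491022399757282,0.37184825256075127
3,0.007595486111111111,0.6283369606637967,0.37937641988246795
4,0.019965277777777776,0.5965811231497468,0.3985512857090627
5,0.027018229166666668,0.548086673450202,0.4225843322154171
6,0.015733506944444444,0.5363749362166019,0.42319073719162326
```

Rows are ordered from the eumelanin end (cursor 0, shortest equivalent
lifetime, mean phasor closest to (1, 0)) to the pheomelanin end (cursor 6).
Each `ratio_fraction` is that cluster's share of all 96×96 image pixels —
e.g. 3.8% of the field maps to cluster 2's pigment mixture — and the mean
(g, s) positions march monotonically along the chord, the signature of a
two-fluorophore ratio. `stats_flim.json` from the same run reports the
cluster-sequence linearity (perpendicular RMS 0.0017 phasor units,
R² = 0.9994) and a Welch t test on the s values of the two extreme clusters
(t = −27.8, p ≈ 6×10⁻²², significant at α = 0.05). The other artifacts
include the phasor-plot render with the universal circle and cursor overlay
(`phasorplot_flim.png`), the color-tagged segmentation (PNG + legend), the
spectral twins of all of the above, and `manifest.json` with a SHA-256 hash
per artifact — rerunning with the same config and seed reproduces every
hash byte-identically.

The same stages are available as composable subcommands (`simulate`,
`flim-phasor`, `spectral-phasor`, `segment`, `profile`, `stats`), and as
plain library calls; `melphasor schema` prints the JSON schema of the run
configuration.

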