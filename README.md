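# tropus

Transmission–reflection optoacoustic ultrasound (TROPUS) analysis of
fatty liver disease, as a tested, reusable Python pipeline. A single
circular transducer ring around a mouse cross-section supports three
imaging modes, and this package implements all three plus the
quantification layer that turns them into disease readouts:

* **MSOT** — multispectral optoacoustic tomography: pulsed-laser
  excitation at 11 wavelengths (740–940 nm, 20 nm steps), dual-speed
  universal back-projection, modified-Bessel fluence correction, and
  per-pixel non-negative linear unmixing of Hb, HbO2, melanin and lipid
  (`min ||A c − s||²`, `c ≥ 0`). Hepatic fat is visible through the
  920 nm lipid absorption peak.
* **RUCT** — reflection ultrasound computed tomography: per-transmitter
  delay-and-sum over a 90° receive aperture (128 of 512 channels),
  envelope detection and multi-view compounding; the compounded image
  delineates the skin surface for cross-sectional area measurement.
* **SoS imaging** — transmission ultrasound: matching-pursuit
  time-of-flight picking against water references on the opposite
  171-element arcs, straight-ray travel-time tomography as the starting
  model, then 40 iterations of gradient-descent waveform inversion over a
  Fresnel-zone ray fan, yielding quantitative speed-of-sound maps in m/s.
  Fatty livers read low (disease ≈ 1475–1495 m/s vs control
  ≈ 1525–1538 m/s).

No imaging data are deposited with the study this package models, so a
first-class synthetic-data module generates digital phantoms and whole
cohorts whose ground truth follows the published group statistics (liver
speed of sound, body area, weight, liver lipid contrast), and every
pipeline stage is validated against that ground truth. It is aimed at
researchers developing or benchmarking hybrid optoacoustic/ultrasound
reconstruction and quantification methods.

## Worked example

Reconstruct the speed of sound of a synthetic excised fatty liver
embedded in agarose, at the package's desk scale (128-element ring,
96×96 grid at 0.5 mm):

```python
from dataclasses import replace

from tropus.phantoms import STUDY_GROUPS, generate_phantom
from tropus.pipeline import scaled_setup, reconstruct_sos_section
from tropus.stats import liver_mean_sos

geometry, config, grid = scaled_setup()
spec = replace(STUDY_GROUPS["exvivo_nafld"], liver_sos_std=0.0)
phantom = generate_phantom(spec, 0, seed=1, grid=grid)

sos_image, state = reconstruct_sos_section(phantom, geometry, config, seed=1)
print(f"truth {phantom.liver_sos:.1f} m/s")
print(f"reconstructed liver mean {liver_mean_sos(sos_image, phantom.liver_mask):.2f} m/s")
print(f"waveform loss {state.loss_history[0]:.3f} -> {state.loss:.3f} "
      f"over {state.iteration} iterations")
```

```
truth 1495.0 m/s
reconstructed liver mean 1499.39 m/s
waveform loss 6541.292 -> 6535.066 over 40 iterations
```

The liver-mask mean lands within 0.3% of the generating 1495 m/s — the
published ex vivo disease-group mean — and the inversion's waveform loss
decreases monotonically from its travel-time initialisation.

The same pattern runs the other modes:
`reconstruct_ruct_section` returns the compounded pulse-echo image, the
automatic body mask and the calibrated cross-sectional area, and
`reconstruct_msot_section` returns the 11-wavelength quantitative stack
and the background-removed liver lipid metric. `run_study` loops a whole
cohort and `tropus.stats.build_report` writes group summaries and
pairwise t-tests.

A command-line interface mirrors the library:

```bash
tropus init-cohort --out study.yaml
tropus simulate --cohort study.yaml --out data/ --seed 7
tropus recon sos  --in data/control_000.h5 --out sos.tif --diag loss.csv
tropus recon ruct --in data/control_000.h5 --out ruct.tif --area-out area.csv
tropus recon msot --in data/control_000.h5 --out stack.tif
tropus unmix --stack stack.tif --out maps.tif
tropus quantify --table cohort.csv --out report/
```

See `docs/methods.md` for the models, defaults and their rationale.

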