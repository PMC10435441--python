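# sweatsense

Photon Monte Carlo simulation of multilayer skin with a topical water/sweat
film under a four-wavelength wrist PPG sensor, plus an analysis pipeline that
detects sweat-film formation in multi-channel PPG + IMU run recordings.

Components:

- **optics_model** — seven-sub-layer skin stack (epidermis/dermis/hypodermis)
  with spectrally resolved absorption assembled from packaged chromophore
  tables (water, oxy-/deoxy-hemoglobin, melanin, tissue baseline) and
  power-law scattering; optional water film on top.
- **mc_transport** — photon-packet random walk: exponential free paths,
  Henyey–Greenstein scattering, continuous Beer–Lambert weight attenuation,
  unpolarized Fresnel boundaries, unbiased Russian roulette, square-aperture
  detection; exact weight-ledger conservation.
- **sensor_maps** — reflectance spectra, film-thickness trends and complete
  film × incidence-angle maps (970/1450 nm show the up/down water-band
  trends; 1450 nm decreases monotonically with film thickness).
- **synthetic_ppg** — seeded generator of 25 Hz run recordings (PPG at
  535/940/970/1450 nm, accelerometer, gyroscope) with HR drift, cadence and
  arm-swing motion artifacts, baseline wander and a film drift that starts
  at a known onset time.
- **feature_extraction** — 11 windowed statistics (mean, median, max, min,
  std, var, skew, kurtosis, iqr, mad, slope) on raw windows and on each
  channel of a generalized-Morse-wavelet spectrum; names follow
  `<wavelength>_<domain>_<function>[_<channel>]`.
- **window_classification** — run-start vs run-end paired-window
  gradient-boosted classifiers (depth 2, learning rate 0.01) swept over
  decreasing window separations with 4-fold run-grouped CV and
  permutation-based feature importance.
- **sweat_onset** — trailing-window trend-slope detector on the 1450 nm
  channel with robust slope normalization and cohort aggregation.
- **sensor_fusion** — IMU spectral-peak artifact identification and
  Fourier-band suppression before feature extraction.

## CLI

```bash
sweatsense simulate --config stack.yaml --photons 100000 --seed 1 --out rec.json
sweatsense map --films 0,100,...,500 --angles 0,15,30 --wavelengths 970,1450 --out map.json
sweatsense gen-data --n-runs 24 --seed 1 --out runs/
sweatsense extract-features --in runs/run_000.csv --window 210 --step 20 --out feats.csv
sweatsense train-windows --runs runs/ --folds 4 --out sweep.json
sweatsense detect-onset --in runs/run_000.csv --channel ppg_1450 --out onset.json
sweatsense run-all --config pipeline.yaml --seed 1 --out out/
```

Example stack config (`stack.yaml`):

```yaml
grid: {wavelengths: [970.0, 1450.0]}
composition: {c_mel: 0.04, c_blood: 1.0, s_blood: 0.97}
film_thickness_um: 100.0
geometry: {full_surface: true}
```

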