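# memdyn

Quantitative analysis of plasma-membrane (PM) dynamics from fluorescence
microscopy, with a synthetic-data generator providing exact ground truth
for every stage.  Built for cell biologists studying endocytosis and
membrane organization — e.g. clathrin-mediated and raft-associated uptake
in plant root epidermal cells under osmotic stress — and for method
developers who need a tested reference implementation of the standard
readouts:

* **Single-particle dynamics** (TIRF-style movies): spot detection,
  trajectory linking, per-track diffusion coefficients from the mean
  squared displacement, MSD(τ) = 4Dτ for 2D Brownian motion, so D =
  slope/4 from a free-intercept line through the first MSD lags; motion
  range as the trajectory diameter; population characteristic values Ĝ as
  Gaussian peaks fitted to the histograms, with BIC-based detection of
  bimodal (two-population) diffusion.
* **Endocytosis quantification** (dye-uptake images): counts and
  intensities of internalized puncta, relative intracellular intensity,
  PM-band intensity as percent of control, percent changes and Student's
  t-tests between treatment groups.
* **Membrane order** (spectral imaging of an environment-sensitive dye):
  λ-stack emission profiles with sub-band peak wavelengths (blue-shift =
  more ordered lipids), the red-to-green ratio RGM = I₆₆₀/I₅₅₀ (lower =
  more ordered), and per-pixel generalized polarization
  GP = (I₅₀₀₋₅₈₀ − G·I₆₂₀₋₇₅₀)/(I₅₀₀₋₅₈₀ + G·I₆₂₀₋₇₅₀) with region-wise
  Gaussian-fitted GP peak values (higher = more ordered).

Inputs are multi-page TIFF movies, two-channel or λ-stack TIFFs (band
centers in a JSON sidecar), labeled region masks (TIFF), and trajectory
tables (CSV).  See `docs/methods.md` for models, assumptions, and design
choices.

## Worked example

Simulate a TIRF-style movie of membrane-bound particles diffusing at
D = 1.95×10⁻³ μm²/s (per-axis step σ = 13.96 nm at 50 ms frames), then
recover the diffusion peak through the full pipeline:

```python
import numpy as np
from memdyn import simgen
from memdyn import spt_dynamics as spt

spec = simgen.TirfSimSpec(n_particles=100, n_frames=50, seed=8,
                          localization_jitter_um=0.02)
movie, truth = simgen.simulate_tirf_movie(spec)
spots = spt.detect_spots_movie(movie)
tracks = spt.link_trajectories(spots, max_step_um=0.3, max_gap=1)
dtab = spt.diffusion_table(tracks, spec.frame_interval_s)
usable = dtab[~dtab.negative_slope & (dtab.D_um2_s > 0)]
fit = spt.fit_peak_histogram(usable.D_um2_s, allow_bimodal=True, log_scale=True)
mr = spt.motion_range_table(tracks)
print(f"true D       : {spec.diffusion_coefficients[0]:.3e} um^2/s")
print(f"tracks       : {tracks.track_id.nunique()} ({len(usable)} usable fits)")
print(f"G-hat        : {fit.components[0].peak:.3e} um^2/s "
      f"({fit.n_components} component)")
print(f"motion range : median {mr.motion_range_um.median():.3f} um")
```

Output:

```
true D       : 1.949e-03 um^2/s
tracks       : 100 (100 usable fits)
G-hat        : 1.913e-03 um^2/s (1 component)
motion range : median 0.207 um
```

All 100 planted particles are detected and linked; the Gaussian-fitted
histogram peak Ĝ recovers the true diffusion coefficient within 2%, and
the median motion range (~0.2 μm over 50 frames) is the spatial extent a
track explores at this mobility.

The ratiometric membrane-order readouts are closed-form: a region whose
ordered/disordered channel ratio is 3.878 has GP = (3.878−1)/(3.878+1) =
0.59 at G = 1, and a region with red/green window means 137.2/200 has
RGM = 0.686.

## Command line

```bash
memdyn run --seed 11 --out out/          # full synthetic pipeline
memdyn simulate --config cfg.yaml --out out/
memdyn dynamics --config cfg.yaml --out out/
memdyn quantify --config cfg.yaml --out out/
memdyn order    --config cfg.yaml --out out/
```

Each command writes its tables (`tracks.csv`, `diffusion.csv`,
`puncta.csv`, `rgm.csv`, …) plus an aggregated `report.json` that
validates against the JSON schema shipped at
`src/memdyn/schemas/report.schema.json`.  Identical config + seed
reproduce the report byte for byte.

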