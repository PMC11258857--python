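# redoxscreen

Label-free metabolic imaging analysis for longitudinal screens of
iPSC-derived cardiomyocytes maturing on synthetic hydrogels — or any other
adherent culture whose metabolism you want to track non-destructively.

Cellular metabolism can be read out from the autofluorescence of two
coenzymes: NAD(P)H (fluorescent when reduced) and FAD (fluorescent when
oxidized). `redoxscreen` implements the two standard measurements end to
end, together with a synthetic-data backbone so every stage is testable
against known ground truth without any microscope:

1. **Widefield optical redox ratio (ORR).** Per field of view (one per
   gel), the NAD(P)H image is rolling-ball corrected for vignetting,
   thresholded into a cell mask, and mean *raw* cell intensities are
   normalized by the mean of three cell-free (gel background) regions:

   ```
   I_NAD(P)H = I_cell,NAD(P)H / I_bg,NAD(P)H
   I_FAD     = I_cell,FAD     / I_bg,FAD
   ORR       = I_NAD(P)H / (I_NAD(P)H + I_FAD)
   ```

   The per-channel background normalization cancels exposure drift, lamp
   power, and substrate autofluorescence, making day-to-day longitudinal
   comparisons meaningful. Lower ORR = more oxidative metabolism.

2. **TCSPC FLIM fitting.** Per pixel, photon-arrival histograms are fit to
   the biexponential decay

   ```
   I(t) = A [ a1 exp(-t/tau1) + a2 exp(-t/tau2) ] ⊛ IRF + C ,  a1 + a2 = 1
   ```

   by Poisson-weighted least squares, after 3×3 spatial binning and with a
   >1000 photons/pixel validity criterion. For NAD(P)H, `tau1` (~hundreds
   of ps) reports the free coenzyme and `tau2` (thousands of ps) the
   protein-bound pool; the mean lifetime is `tau_m = a1*tau1 + a2*tau2`.

3. **Screen reports.** Per-FOV records are aggregated into per-formulation
   trajectories, day-vs-day percent changes, and Welch's unequal-variance
   t-tests between high- and low-differentiation-efficiency groups.

4. **Synthetic data.** Generators for Gaussian IRFs (default 240 ps FWHM,
   256 bins over one 12.5 ns period of an 80 MHz laser), Poisson decay
   cubes, vignetted NAD(P)H/FAD image pairs with elliptical cells and gel
   autofluorescence, and whole longitudinal plates whose per-group ORR
   trajectories rise from day 6 to a day-10 peak, fall by day 16, and keep
   declining through late maturation.

## Worked example

```python
import numpy as np
import redoxscreen as rs
from redoxscreen.screen import process_plate, percent_change, compare_groups

# --- FLIM: simulate and fit a decay cube -------------------------------
irf = rs.make_irf()  # 240 ps FWHM Gaussian, 256 bins over 12.5 ns
truth = rs.DecayGroundTruth(tau1=400, tau2=2500, a1=0.7, photons_target=1000)
cube = rs.simulate_decay_cube(truth, irf, shape=(16, 16), seed=0)
fit = rs.fit_cube(cube, irf, photon_threshold=1000)
print(f"median tau_m = {np.nanmedian(fit.tau_m):.0f} ps (truth {truth.tau_m:.0f} ps)")

# --- widefield: simulate a 2-group screen and report it ----------------
design = rs.make_plate_design(n_formulations=4, days=(6, 10, 16, 30),
                              groups=("high", "low"), replicates=3, seed=0)
records = process_plate(rs.simulate_plate(design))
print(records.groupby(["group", "day"])["orr"].mean().round(3))
pc = percent_change(records, "high", 6, 30)
print(f"high-efficiency ORR change day 6 -> 30: {pc.percent_change:+.2f}%")
res = compare_groups(records, 6, "high", "low")
print(f"day-6 Welch t = {res.statistic:.2f}, p = {res.pvalue:.2e}")
```

prints

```
median tau_m = 1043 ps (truth 1030 ps)
group  day
high   6      0.551
       10     0.623
       16     0.535
       30     0.507
low    6      0.502
       10     0.553
       16     0.502
       30     0.472
Name: orr, dtype: float64
high-efficiency ORR change day 6 -> 30: -8.02%
day-6 Welch t = 13.44, p = 4.62e-12
```

The fitted mean lifetime lands within ~1 % of the generating truth; the
measured ORR trajectories reproduce the designed rise-then-fall pattern,
the encoded -8.15 % high-efficiency decline is recovered to within the
replicate noise, and the 0.05-ORR day-6 offset between efficiency groups
is highly significant.

The same workflows run from the shell on TIFF/CSV inputs:

```bash
redoxscreen simulate plate --out plate/ --seed 1
redoxscreen ori run --manifest plate/manifest.csv --out results/
redoxscreen report run --table results/records.csv --out report/ \
    --compare-days 6 16
redoxscreen simulate decay --tau1 400 --tau2 2500 --a1 0.7 --out cube.tif
redoxscreen flim fit --cube cube.tif --irf cube_irf.csv --out fit/
```

## Layout

- `redoxscreen.synthetic` — ground-truth generators (IRFs, decay cubes,
  widefield pairs, whole plates)
- `redoxscreen.flim` — decay model, 3×3 binning, pixel/cube fitting,
  per-label aggregation
- `redoxscreen.widefield` — rolling-ball correction, masking, background
  ROIs, normalized ORR, the per-FOV pipeline
- `redoxscreen.screen` — ScreenTable aggregation, percent change, Welch's
  t-test, trajectory reports
- `redoxscreen.io` — TIFF/CSV/JSON interfaces; `redoxscreen.cli` — the
  `redoxscreen` command

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
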