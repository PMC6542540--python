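# ramp-tools

Analysis and simulation toolkit for **motor-driven organelle
repositioning** experiments — the kind in which an organelle population
(lysosomes, mitochondria, peroxisomes, ER domains) is pulled to the cell
periphery or the cell center by an inducibly coupled motor protein and then
released, and the question is *where the organelles are* and *how fast they
come back*.

It is written for cell biologists quantifying such experiments and for
modelers comparing them against stochastic transport theory. The package
provides:

- **Radial dispersion statistics** (`ramp.radial`): radial intensity
  profiles around the nucleus center and the *fractional distance*
  `d_f` — the minimal normalized radius containing a fraction *f* of a
  cell's total fluorescence (`d_f → 1` for peripheral clustering, small for
  perinuclear clustering) — plus recovery curves over time, exponential
  fits, the f-selection sweep and box summaries.
- **A tug-of-war transport simulator** (`ramp.tugofwar`): exact
  event-driven simulation of cargos hauled by opposing kinesin and dynein
  teams on radial microtubules, with binding/unbinding rates
  `(N−n)·π0` and `n·ε0·exp(F/(n·F_d))`, linear force–velocity to stall,
  and force-balance cargo velocity
  `v = (F_win − F_lose)/(F_win/v̄_F + F_lose/v̄_B)`. Ensemble releases from
  the periphery or the center reproduce exponential recovery to a common
  steady state.
- **Mitochondrial morphometry** (`ramp.morphology`): the standard
  preprocessing chain (rolling ball → despeckle → CLAHE → bandpass → Li
  threshold), six shape descriptors (count, length, area², aspect ratio,
  form factor `P²/4πA`, area-weighted FF) and the ≥3-metric change rule.
- **Kymograph analysis** (`ramp.kymograph`): path straightening,
  distance × time kymographs and directional segment speeds.
- **A synthetic-data generator** (`ramp.synthetic`): cells, organelle
  fields with known radial distributions, exponential-recovery movies,
  constant-speed particle movies and shape populations — every analysis
  stage is testable with known ground truth.

## Worked example

Simulate a 45-minute movie of a perinuclear-clustered lysosome population
relaxing to its steady state with a 10-minute time constant, then quantify
it exactly as a microscopy movie would be:

```python
import numpy as np
from ramp import synthetic as syn
from ramp.radial import recovery_curve, fit_exponential

geom = syn.make_geometry("circle", cell_radius=100, nucleus_radius=20, seed=0)
movie = syn.make_recovery_movie(
    syn.PERINUCLEAR, syn.STEADY_STATE, tau_min=10.0,
    times=np.arange(0, 46.0), geometry=geom, seed=7,
)
curve = recovery_curve(movie, geom, f=0.75)
fit = fit_exponential(curve.times, curve.values)
print(f"d_75 at t=0:   {curve.values[0]:.3f}")
print(f"d_75 at t=45:  {curve.values[-1]:.3f}")
print(f"fitted tau:    {fit.tau:.1f} min (truth: 10)")
print(f"R^2:           {fit.r_squared:.3f}")
```

```
d_75 at t=0:   0.490
d_75 at t=45:  0.730
fitted tau:    8.9 min (truth: 10)
R^2:           0.868
```

The clustered population starts with 75% of its fluorescence inside 0.49 of
the cell radius; as it disperses, `d_75` rises toward the steady-state
plateau, and the fitted exponential time constant recovers the generator's
truth (single movies scatter around it; the mean over seeds lands within a
few percent).

The same statistic on simulated cargo ensembles:

```python
from ramp import tugofwar as tw
res = tw.simulate_ensemble(n_cargos=500, init="periphery",
                           duration=480, sample_dt=10, seed=3)
s = tw.ensemble_fractional_distance(res, f=0.75)
```

gives the release-and-recovery curves of the transport model, which relax
from either boundary to one common interior plateau.

A CLI mirrors the library for shell use: `ramp generate`, `ramp quantify`,
`ramp simulate`, `ramp morphology`, `ramp kymograph` (see `--help`).

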