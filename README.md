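# mtnuc

Kinetics, simulation, and image analysis for surface-templated microtubule
nucleation assays.

In single-molecule TIRF nucleation assays, ring-complex templates (γTuRCs)
are attached to a passivated coverslip and fire at most once, each
producing a microtubule whose anchored minus end marks the nucleation site
and whose plus end elongates at a constant speed. The cumulative number of
microtubules N(t) then follows a saturating exponential,

    N(t) = N_max · (1 − exp(−k·t / N_max)),

where *k* is the initial nucleation rate (MTs·s⁻¹) and *N_max* the number
of activatable templates. Comparing fitted *k* across conditions is how
the effect of an activator (e.g. the γTuNA/CM1 motif of Cdk5rap2) or an
inhibitor (e.g. the tubulin-sequestering protein stathmin) is quantified.

`mtnuc` packages that entire measurement chain for people who run or
reanalyze such assays:

* **`mtnuc.kinetics`** — the closed-form model, its discrete-time
  recursion (with a two-phase variant for late-activating mutants), and
  the assay's stoichiometric arithmetic (stathmin sequestration, fold
  changes, activator-dimer occupancy).
* **`mtnuc.simulate`** — a synthetic TIRF movie generator: integerized
  nucleation events placed on a plane, constant-speed growth along eight
  discrete orientations, Gaussian-PSF rendering, a plus-end marker
  channel, and a Poisson–Gaussian camera model, all with exact ground
  truth.
* **`mtnuc.pipeline`** — the image analysis: Otsu-masked MT-mass traces,
  Yen-threshold plus-end spot counting, kymograph extraction with
  templated/spontaneous classification, growth speed and maximum length,
  and automated count trajectories by birth detection.
* **`mtnuc.fitting`** — bounded multi-start nonlinear least squares for
  (k, N_max), late-phase linear slopes, replicate aggregation
  (mean ± SEM), control normalization, and two-sample t-tests.
* **`mtnuc.cli`** — `mtnuc simulate | analyze | fit` for shell use.

See `docs/methods.md` for the model assumptions, detector design, and
numerical choices.

## Worked example

Generate noise-free count trajectories at the buffer and
wildtype-activator condition rates, re-fit them, and compare:

```python
import numpy as np
from mtnuc import (NucleationKinetics, CountTrajectory, eq1_counts,
                   fit_eq1, fold_change, late_slope)

t = np.arange(0.0, 151.0, 2.0)                  # one frame every 2 s
wt = CountTrajectory(t, eq1_counts(t, NucleationKinetics(24.5, 300.0)))
buffer = CountTrajectory(t, eq1_counts(t, NucleationKinetics(1.2, 300.0)))

fit_wt, fit_buf = fit_eq1(wt), fit_eq1(buffer)
print(f"wildtype:  k = {fit_wt.k_hat:.2f} MTs/s, N_max = {fit_wt.n_max_hat:.0f}")
print(f"buffer:    k = {fit_buf.k_hat:.2f} MTs/s, N_max = {fit_buf.n_max_hat:.0f}")
print(f"activation: {fold_change(fit_wt.k_hat, fit_buf.k_hat):.1f}-fold")
print(f"late-phase slope (25-150 s): {late_slope(wt):.3f} MTs/s")
```

prints

```
wildtype:  k = 24.50 MTs/s, N_max = 300
buffer:    k = 1.20 MTs/s, N_max = 300
activation: 20.4-fold
late-phase slope (25-150 s): 0.145 MTs/s
```

The recovered rates equal the generating ones (the fit is
self-consistent), their ratio is the ~20-fold activation, and the
late-phase slope shows the near-flat residual rate after the fast
condition saturates.

The same loop works from the shell on rendered movies:

```sh
mtnuc simulate --k 2 --n-max 4 --duration 160 --seed 3 --noise none --out sim/
mtnuc analyze sim/movie.tif --out results/
```

```
wrote 4 tracks, 81 frames to sim
movie: 4 MTs by 150 s
```

— the analysis recovers from the rendered TIFF exactly the four
nucleation events the generator placed.

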