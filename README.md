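# seedfall

Video-based measurement of the falling trajectory and terminal velocity of
wind-dispersed seeds.

The effective terminal velocity `Vt` — the speed at which aerodynamic drag
balances a diaspore's weight — is the key trait in mechanistic models of
seed dispersal by wind. Measuring it by timing a short drop underestimates
`Vt` for fast-falling seeds, which are still accelerating when they land: a
seed with `Vt = 6.4 m/s` needs **8.2 m** of free fall to reach 99% of `Vt`,
and after a 0.45 m drop is at only **44%** of it. `seedfall` implements the
apparatus-side analysis that avoids this bias: a single high-speed camera
plus a mirror film the seed falling through a short backlit corridor from
two perspectives at once; the package reconstructs the 3-D trajectory from
the two views and estimates `Vt` by fitting the physics of drag-limited
fall,

    z(t) = z0 - (Vt^2 / g) * ln cosh(g t / Vt),

to the vertical position series by nonlinear least squares — so the seed
never needs to reach terminal speed inside the corridor.

It is written for dispersal ecologists and plant functional-trait
researchers, and includes everything needed to run and validate the chain
without hardware:

* **physics** — closed-form drag kinematics, acceleration distances,
  relaxation timescale `tau = Vt/g`;
* **calibration** — the three pixel-to-metre conversion models (linear with
  interaction) fitted to grid-board observations;
* **detection** — backlit-blob detection in frame stacks (invert, subtract
  background, threshold, measure components);
* **tracking** — four-step cleaning of object tables into one trajectory,
  and 3-D reconstruction;
* **fitting** — the `(Vt, z0)` fit with R^2 and velocity-RMSE diagnostics;
* **sphere** — theoretical sphere terminal velocities (standard drag curve)
  for first-principles validation;
* **stats** — variance decomposition and intraclass-correlation
  repeatability of replicated `Vt` measurements;
* **synth** — a full synthetic apparatus: trajectory simulation, camera +
  mirror projection, frame rendering, calibration designs, replicated
  datasets.

## Worked example

Simulate one drop of a `Vt = 1.5 m/s` seed through the default apparatus
(0.25 x 0.25 x 0.33 m corridor, camera at 0.58 m, 1920 x 1200 px, 130 fps),
render its frames with default noise, and run the full analysis chain:

```python
import numpy as np
import seedfall as sf

geom = sf.ApparatusGeometry()
rng = np.random.default_rng(7)

# calibrate: 35 grid marks x 25 board placements -> three conversion models
cal = sf.fit_conversion(sf.generate_calibration(geom))
print({k: round(v, 5) for k, v in cal.r_squared.items()})
# {'x': 0.99998, 'y': 0.99999, 'z': 0.99801}

# one synthetic drop, rendered and analysed
traj = sf.simulate_trajectory(Vt=1.5, z0=0.34, geometry=geom)
frames = sf.render_frames(sf.project(traj, geom, noise=sf.NoiseModel(), rng=rng),
                          geom, sf.NoiseModel(), rng=rng)
objects = sf.detect_objects(frames)
rec = sf.reconstruct(sf.clean_and_pair(objects), cal, geom.fps)
fit = sf.fit_fall_model(rec)
print(f"Vt = {fit.model.Vt:.4f} m/s, z0 = {fit.model.z0:.4f} m, "
      f"R^2 = {fit.r_squared:.6f}, velocity RMSE = {fit.velocity_rmse:.4f} m/s")
# Vt = 1.4853 m/s, z0 = 0.3393 m, R^2 = 0.999998, velocity RMSE = 0.0239 m/s
```

Each conversion model explains >99% of the variance in its coordinate; the
fitted `Vt` lands within ~1% of the generating 1.5 m/s from 37 frames, the
trajectory fit is essentially perfect (R^2 > 0.9999), and the velocity RMSE
of 0.024 m/s is the level expected from sub-pixel centroid noise at 130 fps,
indicating no systematic model violation. The same chain runs from the
shell: `seedfall calibrate`, `detect`, `track`, `fit`, `run` (batch),
`sphere-vt`, `stats`, `simulate`, `simulate-dataset`; see `seedfall --help`.

Physics one-liners:

```python
sf.distance_to_velocity_fraction(6.4, 0.99)   # 8.177... m  (~8.2 m)
sf.velocity_fraction_at_distance(6.4, 0.45)   # 0.4403...   (~44%)
```

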