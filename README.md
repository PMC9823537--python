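# hallgait

Desk-scale toolkit for FMCW-radar hallway gait monitoring: a point-scatterer
simulator for a subject walking a marked out-and-back course (with
wall-mirror multipath ghosts and lens / no-lens antenna beams), the
gait-extraction pipeline that recovers per-cycle spatiotemporal parameters
(speed, step times, step points, step/stride lengths, step count, cadence)
from raw radar data cubes, and the hyperbolic dielectric-lens profile
design utility.

## Layout

| module                 | role                                                            |
| ---------------------- | --------------------------------------------------------------- |
| `hallgait.config`      | chirp/frame configuration and derived radar quantities          |
| `hallgait.lens`        | hyperbolic collimating-lens thickness profile, validity, export |
| `hallgait.simulate`    | walk trajectories, ghosts, beams, raw ADC cube synthesis        |
| `hallgait.ranging`     | range FFT, clutter filter, max-bin torso tracking               |
| `hallgait.gait`        | velocity, pass/turn segmentation, step detection, gait report   |
| `hallgait.pipeline`    | one-call cube-to-report chain with a single parameter bundle    |
| `hallgait.io` / `.cli` | cube container, raw I/Q dialect, reports, command line          |

## Command line

```sh
# simulate the default walk (4.2 m course, 0.7 m steps, 3 round trips)
hallgait simulate --out walk.hgc --truth truth.json --seed 1 --beam lens

# extract gait parameters
hallgait process walk.hgc --out-csv steps.csv --out-json summary.json

# compare against simulation ground truth
hallgait evaluate --report summary.json --truth truth.json

# export the lens profile (CSV and ASCII STL)
hallgait lens-profile --csv lens.csv --stl lens.stl
```

## Python API

```python
import hallgait as hg

sim = hg.simulate_walk(hg.WalkScenario(avg_speed=0.87, rng_seed=1))
result = hg.run_pipeline(sim.cube)
print(result.report.step_count, result.report.avg_speed)
print(hg.compare_to_truth(result.report, sim.truth))
```

## Notes on conventions

- Complex (I/Q) baseband sampling; the cube container stores little-endian
  complex64 with a JSON header carrying the chirp configuration.
- Ranges in metres, times in seconds from recording start, 0-based bins.
- Velocity is away-positive; average walking speed includes turn time,
  every other parameter excludes it.
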