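# cbctmotion

Simulation and analysis of motion-distorted CT number (Hounsfield unit)
profiles in cone-beam CT (CBCT).

In image-guided radiotherapy, CBCT volumes are reconstructed from projections
collected over a gantry rotation lasting tens of seconds — several breathing
cycles. A lung tumour (or QA phantom insert) moving along the
superior–inferior axis during that rotation ends up elongated, with reduced
and redistributed CT numbers, and can even appear split in two. `cbctmotion`
implements a first-order projection-occupancy model of this artifact for
physicists and researchers doing phantom QA, artifact characterisation, or
motion-parameter estimation from blurred images.

## The model

A stationary voxel accumulates all `N` projections of the scan in its own
imaging window `w` (one slice thickness), each contributing an equal
increment `ΔCT`, so its reconstructed level is

```
CT_S = ΔCT · N
```

A moving voxel deposits its increments into whichever window it occupies at
each projection time, so a window that captures only `M ≤ N` projections
reconstructs at

```
CT_M = CT_S · M / N
```

Summing the increments of all `V` voxels of a target over all `N` projection
times yields the full mobile profile. Two laws follow directly:

* **Conservation** — as long as the target stays in the imaging view, the
  area under the profile is invariant: `CT_S · w = CT_M · (w + L)`, where `L`
  is the motion-induced elongation.
* **Constant speed** — for unidirectional motion at speed `V_P` over
  acquisition time `T`, the mean mobile level is
  `CT_M = CT_S · w / (w + V_P·T)`.

For cyclic (sinusoidal) motion of amplitude `A` sampled over an integer
number of cycles, the `N → ∞` limit is the arcsine residence-time law: the
occupancy of position `y` is `(arcsin b − arcsin a)/π` with `a, b` the
clipped normalized bounds of the displacement interval covering `y`. The
support of the blurred profile is the stationary length plus the range of
motion `2A`, which inverts to estimate an unknown motion amplitude from the
blurred profile of a marker of known length: `A = (support − L_marker)/2`.

The package provides the discrete simulator (center-containment and
overlap-weighted deposition, with a full per-projection deposition ledger),
the continuous occupancy oracle (closed-form arcsine or time quadrature),
profile metrics (support extent, elongation, level drop, split detection,
PRMS agreement between two profiles), a pseudo-measurement generator (noise,
streak spikes, inter-fan-mode offset), YAML/JSON-configured runners and a
CLI.

## Worked example

The medium thorax-phantom insert (20 mm long, 700 HU above the
lung-equivalent background) breathing sinusoidally with amplitude 10 mm at
15 cycles/min, scanned with 655 projections over 60 s on 2 mm slices:

```python
from cbctmotion import *

grid = WindowGrid(-60.0, 2.0, 60)
target = preset_phantom("medium")
motion = SinusoidalMotion(amplitude=10.0, frequency=0.25)
protocol = ScanProtocol(n_projections=655, scan_duration=60.0)

stationary = stationary_profile(target, grid, protocol)
mobile, ledger = simulate_mobile_profile(target, motion, protocol, grid)

print("stationary extent :", support_extent(stationary), "mm")
print("mobile extent     :", support_extent(mobile), "mm")
print("elongation        :", elongation(mobile, stationary), "mm")
print("level drop        :", round(level_drop(mobile, stationary), 1), "%")
print("split profile     :", detect_split(mobile).split)
print("estimated A       :", estimate_amplitude(mobile, marker_length=20.0), "mm")
```

prints

```
stationary extent : 20.0 mm
mobile extent     : 40.0 mm
elongation        : 20.0 mm
level drop        : 13.6 %
split profile     : False
estimated A       : 10.0 mm
```

The profile broadened by the full range of motion (2A = 20 mm) and the
support-based inversion recovers the amplitude exactly; the maximum level
dropped by 13.6% while the area under the profile stayed fixed (the range of
motion here equals the target length, so the profile has not yet split —
larger amplitudes split it in two peripheral lobes).

The same run from the shell:

```bash
cbctmotion simulate run.yaml --out results/
cbctmotion sweep run.yaml --axis amplitude --values 2.5,5,7.5,10 --engine continuous
cbctmotion analyze results/mobile.csv --reference results/stationary.csv
```

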