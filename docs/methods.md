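# Methods

## Model

`cbctmotion` models the effect of one-dimensional target motion on CBCT
number distributions to first order in projection occupancy. The
reconstructed CT number of a voxel is taken to be proportional to the number
of projections acquired while that voxel occupies a given imaging window
(one slice thickness `w`): each projection contributes a constant increment
`ΔCT = CT_S / N`, where `CT_S` is the stationary level above background and
`N` the projection count of the scan. The simulator schedules `N` uniform
projection times `t_n = n·(T/N)` (starting at `t = 0`, no endpoint sample,
which makes the worked integer examples exact), displaces every voxel by the
trajectory `d(t_n)`, and accumulates increments window by window.

Assumptions inherited from this first-order treatment:

* The per-voxel increment is identical in every projection (attenuation of
  the voxel does not vary with gantry angle or beam energy).
* Angular geometry is ignored: full-fan vs half-fan mode only changes the
  default projection count and is otherwise metadata. No ray tracing,
  filtered back-projection, scatter, detector noise or volume averaging is
  modelled.
* Motion is 1-D along the superior–inferior axis; the couch is stationary.
* Every voxel must remain inside the imaging view at every projection time;
  otherwise the conservation law fails and the simulator raises
  `OutOfViewError` naming the first offending projection.

## Geometry conventions

Windows are 0-indexed half-open intervals `[origin + k·w, origin + (k+1)·w)`
with `y` increasing toward superior. Positions that land a relative rounding
error below a boundary are snapped onto it, so exact-arithmetic
configurations bin deterministically. Targets are voxelized from their low
edge into voxels of thickness `w`; a target length that is not a multiple of
`w` produces a short terminal voxel whose thickness carries its proportional
weight, so voxelization partitions the target exactly and conservation holds
for any length.

## Deposition modes

* `center` — the whole increment goes to the window containing the displaced
  voxel center. Reproduces the integer bookkeeping of the worked examples
  (e.g. a voxel advancing half a window per interval leaves exactly M = 2
  projections in each of 5 windows).
* `overlap` (default) — the increment is split between the at most two
  windows the displaced voxel overlaps, proportionally to overlap length.
  Profiles are smooth and converge to the continuous occupancy limit.

Both modes conserve the deposited total exactly (to float rounding), so the
area check passes at relative 1e-9 regardless of motion.

## Continuous occupancy oracle

The `N → ∞` limit assigns window `k` the value `CT_S` times the
overlap-length-weighted fraction of the scan during which the displaced
target covers window `k`. For sinusoidal motion spanning an integer number
of cycles this is evaluated in closed form from the arcsine residence-time
distribution of a sinusoid (integrated analytically over each window via the
antiderivative of `arcsin`), which is exact and manifestly independent of
the motion phase; windows the displaced target can never reach are zeroed
explicitly rather than left with rounding dust. For all other motions a
midpoint time quadrature with `n_quadrature` samples (default 1e5) is used.
The two paths agree to better than 0.1% of `CT_S` on 2 mm grids, and the
discrete overlap-mode simulator converges to the oracle as `N` grows
(max-norm well below 1% of `CT_S` at `N = 10^4`).

Consequences used by the analysis layer:

* support of the blurred profile = stationary length + range of motion `2A`;
* elongation grows linearly in `A` with slope 2;
* the profile splits into two peripheral lobes with a central dip exactly
  when `2A` exceeds the target length (the target then spends most of each
  cycle near the turning points);
* over integer cycle counts the occupancy profile is independent of both
  phase and frequency — frequency effects in the discrete simulator arise
  only from finite, non-commensurate sampling of the cycle, so no specific
  frequency response is asserted quantitatively.

## Analysis parameters

* **Support threshold** (default 0.05 of the profile maximum): the model
  never defines the "extent" of a distribution operationally, so the support
  is the set of windows above a threshold fraction of the maximum. Exact
  geometric statements (elongation = 2A, amplitude recovery) are tested with
  a near-zero threshold on noise-free profiles. The amplitude sweep uses a
  0.5 mm analysis grid, so that window quantization (up to two windows of
  over-count when the excursion ends mid-window) cannot mask the linear law;
  on the standard 2 mm grid the same quantization bounds the amplitude
  estimator's error by one window width, which is what the recovery check
  asserts.
* **Split detection** (dip fraction default 0.9, smoothing default 3
  windows, peak floor 0.1 of the maximum): a profile is split when two local
  maxima, each at least the peak floor, bracket an interior minimum below
  the dip fraction of the smaller maximum. The smoothing pass exists to
  suppress single-bin streak spikes in measured data; on noise-free model
  profiles it biases the shallow central dip that appears just past the
  splitting threshold, so model-profile checks run with smoothing disabled.
* **PRMS** is computed over the union support (windows where either profile
  is nonzero); the normalization defaults to the maximum of the calculated
  profile but should be the stationary level `CT_S` when comparing mobile
  profiles across motion parameters, and is recorded in the result.
* **Amplitude estimation** floors at zero and warns (returning 0) if the
  support is smaller than the marker length minus one window.

## Synthetic measurements

Measured CBCT profiles differ from the model by per-window noise, sparse
single-window spikes from streaking (dense couch/phantom components), and a
level offset of order ±20 HU between half-fan and full-fan scans of the same
object. `generate_measured_profile` adds exactly these three terms —
i.i.d. Gaussian noise, `n` impulses at distinct seeded windows, and a
constant baseline — and is bit-reproducible given its seed. It does not
emulate detector blur, beam hardening, spatially correlated scatter, or the
2-D geometry of streaks, so agreement of the comparison pipeline on these
fixtures demonstrates correctness of the pipeline, not fidelity of real
scanner noise. Default phantom levels place water-equivalent gel targets
(0 HU) in lung-equivalent foam (−700 HU), i.e. `CT_S = 700` HU above
background; both are configurable, and profiles are stored relative to
background so the model is offset-free.

## Study conditions and problem sizes

The preset targets are 10, 20 and 40 mm long along the motion axis on 2 mm
slices; cyclic sweeps use amplitudes 2.5–20 mm in 2.5 mm steps, frequencies
0.1–0.4 Hz (15 cycles/min = 0.25 Hz as the measurement condition), and
constant speeds 0.25, 0.5 and 1.0 mm/s. Cyclic test scans span 60 s (an
integer 15 cycles at 0.25 Hz) with `N = 655` projections as the conventional
full-rotation default; convergence checks use `N = 10^4`, which runs in
seconds in the vectorized deposition path. These sizes make every check
exact or tightly bounded while keeping the whole suite fast.

## Known limitations

* One-dimensional rigid motion only; no hysteresis or irregular breathing
  beyond user-supplied sampled trajectories.
* The frequency dependence of measured profiles at finite `N` depends on the
  (unstated) commensurability of breathing and gantry periods; the package
  exposes it through the discrete simulator but asserts no numbers.
* Quantitative agreement with any particular scanner's measured profiles
  (e.g. PRMS values of a physical phantom study) requires those measured
  profiles; the synthetic generator is a stand-in with known statistics.
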