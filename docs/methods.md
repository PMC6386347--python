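# Methods

## Model

The network is a constructed (rule-wired, untrained) feed-forward stack of
five layers over an `H x W` sensor grid; layer sizes are `H·W` four times
and then 1. All state is discrete-time: object positions are given per
tick, layers 1–4 are evaluated in order within a tick, and only the track
layer carries state (one tick of arming) across ticks, so the whole
simulation is deterministic and causal.

**Perception geometry.** Each sensor looks straight up through a cone with
full apex angle `θ`. The perception predicate is purely geometric: sensor
`(r, c)` at continuous point `(c·s, r·s)` (pitch `s`, default 1 grid unit)
fires iff the horizontal distance to the object's `(x, y)` is at most
`z·tan(θ/2) + radius`. This is the simplest geometry consistent with the
qualitative behavior being modelled: footprints grow with height, shrink on
approach, and at `z = 0` only an object physically covering a sensor is
seen. The angular placement of neighboring cones is not modelled; all cones
are parallel and vertical, and the pitch is a free default. Multiple
objects OR into one binary frame.

**Ring weights.** With radius parameter `n`, the layer-2 receptive field is
the `(2n-1) x (2n-1)` block and the weight at Chebyshev ring distance `d`
is `w(d) = 2(n-d) - 1`, i.e. rings `d = 0 … n-1` with center `2n-1` and
outermost ring `1`. Stated endpoint weights (`2n-1` at the center, `1` at
the outermost connected ring) together with integer odd-step linear decay
force the outermost ring to `d = n-1`; we adopt that reading, which also
makes `n = 2` yield exactly the 9-connection field of the default network.
Chebyshev (square) rings are the only metric consistent with square
9-connection fields. Receptive fields truncate at the border — no padding,
no wraparound — so corner fan-ins are smaller (4 for layer 2 at `n = 2`);
quoted fan-ins (9, 5, 9) always refer to interior neurons.

**Winner-take-all.** Layer 3 fires a cell iff its range output is
positive, maximal within the wired 5-cell plus neighborhood, and equal to
the layer-wide maximum. Two guards here were genuinely open design points:

* *Zero-activity guard*: equality alone would fire every cell of an empty
  frame; requiring positivity makes an empty field silent.
* *Layer-wide maximum*: the ring-weight scheme is designed so a compact
  perceived disc yields exactly one maximum for the posterior layer to
  find. A purely local equality test would additionally fire the weight-1
  outskirts of the kernel ring whenever only a single sensor is active
  (each such cell ties with its equally dark neighbors); requiring the
  layer maximum preserves the designed one-winner behavior while genuine
  plateaus — adjacent equal maxima, or the flooded far-field surface —
  still fire all tied cells.

**Track layer.** Direction codes follow the single fixed anchor
(upper-left step = 1) and continue clockwise: 2 = N, 3 = NE, 4 = E,
5 = SE, 6 = S, 7 = SW, 8 = W. Arming picks the lowest row-major firing
cell, which disambiguates plateaus deterministically. An armed cell that
re-fires emits nothing (code 0 carries no spike); a spike outside the
Moore neighborhood drops the track and re-arms silently (a teleporting
object is a new track, not a step); no spike at all disarms. Two
consecutive codes refine the heading to 16 angles via the circular mean of
the two step vectors; opposite steps cancel and fall back to the first
code's heading.

**Distance.** The active-sensor count is thresholded into classes 1/2/3
(near/middle/far) at `(c1, c2) = (9, 25)`: the counts reachable by
perceived discs of Chebyshev radius ≤ 1 and ≤ 2. Class 0 is reserved for
an empty frame. Only the perception-count signal is used; the range and
location surfaces carry the same information more noisily.

**Velocity.** One spike is emitted per cell transition, so spikes per
fixed interval grow with speed; window speed is defined as summed step
length (1 axis, √2 diagonal) over the window's tick span, which recovers
true speeds exactly on synthetic trajectories. The plane is tiled into
`4 x 4` sub-fields on the default grid; a window closes when the track
exits its sub-field or after `T = 8` ticks, whichever is first, so an
object circling the field cannot inflate a single endless window. The
window length in the divisor is the actual (possibly early-closed) span.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `grid.height/width` | 8 x 8 | cells | sensor plane; any `H, W ≥ 2n-1` works |
| `grid.spacing` | 1.0 | grid units | sensor pitch |
| `cone.apex_angle` | 120 | degrees | full opening of each viewing cone |
| `kernel_n` | 2 | — | ring radius parameter; field `(2n-1)²` |
| `subfield_size` | 4 | cells | velocity decision tile side |
| `interval_T` | 8 | ticks | maximum decision window |
| `distance_thresholds` | (9, 25) | sensors | near/middle/far cutoffs |

## Synthetic scenes

The generator produces the conditions the design targets: straight
trajectories along the 8 coded directions at a chosen speed and constant
height (diagonal codes step one full cell per axis, √2 grid units per tick
at speed 1, keeping cell transitions aligned with ticks); vertical
approach/recede tracks; static objects; and seeded, border-reflected
random walks. It emulates a single rigid point-or-disc object with exact
per-tick positions. It does not emulate photoreceptor noise, luminance or
contrast, extended textured objects, occlusion, or multiple simultaneous
targets — passing tests therefore demonstrate the circuit logic, not
robustness to real imagery.

## Numerical choices and degenerate inputs

Frames are exact integer arithmetic (the weighted sum is an integer
correlation; the winner-take-all compares integers), so layer outputs have
no floating tolerance. The perception test uses a `1e-12` slack on the
squared-distance comparison so objects exactly on a footprint boundary are
counted in. Ties everywhere are handled explicitly: plateau cells all fire
in layer 3, and the track layer breaks ties by lowest row-major index.
Empty frames, empty scenes and zero-speed trajectories are valid inputs
yielding silent layers, zero events and speed 0. Border cells have
truncated fields; a trajectory reaching the outermost ring of cells can
tie several range cells and deflect the track by one cell, so quantitative
direction/speed checks use interior trajectories.

## Problem sizes

All tests and the acceptance script run on the default 8 x 8 network with
scenes of 2–50 ticks and oracle sweeps of a few hundred random frames —
the scale the construction is specified at; the wiring itself extends
unchanged to any grid admitting the kernel field, covered by construction
tests up to 16 x 16.

## Known limitations

Single-object tracking only (one global track state); no edge detection;
no learned or evolved weights; no modelling of photoreceptor spectral
response or real ommatidial optics; direction codes 2–8 and the distance
cutoffs are conventions fixed here, as only their anchors (upper-left = 1;
three classes, far = 3) are externally given.
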