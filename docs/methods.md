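# Methods

## Model and assumptions

The package simulates a single audio-visual trial as a deterministic
discrete-time dynamical system. Its components, in pipeline order:

1. **Unisensory signals.** Each stimulus is a piecewise-constant 4-D signal
   `(ext, rel, ech, ecv)`. The existence bit is 1 on the half-open window
   `[onset, onset + duration)` — half-open so a sample at a shared on/off
   boundary is counted exactly once. Position angles are accepted in
   degrees at every interface (specs, configs, trace output) and converted
   to radians internally. Positions and reliabilities do not vary during a
   presentation; moving stimuli and sensory noise are out of scope.

2. **Working memory.** An 8-D controlled leaky integrator, four dimensions
   per modality, with each half's leak driven by its input's existence bit.
   At the behavioral level this makes the element a switch: *update to the
   input* while the stimulus is on, *hold bit-exactly* after offset. We
   implement the switch directly rather than as a first-order lag with a
   finite time constant: the lag's time constant is not a quantity the
   model's behavior is specified in terms of, and the switch removes a free
   parameter while leaving the stored contents independent of the grid
   step. A third branch (clear when the leak opens with no input) exists in
   the implementation but is unreachable while the leak tracks existence;
   it is exposed through explicit leak overrides.

3. **Similarity.** The great-circle angle between the two memorized
   positions is integrated over time with gain `k_int` while *either*
   stimulus is physically present, and mapped through
   `sim = 1 − tanh(0.5 · disp)`. Two readings were genuinely open and are
   resolved as follows:

   * *Gate.* The disparity integrator runs whenever at least one stimulus
     is on. This is what makes presentation duration itself evidence: a
     lone ongoing stimulus keeps accumulating disparity against the other
     modality's memory.
   * *Empty memory.* Before a modality's first stimulus arrives its memory
     sits at the spherical origin, and the distance is evaluated literally
     against it. A stimulus's eccentricity therefore acts as the asynchrony
     penalty during the unpaired interval — this literal reading is what
     makes purely temporal disparity reduce similarity at all.

4. **Decision.** The three plan saliencies (two reliabilities, `sim`) form
   the decision variable; a product-of-logistics rule converts it to a
   decision result whose components sum to one by the complement identity
   (`dr_a` is computed as `(1 − g_av)(1 − g_v)` so the partition is exact
   in floating point). The multisensory plan position is the
   reliability-*normalized* weighted average of the memorized positions,
   i.e. a convex combination: an unnormalized weighted sum would leave the
   fused target outside the segment between the stimuli whenever the
   reliabilities do not sum to 1, contradicting the ventriloquism percept
   the plan represents. Averaging is componentwise on `(ech, ecv)`, valid
   on the common-meridian geometry used throughout; great-circle
   interpolation is out of scope. With both reliabilities zero the fused
   position falls back to the origin.

## Parameters

| name    | units | default | role |
|---------|-------|---------|------|
| `k_int` | 1/s   | 21      | disparity integration gain |
| `th_av` | —     | 0.5     | similarity threshold for the common-cause call |
| `sl_av` | —     | 200     | logistic slope, similarity vs threshold |
| `sl_u`  | —     | 200     | logistic slope, reliability comparison |
| `dt`    | s     | 0.001   | simulation step |
| `t_end` | s     | 1.0     | trial span |

`k_int = 21` with distances in radians is a calibration, not an arbitrary
choice: on the default geometry it is the single gain that simultaneously
places all four decision landmarks where the model is meant to put them —
the sameness flip near 10° of spatial disparity for a 0.3-s synchronous
presentation (`2 atanh(0.5)/(21 × 0.3) rad = 9.99°`), near 0.1 s of
auditory onset delay at 7° separation, near 0.4 s of common duration at
7.5°, and the multisensory decision-variable threshold crossing at
t = 0.4 s in the 15°-separation reliability scenario. All four follow in
closed form from the piecewise-linear disparity, so the calibration is
checked analytically, not fitted numerically.

Slopes of 200 make the soft decision rule agree with the categorical
three-way rule to well under 1 % whenever the similarity is more than 0.05
from threshold and the reliabilities differ by more than 0.05; the exact
values used for the model's published dynamics are not documented anywhere,
so steepness-to-categorical-agreement is the design criterion. A
reliability tie with similarity below threshold leaves `dr_v = dr_a = 0.5`;
the categorical trial summary breaks such ties toward the visual plan and
flags the trial as tied. A boundary tie `sim = th_av` maps to sameness 0
(strict `>`); both are measure-zero cases.

## Scenario geometry

Trial conditions never state absolute eccentricities, only disparities, so
the built-in catalog fixes a default geometry once: both stimuli on a
common meridian (`ecv = 0`), visual at `ech = 9°`, auditory at
`ech = 9° + sd`. The great-circle separation then equals `|sd|` and the
visual stimulus sits 9° from the memory origin, which is the eccentricity
the `k_int` calibration above assumes. Default timing is onset 0.2 s and
duration 0.3 s with reliabilities 0.5. The catalog covers five families:
spatial disparity 1.5–21.7°, auditory onset delay 0.05–0.25 s at 7°,
auditory reliability 0.2–0.8 at 15° separation, common duration
0.25–0.55 s at 7.5°, and an asymmetric family (visual 0.2 s, auditory
0.25–0.55 s). Where a family needed a separation the conditions did not
pin down (the reliability and duration families), it was chosen so the
decision landmark lands where the model places it under the calibration —
15° puts the threshold crossing at 0.4 s, 7.5° puts the duration flip at
0.4 s — and recorded here once.

These scenarios are idealized trials: rectangular stimulus profiles, exact
reliabilities, no sensory or decision noise. Passing tests therefore show
that the deterministic circuit reproduces its intended decision boundaries,
not that it predicts graded psychometric percentages — mapping binary calls
onto percent-of-reports would need a noise model the package deliberately
does not invent.

## Numerics

Forward-Euler accumulation on a uniform grid (`dt = 1 ms`). Because the
integrand is piecewise constant, the only discretization error is boundary
granularity: the discrete disparity equals the closed-form piecewise-linear
integral within `k_int · π · dt` per trial, and the engine tests enforce
exactly that bound against an independent analytic oracle
(`closed_form_disparity`). Trace rows record the state *after* the step's
update, so the disparity at time t includes the sample at t. The arccos
argument in the spherical distance is clamped to [−1, 1] against round-off.
Flip points are located by bisection on the end-of-trial sameness call,
with default bracket tolerances of 0.01° (spatial) and 1 ms (temporal);
halving `dt` moves every flip by less than the tolerance. Grid sizes: one
trial is 1001 steps, a bisection ≈ 13 trials — everything runs in seconds
on one CPU.

## Known limitations

* Two stimuli, one per modality; no capacity limits, decay, or
  interference in memory.
* Componentwise position averaging restricts meaningful fused positions to
  near-meridian geometries.
* The disparity never resets within a run; each trial starts from zero
  state (`run_scenario` simulates exactly one trial).
* No reaction-time or stochastic-accumulator dynamics: the decision result
  is an instantaneous function of the decision variable.
* The optional `report_time` key reads the categorical outcome at an
  earlier grid point, emulating a forced report; it does not model the
  report process itself.
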