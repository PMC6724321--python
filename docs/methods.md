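# Methods

This note records the models, the calibrations behind the shipped presets,
the numerical choices, and what the synthetic test conditions do and do
not establish about real devices.

## Buoyancy budget

Components are booked in bench units (mm, g cm⁻³, mN, mL) and converted to
SI only inside the integrators. A component's net buoyancy comes from one
of three routes, in order of precedence: a stored measured value
(`buoyancy_override`), the weight route $B = W(\rho_w/\rho-1)$ when a
weight is given, or the geometric route $B = V(\rho_w-\rho)g$ from
diameter and density. The override exists because a live, water-logged
alga ball does not obey the solid-sphere formula: the reference fixture
stores the measured per-row values verbatim (float +7.8, alga ball −4.9,
weight −2.6, link −1.3 mN), which makes the gas-free total −1.0 mN and the
total at the 2.04 mL bubble cap +19.0 mN. The weight and link rows are
also recomputed from their weights and densities in tests (−1.32,
−2.66 mN) and agree with the stored values within 0.15 mN. Attached gas
contributes $(\rho_w-\rho_g)g \approx 9.80$ mN mL⁻¹.

## Gas production

The light response is phenomenological:
$r = r_{max}\,\mathrm{PAR}/(\mathrm{PAR}+K)\cdot e^{-t/\tau}$, with
defaults $r_{max} = 18$ mL day⁻¹ and $K = 3000$ µmol m⁻² s⁻¹ chosen so the
strong-sunlight preset (1500 µmol m⁻² s⁻¹) produces exactly 6 mL day⁻¹ and
the moderate preset (500) produces 2.6 mL day⁻¹, inside the observed
1–3 mL day⁻¹ band for a ~60 mm ball. A curve this weakly saturating is a
deliberate compromise: the observed strong/moderate rate ratio of ~3 at a
PAR ratio of 3 forces the response to be nearly linear over the bench
range, so $K$ sits well above any usable irradiance and should be read as
a shape parameter, not a physiological half-saturation. Production is
zero during an induction lag after a declared environment change (default
4 h — bubble formation resumes only hours after handling or a water
change), declines exponentially under continuous illumination (default
e-folding 10 days; the decline is not driven by dissolved CO₂ — raising
CO₂ does not restore production), and is zero with a flag above a
photo-damage threshold (default 3000 µmol m⁻² s⁻¹, twice the strong-sun
preset; over-lit balls discolour; no measurement pins this threshold, so
the default is config-overridable).

## Bubble retention and escape

Attached gas escapes with a base hazard (h⁻¹), multiplied while the ball
sits in the column's top band (surface contact and rotation shed bubbles)
and, optionally, while the ball descends faster than a small threshold
speed — a negatively buoyant ball tumbles, and tumbling sheds bubbles;
lowering an assembly's centre of mass reduces this, which is why the
multipliers are per-preset parameters rather than constants. Escape is
implemented as binomial thinning of bubble quanta (default 0.2–2 µL):
the expected loss matches the analytic exponential hazard (verified to
within 3 standard errors in tests), fixed seeds give identical
trajectories, and passing no generator collapses the update to its
expectation, which is what the "ideal" deterministic presets use. Volume
is clipped to a retention cap (default 2.04 mL, the measured ~20 mN lift
ceiling; device presets use smaller caps reflecting their assemblies).

The unlit escape rate and the lit escape fraction are not measured
quantities; the defaults are stated device parameters, and every
device-level conclusion below is conditional on them.

## Vertical dynamics

$m_{eff}\,\dot v = B - k\,v|v|$, with $m_{eff}$ the ball mass plus half
the displaced water mass (standard added mass for a sphere) and quadratic
drag $k$ (default 36.75 N s² m⁻², placing the terminal speed of a 60 mm
ball under 1.5 g-force of lift at ~0.02 m s⁻¹, so transits take seconds to
minutes). The velocity update solves the implicit Euler step exactly — a
quadratic in the new speed — which is unconditionally stable and has the
correct terminal speed as its fixed point at any dt; an earlier
linearised-drag variant was rejected because its terminal speed carried an
O(dt) bias at simulator time steps. Positions are ball-centre heights,
clamped to [floor + r, surface − r] with velocity zeroed on contact. With
near-zero drag the step conserves mechanical energy to O(dt²) (checked
against fine-step integration).

## Optics

Beams are horizontal rays, optionally widened to a band
(`beam_half_width`); a ball occludes a beam when its body overlaps the
band. Divergence applies the geometric attenuation $1/(1+\tan\theta\,L)^2$
over path length, so light never increases along a path. The oscillator
rig uses a band of half-width 50 mm (the physical beam is collimated by an
80 mm tube), which matters dynamically: a rising ball keeps charging while
it climbs out of the lit zone, and the gas it banks there sets its
endurance at the surface. The mirror pair that folds the transmitted beam
onto the floating left ball delivers a deliberately weak feed
(`mirror_coupling`, default 2% after path attenuation): it prolongs the
left ball's float but cannot sustain it, matching its role in the cycle.
Float stacks are opaque/transparent vertical sections translated with the
ball; gate supply beams are thin rays at 0.20 m.

## Oscillator preset calibration

No kinematic, sampling or rate data exist for the original oscillator
recordings, so the shipped presets are the package's own calibration of a
device that exhibits the documented cycle. The "ideal" preset uses an
idealised organism (r_max 72 mL day⁻¹, ~1 mL h⁻¹ when lit in the beam,
lag and decline off), base escape 0.5 h⁻¹, surface multiplier 1.8,
descent-shed multiplier 180, gas cap 0.125 mL, and ballasts −1.12 mN
(left) / −1.0 mN (right). Three of these choices are load-bearing:

* the **descent-shed multiplier** empties a sinking ball, so it reaches
  the floor needing a full recharge instead of re-floating at once;
* the **low gas cap** makes both balls saturate at the same absolute
  volume while charging, so the lighter right ball holds the surface much
  longer than the heavier left one — without the cap, endurance asymmetry
  vanishes;
* the **ballast asymmetry** (left slightly heavier) makes the left ball
  rise later and sink earlier than the right, opening the both-down (00)
  and both-up (11) phases; with identical balls those phases squeeze to
  zero and the machine degenerates to a two-phase alternation.

The resulting phase dwells are ≈3.6 / 7.3 / 5.1 / 3.2 min
(00/01/11/10). The automaton sampling interval is set to 255 s because
extracting the cycle from a sampled nearly periodic chain requires every
dwell to lie between roughly 0.8× and 2× the sampling interval — shorter
dwells are skipped, longer ones make self-transitions dominate. The
"stochastic" preset adds binomial escape noise (0.2 µL quanta); a single
8-hour run recovers the maximum-likelihood cycle for ≈93% of seeds, and
pooling the transition counts of three repeat runs
(`estimate_transitions_multi`) recovered it for all seed triples tried.
Pooling is the natural estimator for repeat recordings of one rig and is
what the end-to-end checks use.

## Motor

Chambers receive cosine-weighted exposure on the lamp-facing side, gas
torque is $\sum_i B_i r \cos\varphi_i$, and a slot sector near the top
vents 90% of a chamber's gas on entry. Rotation is quasi-static
($\omega = \tau/c$): at rev-per-hour speeds the bearing drag dominates
inertia. The drag coefficient default (0.47 N m s) is set so the daylight
preset — 190 µmol m⁻² s⁻¹, the mean PAR of 1 kW h m⁻² day⁻¹ of insolation
at ≈4.57 µmol J⁻¹ — turns the rotor at ≈0.2 rev h⁻¹, the measured
operating point. The speed–insolation and energy-per-revolution laws are
linear through the origin and calibrated at (1 kW h m⁻² day⁻¹,
0.2 rev h⁻¹) and (0.2 rev h⁻¹, 0.9 mJ rev⁻¹) respectively; the energy
constant is treated as a calibration datum, not re-derived.

## Gates

Layouts are data (`presets.yaml`): columns driven by logical inputs, float
stacks (`transmit_when_up` — opaque section above the ball;
`block_when_up` — opaque sleeve on the link below it), and supply-beam
paths to sensors. Output is 1 iff any sensor reads more than half the
supply PAR after the settle window (default 12 h simulated; the gate
organism parameters make balls rise in ~10 min and drain in ~2 h, so
settling is comfortable). A column still flipping across mid-height in
the final quarter of the window raises an explicit non-settling error.
Input beams flood their column (a lit ball stays lit at any height);
occlusion between columns applies to the supply beams only.

## Tri-state hold

The equilibrium preset grades light linearly with height
(PAR(z) = 2242·(1 − z/H)) so that production balances escape
(λ = 2 h⁻¹) exactly at mid-column for the 0.102 mL that neutralises the
−1.0 mN ballast. Because buoyancy feeds back on height only through the
slow gas budget, a freely moving ball overshoots this equilibrium and
relaxation-oscillates between floor and surface; the hover assembly is
therefore configured as heavily damped (drag coefficient 1200 N s² m⁻², a
drag plate in device terms), slowing transit enough for the light
gradient to correct excursions inside the band. Deterministically the
ball then holds the middle band (35–65% of column height) indefinitely;
with escape noise, seeded 6-hour runs hold it for ~40–270 minutes,
comfortably beyond the half hour observed on the bench.

## Synthetic trajectories

`synth_oscillator_trajectory` emulates the *structure* of processed
two-ball video recordings: square-wave positions with period 2 h, quarter-
period lag, optional Gaussian position noise and sample dropout, sampled
four times per period so a noise-free series encodes to the exact
four-state cycle. It is a fixture generator, not a physical model: it
reproduces the data format and the cycle topology, but none of the
charge/drain asymmetries of the simulator. Tests that pass on it
establish the correctness of the encoding/estimation pipeline, not the
physics; physics-level claims rest on the device simulators, whose own
presets are calibrations as described above. Neither captures real-world
features such as ball-to-ball biological variability, temperature
dependence, nucleation on rig surfaces, or bubble coalescence — all out
of scope.

## Degenerate inputs and tie-breaks

Position exactly at the encoding threshold counts as "up" (closed upper
rule). Tied argmax in the cycle extractor resolves to the lowest state in
(00, 01, 10, 11) order. Unobserved transition rows stay NaN (never
uniform-filled) and end the cycle walk as explicit dead ends. Empty
assemblies have zero buoyancy; an empty trajectory file or a non-monotone
time column is a format error with a line number. All simulators derive
independent per-ball random streams from one root seed.

## Problem sizes

Default analysis runs are sized for interactive use: 8 simulated hours at
dt = 1 s for the oscillator (≈25 cycles), 6–24 h at dt = 5 s for the
motor, 12 h at dt = 30–60 s per gate column, and 4–6 h at dt = 2 s for the
hold. Longer runs change none of the qualitative results; they narrow the
transition-probability estimates as 1/√n.
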