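# Methods

## Scope and structure

`spindlemag` has four layers: closed-form magneto-mechanics of tubulin
and microtubules (`magnetophysics`), a stochastic positioning model of
the spindle in an elliptical cell (`simulator`), relaxation-time
extraction and cleavage-delay accumulation (`relaxation`), and synthetic
input generators (`fixtures`).  The CLI (`cli`) and readers/writers
(`io`) are thin plumbing over these.

## Magneto-mechanics

All analytic quantities are pure functions of the angle θ between a
dimer/filament axis and the field, vectorized and in SI units.  The
energy scale is Δχ B²/2µ₀ per dimer; at 9 T this is 4.0 × 10⁻²⁵ J,
about 10⁻⁴ k_BT at 301.65 K — so the *orientational statistics* of free
dimers (and hence the polymerization-rate anisotropy, and the rigid-rod
rotation rate of ~10⁻⁸ rad/s) are minute perturbations.  The *bending*
of an anchored filament is different: the distributed torque integrates
along the filament twice, giving a tip deflection ω_max ∝ L³B², which
reaches tens of micrometres for the 200–400 µm filaments of a
blastomere-scale aster.  This separation of scales — not a tuned
parameter — is what makes bending the dominant pathway in every
downstream result.

Constants and unit readings:

- Δχ = 1.243 × 10⁻³² m³, d₀ = 8 nm, v₀ = 0.125 µm/s, T = 301.65 K
  (the 28.5 °C rearing temperature of zebrafish embryos).
- Flexural rigidity EI = 33.12 pN·µm² = 3.312 × 10⁻²³ N·m², the
  standard magnitude for a single microtubule.  (A literal "pN·m²"
  reading would make magnetic bending ~10⁻¹⁰ µm and remove the dominant
  mechanism; EI is an ordinary configurable field.)
- Rotational drag per unit length ξ = 10⁻³ N·s/m², so that the
  rigid-rod rate 2M/ξL² is in rad/s.
- The dimer orientation density is normalized numerically on the planar
  support [−π/2, π/2) to match the planar simulator; a 3-D
  (sin θ-weighted) option exists behind the `support="spherical"` flag.

The small-deformation formula can formally yield ω_max > L for very long
filaments at 9 T; before the chord projection √(L²−ω²)/L is applied,
ω_max is clamped to 0.99 L and the filament flagged (`clamped_bend`).
This keeps the force real-valued while preserving the physical content:
very long oblique filaments transmit almost no force.

## The positioning model

Two-dimensional plane through the cell's long axis; the default cell is
the first-cleavage ellipse with semi-axes 300 × 150 µm.  The spindle is
a rigid body (half pole separation s = 30 µm, fixed: spindle size
saturates in large blastomeres) moving overdamped with translational and
rotational drags Γ_t = 100 pN·s/µm and Γ_r = 10⁵ pN·s·µm.

Per pole, `n_mt` microtubules (default 100; behavioural studies here use
50) grow radially with two-state dynamic instability: growth at the
zero-field polymerization speed v_g = 0.125 µm/s (modulated by the
Boltzmann factor when the field is on), shrinkage at v_s = 0.25 µm/s,
catastrophe and rescue as Bernoulli events with rates f_cat = 0.002 s⁻¹
and f_res = 0.04 s⁻¹, timestep dt = 0.5 s.  These rates give
net-growing filaments (v_g f_res > v_s f_cat), so asters span the cell —
the regime a blastomere must be in for its astral microtubules to
position the spindle at all; with bounded-growth rates (mean length a
few tens of µm) no centering signal exists in a 600 µm cell.  Tips
beyond the cortex are truncated to the boundary and flagged; a fully
depolymerized filament renucleates immediately in a fresh direction.

Forces per filament: a cytoplasmic pull α_cyto·L (α_cyto = 0.01 pN/µm)
along the growth direction; at the cortex a polymerization push
f_push = 1 pN and, with probability p_bind = 0.1 per step, a cortical
dynein pull f_dyn = 2 pN.  Length-proportional pulling truncated by the
boundary centers the spindle (filaments toward the far cortex are
longer, hence pull harder); the boundary anisotropy of the ellipse
orients it along the long axis.  All force/drag parameters are model
choices of this package, exposed in the configuration; their absolute
scale sets the clock but not the orderings the package asserts, which
are reported in normalized time t* = t/τ.

Field coupling, each independently ablatable:

- `enable_rate` — growth speed times exp(−Δχ B² sin²θ_B/2µ₀k_BT);
- `enable_rotation` — free (non-cortex-bound) filaments rotate toward
  the field axis at the rigid-rod rate; the summed rigid-rod torque also
  acts on the spindle body;
- `enable_bending` — every pulling force is attenuated by the chord
  projection √(L²−ω_max²)/L of the bent filament.

On the bending force *direction*: a mode that additionally redirects the
pull along the pole-to-deflected-tip chord exists
(`bending_redirect=True`) but is off by default.  Measured on paired
ensembles, redirection steers every pull toward the field axis, which
*accelerates* orientation when the field lies on the short axis and
destabilizes alignment for other field angles — the opposite of the
slowdown the mechanism is meant to produce.  Magnitude-only attenuation
slows both positioning and orientation, with bending dominant, and is
therefore the default reading.

Nucleation directions are uniform on [0, 2π); by default they are
*stratified* (one per equal angular bin, uniform within the bin, bin
retained on renucleation).  A computational aster of 50–100 filaments
stands in for a real aster of thousands; with independent sampling the
~1/√n resultant of the direction set acts as a static polarity that
pins the spindle tens of micrometres off center — a small-n artifact,
not physics.  Stratification removes it while keeping the uniform
marginal; `nucleation="iid"` restores independent sampling.

Initial asters: `init_mt="zero"` grows the aster during the run (the
growth transient is then part of the measured relaxation — this is what
makes the big cell slower than the half-scale cell at matched
parameters); `init_mt="spanning"` starts filaments truncated at the
cortex, the steady state of net-growing dynamics, modelling a spindle
released into an already-established aster.  Field-comparison
experiments use the spanning start: from zero length, orientation
relaxes while filaments are still far too short (ω ∝ L³) for any
bending signal to exist.

Randomness: one `numpy` PCG64 generator per run, seeded from the run
seed; a fixed number of uniform draws per step regardless of the field,
so paired runs with shared seeds (common random numbers) see identical
catastrophe/rescue/dynein randomness and differ only through the field
physics.  Trajectories are bit-reproducible for a fixed seed.

## Relaxation times and the cleavage delay

τ is estimated by least squares on (t, ln y) weighted by y² (the
log-domain rewrite of an unweighted linear-domain fit), restricted to
the decay window: samples after the series first drops below 95% of its
initial value and above a floor of 5% of it.  The window exists because
a simulated series has a plateau (aster build-up, or the lag before
the offset moves) and a stochastic noise floor, both of which otherwise
dominate the weighted fit; an exact exponential is unaffected by the
windowing and recovered exactly.  If the fitted slope is not negative
the estimator falls back to the e-folding crossing time; a series that
does not decay raises an error.  On synthetic decays with 1%
multiplicative noise (200 points), the estimator recovers τ with a mean
bias of ~0.06% and per-run errors under 1% (the acceptance script
recomputes both).

The cleavage schedule is the early zebrafish one: first cleavage at
30–45 min post fertilization (modelled at the 37.5 min midpoint), then
8 synchronous 15-min cycles; cell linear dimensions shrink by 2^(−1/3)
per cycle (volume halving).  `accumulate_delay` converts per-cycle
slowdown ratios r_k into extra time Σ (r_k − 1)·φ·T_k, with φ the
configurable fraction of the cycle spent positioning (default 1.0 —
cleavage cycles are dominated by mitosis; halving φ simply halves the
delay, so the sensitivity is linear and not explored further).  The
acceptance script uses the measured first-cleavage ratio for cycle 1 and
the measured half-scale ratio for the synchronous cycles; the package
asserts orderings (slower with field, delay > 0), not the experimental
hatching-delay magnitude, whose link to per-cycle timing is qualitative.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure the analysis assumes:
exponential decays with multiplicative noise, uniformly distributed
initial spindle states inside the half-scale concentric ellipse, paired
field-on/off configurations with shared seeds, and uniform nucleation
fans.  They do not emulate cytoplasmic flow, yolk mechanics, chromosome
or centrosome dynamics, three-dimensional asters, thermal filament
fluctuations, or measurement noise of real imaging — so passing tests
demonstrate internal consistency of the model and the claimed orderings
under its assumptions, not quantitative agreement with real embryos.

## Numerical choices and limitations

- Timestep dt = 0.5 s; event probabilities f·dt are validated ≤ 1 and
  the per-step Bernoulli discretization of catastrophe/rescue is first
  order in dt.  Poles are kept inside the cell with a 1 µm margin;
  a run whose center leaves the cell raises an instability error naming
  the timestep.
- Behavioural studies use ensembles of 20 paired seeds, 50 filaments
  per pole, 3000 s (spanning start) or 6000 s (growing start) of
  simulated time — sizes chosen so the full suite and the acceptance
  script each complete in minutes on one CPU while the assertions hold
  with margin across disjoint seed batches.
- The measured field effects at these conditions: positioning slowed
  ~4–6%, orientation ~1–1.5%, bending accounting for essentially the
  entire slowdown (rate and rotation shares ~10⁻⁴).  The orientation
  effect is small because filaments near the short axis — which carry
  most of the aligning anisotropy when the field lies on that axis —
  are nearly field-aligned and so nearly unbent.
- The size comparison (600 × 300 vs 300 × 150 µm at matched parameters
  and displacement) is asserted for the positioning time, where the
  aster-growth transient gives a clean factor ~2; the orientation fit in
  the half-scale cell is floor-limited (the stochastic angle floor is a
  larger fraction of the initial misalignment) and not used as a claim.
- The model is planar, the spindle rigid, the cortex passive (no
  force-dependent detachment, no cortical flow), and bending is the
  deterministic magnetic cantilever only — no thermal persistence-length
  undulations.
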