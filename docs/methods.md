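# Methods

## The model

N point particles live on a periodic square of side L (lengths in units
of half a worm body length; times in units of the time to travel it).
Particle i has position **r**_i, heading θ_i, rotation rate ω_i and an
activity flag a_i ∈ {0, 1}:

    dr_i/dt = a_i e(θ_i) + Σ_{r_ij<r_r} F_r + Σ_{r_r<r_ij<1} F_a
    dθ_i/dt = a_i ω_i + (1/N_i) Σ_{r_r<r_ij<1} sin 2(θ_j − θ_i)
    dω_i/dt = −(ω_i − ω_0)/τ + sqrt(2/τ) σ_ω ξ_i

with a linear excluded-volume spring F_r = k_r (r_ij − r_r) e_ij inside
r_r, a surface-tension-like attraction F_a = (k_a / r_ij) e_ij in the
shell (r_r, 1), and nematic alignment (symmetric under θ → θ + π,
normalised by the neighbour count N_i) in the same shell.  ξ_i is
unit-variance white noise, so σ_ω is the stationary standard deviation
and τ the correlation time of the rotation rate — the "smooth turning
with memory" of isolated dauer larvae.  Isolated active particles move
at speed exactly 1.  Inactivity (the optogenetics-style protocol)
zeroes exactly two terms: the propulsion e(θ_i) and the intrinsic ω_i
in the heading equation.  Inactive particles still exert and receive
forces, still align, and their ω_i keeps integrating its
Ornstein–Uhlenbeck (OU) dynamics — the protocol silences motor drive,
not the interactions, and nothing suggests the internal rate state
freezes.

Default parameters: k_r = 10, r_r = 0.2 (fixed excluded-volume
constants), ω_0 = 0.0035, σ_ω = 0.35, τ = 10 (wild-type turning
statistics in simulation units), dt = 0.001.  k_a — the humidity-like
attraction control — has no default and must be chosen per experiment;
k_a ≈ 0.002 at density 4 forms the reference dynamical network, and
attraction beyond a critical strength arrests motion into non-motile
aggregates (covered by a trend test, not an exact threshold).

## Integration

Explicit Euler–Maruyama with step dt = 0.001: all right-hand sides are
evaluated at the old state; the rate update is
ω ← ω − (ω − ω_0)·dt/τ + σ_ω·sqrt(2 dt/τ)·N(0,1).  This discretisation
makes the stationary law N(ω_0, σ_ω²) exact to O(dt/τ) and keeps σ_ω
interpretable as the stationary s.d., matching how the track estimator
defines it.  Initial conditions are uniform positions and headings and
stationary rotation rates (removes the rate-relaxation transient from
short runs).  Angles are stored unwrapped on the real line — estimation
needs a continuous θ(t) — and positions are re-wrapped into [0, L)
every step.

Performance-relevant numerics (all verified against a plain all-pairs
NumPy reference to machine precision or better than the discretisation
error):

* Neighbour search: a Verlet pair list with cutoff 1 + 0.1 skin built
  from a linked-cell sweep; each pair is stored once with its periodic
  image shift and re-examined every step; the list is rebuilt when any
  particle has moved half the skin.  Forces and nematic torques use
  Newton's-third-law accumulation (sin 2(θ_j − θ_i) is antisymmetric).
* Headings enter the pair loop through sin/cos; these are advanced
  incrementally by a 5th-order small-angle rotation (per-step error
  ~1e−12, refreshed exactly every 256 steps) — negligible against the
  O(dt²) Euler error.
* Gaussian noise is drawn in chunks from one seeded NumPy generator
  outside the jitted kernel; runs are bitwise reproducible per seed.
* Exactly coincident particles (r_ij < 1e−9, possible only at random
  initialisation) are pushed apart with force magnitude k_r·r_r along a
  deterministic index-hashed direction; a direction is arbitrary there,
  and determinism keeps the force evaluation a pure function of state.
* A non-finite coordinate anywhere aborts the run with the offending
  particle and time in the diagnostic.

## Motility estimation from tracks

Tracks are centroid sequences at uniform Δt (wild-type reference: 38
animals, 60 points, Δt = 0.21669 s).  Headings are directions of the
forward displacements, unwrapped; steps below 1e−3 of the mean step
length inherit the previous heading (the direction of a near-zero
displacement is noise).  v_0 is the mean step length over Δt; ω_0 is
⟨θ(t_e) − θ(0)⟩ / t_e with t_e = (m−1)Δt (with m positions there are
only m−1 headings; the last heading stands in for θ(t_e) — a 1.7%
convention effect, far below the estimator's standard error).

σ_ω and τ come from the sign-weighted ensemble drift
Y(t) = ⟨ s_i (θ_i(t) − ω_0 t) ⟩ with s_i the sign of the animal's net
turn.  If each animal's rate relaxed deterministically from
ω(0) ~ N(ω_0, σ_ω²), then Y(t) = θ_0 + sqrt(2/π) σ_ω τ (1 − e^{−t/τ})
≈ θ_0 + sqrt(2/π) σ_ω (t − t²/2τ), so a least-squares quadratic
a + b t + c t² gives σ_ω = b·sqrt(π/2) and τ = −b/(2c).  The quadratic
is the default model; the full exponential form is available
(`model="exponential"`).  95% CIs are percentile bootstrap over animals
(1000 resamples, seeded).

**Identifiability caveat (important).**  For tracks whose rate is a
*stationary* OU process, the exact expectation is
Y(t) − θ-term = sqrt(2/π)·Cov(A(t), A(T)) / sd(A(T)) with
A(t) = ∫₀ᵗ (ω − ω_0); its curvature, e^{−t/τ} − e^{−(T−t)/τ}, changes
sign at T/2 and nearly integrates away over the window.  At the
wild-type operating point (T ≈ 12.8 s, τ = 27 s) the closed form gives
c ≈ +3e−5 — no concave rise — so τ is *unidentifiable* from such data
and the fit flags it (NaN) rather than report a number; σ_ω is still
recovered to within ~6% (the sign weighting slightly attenuates the
slope).  The derivation behind the quadratic neglects within-window
rotation noise; it holds when rates genuinely relax deterministically
within a trial, and the package recovers both parameters in that model
class (unit-tested against the closed-form fit values).  Consumers of
τ estimates from short stationary tracks should treat them with
suspicion on these grounds.

Unit conversion: length unit ℓ = half body length (worms shorten while
undulating; 431/2 ≈ 215.5 μm for the reference population), time unit
ℓ/v_0.  The printed wild-type values convert to ω_0' ≈ 0.0035,
σ_ω' ≈ 0.38, τ' ≈ 10.9; the simulation operating point rounds these to
(0.0035, 0.35, 10).  The converter reports exact arithmetic and does
not force the rounded values.

Collision angles: incoming (outgoing) is the full angle in [0, π]
between the two animals' net displacement directions over a 10-sample
window before first (after last) contact; pairs still bound at the end
of a run are scored over the final window (bound pairs move together —
the nematic outcome).  Swapping tracks changes nothing.

## Network morphometry

1. **Density rendering**: particle counts per h × h pixel (h = 0.25,
   resolving unit-width bundles while keeping a 24-unit box at 96²
   pixels), averaged over a trailing 10-time-unit window; each frame
   integrates back to N exactly.
2. **Moving average**: trailing boxcar over 100 time units (50 s for
   experimental movies), timestamps at the window end.
3. **Spatial smoothing**: a Gaussian blur of 1.5 px before
   thresholding.  Point particles leave pixel-level shot noise that
   images of finite-width worm bodies do not have; without this step a
   global threshold yields a salt-and-pepper mask and thinning is
   meaningless.  The blur is ~1/3 of a bundle width and does not move
   bundle centrelines.
4. **Binarisation**: Otsu's global threshold by default (reproducible
   and parameter-free), manual override available.  Flat images are
   rejected.
5. **Skeletonisation**: topology-preserving thinning to one-pixel
   curves (loop count is preserved; tested via Euler characteristics).
6. **Compartments**: 4-connected components of the non-skeleton
   background (complementary to the 8-connected skeleton, so regions
   cannot leak through diagonal line pixels), pixel counts × h².
   For camera frames, border-touching components are dropped (the
   field of view truncates them).  For simulation domains the frame is
   a torus: the mask is wrap-padded before thinning and components are
   merged across the seams instead — in a small box nearly every
   compartment touches the border, so the camera-frame convention
   would measure nothing.
7. **Statistics**: compartments above 30 square units enter the mean
   (point particles produce spurious slivers inside bundles; the
   small-size range is excluded).  The large-size tail is summarised by
   a moment fit of a Gaussian to ln(area) above a threshold (50 units²
   for model data) and a quantile–quantile check against the fitted
   normal at plotting positions (k − ½)/n; the linearity statistic is
   the squared correlation of the Q–Q pairs.

## The sweep experiment

`experiments.compartment_sweep` measures the attraction and
turning-noise dependence of compartment sizes: k_a ∈ {0.0015, 0.003,
0.0045} crossed with wild-type (ω_0, σ_ω) = (0.0035, 0.35) and noisy
(0.0045, 0.45) turning statistics, three seeds per condition, in a
24 × 24 box at density 4 (N = 2304) for 200 time units; moving-average
frames ending every 20 time units in (100, 200] are pooled.  Probe runs
show the pattern statistics are stationary by t ≈ 100 at this box size.
At this desk scale only *orderings* are meaningful — larger k_a gives
larger compartments, noisier turning gives smaller ones; the box holds
only a handful of compartments per frame, and absolute means are
inflated relative to the large-box values by finite size and
under-segmentation of weak bundles.  The quantitative reference points
(mean sizes 133/135/167 and 57/63/68 units² in the 64 × 64 box at
≥1000 time units) are kept machine-readable in
`experiments.FULL_SCALE_TARGETS` with a ±20% run-to-run spread and can
be recomputed with `evaluate_full_scale_target` (roughly 10⁶ Euler
steps for N = 16384 — hours per condition on one core).

## What the synthetic data does and does not emulate

The track generator produces smooth-turning OU walkers in the
wild-type parameter regime — it emulates centroid statistics, not worm
bodies: no undulation (the real tracks' short-wavelength oscillation),
no tracking noise, no missing frames.  Estimator tests on it therefore
validate the estimation mathematics, not robustness to segmentation
artefacts.  Line-network images are exact rectangular lattices — they
pin the compartment-counting contract, not the look of real bundle
networks.  Collision scenes use the model itself, so the nematic
outcome test is a property of the model's interaction terms, not an
independent replication of animal behaviour.

## Known limitations

* Point particles: no body shape, undulation, or head/tail asymmetry;
  spurious small compartments inside bundles are an artefact handled by
  the 30-unit² cutoff.
* The humidity → k_a mapping is not modelled; k_a is an abstract
  control, and the real network's humidity dependence is known to be
  steeper than the model's k_a dependence.
* τ from short stationary tracks is unidentifiable by the drift fit
  (see above); the σ_ω estimate carries a small (~5%) downward bias
  from the same source.
* Desk-scale compartment statistics rest on few compartments per frame
  and correlated analysis frames; only ordinal comparisons are robust
  there, and even those only between well-separated conditions — the
  two weakest-attraction conditions differ by ~1% in truth at full
  scale, below the desk-scale sampling resolution (~8% s.e.), so their
  sample means can come out in either order.
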