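# Methods

## The stochastic model

Transcription elongation is simulated as an event-driven kinetic Monte
Carlo process on a 1-D nucleotide lattice (default 5450 nt, the length of an
*rrn* operon). Each RNA polymerase (RNAP) is a hard particle with a 35-nt
footprint addressed by its furthest-downstream nucleotide; inside the
footprint a 17-nt transcription bubble is anchored against twisting, with 9
twistable nucleotides on either flank. Initiation fires at rate `α·β` (the
attempt is discarded when the first lattice site is covered; the polymerase
enters one nucleotide at a time with its body trailing off-lattice), hops
advance one nucleotide with exponentially distributed waiting times, and a
polymerase that reaches the last site leaves as a unit at rate `γ·β`.

Every hop twists the two DNA segments flanking the mover. The torque stored
in a segment shortened from its initiation-time (relaxed) length `L0` to
`L`, both measured bubble-to-bubble in nucleotides, is
`τ(L) = A·ln(L0/L)` with `A = μπ²r⁴/pitch`. With the standard DNA elastic
constants (Young's modulus 300 pN/nm², bending/twisting moduli 230/460
pN·nm², hence Poisson ratio −0.5 and shear modulus 300 pN/nm², rod radius
1 nm) and the 10.5-bp pitch expressed in nanometers (10.5 × 0.34 nm),
`A ≈ 829.4 pN·nm`. The alternative convention that leaves the pitch in base
pairs (`A ≈ 282.0`) is available as `length_convention="bp"`; the
nanometer convention is the default because it reproduces both the observed
pause counts (~2170 per transcript at the highest initiation rate) and the
shape of the computed-torque histogram (heavy mass at the two clamp values),
where the bp convention underproduces both.

The net torque on polymerase *i* is `τᵢ = τ(Lᵢ) − τ(Lᵢ₊₁)` (an absent
neighbor contributes zero) and is clamped to `[−10, +10] pN·nm` before any
response lookup: −10 pN·nm is the DNA melting torque and +10 sits just
below the ~11 pN·nm stall torque and below the vertical asymptote
(~10.42 pN·nm) of the pause-duration fit, keeping all responses finite.
Clamping each *segment* torque before combining is available
(`clamp_segments=True`) but off by default: it funnels ~55% of computed
net torques into the zero bin, whereas the observed distribution at high
initiation rates concentrates ~60% of values at the two extremes with only
~10% near zero, which the net-only clamp reproduces.

## Torque responses

Three fitted response curves drive the dynamics. The nonlinear family uses
a fifth-order polynomial for velocity `V(τ)` (anchored at 45 nt/s at the
melting torque and ~0 at stall), a piecewise quadratic for the per-step
pause probability `F(τ)` (reaching 1 at stall), and a tangent curve for the
pause duration `D(τ)` that diverges toward stall. At the melting anchor the
duration is an *imposed* zero: a pause whose recalculated duration reaches
zero releases immediately. This anchor matters enormously (see below). A
two-segment piecewise-linear family (knot at 5 pN·nm, duration floored near
0.29 s), two hybrids that splice the nonlinear duration into the linear
family on one side of the knot, and a stall family in which `F(11)` is an
adjustable `f_stall ∈ (0, 1]` complete the variants. The stall family's
upper branch is the unique quadratic matching the lower branch's value and
slope at 7.5 pN·nm and passing through `(11, f_stall)`. Velocities (only)
are scaled by `K = β/V(0) ≈ 4.0255` so that a torque-free polymerase moves
at the *rrn* elongation rate `β = 90 nt/s`; pause durations are used as
measured. The `tasep_constant` variant freezes all three responses at their
zero-torque values, giving a constant-rate TASEP with pauses for controlled
comparison.

## Event semantics

After every hop the mover's two segment torques are recomputed, its clamped
net torque mapped to `K·V(τ)` and `F(τ)`, and a uniform draw decides pause
entry; a paused polymerase's exit clock runs at `1/D(τ)`. The pause roll
happens after *every* hop, including one landing in contact with the
leader. This ordering is forced by the constant-rate control: pauses per
transcript stay flat at `~5448·F(0) ≈ 70` across the whole initiation-rate
grid even though collisions grow six-hundred-fold, which cannot happen if
blocked landings skipped the roll. Consequently a polymerase can be blocked
and paused at once; both intervals end at its next translocation.

A hop landing in contact (front-to-front distance equal to one footprint)
opens a collision: the velocity is set to zero and no waiting time is drawn
until the leader moves. The collision ends when the *trailer* translocates,
not when the site is vacated. After any hop the two flanking neighbors get
fresh waiting-time draws at their updated rates — a memoryless restart,
statistically equivalent to rate modulation for exponential clocks — but no
new pause-entry roll. This is how cooperation works mechanically: a trailer
closing in on a paused leader raises the assisting torque, shortens the
leader's recalculated duration (monotonically — torque can only fall while
a polymerase is paused), and at the melting clamp releases it instantly.

The zero-duration release is implemented as an effectively immediate
translocation (exit rate 10⁹/s). The alternative reading — close the pause
and resume at `K·V(τ)` — was evaluated and rejected: it delays the
release kick to the neighbors and measurably degrades the cooperative
(fluid) traffic state. Without the zero anchor altogether (using the raw
tangent value of ~6.7 ms at −10 pN·nm) the dense regime collapses into
jams with mean transcription times of 150–200 s instead of ~100 s; the
imposed zero is the single strongest lever in the model.

## Statistics and censoring

Analyses use right-censoring: only polymerases that both initiate and
terminate within the simulated horizon contribute, and recorded
pause/collision intervals must start before the final recorded termination.
Per-RNAP means divide pooled event totals by the number of censored
polymerases; duration means are event-weighted; replicates are pooled at
the polymerase level before ratios are formed, so the identity
`total_delay = pauses/RNAP × pause_duration + collisions/RNAP ×
collision_duration` is exact on every summary row. Dispersion uses the
unbiased (n−1) variance; coverage is the time-averaged fraction of lattice
sites under footprints over the full horizon, counting the brief entry
phase at full footprint size. The collisions-versus-α fit is zero-intercept
least squares, `slope = Σαy / Σα²`. Computed-torque histograms use
unit-wide `(k−1, k]` bins with dedicated bars for the exactly-clamped
values and an open `(9, 10)` bin.

## Problem sizes

The original design is 11 initiation scalars × 50 replicates × 10,000
simulated seconds × 4 model variants; the sweep runner (`SweepSpec`
defaults) is configured for exactly that. Tests and the acceptance script
use 3–5 replicates × 2,000 s at the top initiation scalar: the strand fills
and reaches its traffic steady state within the first ~300 s, and pooling a
few thousand censored transcripts gives percent-level standard errors for
the constant-rate model. The torque-coupled model at high density switches
intermittently between a fluid, cooperative state and transient jams, so
its per-realization summaries scatter widely (single-replicate mean times
ranged from ~79 s to ~220 s in 1,000-s runs); it is therefore pooled over
more replicates (8) than the control (3), and its estimates remain
noticeably noisier than the control's.

## Known limitations

* With the documented semantics the torque-coupled model reproduces
  published pause counts (within ~4%), coverage, the torque-value
  distribution and the transcription-time scale (within ~20%), but realizes
  mean pause durations of ~0.035 s versus the reported 0.02 s and roughly
  four times the reported collisions per transcript (~230 vs ~53).
* The constant-rate control matches published transcription times, pause
  statistics, collision counts and coverage to a few percent, but its
  realized collision durations run ~14% long (0.118 s vs 0.104 s), and the
  total-delay column inherits that bias. The collision interval here opens
  at the hop that lands in contact; opening it at the first blocked attempt
  instead would shorten durations but also drop short contacts from the
  count, and the convention used in the original analysis is not stated. The
  excess comes from transient jam episodes seeded by tightly spaced pairs —
  a polymerase that initiates close behind its leader records a small
  relaxed spacing and then resists the leader's advance. The alternative
  entry conventions examined (requiring a full footprint of free sites;
  measuring the relaxed spacing only after full entry) remove or worsen
  different discrepancies while breaking the constant-rate control's exact
  agreement, and were rejected.
* Supercoils interact only between nearest neighbors; no writhe,
  plectonemes, sequence-dependent elasticity or torque diffusion beyond the
  two flanking segments, and no RNAP mass or rotation dynamics.
* Ubiquitous pauses only: pause entry is position-independent; backtracking
  and hairpin pauses are out of scope.
* The synthetic scenarios produced by `make_fixture` are tiny, seeded runs
  selected to exhibit one mechanism each (a lone runner, a collision, a
  pushed pause); they exercise bookkeeping, not biology, and passing them
  says nothing about real traffic statistics.
* The mean-field relation takes its sensitivity constant `C` as user input;
  the reduction fixes it only up to the choice of linearized velocity
  response.
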