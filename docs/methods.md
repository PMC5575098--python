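# Methods

This note records the models implemented in `dnacyclize`, the defaults and
units of every parameter that matters, the numerical choices made where the
underlying literature leaves the construction open, and the limits of what
the synthetic test material can demonstrate.

## 1. The two coupled models

### 1.1 Breathing lattice (per-base-pair opening probabilities)

DNA "breathing" — transient, thermally driven local strand separation — is
modelled with a quasi-two-dimensional nonlinear lattice of the
Peyrard–Bishop–Dauxois family, extended with strand- and
dinucleotide-resolved stacking.  Base pair *n* carries two transverse
displacements u_n (right strand) and v_n (left strand), in Å.  The potential
is

    V = Σ_n  U(u_n, v_n) + W(u_{n-1}, u_n; v_{n-1}, v_n)

    U = D_n (exp(-a_n (u_n - v_n)) - 1)²
    W = K_u/2 (u_n - u_{n-1})² + K_v/2 (v_n - v_{n-1})²
        + ρ/4 · exp(-β[(u_n - v_n) + (u_{n-1} - v_{n-1})])
          · (√K_u (u_n - u_{n-1}) - √K_v (v_n - v_{n-1}))²

The Morse term U represents hydrogen bonding plus backbone electrostatics;
D and a come in two classes (A:T with two hydrogen bonds, G:C with three).
The anharmonic factor in W softens stacking when either neighbour leaves the
stack, which is the entropic mechanism that sharpens melting.  The lattice is
periodic (site 1 stacks on site N), matching the ring topology of the chain
model.

Defaults (`EPBDParameters`): D_AT = 0.05 eV, D_GC = 0.075 eV, a_AT = 4.2 Å⁻¹,
a_GC = 6.9 Å⁻¹, ρ = 2, β = 0.35 Å⁻¹ — the classic lattice-melting parameter
set — with a *uniform* dinucleotide stacking table K = 0.025 eV/Å².  The
code carries the full 16-entry per-strand table (the left strand is looked
up through the complementary dinucleotide read antiparallel), so a
sequence-dependent set fitted to melting data can be dropped in via YAML
without code changes.  We deliberately ship the uniform table rather than
invent sequence-dependent numbers.

Sampling (`MCMCSettings`, `sample_opening_profile`): single-site Metropolis
with a symmetric uniform displacement proposal.  One sweep is N proposals on
the u strand then N on the v strand.  A base pair counts as *open* when its
stretch y_n = u_n − v_n exceeds 2.5 Å (the local-melting criterion, applied
to the Morse argument y rather than to either strand separately, because y
is the coordinate the pair potential is written in); p_n is the fraction of
sampled states with y_n above threshold.  Numerical choices:

- **Proposal half-width 0.3 Å** (default).  The closed-state well is stiff
  (σ_y ≈ 0.12 Å at 300 K), so widths much below ~0.2 Å accept nearly every
  move and diffuse slowly; 0.3 Å keeps acceptance roughly in the 0.3–0.8
  band across sequences and temperatures, and the sampler logs a warning
  when the realized rate leaves [0.2, 0.6].
- **Stretch cap y_max = 50 Å.**  The dissociated Morse plateau is flat and
  non-normalizable; proposals taking y beyond the cap are rejected (an
  infinite-wall boundary, which preserves detailed balance).  The cap is a
  genuine model parameter: it sets the configurational volume — hence the
  entropy — of the open state, and with it the absolute scale of the opening
  probabilities.  Oracle tests that compare the sampler against quadrature
  use a matching domain.
- **Zero-mode re-centring.**  V is blind to a rigid common shift of both
  strands; after every sweep the mean of (u+v)/2 is subtracted from both
  strands (a gauge transformation that changes no stretch) so the state
  cannot drift to large absolute values.
- A **mismatched base pair** (e.g. C:C) is permanently open: its profile
  entry is forced to exactly 1 after sampling.

### 1.2 Rigid base-pair chain (closure statistics)

A configuration is an ordered list of base-pair frames (origin + orthonormal
right-handed triad; the third axis is the base-pair normal).  Consecutive
frames differ by six step parameters (tilt, roll, twist in degrees; shift,
slide, rise in Å).  Equilibrium values Θ⁰ come from a 64-entry trinucleotide
table — they encode intrinsic curvature — and thermal fluctuations are
Gaussian in the three *angles only*, with state-dependent RMS widths:

| state          | tilt, roll RMS | twist RMS | persistence length |
|----------------|---------------|-----------|--------------------|
| duplex         | 4.84°         | 4.09°     | ≈ 140–147 bp       |
| single strand  | 30.08°        | 27.96°    | ≈ 3.5 bp           |

The general elastic description is a quadratic form in the six step
deviations; after diagonalization it is a product of independent normal
modes.  The implementation realizes the special case actually used — a
diagonal angular covariance with the RMS values above — and accepts an
optional full 3×3 angular covariance on the slow (non-kernel) sampling path
for forward compatibility.  Shift/slide/rise are held at their equilibrium
values; the stated flexibilities describe bending and twisting only, and
isotropic bending (equal tilt/roll RMS) makes the duplex persistence length
L_p = 2/(σ_tilt² + σ_roll²) ≈ 140 bp in the small-angle limit.  The widths
were historically chosen for 147 bp; the ~5 % gap between 2/(2σ²) and 147 bp
is inherited from that convention and both values are checked in the tests
(3 % against the closed form, 10 % against 147 bp).

**Frame composition** uses the symmetric mid-step construction: with bend
magnitude Γ = hypot(tilt, roll) and bend phase φ = atan2(tilt, roll),

    R_step = R_z(Ω/2 − φ) · R_y(Γ) · R_z(Ω/2 + φ)

and the displacement is applied in the half-rotated mid-step frame
R_z(Ω/2 − φ)·R_y(Γ/2)·R_z(φ).  Pure twist rotates about the base-pair
normal; tilt and roll act about the mid-frame x/y axes; the construction is
invariant under strand relabelling.  The running triad is projected back to
the nearest orthonormal matrix (modified Gram–Schmidt) every 64
compositions, which keeps orthonormality drift below 1e-8 over 10⁴ steps.

**Ring topology.**  A sequence of N base pairs is periodically extended by
copying base pairs 1–2 to the end; the ring then has N steps and every step
has a full trinucleotide context (base_{c−1}, base_c, base_{c+1}) for its
central base pair c, taken cyclically.  Closure observables compare frame 1
with frame N+1 (the periodic image of base pair 1).

### 1.3 Coupling: hinges

For every generated chain, one uniform number per base pair is compared with
the opening profile: mask_n = (U_n ≤ p_n).  An open base pair makes *the
step entering it* adopt the single-strand widths (the minimal per-step
attribution of a per-base-pair state; the alternative "either flank open"
rule can be built from the same mask).  The mask is redrawn per chain, so a
p = 1 site (mismatch) is single-stranded in every chain and p = 0 never is.
With a zero profile the coupled model reduces *bit-for-bit* to the pure
chain model: hinge uniforms are consumed unconditionally, so the random
streams are identical.

## 2. J-factor estimator

    J = (4π/N_A) · W(r≈0) · Γ_r(cos γ≈1) · Φ_{r,cos γ}(φ≈0)

estimated with nested gates r < 30 Å, cos γ > 0.86, cos φ > 0.86 (defaults):

    Ŵ = (n_r/n_total) / V_c,  V_c = 4/3 π r_c³ (converted to liters, 1e-27 L/Å³)
    Γ̂ = (n_γ/n_r) / (1 − c_γ)                    [per unit cos γ]
    Φ̂ = (n_φ/n_γ) / (2 arccos c_φ)               [per radian]

cos γ is the dot product of the first and last base-pair normals; cos φ
compares the first frame's in-plane x axis with the last frame's x axis
projected onto the first base-pair plane (torsional register; a degenerate
projection is scored −1 and can never pass).  The normalizations are fixed
by two independent anchors: an ideal chain (uniform orientations and
register) collapses J to the classic Jacobson–Stockmayer W(0)/N_A, and the
torsion-relaxed density (2/N_A)·Ŵ·Γ̂ reproduces the Shimada–Yamakawa
worm-like-chain closed form

    J_SY = 896.32/(4π ν⁵) · exp(−14.054/ν + 0.246 ν) / (N_A l_p³),   ν = L/l_p

within 15 % at 500 bp in our simulations (the test allows a factor of two;
the transcription of the closed form, whose published variants differ by
factors of 4π, was itself pinned against an independent discrete worm-like
chain simulation before being frozen).

Uncertainty: the three conditional pass fractions are treated as independent
binomials and combined in quadrature on log J; zero fully-closed chains give
J = 0 with an `insufficient_sampling` flag.  Counting is streamed in chunks
(O(1) memory in n_chains); chunk k draws from the substream keyed
(seed, spawn_key=k), so partitioning chains across workers at chunk
granularity and summing counts reproduces a single run exactly, independent
of execution order.

Diagnostic only: `free_energy_equivalent` reports −ln p_n per site (in k_BT)
and its finite-entry mean.  It is a descriptive reading of a profile, not an
input to any computation.

## 3. Benchmark statistics

For records with experimental J-factors, the headline curve is the fraction
of sequences with |log10(J_calc/J_exp)| ≤ k, over a k grid, for each model
(pure chain vs coupled) and three strata: all, shorter than 100 bp, and
100 bp or longer (exactly 100 bp is long).  Records lacking a positive
experimental J are skipped with a warning; strata recombine to the pooled
fraction weighted by stratum size (tested).

## 4. Synthetic data

The generators in `dnacyclize.synthetic` stand in for externally measured
inputs and are labelled as such:

- `random_sequence(length, gc)` — i.i.d. bases at a target GC content.
- `straight_step_table()` — intrinsically straight B-DNA (twist 34.3°, rise
  3.4 Å); `toy_step_table(seed)` — trinucleotide tables with ~2° intrinsic
  tilt/roll jitter; `circle_step_table(n)` — a planar-circle fixture.
- `synthetic_profile` — log-uniform baseline opening probabilities in
  [1e-5, 1e-3] with AT-tract hotspots up to ~1e-2 (AT-rich windows of ≥80 %
  A/T over 5 bp), mismatches at probability one.
- `make_synthetic_panel` — sequences of 50–325 bp at GC 0.3–0.7 with toy
  "experimental" J-factors: the coupled-model prediction perturbed by
  lognormal noise (default 0.5 decades).  Direct simulation of duplex
  closure at 50–100 bp is a rare event (closure probabilities below ~1e-9,
  i.e. ≥1e9 chains per sequence for O(1) closed counts), so the default
  toy-J source is the worm-like-chain closed form evaluated at a
  *hinge-diluted effective persistence length*: per-step decay factors
  λ = E[cos Γ] of the duplex and single-strand states (computed by
  Gauss–Hermite quadrature) are mixed with the per-site opening
  probabilities and L_p,eff = −1/mean(ln λ_n).  A `simulation` source that
  runs the full Monte Carlo per sequence is available for lengths where
  counts exist.

What passing tests on this material do and do not show: they validate the
estimator algebra, the coupling mechanics, the geometry kernels and the
benchmark plumbing on data with *known* structure; they do not validate
sequence-specific predictions against laboratory measurements, which require
an externally supplied panel (experimental J-factors, a fitted trinucleotide
table, and opening profiles computed with melting-calibrated stacking
parameters).  In particular the synthetic profiles share only the coarse
statistics of lattice-model output (scale and AT-enrichment), not its
sequence detail, and the uniform stacking table makes breathing depend on
base composition but not on stacking context.

## 5. Problem sizes used by the shipped checks

Chosen to make every statistical assertion pass with ≥3σ margin at fixed
seeds: persistence length, 6 000 chains × 600 steps (acceptance script:
4 000 chains); two-site lattice oracle, 8 independent replicas of 170 000
sweeps against a 600×600×201-point quadrature; hinge-effect and
monotonicity checks, 10⁶ chains of an 84 bp ring; worm-like-chain
comparison, 2×10⁶ chains of a 500 bp ring with a widened 150 Å contact gate
(the density estimator divides the window out; the wider gate trades a
small, measured bias for ~3× more counts); benchmark noise check, 160-record
panel.

## 6. Known limitations

- Per-site opening probabilities are marginals; correlated multi-base-pair
  bubbles are not represented (an open site opens its step independently of
  its neighbours' states).
- The lattice sampler near and above melting mixes slowly across the
  dissociated plateau; opening probabilities there depend on y_max and on
  schedule length.  The shipped defaults target the breathing regime well
  below melting.
- No excluded volume, electrostatics, or linking-number bookkeeping; closure
  is scored purely through (r, cos γ, cos φ).
- The uniform default stacking table makes lattice output less
  sequence-specific than a melting-calibrated table would be; supply one via
  YAML for production use.
- Sub-persistence-length closure without hinges is a rare event by physics,
  not by implementation: direct sampling at such lengths needs ≥1e9 chains
  per sequence.
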