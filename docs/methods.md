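# Methods

This note documents the model, the numerical choices and the known
limitations of `neurice`, in the order a reader would meet them: the
effective cable model, the closed-form and spectral voltage statistics,
Rice's upcrossing rate, the stochastic lattice simulator, and what the
test suite's synthetic conditions do and do not establish.

## Effective model and parametrization

The membrane voltage v(x, t) of each synaptically driven dendrite
(measured in mV above the leak reversal E_L) obeys

    τ_v ∂v/∂t = μ − v + λ² ∂²v/∂x² + s(x, t)
    τ_s ∂s/∂t = −s + 2σ_s √(λ τ_s) ξ(x, t)

where ξ is zero-mean spatio-temporal Gaussian white noise,
⟨ξ(x,t)ξ(x′,t′)⟩ = δ(x−x′)δ(t−t′).  The drive s is temporally filtered
(Ornstein–Uhlenbeck in time) but spatially white; σ_s is treated as
uniform along the dendrite, which is accurate when the synaptic
reversal (≈ 0 mV) is far from rest (≈ −65 mV).  The analytic pipeline is
parametrized directly by the effective quantities — no absolute
conductances or radii ever enter; only the combinations below do:

| parameter | units | default | meaning |
|---|---|---|---|
| μ | mV | 4–12 | effective resting potential above leak |
| σ_s | mV | 1–3 | synaptic noise amplitude |
| τ_s | ms | 5 | synaptic filter time constant |
| τ_1 | ms | 10 | dendritic membrane time constant under load |
| λ_1 | μm | 200 | dendritic electrotonic length under load |
| ε | – | derived | (E_L−E_s)/(E_L+μ−E_s) = total/leak conductance |
| τ_α, τ_0 | ms | ετ_1 | passive axonal/somatic time constant |
| a_α/a_1 | – | 0–1 | axon/dendrite radius ratio |
| λ_α | μm | λ_1√(ε·a_α/a_1) | axonal length constant |
| ρ_1 | – | 1–16 | dendritic dominance factor G_λ1/G_0 |
| ρ_α | – | ρ_1 λ_α³/(λ_1³ε²) | axonal dominance factor |
| v_th, v_re | mV | 10, 0 | threshold and reset |
| x_th | μm | 0 or 30 | trigger position (junction or axon initial segment) |

The dendrite carries the mean synaptic conductance, so its conductance
per area relative to leak is ε while axon and soma are passive (ratio
1); this single convention fixes τ_α = ετ_1, the λ_α(a_α/a_1) map and
the ρ_α(ρ_1) map, and makes the caption-level derived values
self-consistent (τ_α = 10.8/11.3/12.1 ms at μ = 5/8/12 mV; holding λ_1
fixed while μ varies requires a_1 ∝ g_1(μ), a 5% radius adjustment
between μ = 8 and 11 mV).  Keeping τ_v and λ fixed across the μ range
isolates the dependence of the rate on the mean drive alone.

Validation is strict-fail: out-of-range parameters raise instead of
being clamped, so sweeps cannot silently drift out of the model's
domain.  A helper maps microscopic synaptic parameters (per-event
conductance γ_s, areal density ϱ_s, rate r_s) to (μ, σ_s); the noise
prefactor is taken as γ_s(E_s−⟨V⟩)/(2g)·√(ϱ_s r_s τ_s/(2πaλ)), the
reading consistent with the Gaussian approximation of Poisson shot
noise, and nothing else depends on it.

## Closed-form statistics (sealed cable)

For a cable of length L sealed at both ends, the stationary variance and
rate-of-change variance follow from the boundary kernel

    C(x, η) = cosh((L−x)√η/λ) cosh(x√η/λ) / (√η sinh(L√η/λ))

as σ_v²(x) = 2σ_s²(τ_s/τ_v)[C(x,1) − C(x,κ)] and
σ_v̇²(x) = (2σ_s²/(τ_vτ_s)) C(x,κ), with κ = 1 + τ_v/τ_s stored once at
construction.  C is evaluated in log space (exponential-difference
forms, with the large arguments cancelling analytically), so profiles
remain finite and symmetric for L√η/λ up to 10⁴ and beyond.  In the
semi-infinite limit C(0,η) → 1/√η and C(L/2,η) → 1/(2√η), giving the
sealed-end (one-dendrite) and bulk (two-dendrite) statistics quoted in
the README; the two-dendrite variances are exactly half the one-dendrite
ones, and neither depends on λ.

## Spectral statistics (composite morphologies)

With an axon, several dendrites, or a lumped soma, the statistics at the
trigger are integrals of the voltage PSD,

    σ_v² = (1/π)∫₀^∞ S dω,   σ_v̇² = (1/π)∫₀^∞ ω²S dω,

with the composition

    S(ω; x_th) = n |f̃(ω)|² exp(−2 x_th Re γ_α(ω)/λ_α) · S_end(ω),
    S_end(ω) = 2σ_s²τ_s / [(1+ω²τ_s²) √(1+ω²τ_v²) Re γ_v(ω)],

derived from the junction Green's function: each of the n independent
dendrites feeds the junction through its relative input admittance f̃,
and the attenuation along the undriven axon is the two-sided
|e^{−γ_α x/λ_α}|².  The admittance factors use per-neurite weights
G_λ ∝ g²λ³ (radius tied to conductance at fixed per-area parameters):

    no soma:   f̃_n(ω) = W₁γ₁ / (n W₁γ₁ + W_αγ_α)
    with soma: f̃_n0(ω) = ρ₁γ₁ / (γ₀² + n ρ₁γ₁ + ρ_αγ_α),  γ₀² = 1+iωτ₀

with γ_j(ω) = √(1+iωτ_j) on the principal branch (the square root is
required for a semi-infinite cable's input admittance; the DC limits are
unaffected).  The mean transfers as ⟨v⟩ = nμ f̃(0) e^{−x_th/λ_α}.
Correctness of the composition is enforced by limit checks (vanishing
axon → sealed-end closed form; identical twin neurite → one half; soma
dominance ρ₁ → ∞ → nominal junction) and by the stochastic simulator.

Quadrature: Gauss–Legendre panels (24 geometric panels, 48 nodes each)
from ω ≈ 10⁻⁵ to 10⁴ rad/ms, plus a tail panel under the substitution
u = ω^{−1/2}, which maps the slowly decaying ω²S ∼ ω^{−3/2} tail onto a
finite interval where the transformed integrand is smooth — the tail is
integrated, not truncated, because truncating it biases σ_v̇ and hence
every Rice rate.  Each evaluation is repeated on a 1.5× refined grid;
a relative disagreement above 10⁻⁸ raises a convergence error instead
of returning a silently degraded value.

## Rates

Rice's formula r_uc = (σ_v̇/2πσ_v) exp(−(v_th−⟨v⟩)²/2σ_v²) is computed
in kHz (all internal times are ms) and converted to Hz at one site.
`model_rate` routes bare junction-triggered morphologies to the closed
forms and everything else to the spectral engine, recording which path
was used.  Calibration of σ_s to a target rate uses Brent's method on a
geometrically expanded bracket (default [0.1, 10] mV — the rate is
monotone in σ_s below threshold, so the root is unique).  Peak finding
over the radius ratio scans a fixed 50-point grid with a local quadratic
refinement of the argmax; derivative-based optimization is avoided
because the rate surface is flat near the peak and evaluations are
cheap.  The optimal dendrite count n_max is an integer argmax with ties
broken toward smaller n.

## Stochastic lattice simulator

The simulator discretizes every neurite with v and s at half-integer
nodes (k+½)Δx and ∂v/∂x at integer nodes, stepping explicitly:

    v ← v + (Δt/τ_v)[μ − v + (λ²/Δx)(∂xv_{k+1} − ∂xv_k) + s]
    ∂xv ← forward difference of the updated v
    s ← s + (Δt/τ_s)[−s + 2σ_s√(λτ_s/(ΔxΔt)) ψ]

with one independent standard normal ψ per driven site and step.
Defaults Δx = 20 μm and Δt = 0.02 ms satisfy the explicit-scheme bound
(Δt/τ)(1+4λ²/Δx²) < 2, which is checked at build time together with the
corresponding somatic bound; semi-infinite neurites are truncated at
L = max(1000 μm, 10λ) with sealed far ends.  Sealed ends impose a zero
derivative node.  Neurites joined at a nominal soma share one junction
voltage — the G_λλ-weighted average that zeroes the net flux, which for
two identical dendrites reproduces the continuous lattice exactly.  A
lumped soma advances τ_0 dv_0/dt = −v_0 + Σ ρ_kλ_k ∂v_k/∂x by the same
explicit step, with neurite-end derivatives taken against v_0
(continuity).  When the monitored voltage reaches v_th the entire
voltage field (soma included) is reset to v_re; the synaptic field is
untouched.  In no-reset mode positive-going crossings are counted
instead, the direct Monte-Carlo estimate of the upcrossing rate.

Conventions and estimators:

- x_th = 0 monitors the junction voltage when a junction exists,
  otherwise the first voltage node (x = Δx/2) of the sealed cable; any
  other x_th must coincide with a voltage node or building the lattice
  fails.
- The noise stream is a single seeded generator consumed in a fixed
  (step, site) order in vectorized chunks, so runs are bit-reproducible;
  the compiled (numba) kernel and the numpy reference path produce
  identical trajectories.
- The default discarded transient is 10× the largest time constant;
  rates carry a Poisson standard error, and the voltage moments carry
  batch-means standard errors over 20 subdivisions of the run.
- σ_v̇ is estimated by forward differences of the stored trigger
  voltage; this is biased at O(Δt) and is used only for cross-checking
  the analytic σ_v̇, never inside the analytic pipeline.

## Synthetic conditions: what the tests show

There is no external data; the simulator *is* the synthetic data
generator, and its defaults are the study conditions (Δx = 20 μm,
Δt = 0.02 ms, L ≥ 1000 μm, drive in the μ = 4–12 mV, σ_s = 1–3 mV
range).  It emulates a passive neuron under stationary, spatially
homogeneous, Gaussian synaptic bombardment.  It does not emulate
conductance (multiplicative) synapses, non-Poissonian or spatially
correlated input, active membranes, back-propagating spikes or a
refractory period — so passing tests establish the internal consistency
of the analytic machinery and its Monte-Carlo ground truth under the
model's own assumptions, not fidelity to any recorded neuron.

Monte-Carlo problem sizes in the test suite are deliberate: sealed-end
variance uses 10 × 20 s runs (≈ 3% standard error on the variance);
crossing-rate checks use 4 × 60 s; the reset-rate comparison uses
100–300 s per drive point, sized for ≳ 100 expected spikes.  Tolerances
on stochastic comparisons are 3 standard errors, with a 2% allowance
where the O(Δx) junction discretization is known to bias the variance.

## Known limitations

- **Upcrossing vs reset rate.**  The upcrossing rate counts every
  positive-going crossing, and crossings of a smooth (C¹) Gaussian
  process cluster: after a first passage the voltage hovers near
  threshold and may recross several times, whereas the reset process
  fires once per cluster.  The ratio r_uc/r_IF is therefore the mean
  cluster multiplicity, which decays with the reduced gap
  (v_th−⟨v⟩)/σ_v but not with the rate itself; at τ_s/τ_v = 0.5 the
  measured integrate-and-fire rate sits ≈ 20% below r_uc near 0.3 Hz and
  25–40% below in the 1–5 Hz band.  The approximation is best viewed on
  the logarithmic scale on which subthreshold rates vary over decades,
  and improves when spatial filtering separates drive from trigger
  (axonal trigger points).
- Trigger points at x > 0 on a *driven* dendrite are not implemented
  (the admittance composition assumes the trigger neurite is undriven
  beyond the junction).
- The junction discretization is O(Δx); with the default lattice the
  junction variance carries a ≈ 1–2% bias that halves with Δx.
- Rice's formula requires finite σ_v̇: temporally white drive
  (τ_s → 0) is outside the model class.
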