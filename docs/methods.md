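# Methods

## Spectral model

The incoherent dynamic structure factor is modelled per momentum
transfer Q as a sum of Lorentzian quasi-elastic components convolved
with the instrument resolution plus a flat background:

    S(Q,E) = [ Σ_α A_α L(Γ_α, E) ] ⊗ R(Q,E) + BG .

Assumptions baked into the model:

- **No separate elastic delta term.**  At finite resolution the
  narrowest Lorentzian plays the role of the quasi-elastic/elastic
  line; an explicit δ(E) would be degenerate with it.
- **Symmetric lineshapes.**  Detailed-balance asymmetry is neglected;
  both instrument windows used here are narrow relative to k_BT.
- **Three modes per hydrogen population.**  Headgroup: slow
  (membrane-scale fluctuation, Fickian), medium (whole-molecule
  fluctuation, jump-diffusion-like), fast (localized rotation of H
  around N/C, Q-independent).  Water: slow and medium-speed
  (translational, jump diffusion) and fast (rotational,
  Q-independent).  Model order is fixed; no automatic selection.

Internal energy unit is μeV everywhere (ħ = 6.582119569e-10 μeV·s is
the single conversion constant); meV appears only in I/O and prose.

## Channel binning and convolution

Measured spectra are *channel contents*, not point samples.  Evaluating
a Lorentzian pointwise on a grid coarser than its width aliases badly:
a Γ = 0.1 μeV line sampled at 4 μeV spacing carries a discrete mass of
≈ Δ/(πΓ) ≈ 13 instead of 1.  All forward evaluations therefore use the
exact bin average

    L̄(E) = [arctan((E+Δ/2)/Γ) − arctan((E−Δ/2)/Γ)] / (πΔ),

and parametric Gaussian kernels are binned with the error function.
This matters: the slow headgroup mode at low Q is orders of magnitude
narrower than either resolution.

Convolution is a direct sliding-dot Riemann sum restricted to the
instrument window (cost n_out × n_kernel, independent of padding), with
the model evaluated on a grid padded by five kernel supports so window
edges see the full Lorentzian tails.  Grids are small (≤ a few thousand
points), so FFT would buy nothing while complicating edge handling.
The discrete convolution reproduces the analytic Lorentzian width-sum
identity to better than 1e-6 when the kernel's own truncated area is
unity at that level; with practical kernel supports the agreement is
limited by the kernel-truncation fraction, not by the summation.

## The staged fitting protocol

Per-Q fits are independent weighted least squares (weights 1/σ²),
run with lmfit/Levenberg–Marquardt under seeded multi-start
(default 8 starts; width ladders log-spaced across the window and
jittered, amplitudes from an area heuristic, background from the outer
10% of the window).  Best χ² wins; ties break toward the smaller slow
width.  The width ordering Γ_slow < Γ_medium < Γ_fast is enforced
structurally: free widths of one mode family are chained as
Γ_k = Γ_{k−1} + δ_k with δ_k > 0 bounded.  The chain never crosses
families — water widths are ordered among themselves, not against the
fixed headgroup widths they overlay.

Stages:

1. **Headgroup, wide window** — three free Lorentzians + BG.
2. **Headgroup, narrow window** — slow mode + BG free; medium (A, Γ)
   fixed per Q from stage 1, bit-exactly.  The fast mode is omitted:
   inside ±30/60 μeV a ≈260 μeV Lorentzian is flat and lands in BG.
3. **Water, narrow window** — all six headgroup parameters fixed (slow
   from stage 2, medium/fast from stage 1); only the slow water mode
   and BG free.
4. **Water, wide window** — three water modes with Γ_slow HW fixed from
   stage 3, freed only at Q bins where stage 3 failed to converge.

Fixed parameters are carried as the identical floats, never re-rounded
(tested to bit exactness).  Amplitudes are stored in count·μeV units
(shape × channel width) so they transfer between grids of different
binning — required by the cross-resolution fixing contract.

### Uncertainties: covariance vs protocol bootstrap

Covariance-derived 1σ are well calibrated for identifiable parameters
(a 100-seed calibration test finds ≈68% nominal-1σ coverage).  They
fail in a specific, predictable place: at low Q both the slow and
medium widths fall below both resolutions, the stage-1 medium fix is
itself uncertain, and the stage-2 covariance cannot see that error.
The result is overconfident, biased low-Q Γ_slow values that drag the
weighted Fickian fit by tens of percent.

The remedy is a seeded parametric bootstrap of the *whole* two-stage
chain (`bootstrap_slow_profile`, default 16 replicates): replicate
spectra are drawn around the fitted models with the per-bin counting σ
and the complete protocol is replayed.  Degenerate bins then show
honestly large error bars, the standard relative-error screen
(σ(Γ)/Γ > 0.5 excluded) removes the worst of them, and the surviving
weighted origin-constrained fit recovers the generative D within a few
percent (typically 1–3% at the default study conditions).

### Known protocol limitation

Stage 3 omits the medium-speed and fast water modes (the narrow window
cannot resolve them).  Their residual curvature inside the window leaks
partly into Γ_slow HW, which is therefore biased high by ~10–40% at
low-to-mid Q even on synthetic data that satisfies every other model
assumption; at high Q the bias is within ~3σ.  This is a property of
the staged protocol itself, not of its implementation — the null case
(water amplitudes generated as zero) recovers water amplitudes
consistent with zero, and the wide-window fast-water width is recovered
within 3σ across essentially all Q.  Conclusions drawn from slow-HW
jump-diffusion parameters should keep this systematic in mind.

## Γ(Q²) models and derived quantities

- **Fick**: weighted linear fit of Γ = ħDQ² *through the origin*; an
  intercept variant exists only as a diagnostic and never feeds
  reported D.
- **Jump diffusion**: Γ = ħDQ²/(1 + DQ²τ₀) fitted in log-parameters
  (positivity by construction) with multi-start over τ₀ decades;
  nested-model check: at DQ²τ₀ ≪ 1 it agrees with the Fickian fit.
- **Localized modes**: unweighted mean/std of Γ in a Q² window (default
  fast-mode window 0.39–2.80 Å⁻²), with a flatness flag (weighted slope
  consistent with zero at 2σ).
- **Arrhenius**: unweighted regression of ln(value) on 1/T by default
  (a 1/σ² weighted option exists); Ea = +slope·R for residence times,
  −slope·R for diffusion coefficients.  Two-point fits require an
  explicit override.
- **Relaxation time**: τ = ħ/Γ, no h-vs-ħ or factor-2 variants.
- **Incoherent bookkeeping**: bound incoherent cross sections
  H 80.27, D 2.05, C 0.001, N 0.50, O 0.0008, P 0.005 barn (standard
  bound-atom tabulation, version-tagged because the derived shares
  depend on it).  d₅₄-DMPE (C33, 12 H, 54 D, N, O₈, P) + 10 D₂O puts
  86.4% of the total on the 12 headgroup hydrogens; with 10 H₂O the
  headgroup and water shares are ≈0.36 and ≈0.60.

## Elastic-scan analysis

Elastic intensity per temperature is the sum over Q bins in a band
(defaults 0.375–1.325 and 1.375–1.725 Å⁻¹, edges inclusive) of counts
with |E| ≤ half the nominal resolution width (the elastic window is not
an instrument constant here, so half-FWHM is the documented default).
The harmonic baseline is a straight-line fit of ln I vs T whose
residuals expose anharmonic onsets.

Transition detection is segmented log-linear regression: one or two cut
points chosen by exhaustive search (prefix-sum O(1) segment fits), each
segment with free slope *and intercept*.  Allowing the intercept jump is
deliberate: the physical signature is a drastic intensity *drop*, and a
continuity-constrained piecewise-linear fit systematically misplaces a
step (by ~20 K for a 40% drop on a 130 K window) because no continuous
two-segment line can follow it.  A pure slope kink is still located at
grid precision, detection is invariant under positive scaling of the
trace, significance is a fractional SSE-improvement threshold against
the no-break line (default 0.25), and cut 1σ comes from a seeded
residual bootstrap.

## Trajectory observables

- **MSD**: ⟨|r(t+τ)−r(t)|²⟩ over all time origins (stride configurable)
  and group atoms; log-spaced default lag grid; MSD(0) = 0 exactly.
  Wrapped coordinates require box metadata and are unwrapped by
  minimum-image accumulation; drift removal is an option, off by
  default.
- **Rotational correlation**: first-rank ⟨cos θ(τ)⟩ of named unit
  vectors (e.g. P→N), exactly 1 at τ = 0; for isotropic rotational
  diffusion it decays as exp(−2 D_r t).
- **Tail order**: S = ⟨(3cos²β − 1)/2⟩ against the bilayer normal.
  Default convention is successive-carbon C→C vectors, with a C–H
  (S_CD-style) option — both are standard, and the choice is labelled
  in the API rather than guessed.

## Synthetic-data generator

Every generator is a pure function of (parameters, seed), and the
ground truth is serialized (YAML) next to the data so downstream checks
read it rather than hard-code it.

Defaults define the emulated study: six temperatures (300, 313, 330,
343, 358, 368 K), 17 Q bins over 0.17–1.82 Å⁻¹, Gaussian kernels of
3.6 / 13 μeV FWHM (optionally ±5% Q-jittered to mimic measured
kernels), Poisson counting noise with σ = √counts (floor 1), wide-window
peak ≈10⁴ counts, and amplitude split 12 : 20 between headgroup and
water hydrogens per the per-lipid hydrogen inventory.  Mode truths
(reference temperature 358 K, Arrhenius-tied across temperature):

| mode | law | defaults | rationale |
|---|---|---|---|
| headgroup slow | Fick | D = 3.43e9 Å²/s, Ea 30 kJ/mol | liquid-crystalline-phase headgroup value |
| headgroup medium | jump | D = 5e10 Å²/s, τ₀ = 5 ps, Ea 20/10 kJ/mol | whole-molecule fluctuation, widths of a few tens of μeV |
| headgroup fast | constant | Γ = 260 μeV, Ea 5 kJ/mol | inside the observed 0.1–0.4 meV band; τ ≈ 2.5 ps |
| water slow | jump | D = 2.5e9 Å²/s, τ₀ = 60 ps, Ea(τ₀) 23 kJ/mol | loosely-bound-like water |
| water medium | jump | D = 8e10 Å²/s, τ₀ = 2 ps, Ea(τ₀) 4 kJ/mol | free-water-like; D within an order of bulk water, jump length √(6Dτ₀) ≈ 1 Å |
| water fast | constant | Γ = 300 μeV, Ea 3 kJ/mol | rotational water, τ ≈ 2 ps |

Elastic traces are log-linear baselines multiplied by sigmoidal drops
(default width 2 K) with multiplicative Gaussian noise.  Trajectories
are Brownian anchors (per-axis step variance 2·D_t·dt) plus rigid unit
vectors under isotropic rotational diffusion; rotational steps are
internally subdivided so the small-angle update stays unbiased (a
single kick of variance 2·D_r·dt under-rotates by O((D_r dt)²) —
without subdivision the recovered decay rate is ~15% low at
D_r·dt = 0.05).

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: asymmetric measured
resolution lineshapes (the Gaussian surrogate is a declared
simplification), detector-level effects (multiple scattering,
self-shielding, detailed balance), coherent contamination at high Q,
and any mismatch between the true dynamics and the 3+3 Lorentzian
family.  Parameter-recovery results bound the *statistical* performance
of the protocol under its own model class, not its systematic accuracy
on a real instrument.

## Problem sizes used in checks

The packaged end-to-end checks run the staged protocol on one
temperature (358 K, 17 Q bins, both resolution modes) with a
16-replicate protocol bootstrap, detect transitions over 20 noisy
traces, and use 60–100 seed repeats for fit-calibration statistics —
sizes chosen so the whole suite exercises every stage in a few minutes
while keeping Monte-Carlo assertions stable.

## Other numerical choices

- Multi-start count, seeds, thresholds and Q-band edges are exposed in
  `RunConfig` and serialized into every output directory.
- Fit non-convergence is a flagged result, never an exception;
  downstream profile assembly skips flagged bins.
- Q grids between paired spectra must match within 0.02 Å⁻¹.
- The DMPC comparison constants (D = 3.8e9 Å²/s at 316 K; Ea 19.0 and
  27.5 kJ/mol) are literature values stored in a versioned data file
  and are never recomputed.
- Instrument-window-to-timescale folklore (e.g. "13 μeV ↔ ~97 ps") does
  not follow from τ = ħ/ΔE under any single convention; no such
  conversion is implemented for windows, only the per-mode τ = ħ/Γ.
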