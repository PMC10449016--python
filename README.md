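# lipidqens

Quasi-elastic neutron scattering (QENS) analysis of phospholipid
**headgroup** and **hydration-water** dynamics in stacked bilayers, built
as a tested, reproducible pipeline with a synthetic-data generator that
carries known ground truth.

## Who this is for

Neutron-scattering practitioners who analyse backscattering /
time-of-flight QENS data on selectively deuterated membrane samples, and
anyone who wants to study how well the standard staged multi-Lorentzian
protocol recovers diffusion parameters under realistic counting noise.

The package models the experimental contrast of tail-deuterated
DMPE hydrated with either D₂O (headgroup signal only — the 12
headgroup/glycerol hydrogens carry ≈86% of the bound incoherent cross
section) or H₂O (headgroup + 20 water hydrogens per lipid), measured in
two resolution modes (3.6 and 13 μeV FWHM, windows −30…60 μeV and
−0.5…1.5 meV) over Q = 0.17–1.82 Å⁻¹ at 300–368 K.

## The model

Each spectrum is decomposed per Q into resolution-convolved Lorentzians
over a flat background,

    S(Q,E) = [ Σ_α A_α · L(Γ_α, E) ] ⊗ R(Q,E) + BG,
    L(Γ,E) = (1/π) · Γ / (E² + Γ²),

with three headgroup modes (slow / medium / fast) and, for the H₂O
sample, three additional water modes.  Fitting is *staged*: the wide
window fixes the medium mode for the narrow-window fit that resolves
Γ_slow; the headgroup parameters from the D₂O sample are then frozen in
the H₂O fits so only water parameters remain free.  Γ(Q²) profiles are
interpreted with

- Fick's law `Γ = ħ D Q²` (origin-constrained) for the headgroup slow mode,
- the jump-diffusion law `Γ = ħ D Q² / (1 + D Q² τ₀)` for translational
  water modes (plateau ħ/τ₀ at high Q),
- Q-independent averages (`τ = ħ/Γ`) for localized/rotational modes,
- Arrhenius fits of D(T) or τ₀(T) for activation energies.

Elastic-scan traces are analysed by segmented log-linear change-point
fitting (the main gel → liquid-crystalline transition sits near 325 K),
and trajectory observables (MSD, first-rank rotational correlation
⟨cos θ(t)⟩, acyl-tail order parameters) support the physical assignment
of the modes.

## Worked example

```python
import numpy as np
from lipidqens.synthetic import (default_ground_truth, default_q_grid,
                                 generate_qens_dataset, generate_resolution)
from lipidqens.fitting import (headgroup_protocol, bootstrap_slow_profile)
from lipidqens.modes import exclude_unreliable, fick_fit

truth = default_ground_truth(seed=1)          # slow-mode D = 3.43e9 Å²/s at 358 K
q = default_q_grid()                          # 17 bins, 0.17–1.82 Å⁻¹
res_hi = generate_resolution("high_intensity", q)
res_hr = generate_resolution("high_resolution", q)
data = generate_qens_dataset(truth, design=[
    ("headgroup_only", "high_intensity", 358.0),
    ("headgroup_only", "high_resolution", 358.0)], q_values=q)
hi = data[("headgroup_only", "high_intensity", 358.0)]
hr = data[("headgroup_only", "high_resolution", 358.0)]

base = headgroup_protocol(hi, hr, res_hi, res_hr, seed=7, n_starts=8)
prof = bootstrap_slow_profile(hi, hr, res_hi, res_hr, base,
                              n_bootstrap=16, seed=11, n_starts=4)
fit = fick_fit(exclude_unreliable(prof, 0.5))
print(f"D_slow = {fit.D:.3e} ± {fit.D_sigma:.1e} Å²/s")
```

prints (seeds as above)

```
D_slow = 3.469e+09 ± 2.9e+07 Å²/s
```

i.e. the staged protocol recovers the generative slow-mode diffusion
coefficient (3.43 × 10⁹ Å² s⁻¹) within ~1% on this realization.  A full
multi-stage run (elastic scan → headgroup → water → Γ(Q²) models →
Arrhenius → comparison table) is available through
`lipidqens run --seed 5 --outdir out/` or
`lipidqens.pipeline.run_full_analysis`; the other CLI subcommands
(`simulate`, `fit-headgroup`, `fit-water`, `profiles`, `arrhenius`,
`elastic`, `mdanalyze`) wrap one module each.

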