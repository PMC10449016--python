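# Literature comparison constants for DMPC bilayer hydration water.
# These are published reference values used only for side-by-side
# comparison tables; they are never recomputed by this package.
version: 1
headgroup_slow_mode:
  D: 3.8e+09          # Å² s⁻¹, protiated DMPC-35D2O at 316 K (liquid crystalline)
  temperature: 316.0  # K
hydration_water_activation_energies:
  free_HW:
    Ea: 19.0          # kJ mol⁻¹, mean residence time, free HW between DMPC bilayers
    Ea_sigma: 2.5
  loosely_bound_HW:
    Ea: 27.5          # kJ mol⁻¹, loosely bound HW between DMPC bilayers
    Ea_sigma: 3.2
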