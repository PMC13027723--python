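"""Time-resolved flickering: per-cell viscoelastic descriptors.

Simulates a cell's fluctuation field (64 angle series of stationary
Ornstein-Uhlenbeck dynamics, 6000 frames at 2000 fps) with known stiffness
and friction, then recovers the effective rigidity, Einstein diffusivity,
friction and relaxation frequency from the field alone.
"""

from flickerscope import (OuSpec, ThermalContext, cell_summary,
                          generate_angle_dynamics)

thermal = ThermalContext()
spec = OuSpec(n_angles=64, n_frames=6000, fps=2000,
              stiffness_true=3e-6, friction_true=1e-7, seed=7)
field, truth = generate_angle_dynamics(spec)
rec = cell_summary(field, thermal)

print(f"k_eff:   {rec.k_eff:.3e} N/m   (true {truth['stiffness_true']:.3e})")
print(f"D:       {rec.D:.3e} m^2/s (true {truth['D_true']:.3e})")
print(f"gamma:   {rec.gamma:.3e} kg/s  (true {truth['friction_true']:.3e})")
print(f"omega_c: {rec.omega_c:.2f} 1/s     (true {truth['omega_true']:.2f})")
print(f"volatility: {rec.volatility*1e9:.2f} nm over {rec.n_angles_used} angles")

# gamma = k_BT/D by the Einstein relation and omega_c = k_eff/gamma; the
# recovered values sit within a few percent of truth at these record lengths.
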