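"""Fit an individual force-length curve from (noisy) MVC data.

Eight maximal contractions at different joint angles give pairs of fascicle
length and tendon force; a concave quadratic fit yields the optimal
fascicle length L_0 (vertex abscissa) and maximal force F_max (ordinate).
"""

from mtulab import fit_force_length, fl_potential, generate_mvc_dataset

mvc = generate_mvc_dataset(L0_mm=41.3, Fmax_N=2887.0, n_angles=8, noise_sd=50.0, seed=3)
curve = fit_force_length(mvc["fascicle_mm"], mvc["force_N"])

print(mvc.round(1).to_string(index=False))
print(f"\nfitted L0   = {curve.L0_mm:.1f} mm  (generator truth 41.3 mm)")
print(f"fitted Fmax = {curve.Fmax_N:.0f} N   (generator truth 2887 N)")
print(f"force-length potential at 0.85 L0: {fl_potential(0.85 * curve.L0_mm, curve):.3f}")
# The potential is F(L)/F_max: the fraction of maximal force available at
# that fascicle length, 1.0 exactly at L_0.
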