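"""Build the enthalpy efficiency-velocity curve and evaluate both muscles.

A classic whole-muscle load-efficiency table (relative load p = P/P_0 vs
enthalpy efficiency, a/P_0 = 0.25) is transposed to normalized shortening
velocity with the Hill relation v/V_max = (1-p)/(1+p/(a/P_0)) and splined,
giving a right-skewed curve with a single peak.
"""

from mtulab import MuscleParameters, evaluate_efficiency, reference_efficiency_curve

curve = reference_efficiency_curve()
print(f"peak efficiency {curve.peak_efficiency:.3f} at v/Vmax = {curve.peak_velocity:.3f}")

soleus = MuscleParameters.soleus()
vl = MuscleParameters.vastus_lateralis()
for name, params, v in (("soleus", soleus, 0.799), ("vastus lateralis", vl, 0.084)):
    eta = evaluate_efficiency(v, params, curve)
    print(f"{name:17s} mean velocity {v:.3f} L0/s -> efficiency {eta:.3f} "
          f"({100 * eta / curve.peak_efficiency:.0f}% of peak)")

# V_max sensitivity: scale V_max +/-30% (b_rel rescales with it)
for f in (0.7, 1.3):
    eta = evaluate_efficiency(0.799, soleus.with_vmax_factor(f), curve)
    print(f"soleus efficiency with Vmax x{f}: {eta:.3f}")
# The soleus shortens near the efficiency optimum; the near-isometric
# vastus lateralis produces almost no work, hence low efficiency.
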