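"""Generate a soleus-like synthetic stance trial and inspect its ground truth.

The preset prescribes continuous fascicle shortening from 0.994 to 0.752
L/L_0 over a 304 ms stance with an MTU lengthening-shortening profile, so
every stance-averaged quantity the analysis should recover is known
analytically before any signal processing happens.
"""

from mtulab import SyntheticTrialConfig, generate_trial

cfg = SyntheticTrialConfig.from_preset("soleus_like", seed=42)
trial = generate_trial(cfg)

df = trial.to_dataframe()
print(f"trial: {len(df)} samples at {cfg.sample_rate:.0f} Hz, columns {list(df.columns)}")
print(f"stance window: samples {trial.window.touchdown_index}-{trial.window.toeoff_index}")
print("analytic ground truth (stance averages):")
for key in ("fl_potential", "fv_potential", "flv_potential", "efficiency",
            "dc_tendon", "dc_belly", "dc_mtu", "mean_fascicle_velocity_norm"):
    print(f"  {key:30s} {trial.ground_truth[key]:.4f}")

# trial.save("trial.csv")  # export as delimited text if needed
# The potentials say what fraction of maximal force is available at the
# operating length/velocity; the DC values are velocity differences between
# MTU, belly, and fascicles in units of V_max.
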