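"""Behavioral phase tuning, context modulation, and PAC with a shift predictor.

Three analyses downstream of a detected coupling network:
1. accuracy and RT as a function of each segment's delay from the optimal
   phase relation (cosine tuning planted by the generator);
2. the context modulation index (same - different)/(same + different) of
   beta power relative to the previous item;
3. theta-phase -> beta-amplitude coupling quantified by the KL modulation
   index, normalized against a trial-shuffling shift predictor.
"""

import numpy as np

from oscnet import coupling, phase_context, synthgen, taskgen

config = synthgen.default_scenario()
rng = np.random.default_rng(11)

# --- 1. phase tuning of behavior ------------------------------------------
trials = taskgen.simulate_session(
    6000, performance_model=config.performance_model(), rng=rng
)
delays = np.array([t.phase_delay for t in trials]) - config.preferred_lag
correct = np.array([t.correct for t in trials])
rts = np.array([t.rt_ms for t in trials])

acc = phase_context.split_half_accuracy_tuning(delays, correct, rng)
rt = phase_context.rt_tuning_curve(delays[correct], rts[correct])
print("phase-delay bin centers (rad):", np.round(acc.bin_centers, 2))
print("hit % (mean-removed):         ", np.round(acc.values, 1))
print("RT ms (mean-removed):         ", np.round(rt.values, 1))
print(f"-> accuracy peaks / RT troughs at the zero-delay bin "
      f"(bins {np.nanargmax(acc.values)} / {np.nanargmin(rt.values)})")

rho, p, _ = phase_context.absolute_delay_correlation(delays, correct.astype(float))
print(f"Spearman rho over equal-count |delay| bins: {rho:.2f} (p = {p:.3f})")

# --- 2. context modulation of beta power ----------------------------------
epochs = synthgen.generate_source_epochs(config, trials[:800], rng)
site = config.beta_sites[1]
env = coupling.bandpass_phase_amplitude(epochs, site, (12, 32), "amplitude")
power = (env**2).mean(axis=1)
ctx = epochs.labels["context_prev"].to_numpy()
mi = phase_context.context_modulation_index(
    power[ctx == "same"].mean(), power[ctx == "different"].mean()
)
print(f"\ncontext MI of beta power at location {site}: {mi:+.3f} "
      f"(planted gain {config.context_gain_same} same vs {config.context_gain_diff} different)")

# --- 3. PAC against the shift predictor -----------------------------------
phase = coupling.bandpass_phase_amplitude(epochs, config.pac_phase_sites[0], (5, 7), "phase")
amp = coupling.bandpass_phase_amplitude(epochs, config.pac_amp_sites[0], (12, 32), "amplitude")
raw = coupling.pac_modulation_index(phase, amp)
surrogates = coupling.shift_predictor_mi(phase, amp, n_surrogates=100, rng=rng)
res = coupling.pac_contrast(raw, surrogates)
print(f"PAC: raw MI {res.raw_mi:.4f}, shift predictor "
      f"{res.predictor_mean:.4f} +/- {res.predictor_sd:.4f}, "
      f"contrast {res.contrast:+.4f} (z = {res.z:.1f})")
print("-> within-trial theta-beta coupling exceeds the trial-shuffled control.")
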