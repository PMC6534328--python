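"""Generate beta-mixture trial stimuli and their true statistics.

Builds the 162-trial position design (3 component shapes x 6 weight
permutations x 9 repeats), draws one trial's 70 samples, and prints the
statistics an observer is asked to report: the sample mean, the skewness,
and the mode defined as the peak of a diffusion kernel density estimate.
"""

from cosmodel import stimgen

design = stimgen.build_design("E1", rng_seed=7)
print(f"design: {len(design.trials)} trials, target SD {design.target_sd} cm")

cond = design.trials[0]
print(f"first trial: {cond.shape_label}, weights {cond.weights} (code {cond.weight_label})")

trial = stimgen.sample_trial(cond, design, rng_seed=42)
stats = stimgen.true_stats(trial, design)
print(f"sample SD      : {trial.positions.std(ddof=1):.4f} cm (scaled exactly)")
print(f"true mean      : {stats.true_mean:.3f} cm")
print(f"true skewness  : {stats.true_skewness:.3f}")
print(f"true mode (KDE): {stats.true_mode:.3f} cm")
# The mode and mean disagree whenever the mixture is skewed; observer models
# are scored on how subjects' reports deviate from these two true values.
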