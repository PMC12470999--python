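"""Filter a cohort, split it in time, and simulate wrong-blood-in-tube.

Shows the three-stage filter trace (post-transfusion window, singleton
patients, incomplete panels), the leakage-free temporal split, and the
ward/day-constrained swap simulation.  The printed WBIT fraction should
sit near the 50% target; the day x ward grouping limits how exactly a
small cohort can hit it.
"""

import wbitlab as wl

cfg = wl.PipelineConfig(train_days=300, test_days=100)
cohort_cfg = wl.CohortConfig(n_patients=1500, duration_days=400,
                             transfusion_rate=0.08, rng_seed=2)
cohort, events = wl.generate_cohort(cohort_cfg)

filtered, trace = wl.apply_filters(cohort, events,
                                   cfg.transfusion_window_days)
print("filter trace (samples, patients, non-increasing):")
print(trace.to_json())

train_c, test_c = wl.temporal_split(filtered, cfg.train_days)
print(f"\ntrain: {len(train_c)} samples, test: {len(test_c)} samples "
      "(pairing never crosses the split)")

pairs = wl.build_nonwbit_pairs(train_c, cfg.max_pair_gap_days)
swapped = wl.simulate_wbit(pairs, cfg.wbit_interval_hours,
                           cfg.wbit_target_fraction, seed=3)
print(f"\npairs: {len(pairs)}, simulated WBIT fraction: "
      f"{wl.wbit_fraction(swapped):.3f} (target {cfg.wbit_target_fraction})")

features = wl.delta_features(swapped)
print("\nfirst rows of the delta-feature table (fL, %, pg, ... per analyte):")
print(features.head(3).round(2).to_string())
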