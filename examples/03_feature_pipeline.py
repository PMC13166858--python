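"""Feature screening, multiple imputation and sliding-window construction.

Windows pair the exposure (a participant depressed and MCI-free at wave t)
with the outcome (MCI at wave t+1); features span the window's two waves.
"""

from depmci import (
    CohortConfig, simulate_cohort, annotate_cohort, default_declarations,
    compute_feature_meta, screen_features, encode_features, impute_mi_mean,
    build_windows, split_dataset,
)

cfg = CohortConfig(n_participants=800, seed=7)
scored = annotate_cohort(simulate_cohort(cfg))

meta = compute_feature_meta(scored, default_declarations(cfg.n_aux_features))
retained = screen_features(meta)
dropped = [m.name for m in meta if m.name not in retained]
print(f"screening: {len(meta)} declared -> {len(retained)} retained")
print(f"  dropped (outcome-derived / composite): {dropped}")

encoded, names = encode_features(scored, retained)
print(f"encoded to {len(names)} numeric features "
      f"({encoded.isna().to_numpy().mean():.1%} cells missing before imputation)")
completed = impute_mi_mean(encoded, m=5, iters=5, seed=7)
assert not completed.isna().to_numpy().any()

windows = build_windows(scored, completed)
train, val, test = split_dataset(windows, (0.7, 0.15, 0.15), seed=7)
pos = sum(w.label for w in windows) / len(windows)
print(f"{len(windows)} (t -> t+1) windows, {pos:.1%} positive (incident MCI)")
print(f"participant-disjoint splits: {len(train)}/{len(val)}/{len(test)} windows")
# Every window carries a (2, n_features) sequence; splits never share a
# participant, so no person's windows leak between train and test.
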