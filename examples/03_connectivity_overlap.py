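"""Which connectivity edges do the two protocols disagree on?

Simulates a phase-locking-value feature table (all channel-pair x band edges
of a 45-channel montage) with three strong planted frontal theta/gamma
edges, runs the nested protocol to get per-loop selections, and categorizes
every involved edge against the leaky protocol's fixed set.  One planted
edge is deliberately withheld from the fixed set to show how the overlap
report flags consistently selected features that leaky selection misses.
"""

import leakage_lab as ll
from leakage_lab.overlap import classify_edges

spec = ll.ConnectivitySpec(n_per_class=25, seed=6)
data, index = ll.generate_connectivity_features(spec)
planted = index.feature_id_for("Fp1", "F3", "theta")

vote = ll.VoteParams(n_reps=50, seed=7)
plan = ll.make_cv_plan(data.labels, n_folds=5, n_repetitions=4, seed=8)
within = ll.run_within_cv_protocol(data, [45], (ll.ClassifierSpec("svm"),), plan, vote)
loops = within.per_loop_selected[45]

std, _ = ll.zscore_standardize(data)
outside = ll.select_by_threshold(ll.vote_count(std, vote), 45)
withheld = [f for f in outside.feature_ids if f != planted]

report = ll.overlap_ratio(withheld, loops)
freq = ll.selection_frequency(loops)
frame = classify_edges(withheld, freq, index, cutoff=plan.n_loops // 2)

print(f"mean per-loop overlap ratio: {report.mean_percent:.1f}%")
print(frame[frame["frequency"] >= plan.n_loops // 2].to_string(index=False))
print(
    f"\nThe withheld planted edge ({planted}) appears as 'within_only_high':\n"
    "the nested protocol selects it in most CV loops, yet it is absent from\n"
    "the fixed leaky set - the kind of genuinely informative feature a leaky\n"
    "pipeline can silently discard."
)
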