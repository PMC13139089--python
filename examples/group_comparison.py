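"""Two-group study with an injected memory deficit.

Simulates 7 control subjects and 7 subjects whose novel-object bout
durations are scaled to 30% (a recognition-memory deficit), scores every
session, and runs the per-family inference workflow: Shapiro-Wilk/Levene
driven test choice, Benjamini-Hochberg corrected q-values, Cohen's d or
rank r effect sizes.
"""

from norkit import compare_metric_tables, generate_group_study, metric_families
from norkit.synthetic import metric_sets_to_table

group_a, group_b = generate_group_study(n_per_group=7, effect=0.3, seed=11)
results = compare_metric_tables(
    metric_sets_to_table(group_a),
    metric_sets_to_table(group_b),
    metric_families(),
    label_a="control", label_b="deficit",
)

print(f"{'indicator':18s} {'family':11s} {'test':12s} {'q':>7s} {'effect':>7s}")
for r in sorted(results, key=lambda r: (r.q if r.q == r.q else 2)):
    if r.q == r.q and r.q < 0.05:
        print(f"{r.metric:18s} {r.family:11s} {r.test:12s} {r.q:7.4f} "
              f"{r.effect_size:7.2f} ({r.effect_type})")
print()
print("Only duration-class metrics respond: the deficit group spends less")
print("time at the novel object, so novel-object durations and duration")
print("preferences drop. Positive Cohen's d = decline relative to the")
print("control (reference) group; frequencies are untouched by design.")
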