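"""Full two-group analysis on a synthetic cohort.

Generates a 13-vs-14-subject cohort (16 channels, test-scale epochs) whose
groups differ only in integration-core coupling, runs every subject through
the full pipeline, and prints the per-metric gated comparison — the same
table the command line `jdnet run` writes as comparison.json.
"""

from jdnet import CohortSpec, PipelineConfig, generate_cohort, run_cohort

spec = CohortSpec(epoch_len=115, prestim=15, seed=7, between_weights=(0.0, 0.6))
result = run_cohort(generate_cohort(spec), PipelineConfig(seed=7))

means = result.metrics.groupby("group")[
    ["clustering", "path_length", "eccentricity", "small_world_q"]
].mean()
print(means.round(3), "\n")

print(f"{'metric':15s} {'test':8s} {'p':>9s}")
for r in result.comparisons:
    flag = " *" if r.significant else ""
    print(f"{r.metric:15s} {r.test:8s} {r.p_value:9.5f}{flag}")

print(
    "\nGroup A has no integration-core coupling: its networks are less"
    "\nclustered and less small-world, with higher eccentricity. Starred"
    "\nrows reject at the 5% level under the Jarque-Bera-gated test."
)
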