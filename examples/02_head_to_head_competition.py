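"""Head-to-head primer competition: mismatch position and temperature effects.

Template ST0 amplified by DePCR with two equimolar primers: the perfect
match (V0) plus one single-mismatch primer (V1..V9).  The mismatch ratio
(mismatch / perfect-match copy events) estimates the annealing penalty of
that mismatch directly.
"""

from depcrsim import ExperimentConfig, run_head_to_head_grid

cfg = ExperimentConfig(
    experiment_id="A+", temperatures=(45.0, 55.0), replicates=4,
    reads_per_replicate=20_000, rarefaction_depth=None,
    error_rate_preset="QB-like", seed=1,
)
result = run_head_to_head_grid(cfg)

cells = {}
for r in result.report["metrics"]:
    cells.setdefault((r["primer"], r["temperature"]), {})[r["metric"]] = r["value"]
print(f"{'primer':>6} {'position':>8} {'pairing':>8} {'45C':>7} {'55C':>7}")
primers = sorted({p for p, _ in cells}, key=lambda v: int(v[1:]))
for vk in primers:
    c45, c55 = cells[(vk, 45.0)], cells[(vk, 55.0)]
    print(f"{vk:>6} {c45['position']:>8} {c45['pairing']:>8} "
          f"{c45['mismatch_ratio_mean']:7.3f} {c55['mismatch_ratio_mean']:7.3f}")
# 5' mismatches are well tolerated (ratio ~0.65 at 45C), 3' mismatches are
# strongly inhibitory (~0.13 at 45C, ~0.01 at 55C), and every position is
# more tolerated at the lower annealing temperature.

for comp in result.comparisons[:3]:
    print(comp.metric, comp.stars)
# Welch's t-test between temperatures per primer, with significance stars.
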