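"""Spike-in enrichment above the background diagonal (the headline result).

Runs the full demo scenario — a 10,000-member library (with a small reversible
fraction) plus two covalent tool compounds × four input tags — at 2 µM vs 0 µM
protein on the resin matrix, scores every member's target-vs-control
enrichment, and asks whether each spike-in sits above the 99th percentile of
the library (background) score distribution, the computable analogue of
"significantly above the diagonal line".

Writes results/enrichment.tsv and results/summary.json (scatter-ready:
x = norm_control, y = norm_target).
"""

from pathlib import Path

from covselect.demo import demo_condition, demo_design
from covselect.enrich import ConditionPair, enrichment_scores, export_report
from covselect.pipeline import simulate_readout

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

design = demo_design(n_members=10_000, n_reversible=100)
target = simulate_readout(
    design, demo_condition("resin", 2.0, n_reads=1_000_000, seed=42), label="2uM"
).counts
control = simulate_readout(
    design, demo_condition("resin", 0.0, n_reads=1_000_000, seed=43), label="0uM"
).counts

records = enrichment_scores(ConditionPair(target=target, control=control), design=design)
background_p99 = records.loc[~records["spike_in"], "score"].quantile(0.99)
spikes = records.loc[records["spike_in"]].sort_values("score", ascending=False)
tsv, js = export_report(records, OUT)

print(f"library background score 99th percentile: {background_p99:.3f} log10 units")
print("spike-in tool-compound tags (target vs no-protein control):")
for r in spikes.itertuples(index=False):
    print(
        f"  member {r.member_id}: events {r.count_target} vs {r.count_control}, "
        f"score {r.score:.2f}, z {r.z:.1f}"
    )
n_above = int((spikes["score"] > background_p99).sum())
print(
    f"{n_above}/{len(spikes)} spike-in tags score above the background 99th "
    "percentile — specific enrichment well above the diagonal"
)
print(f"wrote {tsv} and {js}")
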