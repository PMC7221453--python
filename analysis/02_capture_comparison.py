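"""Capture-matrix comparison: microscale affinity resin vs magnetic beads.

Runs paired selections (same seed, same library, 2 µM protein) on the two
capture matrices and compares per-spike-in recovery — collision-corrected
output molecules per input molecule. Under the package defaults the resin
captures more of the protein (0.5 vs 0.2), reproducing the experimental
finding that the affinity resins gave a higher recovery of the input copies.

Writes results/recovery.tsv and results/recovery_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from covselect.demo import demo_condition, demo_design
from covselect.enrich import recovery_table
from covselect.pipeline import simulate_readout

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_SEEDS = 5
# the capture-method titration ran the tool compounds alone (no library), so
# sequencing saturates the retained pool and recovery reflects the matrix
design = demo_design(n_members=0, spike_inputs=(1_000, 10_000, 100_000))

frames = []
for seed in range(N_SEEDS):
    for matrix in ("resin", "beads"):
        cond = demo_condition(matrix, 2.0, n_reads=400_000, seed=3000 + seed)
        counts = simulate_readout(design, cond).counts
        rec = recovery_table(counts, design)
        rec.insert(0, "matrix", matrix)
        rec.insert(0, "seed", seed)
        frames.append(rec)

df = pd.concat(frames, ignore_index=True)
df.to_csv(OUT / "recovery.tsv", sep="\t", index=False)

wide = df.pivot_table(
    index=["seed", "member_id"], columns="matrix", values="recovery"
).reset_index()
resin_wins = float((wide["resin"] > wide["beads"]).mean())
summary = {
    "n_seeds": N_SEEDS,
    "fraction_spike_tags_resin_gt_beads": resin_wins,
    "median_recovery_resin": float(wide["resin"].median()),
    "median_recovery_beads": float(wide["beads"].median()),
}
(OUT / "recovery_summary.json").write_text(json.dumps(summary, indent=1))

print(
    f"paired comparison over {N_SEEDS} seeds: resin recovery exceeded beads for "
    f"{resin_wins:.0%} of spike-in tags "
    f"(median {summary['median_recovery_resin']:.3f} vs {summary['median_recovery_beads']:.3f})"
)
print(f"wrote {OUT/'recovery.tsv'} and {OUT/'recovery_summary.json'}")
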