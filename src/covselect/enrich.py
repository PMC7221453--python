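"""Condition-level analysis: enrichment over the no-protein background.

The central comparison is target-present vs no-protein control, the simulated
analogue of plotting copy counts against the negative control and asking which
members sit significantly above the background diagonal. Counts are depth-
normalised to events per million assigned reads, scored as a pseudocounted
log10 ratio, and standardised with a Poisson-approximate z. Titration
correlation (input amount vs output events), the signal window (log10 ratio of
output with vs without protein) and capture-matrix recovery round out the
readouts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decode import CountTable
from .library import LibraryDesign

__all__ = [
    "ConditionPair",
    "normalize_counts",
    "enrichment_scores",
    "signal_window",
    "titration_correlation",
    "recovery_fraction",
    "recovery_table",
    "export_report",
]


@dataclass
class ConditionPair:
    """Target (protein present) and control (no protein) count tables from the
    same library design."""

    target: CountTable
    control: CountTable
    target_label: str = "target"
    control_label: str = "control"


def normalize_counts(table: CountTable, per: float = 1e6) -> pd.DataFrame:
    """Events per ``per`` total events: norm = unique_events × per / total."""
    df = table.counts
    if df.empty:
        raise ValueError("cannot normalise an empty count table")
    total = df["unique_events"].sum()
    if total <= 0:
        raise ValueError("cannot normalise: zero total events")
    out = df.copy()
    out["norm_events"] = out["unique_events"] * per / total
    return out


def enrichment_scores(
    pair: ConditionPair,
    pseudocount: float = 0.5,
    design: Optional[LibraryDesign] = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-member enrichment of target over control.

    score = log10((norm_target + α)/(norm_control + α)) with α the
    pseudocount; z = (c_t − r·c_c)/sqrt(c_t + r²·c_c) with r the ratio of
    assigned depths (a Poisson-approximate standardised difference). Members
    absent from one table enter with count 0. ``fdr=True`` appends
    Benjamini–Hochberg q-values computed from the two-sided normal p of z.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    t, c = pair.target.counts, pair.control.counts
    if t.empty or c.empty:
        raise ValueError("both count tables must be nonempty")
    tot_t = t["unique_events"].sum()
    tot_c = c["unique_events"].sum()
    merged = pd.merge(
        t[["member_id", "unique_events"]].rename(columns={"unique_events": "count_target"}),
        c[["member_id", "unique_events"]].rename(columns={"unique_events": "count_control"}),
        on="member_id",
        how="outer",
    ).fillna(0)
    merged["count_target"] = merged["count_target"].astype(np.int64)
    merged["count_control"] = merged["count_control"].astype(np.int64)
    merged["norm_target"] = merged["count_target"] * 1e6 / tot_t
    merged["norm_control"] = merged["count_control"] * 1e6 / tot_c
    merged["score"] = np.log10(
        (merged["norm_target"] + pseudocount) / (merged["norm_control"] + pseudocount)
    )
    r = tot_t / tot_c
    denom = np.sqrt(merged["count_target"] + r * r * merged["count_control"])
    with np.errstate(invalid="ignore"):
        z = (merged["count_target"] - r * merged["count_control"]) / denom
    merged["z"] = np.where(denom > 0, z, 0.0)
    if design is not None:
        flags = design.member_table.set_index("member_id")["spike_in"]
        merged["spike_in"] = (
            merged["member_id"].map(flags).fillna(False).astype(bool)
        )
    else:
        merged["spike_in"] = False
    if fdr:
        p = 2.0 * sps.norm.sf(np.abs(merged["z"]))
        merged["q"] = _benjamini_hochberg(p)
    return merged.sort_values("member_id", ignore_index=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def signal_window(output_with: float, output_without: float) -> float:
    """log10 ratio of selection output with vs without protein.

    The experimental anchor is a window of about two orders of magnitude
    between the 2 µM and 0 µM arms. Returns +inf when the no-protein output is
    zero but the with-protein output is not, and NaN when both are zero (an
    undefined window; callers should treat non-finite values as flags).
    """
    if output_with < 0 or output_without < 0:
        raise ValueError("outputs must be >= 0")
    if output_without == 0:
        return math.nan if output_with == 0 else math.inf
    if output_with == 0:
        return -math.inf
    return math.log10(output_with / output_without)


def titration_correlation(
    inputs: Sequence[float], outputs: Sequence[float]
) -> float:
    """Spearman rank correlation between input molecule amounts and output
    events (ties get average ranks)."""
    if len(inputs) != len(outputs):
        raise ValueError("inputs and outputs must have equal length")
    if len(inputs) < 3:
        raise ValueError("need at least 3 titration points")
    rho, _ = sps.spearmanr(inputs, outputs)
    return float(rho)


def recovery_fraction(unique_events: float, input_molecules: float) -> float:
    """Fraction of input molecules recovered as binding events."""
    if input_molecules <= 0:
        raise ValueError("input_molecules must be positive")
    if unique_events < 0:
        raise ValueError("unique_events must be >= 0")
    return unique_events / input_molecules


def recovery_table(
    table: CountTable, design: LibraryDesign, use_estimated: bool = True
) -> pd.DataFrame:
    """Per-spike-in recovery; uses collision-corrected ``estimated_molecules``
    when available (and says so in the ``statistic`` column), else raw
    ``unique_events``."""
    stat = "estimated_molecules" if use_estimated else "unique_events"
    spikes = design.member_table.query("spike_in")
    rows = []
    counts = table.counts.set_index("member_id")
    for rec in spikes.itertuples(index=False):
        val = float(counts[stat].get(rec.member_id, 0.0))
        rows.append(
            (
                rec.member_id,
                rec.input_molecules,
                val,
                recovery_fraction(val, rec.input_molecules),
                stat,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["member_id", "input_molecules", "output", "recovery", "statistic"],
    )


def export_report(
    records: pd.DataFrame, out_dir: str | Path, extra_summary: Optional[dict] = None
) -> tuple[Path, Path]:
    """Write the scatter-ready enrichment TSV (x = control, y = target) and a
    summary JSON with spike-in ranks and the nonbinder score distribution."""
    if records.empty:
        raise ValueError("no enrichment records to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "enrichment.tsv"
    records.to_csv(tsv, sep="\t", index=False)
    ranked = records.sort_values("score", ascending=False, ignore_index=True)
    ranks = {
        int(r.member_id): i + 1
        for i, r in enumerate(ranked.itertuples(index=False))
        if r.spike_in
    }
    background = records.loc[~records["spike_in"], "score"]
    summary = {
        "n_members": int(len(records)),
        "n_spike_ins": int(records["spike_in"].sum()),
        "spike_in_ranks_by_score": ranks,
        "background_score_p99": float(background.quantile(0.99)) if len(background) else None,
        "background_score_median": float(background.median()) if len(background) else None,
        "min_spike_in_score": float(records.loc[records["spike_in"], "score"].min())
        if ranks
        else None,
    }
    if extra_summary:
        summary.update(extra_summary)
    js = out_dir / "summary.json"
    js.write_text(json.dumps(summary, indent=1))
    return tsv, js
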