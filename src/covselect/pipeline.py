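"""End-to-end orchestration: simulate → decode → enrich, with provenance.

``simulate_readout`` chains the selection, qPCR-guided cycle choice, PCR and
sequencing stages and decodes the result; it is the workhorse behind the CLI,
the analysis drivers and the acceptance checks. ``run_end_to_end`` runs a
target/control pair from a YAML config and writes count tables, truth ledgers,
the enrichment report and a provenance log; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decode import CountTable, DecodeStats, collapse_umi, decode_read_matrix
from .enrich import ConditionPair, enrichment_scores, export_report
from .library import LibraryDesign, read_library_design
from .simulate import (
    BoundPool,
    CycleSelection,
    SelectionCondition,
    sample_read_matrix,
    select_pcr_cycles,
    simulate_pcr,
    simulate_selection,
    qpcr_quantify,
    write_fastq,
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and its input."""


@dataclass
class ReadoutResult:
    pool: BoundPool
    qpcr_estimate: float
    cycle_selection: CycleSelection
    counts: CountTable
    stats: DecodeStats


def simulate_readout(
    design: LibraryDesign,
    cond: SelectionCondition,
    seed: Optional[int] = None,
    fastq_path: Optional[str | Path] = None,
    label: str = "",
) -> ReadoutResult:
    """Full simulated readout of one selection arm.

    All stochastic stages draw from one generator seeded by *seed* (default
    ``cond.seed``), so a run is bit-reproducible. When ``fastq_path`` is given
    the reads are also written to disk; decoding always happens from the
    in-memory read matrix.
    """
    rng = np.random.default_rng(cond.seed if seed is None else seed)
    pool = simulate_selection(design, cond, rng)
    qpcr = qpcr_quantify(pool, cond.qpcr_cv, rng)
    sel = select_pcr_cycles(
        max(qpcr, 1.0), cond.pcr_efficiency, cond.pcr_volume, cond.amplicon_window
    )
    copies = simulate_pcr(pool, sel.cycles, cond.pcr_efficiency, rng)
    reads, mol_idx = sample_read_matrix(
        pool, copies, design, cond.n_reads, cond.seq_error_rate, rng
    )
    if fastq_path is not None:
        write_fastq(reads, fastq_path, mol_idx)
    frame = decode_read_matrix(reads, design)
    from .decode import _stats_from_frame  # single source for the partition

    stats = _stats_from_frame(frame)
    counts = collapse_umi(frame, umi_space=design.schema.umi_space, label=label)
    return ReadoutResult(
        pool=pool, qpcr_estimate=qpcr, cycle_selection=sel, counts=counts, stats=stats
    )


@dataclass
class RunConfig:
    design: Path
    target_condition: Path
    control_condition: Path
    out_dir: Path
    seed: int = 0
    scale: float = 1.0
    write_fastq: bool = False

    def __post_init__(self) -> None:
        for name in ("design", "target_condition", "control_condition"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ConfigError(f"{name} file does not exist: {p}")
        self.out_dir = Path(self.out_dir)
        if self.scale <= 0:
            raise ConfigError("scale must be positive")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    known = {
        "design",
        "target_condition",
        "control_condition",
        "out_dir",
        "seed",
        "scale",
        "write_fastq",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = {"design", "target_condition", "control_condition", "out_dir"} - set(raw)
    if missing:
        raise ConfigError(f"missing config keys: {sorted(missing)}")
    return RunConfig(**raw)


def load_condition(path: str | Path) -> SelectionCondition:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"condition {path} is not a mapping")
    try:
        return SelectionCondition.from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid condition {path}: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> Path:
    """Run simulate → decode → enrich for the target/control pair.

    Writes, under ``out_dir``: per-arm truth ledgers, count tables and decode
    stats; the enrichment TSV + summary JSON; and provenance.json echoing the
    seed, versions and every condition parameter.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        design = read_library_design(config.design)
    except Exception as exc:
        raise StageError(f"stage load_design failed on {config.design}: {exc}") from exc

    arms = {}
    conditions = {}
    for label, cond_path in (
        ("target", config.target_condition),
        ("control", config.control_condition),
    ):
        try:
            cond = load_condition(cond_path)
            if config.scale != 1.0:
                d = cond.to_dict()
                d["n_reads"] = max(1, int(round(d["n_reads"] * config.scale)))
                cond = SelectionCondition.from_dict(d)
            conditions[label] = cond
            fastq = out / f"{label}.fastq" if config.write_fastq else None
            res = simulate_readout(
                design, cond, seed=config.seed + (0 if label == "target" else 1),
                fastq_path=fastq, label=label,
            )
        except Exception as exc:
            raise StageError(
                f"stage simulate_readout({label}) failed on {cond_path}: {exc}"
            ) from exc
        res.pool.to_truth_tsv(out / f"{label}.truth.tsv")
        res.counts.to_tsv(out / f"{label}.counts.tsv")
        res.stats.to_json(out / f"{label}.decode_stats.json")
        arms[label] = res

    try:
        pair = ConditionPair(target=arms["target"].counts, control=arms["control"].counts)
        records = enrichment_scores(pair, design=design)
        export_report(records, out)
    except Exception as exc:
        raise StageError(f"stage enrich failed: {exc}") from exc

    provenance = {
        "covselect_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "scale": config.scale,
        "design_file": str(config.design),
        "design_sha256": _sha256(Path(config.design)),
        "conditions": {k: v.to_dict() for k, v in conditions.items()},
        "read_conservation": {
            k: {
                "total": a.stats.total_reads,
                "assigned": a.stats.assigned,
                "unassigned": a.stats.unassigned,
                "ambiguous": a.stats.ambiguous,
            }
            for k, a in arms.items()
        },
        "molecule_conservation": {
            k: {
                "input": int(a.pool.stages["input"].sum()),
                "retained_after_elution": int(
                    a.pool.stages["retained_after_elution"].sum()
                ),
            }
            for k, a in arms.items()
        },
        "pcr_cycles": {k: a.cycle_selection.cycles for k, a in arms.items()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return out
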