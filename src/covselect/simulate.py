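"""Stochastic simulation of one round of covalent DEL selection.

The simulated experiment mirrors the single-round covalent selection workflow:
the library is incubated with the target protein, the protein is captured on an
affinity matrix (microscale resin column or magnetic beads), unbound molecules
are washed away, reversible binders are released by heat elution, and the
retained molecules — covalent binders plus matrix background — are quantified
by qPCR, PCR-amplified for a chosen number of cycles, and sequenced.

Model summary, per member with n input molecules:

* covalent binding:   Binomial(n, p_cov · capture_efficiency) with
  p_cov = 1 − exp(−k_obs · t), k_obs = kinact·[P]/(K_I + [P])
* reversible binding: Binomial(n, θ · capture_efficiency), θ = [P]/([P] + Kd)
* matrix background:  Binomial(n_unbound, background_stick_prob), attenuated
  through washes by wash_retention^n_washes
* heat elution releases each protein-bound reversible molecule with
  ``reversible_release_prob`` (default 1: complete elution) and each covalent
  molecule with 1 − ``covalent_retention_prob``; matrix-stuck background is
  adhesion to the support, not protein binding, and survives elution.

Every retained molecule receives an independent uniform UMI from the 4^12
space; PCR duplicates of one molecule share that UMI, which is what the decoder
collapses back into binding events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from ._bases import BASE_ASCII, CODE_OF, seq_to_ascii, umi_ints_to_ascii
from .library import KineticParams, LibraryDesign

__all__ = [
    "KineticParams",
    "SelectionCondition",
    "BoundPool",
    "CycleSelection",
    "covalent_binding_prob",
    "simulate_selection",
    "qpcr_quantify",
    "select_pcr_cycles",
    "simulate_pcr",
    "sample_read_matrix",
    "simulate_sequencing",
    "write_fastq",
    "resin_condition",
    "beads_condition",
]


@dataclass(frozen=True)
class SelectionCondition:
    """Parameters of one selection arm.

    Notes on defaults: washes/elution temperatures follow the published
    protocol (five 100 µL washes and 80 °C / 10 min for resin columns; one
    wash and 95 °C / 10 min for magnetic beads); the amplicon window is the
    protocol's 3–40 nM; background_stick_prob × wash_retention^n_washes gives
    the net per-molecule background of ~1e-3 that produces a ~2-order signal
    window. Use :func:`resin_condition` / :func:`beads_condition` for the
    matrix-specific defaults.
    """

    protein_conc: float  # µM
    incubation_time: float = 3600.0  # s
    matrix: str = "resin"
    capture_efficiency: float = 0.5
    n_washes: int = 5
    wash_retention: float = 0.631  # per-wash background retention; 0.631^5 ≈ 0.1
    elution_temp: float = 80.0  # °C
    reversible_release_prob: float = 1.0
    covalent_retention_prob: float = 0.95
    background_stick_prob: float = 0.01
    pcr_efficiency: float = 0.9
    pcr_volume: float = 50e-6  # L
    amplicon_window: tuple[float, float] = (3.0, 40.0)  # nM
    n_reads: int = 1_000_000
    seq_error_rate: float = 0.005
    qpcr_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix not in ("resin", "beads"):
            raise ValueError(f"matrix must be 'resin' or 'beads', got {self.matrix!r}")
        probs = dict(
            capture_efficiency=self.capture_efficiency,
            wash_retention=self.wash_retention,
            reversible_release_prob=self.reversible_release_prob,
            covalent_retention_prob=self.covalent_retention_prob,
            background_stick_prob=self.background_stick_prob,
            pcr_efficiency=self.pcr_efficiency,
            seq_error_rate=self.seq_error_rate,
        )
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.protein_conc < 0 or self.incubation_time < 0:
            raise ValueError("protein_conc and incubation_time must be >= 0")
        if self.n_washes < 0:
            raise ValueError("n_washes must be >= 0")
        lo, hi = self.amplicon_window
        if not (0 < lo < hi):
            raise ValueError("amplicon_window must satisfy 0 < low < high")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplicon_window"] = list(self.amplicon_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionCondition":
        d = dict(d)
        if "amplicon_window" in d:
            d["amplicon_window"] = tuple(d["amplicon_window"])
        return cls(**d)


def resin_condition(protein_conc: float, **kw) -> SelectionCondition:
    """Microscale affinity-column arm: higher capture, five washes, 80 °C elution."""
    base = dict(
        matrix="resin",
        capture_efficiency=0.5,
        n_washes=5,
        wash_retention=0.631,
        elution_temp=80.0,
    )
    base.update(kw)
    return SelectionCondition(protein_conc=protein_conc, **base)


def beads_condition(protein_conc: float, **kw) -> SelectionCondition:
    """Magnetic-bead arm: lower capture, one large wash, 95 °C elution."""
    base = dict(
        matrix="beads",
        capture_efficiency=0.2,
        n_washes=1,
        wash_retention=0.1,
        elution_temp=95.0,
    )
    base.update(kw)
    return SelectionCondition(protein_conc=protein_conc, **base)


def covalent_binding_prob(k: KineticParams, protein_conc: float, t: float) -> float:
    """Probability that a covalent binder is labeled within *t* seconds.

    Standard time-dependent-inhibition kinetics: k_obs = kinact·[P]/(K_I+[P]),
    p = 1 − exp(−k_obs·t). Monotone nondecreasing in [P], t and kinact.
    """
    if protein_conc < 0 or t < 0:
        raise ValueError("protein_conc and t must be >= 0")
    if k.kinact is None or k.KI is None:
        raise ValueError("covalent binding requires kinact and KI")
    if protein_conc == 0:
        return 0.0
    kobs = k.kinact * protein_conc / (k.KI + protein_conc)
    return -math.expm1(-kobs * t)


@dataclass
class BoundPool:
    """Audit trail of one simulated selection.

    ``stages`` has one row per member (input, bound_after_incubation,
    retained_after_wash, retained_after_elution); the retained pool is
    materialised per molecule so each carries its UMI. ``molecule_member``
    holds the member *row index* in the design, ``molecule_umi`` the UMI as an
    integer in [0, 4^umi_length).
    """

    stages: pd.DataFrame
    molecule_member: np.ndarray
    molecule_umi: np.ndarray
    umi_space: int

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_member.size)

    def distinct_umis_per_member(self) -> pd.Series:
        """Ground-truth distinct (member, UMI) pairs, indexed by member row."""
        if self.n_molecules == 0:
            return pd.Series(dtype=np.int64)
        df = pd.DataFrame(
            {"member": self.molecule_member, "umi": self.molecule_umi}
        ).drop_duplicates()
        return df.groupby("member").size()

    def to_truth_tsv(self, path: str | Path) -> None:
        out = self.stages.copy()
        distinct = self.distinct_umis_per_member()
        out["distinct_umis"] = (
            distinct.reindex(range(len(out)), fill_value=0).to_numpy()
        )
        out.to_csv(path, sep="\t", index=False)


def _member_arrays(design: LibraryDesign):
    t = design.member_table
    return (
        t["input_molecules"].to_numpy(np.int64),
        t["binder_class"].to_numpy(),
        t["kinact"].to_numpy(float),
        t["KI"].to_numpy(float),
        t["Kd"].to_numpy(float),
    )


def simulate_selection(
    design: LibraryDesign,
    cond: SelectionCondition,
    rng: Optional[np.random.Generator] = None,
) -> BoundPool:
    """One round of selection; deterministic given ``cond.seed`` (or *rng*)."""
    if rng is None:
        rng = np.random.default_rng(cond.seed)
    n, bclass, kinact, KI, Kd, = _member_arrays(design)
    P, t = cond.protein_conc, cond.incubation_time

    p_spec = np.zeros(len(n))
    cov = bclass == "covalent"
    rev = bclass == "reversible"
    if P > 0:
        if cov.any():
            kobs = kinact[cov] * P / (KI[cov] + P)
            p_spec[cov] = -np.expm1(-kobs * t) * cond.capture_efficiency
        if rev.any():
            p_spec[rev] = P / (P + Kd[rev]) * cond.capture_efficiency

    bound_spec = rng.binomial(n, p_spec)
    # matrix adhesion is an independent channel over all input molecules, so a
    # binder's background equals a nonbinder's; capped so bound <= input
    back_pre = rng.binomial(n, cond.background_stick_prob)
    back_pre -= np.maximum(bound_spec + back_pre - n, 0)
    back_wash = rng.binomial(back_pre, cond.wash_retention ** cond.n_washes)

    surv_spec = np.zeros_like(bound_spec)
    surv_spec[cov] = rng.binomial(bound_spec[cov], cond.covalent_retention_prob)
    surv_spec[rev] = rng.binomial(bound_spec[rev], 1.0 - cond.reversible_release_prob)
    retained = surv_spec + back_wash

    stages = pd.DataFrame(
        {
            "member_id": design.member_table["member_id"].to_numpy(),
            "input": n,
            "bound_after_incubation": bound_spec + back_pre,
            "retained_after_wash": bound_spec + back_wash,
            "retained_after_elution": retained,
        }
    )
    # Stage monotonicity is structural; assert it on every run.
    s = stages.to_numpy()[:, 1:]
    assert (np.diff(s.astype(np.int64), axis=1) <= 0).all(), "stage counts must be non-increasing"

    member_rows = np.repeat(
        np.arange(len(n), dtype=np.int64), retained
    )
    umis = rng.integers(0, design.schema.umi_space, size=member_rows.size, dtype=np.int64)
    return BoundPool(
        stages=stages,
        molecule_member=member_rows,
        molecule_umi=umis,
        umi_space=design.schema.umi_space,
    )


def qpcr_quantify(
    pool: BoundPool | int,
    cv: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> float:
    """qPCR estimate of total molecules: truth × lognormal noise of mean 1 and
    coefficient of variation *cv* (cv = 0 returns the truth exactly)."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    truth = pool.n_molecules if isinstance(pool, BoundPool) else int(pool)
    if truth == 0 or cv == 0:
        return float(truth)
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma2 = math.log1p(cv * cv)
    factor = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2))
    return truth * factor


@dataclass(frozen=True)
class CycleSelection:
    cycles: int
    expected_conc_nM: float
    exceeds_window: bool


def select_pcr_cycles(
    n_molecules: float,
    efficiency: float,
    volume: float,
    window: tuple[float, float] = (3.0, 40.0),
) -> CycleSelection:
    """Smallest cycle count whose expected amplicon concentration reaches the
    lower edge of the target window.

    Expected concentration after c cycles is n·(1+e)^c / (N_A·V); the routine
    mirrors the protocol step of choosing PCR cycles from the qPCR copy number
    so the final amplicon lands in the 3–40 nM loading window. The returned
    record carries the achieved expected concentration (nM) and a flag if it
    overshoots the upper edge.
    """
    if n_molecules < 1:
        raise ValueError("nothing to amplify: n_molecules must be >= 1")
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    if volume <= 0:
        raise ValueError("volume must be positive (litres)")
    low, high = window
    conc0_nM = n_molecules / (Avogadro * volume) * 1e9
    if conc0_nM >= low:
        c = 0
    else:
        c = math.ceil(math.log(low / conc0_nM) / math.log1p(efficiency))
        # guard against floating-point edge of the ceiling
        while conc0_nM * (1 + efficiency) ** c < low:
            c += 1
    expected = conc0_nM * (1 + efficiency) ** c
    return CycleSelection(cycles=c, expected_conc_nM=expected, exceeds_window=expected > high)


def _gw_mean_var(cycles: int, efficiency: float) -> tuple[float, float]:
    """Mean and variance of a single molecule's copy number after PCR,
    modelled as a Galton–Watson process with offspring 1 + Bernoulli(e)."""
    m = 1.0 + efficiency
    mean = m ** cycles
    if cycles == 0 or efficiency in (0.0, 1.0):
        return mean, 0.0
    s2 = efficiency * (1.0 - efficiency)
    var = s2 * m ** (cycles - 1) * (m ** cycles - 1.0) / (m - 1.0)
    return mean, var


def simulate_pcr(
    pool: BoundPool | int,
    cycles: int,
    efficiency: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    mode: str = "auto",
    exact_threshold: float = 1e4,
) -> np.ndarray:
    """Per-molecule copy numbers after *cycles* of PCR.

    Exact mode simulates every cycle (copies += Binomial(copies, e)); it is the
    oracle and is used automatically when the total expected copy count is at
    most ``exact_threshold``. Above that, each molecule's copy number is drawn
    from a lognormal matched to the exact branching-process mean (1+e)^c and
    variance e(1−e)·m^(c−1)(m^c−1)/(m−1), m = 1+e.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not (0 <= efficiency <= 1):
        raise ValueError("efficiency must be in [0, 1]")
    if mode not in ("auto", "exact", "approx"):
        raise ValueError("mode must be auto, exact or approx")
    n = pool.n_molecules if isinstance(pool, BoundPool) else int(pool)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    mean, var = _gw_mean_var(cycles, efficiency)
    if cycles == 0 or efficiency == 0:
        return np.ones(n, dtype=np.int64)
    if rng is None:
        rng = np.random.default_rng(seed)
    use_exact = mode == "exact" or (mode == "auto" and n * mean <= exact_threshold)
    if use_exact:
        copies = np.ones(n, dtype=np.int64)
        for _ in range(cycles):
            copies = copies + rng.binomial(copies, efficiency)
        return copies
    sigma2 = math.log1p(var / mean ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    draw = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    return np.maximum(np.rint(draw), 1.0).astype(np.int64)


def _apply_substitution_errors(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator, chunk: int = 100_000
) -> None:
    """In-place i.i.d. substitution errors; an erroneous base is uniform over
    the three other bases. Chunked to bound memory."""
    if error_rate == 0 or reads.size == 0:
        return
    n = reads.shape[0]
    for start in range(0, n, chunk):
        block = reads[start : start + chunk]
        mask = rng.random(block.shape, dtype=np.float32) < error_rate
        r, c = np.nonzero(mask)
        if r.size == 0:
            continue
        codes = CODE_OF[block[r, c]]
        shift = rng.integers(1, 4, size=r.size)
        block[r, c] = BASE_ASCII[(codes + shift) % 4]


def sample_read_matrix(
    pool: BoundPool,
    copies: np.ndarray,
    design: LibraryDesign,
    n_reads: int,
    seq_error_rate: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample sequencing reads in memory.

    Returns ``(reads, molecule_index)``: an (n_reads, layout_length) ASCII byte
    matrix with substitution errors applied, and for each read the index of the
    pool molecule it came from (the ground truth used by the tests). Reads are
    drawn with probability proportional to post-PCR copy number.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    schema = design.schema
    L = schema.layout_length
    if n_reads == 0:
        return np.empty((0, L), dtype=np.uint8), np.empty(0, dtype=np.int64)
    if pool.n_molecules == 0:
        raise ValueError(
            "cannot sequence an empty pool: no molecules survived selection"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    copies = np.asarray(copies, dtype=np.float64)
    if copies.shape != (pool.n_molecules,):
        raise ValueError("copies must have one entry per retained molecule")
    cdf = np.cumsum(copies)
    mol_idx = np.searchsorted(cdf, rng.random(n_reads) * cdf[-1], side="right")
    mol_idx = np.minimum(mol_idx, pool.n_molecules - 1).astype(np.int64)

    prefix = design.prefix_ascii
    pw = prefix.shape[1]
    u0, u1 = schema.umi_span
    reads = np.empty((n_reads, L), dtype=np.uint8)
    reads[:, :pw] = prefix[pool.molecule_member[mol_idx]]
    reads[:, u0:u1] = umi_ints_to_ascii(pool.molecule_umi[mol_idx], schema.umi_length)
    if schema.downstream_constant:
        reads[:, u1:] = seq_to_ascii(schema.downstream_constant)
    _apply_substitution_errors(reads, seq_error_rate, rng)
    return reads, mol_idx


def write_fastq(
    reads: np.ndarray, path: str | Path, mol_idx: Optional[np.ndarray] = None
) -> None:
    """Write an ASCII read matrix as a 4-line-record FASTQ with constant
    quality 'I'. Headers are ``@r<i>`` (plus the source molecule index when
    known, as an informational comment)."""
    n, L = reads.shape
    body = reads.tobytes()
    qual = b"I" * L
    with open(path, "wb") as fh:
        w = fh.write
        if mol_idx is None:
            for i in range(n):
                w(b"@r%d\n" % i)
                w(body[i * L : (i + 1) * L])
                w(b"\n+\n")
                w(qual)
                w(b"\n")
        else:
            for i in range(n):
                w(b"@r%d mol:%d\n" % (i, mol_idx[i]))
                w(body[i * L : (i + 1) * L])
                w(b"\n+\n")
                w(qual)
                w(b"\n")


def simulate_sequencing(
    pool: BoundPool,
    copies: np.ndarray,
    design: LibraryDesign,
    cond: SelectionCondition,
    path: str | Path,
    rng: Optional[np.random.Generator] = None,
) -> Path:
    """Sample ``cond.n_reads`` reads and write them to *path* as FASTQ."""
    reads, mol_idx = sample_read_matrix(
        pool, copies, design, cond.n_reads, cond.seq_error_rate, rng=rng, seed=cond.seed
    )
    write_fastq(reads, path, mol_idx)
    return Path(path)
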