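"""Read decoding and UMI-based binding-event counting.

Each sequencing read is sliced at the fixed offsets of the tag schema, its
constant regions are checked (up to ``max_const_mismatch`` substitutions each,
default 2), each cycle codon is matched to its book exactly or corrected to a
unique Hamming-distance-1 codon, and the codon tuple is resolved to a library
member. Reads of one condition are then collapsed on exact (member, N12)
identity: sequences with identical N12 regions are counted as a single binding
event, which removes PCR duplicates.

``estimate_molecules`` additionally inverts the UMI occupancy ("birthday")
saturation, −S·ln(1 − u/S): with u distinct UMIs observed out of a space of S,
the maximum-likelihood number of molecules is slightly above u because two
molecules can draw the same UMI by chance. The raw ``unique_events`` remains
the primary statistic; the corrected estimate is reported alongside it.

UMIs are deliberately *not* error-corrected (no Hamming-1 clustering) by
default: the collapse rule is exact N12 identity. Sequencing errors inside the
UMI therefore bias unique_events upward; an optional directional one-off
clustering is available behind ``cluster_umis=True``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._bases import hamming, seq_to_ascii
from .library import CodonBook, LibraryDesign, TagSchema

__all__ = [
    "ReadAssignment",
    "ParsedRead",
    "CountTable",
    "DecodeStats",
    "parse_read",
    "assign_member",
    "decode_read_matrix",
    "decode_reads",
    "decode_fastq",
    "collapse_umi",
    "estimate_molecules",
]

STATUS_ASSIGNED = "assigned"
STATUS_UNASSIGNED = "unassigned"
STATUS_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ParsedRead:
    ok: bool
    reason: Optional[str]
    codons: Optional[tuple[str, ...]]
    umi: Optional[str]
    upstream_mismatches: int = 0
    downstream_mismatches: int = 0


@dataclass(frozen=True)
class ReadAssignment:
    read_id: Union[int, str]
    status: str
    member_id: Optional[int] = None
    umi: Optional[str] = None
    n_corrected_codons: int = 0
    reason: Optional[str] = None


@dataclass
class DecodeStats:
    """Partition of reads; assigned + unassigned + ambiguous = total."""

    total_reads: int = 0
    assigned: int = 0
    unassigned: int = 0
    ambiguous: int = 0
    reasons: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


@dataclass
class CountTable:
    """Per-member counts for one condition.

    ``counts`` has columns member_id, raw_reads, unique_events,
    estimated_molecules; only observed members appear. ``total_assigned`` is
    the number of assigned reads (the depth used for normalisation).
    """

    counts: pd.DataFrame
    total_assigned: int
    umi_space: int
    label: str = ""

    def events(self, member_id: int) -> int:
        row = self.counts.loc[self.counts["member_id"] == member_id]
        return 0 if row.empty else int(row["unique_events"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, umi_space: int = 4 ** 12, label: str = ""
    ) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        need = {"member_id", "raw_reads", "unique_events", "estimated_molecules"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"count table {path} missing columns {sorted(missing)}")
        return cls(
            counts=df,
            total_assigned=int(df["raw_reads"].sum()),
            umi_space=umi_space,
            label=label,
        )


def estimate_molecules(unique_events: float, umi_space: int) -> float:
    """Occupancy inversion: molecules ≈ −S·ln(1 − u/S), u distinct UMIs of S."""
    if umi_space <= 0:
        raise ValueError("umi_space must be positive")
    if unique_events < 0:
        raise ValueError("unique_events must be >= 0")
    if unique_events >= umi_space:
        raise ValueError(
            f"UMI space saturated: {unique_events} events >= space {umi_space}"
        )
    if unique_events == 0:
        return 0.0
    return -umi_space * math.log1p(-unique_events / umi_space)


# ---------------------------------------------------------------------------
# Scalar reference path (also the API for single reads).

def parse_read(
    sequence: str, schema: TagSchema, max_const_mismatch: int = 2
) -> ParsedRead:
    """Slice one read at the schema's fixed offsets.

    Reads shorter than the layout are unassignable ("truncated"); constant
    regions may carry up to ``max_const_mismatch`` substitutions each.
    """
    L = schema.layout_length
    if len(sequence) < L:
        return ParsedRead(False, "truncated", None, None)
    up = sequence[: len(schema.upstream_constant)]
    up_mm = hamming(up, schema.upstream_constant) if schema.upstream_constant else 0
    u0, u1 = schema.umi_span
    down = sequence[u1:L]
    down_mm = (
        hamming(down, schema.downstream_constant) if schema.downstream_constant else 0
    )
    if up_mm > max_const_mismatch or down_mm > max_const_mismatch:
        return ParsedRead(
            False, "constant_mismatch", None, None, up_mm, down_mm
        )
    codons = tuple(sequence[a:b] for a, b in schema.codon_spans)
    return ParsedRead(True, None, codons, sequence[u0:u1], up_mm, down_mm)


def _match_codon(codon: str, book: CodonBook) -> tuple[Optional[int], int, Optional[str]]:
    """(index, n_corrections, failure_reason) for one codon against its book."""
    try:
        return book.codons.index(codon), 0, None
    except ValueError:
        pass
    hits = [i for i, c in enumerate(book.codons) if hamming(codon, c) == 1]
    if len(hits) == 1:
        return hits[0], 1, None
    if len(hits) > 1:
        return None, 0, "ambiguous_codon"
    return None, 0, "bad_codon"


def assign_member(
    codons: Sequence[str], design: LibraryDesign
) -> tuple[str, Optional[int], int, Optional[str]]:
    """Resolve a codon tuple to a member.

    Returns (status, member_id, n_corrected_codons, reason). With books at
    min_hamming >= 3 a single substitution per codon is always corrected to
    the unique nearest codon and never misassigns.
    """
    if len(codons) != design.schema.n_cycles:
        raise ValueError("one codon string per cycle is required")
    indices = []
    n_corr = 0
    for codon, book in zip(codons, design.codon_books):
        idx, corr, reason = _match_codon(codon, book)
        if idx is None:
            status = STATUS_AMBIGUOUS if reason == "ambiguous_codon" else STATUS_UNASSIGNED
            return status, None, 0, reason
        indices.append(idx)
        n_corr += corr
    member = design.member_by_codon_indices(indices)
    if member is None:
        return STATUS_UNASSIGNED, None, n_corr, "no_member"
    return STATUS_ASSIGNED, member.member_id, n_corr, None


# ---------------------------------------------------------------------------
# Vectorised path.


class _Decoder:
    """Precomputed lookup tables for a design: per-cycle codon dictionaries
    (exact + all Hamming-1 neighbours) and the codon-tuple -> member map."""

    def __init__(self, design: LibraryDesign):
        self.design = design
        self.cycle_maps: list[dict[bytes, tuple[int, int]]] = []
        for book in design.codon_books:
            table: dict[bytes, tuple[int, int]] = {}
            for idx, codon in enumerate(book.codons):
                table[codon.encode()] = (idx, 0)
            for idx, codon in enumerate(book.codons):
                b = bytearray(codon.encode())
                for pos in range(len(b)):
                    orig = b[pos]
                    for repl in b"ACGT":
                        if repl == orig:
                            continue
                        b[pos] = repl
                        key = bytes(b)
                        prev = table.get(key)
                        if prev is None:
                            table[key] = (idx, 1)
                        elif prev[1] == 1 and prev[0] != idx:
                            table[key] = (-2, 1)  # ambiguous neighbour
                    b[pos] = orig
            self.cycle_maps.append(table)
        self.sizes = [len(b) for b in design.codon_books]
        self.member_ids = design.member_table["member_id"].to_numpy(np.int64)


def _get_decoder(design: LibraryDesign) -> _Decoder:
    dec = getattr(design, "_decoder_cache", None)
    if dec is None or dec.design is not design:
        dec = _Decoder(design)
        design._decoder_cache = dec
    return dec


def decode_read_matrix(
    reads: np.ndarray,
    design: LibraryDesign,
    max_const_mismatch: int = 2,
) -> pd.DataFrame:
    """Decode an (n, layout_length) ASCII byte matrix.

    Returns a DataFrame with columns status, member_id (−1 if absent), umi
    (bytes), n_corrected, reason — one row per read, in input order.
    """
    schema = design.schema
    n = reads.shape[0]
    if n and reads.shape[1] != schema.layout_length:
        raise ValueError("read matrix width must equal the schema layout length")
    dec = _get_decoder(design)

    status = np.zeros(n, dtype=np.int8)  # 0 assigned, 1 unassigned, 2 ambiguous
    reason = np.zeros(n, dtype=np.int8)  # 0 -, 1 constant, 2 bad codon, 3 ambig codon, 4 no member
    member_row = np.full(n, -1, dtype=np.int64)
    n_corrected = np.zeros(n, dtype=np.int8)

    if n == 0:
        return _assignment_frame(reads, design, status, reason, member_row, n_corrected)

    up = schema.upstream_constant
    if up:
        mm = (reads[:, : len(up)] != seq_to_ascii(up)).sum(axis=1)
        bad = mm > max_const_mismatch
    else:
        bad = np.zeros(n, dtype=bool)
    down = schema.downstream_constant
    if down:
        u1 = schema.umi_span[1]
        mm = (reads[:, u1:] != seq_to_ascii(down)).sum(axis=1)
        bad |= mm > max_const_mismatch
    status[bad] = 1
    reason[bad] = 1

    key = np.zeros(n, dtype=np.int64)
    for k, (a, b) in enumerate(schema.codon_spans):
        col = np.ascontiguousarray(reads[:, a:b]).view(f"S{b - a}").ravel()
        uniq, inv = np.unique(col, return_inverse=True)
        table = dec.cycle_maps[k]
        idx_u = np.empty(len(uniq), dtype=np.int64)
        corr_u = np.zeros(len(uniq), dtype=np.int8)
        for i, u in enumerate(uniq):
            hit = table.get(u)
            if hit is None:
                idx_u[i] = -1
            else:
                idx_u[i] = hit[0]
                corr_u[i] = hit[1]
        idx = idx_u[inv]
        ok = status == 0
        miss = ok & (idx == -1)
        status[miss] = 1
        reason[miss] = 2
        ambig = ok & (idx == -2)
        status[ambig] = 2
        reason[ambig] = 3
        ok &= idx >= 0
        n_corrected[ok] += corr_u[inv][ok]
        key = key * dec.sizes[k] + np.where(idx >= 0, idx, 0)

    ok = status == 0
    if ok.any():
        uk, invk = np.unique(key[ok], return_inverse=True)
        lut = dec.design.codon_key_to_row
        row_u = np.array([lut.get(int(x), -1) for x in uk], dtype=np.int64)
        rows = row_u[invk]
        sel = np.flatnonzero(ok)
        member_row[sel] = rows
        nom = sel[rows == -1]
        status[nom] = 1
        reason[nom] = 4
    return _assignment_frame(reads, design, status, reason, member_row, n_corrected)


_REASONS = {0: None, 1: "constant_mismatch", 2: "bad_codon", 3: "ambiguous_codon", 4: "no_member"}
_STATUS = {0: STATUS_ASSIGNED, 1: STATUS_UNASSIGNED, 2: STATUS_AMBIGUOUS}


def _assignment_frame(reads, design, status, reason, member_row, n_corrected):
    schema = design.schema
    n = len(status)
    if n:
        u0, u1 = schema.umi_span
        umi = np.ascontiguousarray(reads[:, u0:u1]).view(f"S{schema.umi_length}").ravel()
    else:
        umi = np.empty(0, dtype=f"S{schema.umi_length}")
    member_id = np.where(
        member_row >= 0,
        _get_decoder(design).member_ids[np.maximum(member_row, 0)],
        -1,
    )
    member_id[status != 0] = -1
    return pd.DataFrame(
        {
            "status": pd.Categorical.from_codes(
                status, categories=[STATUS_ASSIGNED, STATUS_UNASSIGNED, STATUS_AMBIGUOUS]
            ),
            "member_id": member_id,
            "umi": umi,
            "n_corrected": n_corrected,
            "reason": pd.Series(reason).map(_REASONS),
        }
    )


def decode_reads(
    sequences: Iterable[str] | np.ndarray,
    design: LibraryDesign,
    max_const_mismatch: int = 2,
) -> tuple[pd.DataFrame, DecodeStats]:
    """Decode reads given as strings (any lengths) or as an ASCII matrix.

    Reads shorter than the layout are unassigned with reason "truncated";
    longer reads are decoded from their first layout_length bases.
    """
    schema = design.schema
    L = schema.layout_length
    if isinstance(sequences, np.ndarray):
        frame = decode_read_matrix(sequences, design, max_const_mismatch)
    else:
        seqs = list(sequences)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        full = np.flatnonzero(lengths >= L)
        mat = np.empty((len(full), L), dtype=np.uint8)
        for j, i in enumerate(full):
            mat[j] = seq_to_ascii(seqs[i][:L])
        sub = decode_read_matrix(mat, design, max_const_mismatch)
        frame = pd.DataFrame(
            {
                "status": pd.Categorical.from_codes(
                    np.ones(len(seqs), dtype=np.int8),
                    categories=[STATUS_ASSIGNED, STATUS_UNASSIGNED, STATUS_AMBIGUOUS],
                ),
                "member_id": np.full(len(seqs), -1, dtype=np.int64),
                "umi": np.zeros(len(seqs), dtype=f"S{schema.umi_length}"),
                "n_corrected": np.zeros(len(seqs), dtype=np.int8),
                "reason": ["truncated"] * len(seqs),
            }
        )
        if len(full):
            for col in ("status", "member_id", "umi", "n_corrected", "reason"):
                frame.loc[full, col] = sub[col].to_numpy()
    stats = _stats_from_frame(frame)
    return frame, stats


def _stats_from_frame(frame: pd.DataFrame) -> DecodeStats:
    vc = frame["status"].value_counts()
    reasons = frame.loc[frame["reason"].notna(), "reason"].value_counts().to_dict()
    stats = DecodeStats(
        total_reads=len(frame),
        assigned=int(vc.get(STATUS_ASSIGNED, 0)),
        unassigned=int(vc.get(STATUS_UNASSIGNED, 0)),
        ambiguous=int(vc.get(STATUS_AMBIGUOUS, 0)),
        reasons={k: int(v) for k, v in reasons.items()},
    )
    assert stats.assigned + stats.unassigned + stats.ambiguous == stats.total_reads
    return stats


def collapse_umi(
    assignments: pd.DataFrame | Iterable[ReadAssignment],
    umi_space: int = 4 ** 12,
    label: str = "",
    cluster_umis: bool = False,
) -> CountTable:
    """Collapse assigned reads into binding events.

    A binding event is one distinct (member_id, UMI) pair: all reads of a
    member that share an N12 are PCR duplicates of one molecule and count
    once. ``raw_reads`` is the number of assigned reads per member.
    ``cluster_umis=True`` additionally merges within-member UMIs at Hamming
    distance 1 into their more-frequent neighbour (off by default; the
    published rule is exact identity).
    """
    if not isinstance(assignments, pd.DataFrame):
        rows = [
            (a.member_id, a.umi.encode() if isinstance(a.umi, str) else a.umi)
            for a in assignments
            if a.status == STATUS_ASSIGNED
        ]
        df = pd.DataFrame(rows, columns=["member_id", "umi"])
    else:
        mask = assignments["status"] == STATUS_ASSIGNED
        df = assignments.loc[mask, ["member_id", "umi"]]
    if df.empty:
        counts = pd.DataFrame(
            columns=["member_id", "raw_reads", "unique_events", "estimated_molecules"]
        )
        return CountTable(counts=counts, total_assigned=0, umi_space=umi_space, label=label)
    raw = df.groupby("member_id").size()
    pairs = df.drop_duplicates()
    if cluster_umis:
        pairs = _cluster_umis_directional(df)
    events = pairs.groupby("member_id").size()
    counts = pd.DataFrame(
        {
            "member_id": raw.index.to_numpy(np.int64),
            "raw_reads": raw.to_numpy(np.int64),
            "unique_events": events.reindex(raw.index, fill_value=0).to_numpy(np.int64),
        }
    )
    counts["estimated_molecules"] = [
        estimate_molecules(u, umi_space) for u in counts["unique_events"]
    ]
    return CountTable(
        counts=counts.sort_values("member_id", ignore_index=True),
        total_assigned=int(raw.sum()),
        umi_space=umi_space,
        label=label,
    )


def _cluster_umis_directional(df: pd.DataFrame) -> pd.DataFrame:
    """Within each member, absorb a UMI into a Hamming-1 neighbour with a
    strictly higher read count (directional one-off clustering)."""
    kept = []
    for member, grp in df.groupby("member_id"):
        freq = grp.groupby("umi").size().sort_values(ascending=False)
        survivors: dict[bytes, int] = {}
        for umi, cnt in freq.items():
            absorbed = False
            b = bytearray(umi)
            for pos in range(len(b)):
                orig = b[pos]
                for repl in b"ACGT":
                    if repl == orig:
                        continue
                    b[pos] = repl
                    parent = survivors.get(bytes(b))
                    if parent is not None and parent > cnt:
                        absorbed = True
                        break
                b[pos] = orig
                if absorbed:
                    break
            if not absorbed:
                survivors[bytes(umi)] = cnt
        kept.extend((member, u) for u in survivors)
    return pd.DataFrame(kept, columns=["member_id", "umi"])


def decode_fastq(
    path: str | Path,
    design: LibraryDesign,
    max_const_mismatch: int = 2,
    label: str = "",
    cluster_umis: bool = False,
) -> tuple[CountTable, DecodeStats]:
    """Stream a FASTQ file through parse → assign → collapse."""
    seqs: list[str] = []
    try:
        with open(path) as fh:
            for _title, seq, _q in FastqGeneralIterator(fh):
                seqs.append(seq)
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record near index {len(seqs)} in {path}: {exc}"
        ) from exc
    frame, stats = decode_reads(seqs, design, max_const_mismatch)
    table = collapse_umi(
        frame, umi_space=design.schema.umi_space, label=label, cluster_umis=cluster_umis
    )
    return table, stats
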