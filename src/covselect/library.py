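"""DNA-encoded library design: tag layout, error-correcting codon books, members.

A DEL member is identified by one codon per chemistry cycle; the full DNA tag of
a sequenced molecule is

    upstream_constant | codon_1 | ... | codon_k | UMI (N12) | downstream_constant

at fixed offsets (no indels). Codon books are designed with a minimum pairwise
Hamming distance (default 3) so any single substitution within a codon can be
corrected unambiguously. Spike-in tool compounds are ordinary members flagged
``spike_in=True``, one member per (compound, input amount) tag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from ._bases import ALPHABET, BASE_ASCII, is_valid_seq, seq_to_ascii

BINDER_CLASSES = ("nonbinder", "reversible", "covalent")


@dataclass(frozen=True)
class KineticParams:
    """Binding kinetics of one library member.

    Parameters
    ----------
    kinact : float, optional
        Maximal inactivation rate of a covalent binder, s^-1.
    KI : float, optional
        Inhibitor concentration at half-maximal k_obs, µM. Together with
        ``kinact`` this gives the standard irreversible-inhibition rate
        k_obs = kinact·[P]/(KI + [P]).
    Kd : float, optional
        Equilibrium dissociation constant of a reversible binder, µM.
    """

    kinact: Optional[float] = None
    KI: Optional[float] = None
    Kd: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("kinact", "KI", "Kd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"KineticParams.{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class TagSchema:
    """Fixed-offset layout of the sequenced DNA tag."""

    upstream_constant: str
    cycle_codon_lengths: tuple[int, ...]
    downstream_constant: str
    umi_length: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycle_codon_lengths", tuple(self.cycle_codon_lengths))
        if not self.cycle_codon_lengths or any(l <= 0 for l in self.cycle_codon_lengths):
            raise ValueError("cycle_codon_lengths must be positive integers")
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        for name in ("upstream_constant", "downstream_constant"):
            if not is_valid_seq(getattr(self, name)):
                raise ValueError(f"{name} must be uppercase ACGT")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_codon_lengths)

    @property
    def layout_length(self) -> int:
        return (
            len(self.upstream_constant)
            + sum(self.cycle_codon_lengths)
            + self.umi_length
            + len(self.downstream_constant)
        )

    @property
    def codon_spans(self) -> list[tuple[int, int]]:
        """(start, end) column span of each cycle codon in the read."""
        spans = []
        pos = len(self.upstream_constant)
        for l in self.cycle_codon_lengths:
            spans.append((pos, pos + l))
            pos += l
        return spans

    @property
    def umi_span(self) -> tuple[int, int]:
        start = len(self.upstream_constant) + sum(self.cycle_codon_lengths)
        return start, start + self.umi_length

    @property
    def umi_space(self) -> int:
        return 4 ** self.umi_length


@dataclass(frozen=True)
class CodonBook:
    """Ordered set of equal-length codons for one chemistry cycle.

    Pairwise Hamming distance is at least ``min_hamming`` (checked on
    construction with an exhaustive O(n²) scan).
    """

    cycle_index: int
    codons: tuple[str, ...]
    min_hamming: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "codons", tuple(self.codons))
        if not self.codons:
            raise ValueError("codon book must contain at least one codon")
        L = len(self.codons[0])
        for c in self.codons:
            if len(c) != L:
                raise ValueError("all codons in a book must have equal length")
            if not is_valid_seq(c):
                raise ValueError(f"codon {c!r} is not uppercase ACGT")
        if len(set(self.codons)) != len(self.codons):
            raise ValueError("codons must be distinct")
        mat = np.frombuffer("".join(self.codons).encode(), dtype=np.uint8).reshape(
            len(self.codons), L
        )
        for i in range(len(self.codons)):
            d = (mat[i + 1 :] != mat[i]).sum(axis=1)
            if d.size and int(d.min()) < self.min_hamming:
                j = i + 1 + int(np.argmin(d))
                raise ValueError(
                    f"codons {self.codons[i]!r} and {self.codons[j]!r} are at "
                    f"Hamming distance {int(d.min())} < min_hamming={self.min_hamming}"
                )

    @property
    def codon_length(self) -> int:
        return len(self.codons[0])

    def __len__(self) -> int:
        return len(self.codons)


def generate_codon_book(
    n_codons: int, length: int, min_hamming: int, seed: int
) -> CodonBook:
    """Randomised-greedy design of ``n_codons`` codons at pairwise distance
    >= ``min_hamming``.

    Deterministic for a fixed seed. Raises ``ValueError`` naming the achieved
    count if the request is infeasible within the search budget.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if not (length >= min_hamming >= 1):
        raise ValueError("need length >= min_hamming >= 1")
    if 4 ** length < n_codons:
        raise ValueError(f"4^{length} < {n_codons}: not enough distinct codons")
    rng = np.random.default_rng(seed)
    kept = np.empty((0, length), dtype=np.uint8)
    tries = 0
    budget = max(20_000, 2_000 * n_codons)
    while len(kept) < n_codons and tries < budget:
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        tries += 1
        if len(kept) == 0 or int((kept != cand).sum(axis=1).min()) >= min_hamming:
            kept = np.vstack([kept, cand])
    if len(kept) < n_codons:
        raise ValueError(
            f"could only place {len(kept)} of {n_codons} codons of length "
            f"{length} at pairwise Hamming distance >= {min_hamming}"
        )
    codons = tuple(BASE_ASCII[kept[i]].tobytes().decode() for i in range(n_codons))
    return CodonBook(cycle_index=0, codons=codons, min_hamming=min_hamming)


@dataclass(frozen=True)
class LibraryMember:
    member_id: int
    codon_indices: tuple[int, ...]
    binder_class: str = "nonbinder"
    kinetics: Optional[KineticParams] = None
    spike_in: bool = False
    input_molecules: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "codon_indices", tuple(self.codon_indices))
        if self.binder_class not in BINDER_CLASSES:
            raise ValueError(
                f"member {self.member_id}: unknown binder_class {self.binder_class!r}"
            )
        if self.input_molecules < 0:
            raise ValueError(f"member {self.member_id}: negative input_molecules")
        if self.binder_class == "covalent":
            k = self.kinetics
            if k is None or not k.kinact or not k.KI:
                raise ValueError(
                    f"member {self.member_id}: covalent binder requires "
                    "kinetics with kinact > 0 and KI > 0"
                )
        if self.binder_class == "reversible":
            k = self.kinetics
            if k is None or not k.Kd:
                raise ValueError(
                    f"member {self.member_id}: reversible binder requires "
                    "kinetics with Kd > 0"
                )


@dataclass
class LibraryDesign:
    """The encoded library: tag schema, one codon book per cycle, members."""

    schema: TagSchema
    codon_books: list[CodonBook]
    members: list[LibraryMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.codon_books) != self.schema.n_cycles:
            raise ValueError("one codon book per chemistry cycle is required")
        for book, l in zip(self.codon_books, self.schema.cycle_codon_lengths):
            if book.codon_length != l:
                raise ValueError(
                    f"codon book length {book.codon_length} does not match "
                    f"schema codon length {l}"
                )
        capacity = math.prod(len(b) for b in self.codon_books)
        if len(self.members) > capacity:
            raise ValueError(
                f"{len(self.members)} members exceed codon-space capacity {capacity}"
            )
        seen: set[tuple[int, ...]] = set()
        for m in self.members:
            if len(m.codon_indices) != self.schema.n_cycles:
                raise ValueError(f"member {m.member_id}: wrong number of codons")
            for k, idx in enumerate(m.codon_indices):
                if not (0 <= idx < len(self.codon_books[k])):
                    raise ValueError(
                        f"member {m.member_id}: codon index {idx} out of range "
                        f"for cycle {k}"
                    )
            if m.codon_indices in seen:
                raise ValueError(
                    f"member {m.member_id}: duplicate codon tuple {m.codon_indices}"
                )
            seen.add(m.codon_indices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryDesign):
            return NotImplemented
        return (
            self.schema == other.schema
            and list(self.codon_books) == list(other.codon_books)
            and list(self.members) == list(other.members)
        )

    @property
    def n_members(self) -> int:
        return len(self.members)

    @cached_property
    def member_table(self) -> pd.DataFrame:
        """Per-member parameters as a DataFrame (row order = member order)."""
        rows = []
        for m in self.members:
            k = m.kinetics or KineticParams()
            rows.append(
                (
                    m.member_id,
                    m.binder_class,
                    k.kinact if k.kinact is not None else np.nan,
                    k.KI if k.KI is not None else np.nan,
                    k.Kd if k.Kd is not None else np.nan,
                    m.spike_in,
                    m.input_molecules,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "member_id",
                "binder_class",
                "kinact",
                "KI",
                "Kd",
                "spike_in",
                "input_molecules",
            ],
        )

    @cached_property
    def prefix_ascii(self) -> np.ndarray:
        """(n_members, prefix_len) ASCII bytes: upstream constant + codons."""
        up = seq_to_ascii(self.schema.upstream_constant)
        books_ascii = [
            np.frombuffer("".join(b.codons).encode(), dtype=np.uint8).reshape(
                len(b), b.codon_length
            )
            for b in self.codon_books
        ]
        parts = [np.tile(up, (self.n_members, 1))] if len(up) else []
        idx = np.array([m.codon_indices for m in self.members], dtype=np.int64)
        for k, ba in enumerate(books_ascii):
            parts.append(ba[idx[:, k]])
        return np.concatenate(parts, axis=1) if parts else np.empty((self.n_members, 0), np.uint8)

    @cached_property
    def codon_key_to_row(self) -> dict[int, int]:
        """Mixed-radix codon-tuple key -> member row index."""
        sizes = [len(b) for b in self.codon_books]
        out: dict[int, int] = {}
        for row, m in enumerate(self.members):
            key = 0
            for idx, s in zip(m.codon_indices, sizes):
                key = key * s + idx
            out[key] = row
        return out

    def member_by_codon_indices(self, indices: Sequence[int]) -> Optional[LibraryMember]:
        sizes = [len(b) for b in self.codon_books]
        key = 0
        for idx, s in zip(indices, sizes):
            key = key * s + idx
        row = self.codon_key_to_row.get(key)
        return None if row is None else self.members[row]


def molecules_per_member(total_amount_mol: float, n_members: int) -> float:
    """Molecules available per library member for a given total amount.

    ``total_amount_mol`` is in mol; e.g. 2.5 nmol over 7.6 million members is
    about 2e8 molecules of each member.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if total_amount_mol < 0:
        raise ValueError("total_amount_mol must be >= 0")
    return total_amount_mol * Avogadro / n_members


def assemble_tag(
    member: LibraryMember,
    umi: str,
    schema: TagSchema,
    codon_books: Sequence[CodonBook],
) -> str:
    """Error-free DNA tag of one molecule of *member* carrying *umi*."""
    if len(umi) != schema.umi_length or not is_valid_seq(umi):
        raise ValueError(
            f"UMI must be a {schema.umi_length}-nt ACGT string, got {umi!r}"
        )
    codons = [
        codon_books[k].codons[idx] for k, idx in enumerate(member.codon_indices)
    ]
    seq = schema.upstream_constant + "".join(codons) + umi + schema.downstream_constant
    assert len(seq) == schema.layout_length
    return seq


# ---------------------------------------------------------------------------
# File representation: members TSV + schema/codon-book JSON sidecar.

_TSV_BASE_COLS = ["member_id", "binder_class", "kinact", "KI", "Kd", "spike_in", "input_molecules"]


def _sidecar_path(tsv_path: Path) -> Path:
    return tsv_path.with_suffix(".json")


def write_library_design(design: LibraryDesign, path: str | Path) -> None:
    """Write members to ``path`` (TSV) and schema/codon books to a ``.json``
    sidecar with the same stem."""
    path = Path(path)
    k = design.schema.n_cycles
    rows = []
    for m in design.members:
        kin = m.kinetics or KineticParams()
        row = {"member_id": m.member_id}
        for c in range(k):
            row[f"codon_{c + 1}"] = design.codon_books[c].codons[m.codon_indices[c]]
        row.update(
            binder_class=m.binder_class,
            kinact="" if kin.kinact is None else repr(kin.kinact),
            KI="" if kin.KI is None else repr(kin.KI),
            Kd="" if kin.Kd is None else repr(kin.Kd),
            spike_in=int(m.spike_in),
            input_molecules=m.input_molecules,
        )
        rows.append(row)
    cols = ["member_id"] + [f"codon_{c + 1}" for c in range(k)] + _TSV_BASE_COLS[1:]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "schema": {
            "upstream_constant": design.schema.upstream_constant,
            "cycle_codon_lengths": list(design.schema.cycle_codon_lengths),
            "downstream_constant": design.schema.downstream_constant,
            "umi_length": design.schema.umi_length,
        },
        "codon_books": [
            {
                "cycle_index": b.cycle_index,
                "min_hamming": b.min_hamming,
                "codons": list(b.codons),
            }
            for b in design.codon_books
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_library_design(path: str | Path) -> LibraryDesign:
    """Read a design written by :func:`write_library_design`; all invariants
    are re-checked on load and the first offending record is named."""
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    schema = TagSchema(
        upstream_constant=meta["schema"]["upstream_constant"],
        cycle_codon_lengths=tuple(meta["schema"]["cycle_codon_lengths"]),
        downstream_constant=meta["schema"]["downstream_constant"],
        umi_length=meta["schema"]["umi_length"],
    )
    books = [
        CodonBook(
            cycle_index=b["cycle_index"],
            codons=tuple(b["codons"]),
            min_hamming=b["min_hamming"],
        )
        for b in meta["codon_books"]
    ]
    df = pd.read_csv(path, sep="\t", dtype={"binder_class": str}, keep_default_na=False)
    lookup = [{c: i for i, c in enumerate(b.codons)} for b in books]
    members = []
    for rec in df.itertuples(index=False):
        rec = rec._asdict()
        indices = []
        for c in range(schema.n_cycles):
            codon = rec[f"codon_{c + 1}"]
            if codon not in lookup[c]:
                raise ValueError(
                    f"member {rec['member_id']}: codon {codon!r} not in "
                    f"cycle-{c + 1} book"
                )
            indices.append(lookup[c][codon])

        def _opt(v):
            return None if v in ("", None) else float(v)

        kin = KineticParams(_opt(rec["kinact"]), _opt(rec["KI"]), _opt(rec["Kd"]))
        if kin == KineticParams():
            kin = None
        members.append(
            LibraryMember(
                member_id=int(rec["member_id"]),
                codon_indices=tuple(indices),
                binder_class=rec["binder_class"],
                kinetics=kin,
                spike_in=bool(int(rec["spike_in"])),
                input_molecules=int(rec["input_molecules"]),
            )
        )
    return LibraryDesign(schema=schema, codon_books=books, members=members)
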