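"""Desk-scale demo scenario mirroring the validation experiment.

The published experiment spiked two on-DNA covalent tool compounds, each
carried by four DNA tags encoding the input amount, into a multimillion-member
library and selected at 2 µM vs 0 µM target protease on two capture matrices.
The demo reproduces that structure at desk scale: a 10,000-member library of
nonbinders (optionally with a reversible fraction), two covalent compounds ×
four input-amount tags, resin and bead conditions at 2 µM and 0 µM.

The tool-compound kinetics are package conventions (the experiment reports
only relative potency): compound A is potent enough to label essentially every
protein encounter within the 1 h incubation, compound B is clearly weaker but
still detectable, so their event counts are ordered the way the enzyme-assay
potencies were.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .library import (
    CodonBook,
    KineticParams,
    LibraryDesign,
    LibraryMember,
    TagSchema,
    generate_codon_book,
)
from .simulate import SelectionCondition, beads_condition, resin_condition

DEFAULT_SCHEMA = TagSchema(
    upstream_constant="ACGTACGTACGTACGTACGT",
    cycle_codon_lengths=(8, 8, 8),
    downstream_constant="TGCATGCATGCATGCATGCA",
    umi_length=12,
)

# kinact (s^-1), KI (µM): A saturates within 1 h at 2 µM, B labels ~40%.
SPIKE_KINETICS = {
    "A": KineticParams(kinact=0.01, KI=1.0),
    "B": KineticParams(kinact=2e-4, KI=1.0),
}


def demo_design(
    n_members: int = 10_000,
    member_input: int = 10_000,
    n_reversible: int = 0,
    reversible_Kd: float = 1.0,
    spike_compounds: Sequence[str] = ("A", "B"),
    spike_inputs: Sequence[int] = (1_000, 10_000, 100_000, 1_000_000),
    seed: int = 2018,
) -> LibraryDesign:
    """Build the demo library.

    ``n_members`` library members at ``member_input`` molecules each (the
    first ``n_reversible`` of them reversible binders with the given Kd, the
    rest nonbinders), plus one spike-in member per (compound, input amount)
    tag. ``spike_inputs`` scales the published 10^6–10^9 molecule titration
    down by three orders of magnitude.
    """
    n_spikes = len(spike_compounds) * len(spike_inputs)
    total = n_members + n_spikes
    per_cycle = max(2, math.ceil(total ** (1 / 3)) + 1)
    books = []
    for k in range(3):
        b = generate_codon_book(per_cycle, 8, 3, seed=seed + k)
        books.append(CodonBook(cycle_index=k, codons=b.codons, min_hamming=b.min_hamming))

    def codon_tuple(i: int) -> tuple[int, int, int]:
        return (
            i // (per_cycle * per_cycle),
            (i // per_cycle) % per_cycle,
            i % per_cycle,
        )

    members = []
    for i in range(n_members):
        if i < n_reversible:
            members.append(
                LibraryMember(
                    member_id=i,
                    codon_indices=codon_tuple(i),
                    binder_class="reversible",
                    kinetics=KineticParams(Kd=reversible_Kd),
                    input_molecules=member_input,
                )
            )
        else:
            members.append(
                LibraryMember(
                    member_id=i,
                    codon_indices=codon_tuple(i),
                    binder_class="nonbinder",
                    input_molecules=member_input,
                )
            )
    next_id = n_members
    for comp in spike_compounds:
        for amount in spike_inputs:
            members.append(
                LibraryMember(
                    member_id=next_id,
                    codon_indices=codon_tuple(next_id),
                    binder_class="covalent",
                    kinetics=SPIKE_KINETICS[comp],
                    spike_in=True,
                    input_molecules=int(amount),
                )
            )
            next_id += 1
    return LibraryDesign(schema=DEFAULT_SCHEMA, codon_books=books, members=members)


def spike_member_ids(design: LibraryDesign) -> list[int]:
    return design.member_table.query("spike_in")["member_id"].astype(int).tolist()


def demo_condition(
    matrix: str,
    protein_conc: float,
    n_reads: int = 1_000_000,
    seed: int = 0,
    **kw,
) -> SelectionCondition:
    """Matrix-specific demo condition at the given protein concentration."""
    factory = resin_condition if matrix == "resin" else beads_condition
    return factory(protein_conc, n_reads=n_reads, seed=seed, **kw)


def spike_signal_windows(
    n_seeds: int = 20,
    base_seed: int = 1,
    n_members: int = 10_000,
    member_input: int = 10_000,
    spike_input: int = 10_000,
    n_reads: int = 1_000_000,
    protein_conc: float = 2.0,
) -> list[float]:
    """Signal window of a single covalent spike-in, per seed.

    For each seed, selects a nonbinder library carrying one potent covalent
    spike-in (kinact 0.01 s^-1, K_I 1 µM, 1 h incubation) at ``protein_conc``
    and at 0 µM on the resin matrix, decodes both arms, and returns
    log10(spike-in events with protein / without). The no-protein event count
    is floored at 1 so a seed where background yields zero spike-in events
    reports a finite (conservative) window.
    """
    from .enrich import signal_window
    from .pipeline import simulate_readout

    design = demo_design(
        n_members=n_members,
        member_input=member_input,
        spike_compounds=("A",),
        spike_inputs=(spike_input,),
    )
    spike_id = spike_member_ids(design)[0]
    seed_rng = np.random.default_rng(base_seed)
    arm_seeds = seed_rng.integers(0, 2 ** 31, size=(n_seeds, 2))
    windows = []
    for s_t, s_c in arm_seeds:
        cond_t = demo_condition("resin", protein_conc, n_reads=n_reads, seed=int(s_t))
        cond_c = demo_condition("resin", 0.0, n_reads=n_reads, seed=int(s_c))
        ev_t = simulate_readout(design, cond_t).counts.events(spike_id)
        ev_c = simulate_readout(design, cond_c).counts.events(spike_id)
        windows.append(signal_window(ev_t, max(ev_c, 1)))
    return windows
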