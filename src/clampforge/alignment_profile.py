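"""Per-column conservation profiles over a host + microbe multiple alignment.

The clamp-design workflow starts from a pre-computed multiple alignment of
host organellar/ITS references and microbial homologs.  This module reduces
that alignment to a per-column profile (host consensus, host conservation,
microbial base frequencies) and locates maximal host-conserved blocks — the
only places a clamp that binds every host haplotype can live.  Aligning is
deliberately out of scope: aligner choice is orthogonal to the method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seq_core import GAP, Role, SequenceRecord

__all__ = [
    "MultipleAlignment",
    "ConservationProfile",
    "build_profile",
    "host_conserved_blocks",
    "column_to_host_coordinate",
    "host_coordinate_to_column",
]

# Deterministic consensus tie-break order.
_BASE_ORDER = "ACGTRYSWKMBDHVN"


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped records; at least one host and one microbe are
    required for profiling."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    def by_role(self, role: Role) -> list[SequenceRecord]:
        return [r for r in self.records if r.role is role]

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(f"no record {rec_id!r} in alignment")


@dataclass
class ConservationProfile:
    """Column-wise summary of a host/microbe alignment.

    ``host_consensus[j]`` is the majority host residue in column ``j`` (ties
    broken by fixed base order A<C<G<T<...), ``host_conservation[j]`` the
    fraction of host rows carrying it.  Microbial frequencies include the
    gap fraction and sum to 1 per column.
    """

    host_consensus: list[str]
    host_conservation: list[float]
    host_gap_fraction: list[float]
    microbe_base_frequencies: list[dict[str, float]]
    microbe_gap_fraction: list[float]
    n_host: int
    n_microbe: int
    alignment: MultipleAlignment | None = field(default=None, repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.host_consensus)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(self.n_columns):
            rows.append({
                "column": j,
                "host_consensus": self.host_consensus[j],
                "host_conservation": self.host_conservation[j],
                "host_gap_fraction": self.host_gap_fraction[j],
                "microbe_gap_fraction": self.microbe_gap_fraction[j],
                "microbe_base_frequencies": json.dumps(
                    self.microbe_base_frequencies[j], sort_keys=True),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_profile(alignment: MultipleAlignment) -> ConservationProfile:
    """Tally each column into a :class:`ConservationProfile`."""
    hosts = alignment.by_role(Role.HOST)
    microbes = alignment.by_role(Role.MICROBE)
    if not hosts:
        raise ValueError("profiling requires at least one host record")
    if not microbes:
        raise ValueError("profiling requires at least one microbe record")

    consensus: list[str] = []
    conservation: list[float] = []
    host_gap: list[float] = []
    mic_freqs: list[dict[str, float]] = []
    mic_gap: list[float] = []

    n_h, n_m = len(hosts), len(microbes)
    for j in range(alignment.n_columns):
        h_col = [r.residues[j] for r in hosts]
        m_col = [r.residues[j] for r in microbes]

        counts: dict[str, int] = {}
        for ch in h_col:
            counts[ch] = counts.get(ch, 0) + 1
        # majority residue; ties broken by fixed base order, gap last
        order = {b: i for i, b in enumerate(_BASE_ORDER)}
        cons = max(counts, key=lambda b: (counts[b], -order.get(b, len(order))))
        consensus.append(cons)
        conservation.append(counts[cons] / n_h)
        host_gap.append(h_col.count(GAP) / n_h)

        freqs: dict[str, float] = {}
        for ch in m_col:
            if ch != GAP:
                freqs[ch] = freqs.get(ch, 0.0) + 1.0 / n_m
        mic_freqs.append(freqs)
        mic_gap.append(m_col.count(GAP) / n_m)

    return ConservationProfile(
        host_consensus=consensus,
        host_conservation=conservation,
        host_gap_fraction=host_gap,
        microbe_base_frequencies=mic_freqs,
        microbe_gap_fraction=mic_gap,
        n_host=n_h,
        n_microbe=n_m,
        alignment=alignment,
    )


def host_conserved_blocks(
    profile: ConservationProfile,
    min_conservation: float = 1.0,
    min_len: int = 12,
) -> list[tuple[int, int]]:
    """Maximal column intervals (0-based, half-open) that are host-usable.

    A column qualifies when no host row has a gap there and the host
    conservation reaches ``min_conservation``.  Only runs of length
    ``min_len`` or more are returned, sorted by start.
    """
    if not (0.0 < min_conservation <= 1.0):
        raise ValueError("min_conservation must be in (0, 1]")
    ok = [
        profile.host_gap_fraction[j] == 0.0
        and profile.host_consensus[j] != GAP
        and profile.host_conservation[j] >= min_conservation
        for j in range(profile.n_columns)
    ]
    blocks: list[tuple[int, int]] = []
    start = None
    for j, flag in enumerate(ok):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            if j - start >= min_len:
                blocks.append((start, j))
            start = None
    if start is not None and profile.n_columns - start >= min_len:
        blocks.append((start, profile.n_columns))
    return blocks


def column_to_host_coordinate(
    alignment: MultipleAlignment, host_id: str, column: int
) -> int | None:
    """Map an alignment column to the 0-based ungapped position on one host
    sequence, or ``None`` when that host has a gap there."""
    rec = alignment.get(host_id)
    if not (0 <= column < len(rec)):
        raise IndexError(f"column {column} outside alignment")
    if rec.residues[column] == GAP:
        return None
    return column - rec.residues[:column].count(GAP)


def host_coordinate_to_column(
    alignment: MultipleAlignment, host_id: str, position: int
) -> int:
    """Inverse of :func:`column_to_host_coordinate` for non-gap positions."""
    rec = alignment.get(host_id)
    seen = -1
    for j, ch in enumerate(rec.residues):
        if ch != GAP:
            seen += 1
            if seen == position:
                return j
    raise IndexError(f"position {position} beyond ungapped length of {host_id!r}")
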