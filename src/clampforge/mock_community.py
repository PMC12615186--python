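"""Copy-number normalization for defined mock communities.

A mock community is a defined DNA mix used as a positive control in
metabarcoding: each member contributes a known expected number of marker
(e.g. 16S) gene copies.  Given per-extract DNA concentration, genome length
and marker copies per genome, this module converts concentrations to marker
copies per microliter (genome-equivalent arithmetic: one bp averages
650 g/mol, i.e. 650/N_A = 1.0794e-12 ng), derives pipetting volumes that
equalize copies across members (balanced mix) or hit arbitrary target
proportions (unbalanced mix), and compares observed read fractions against
the expected copy fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "MASS_PER_BP_NG",
    "MockMember",
    "MockRecipe",
    "ComparisonReport",
    "marker_copies_per_microliter",
    "balanced_volumes",
    "unbalanced_volumes",
    "compare_observed_expected",
]

#: Average mass of one double-stranded bp: 650 g/mol / Avogadro, in ng.
MASS_PER_BP_NG = 650.0 / 6.02214076e23 * 1e9  # = 1.0794e-12 ng


@dataclass(frozen=True)
class MockMember:
    name: str
    dna_concentration: float  # ng/uL
    genome_length: float      # bp
    marker_copies_per_genome: int

    def __post_init__(self) -> None:
        if min(self.dna_concentration, self.genome_length,
               self.marker_copies_per_genome) <= 0:
            raise ValueError(f"member {self.name!r}: all numeric fields must be > 0")


@dataclass
class MockRecipe:
    volumes: dict[str, float]                 # uL per member
    expected_copy_fraction: dict[str, float]  # sums to 1
    total_copies: float

    def __post_init__(self) -> None:
        s = sum(self.expected_copy_fraction.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"expected fractions sum to {s}, not 1")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": list(self.volumes),
            "volume_ul": [self.volumes[n] for n in self.volumes],
            "expected_fraction": [self.expected_copy_fraction[n] for n in self.volumes],
        })


def marker_copies_per_microliter(
    member: MockMember, mass_per_bp: float = MASS_PER_BP_NG
) -> float:
    """Marker gene copies per uL of the member's DNA extract."""
    if mass_per_bp <= 0:
        raise ValueError("mass_per_bp must be positive")
    genomes_per_ul = member.dna_concentration / (member.genome_length * mass_per_bp)
    return genomes_per_ul * member.marker_copies_per_genome


def balanced_volumes(
    members: Sequence[MockMember],
    target_copies_per_member: float = 1e7,
    mass_per_bp: float = MASS_PER_BP_NG,
) -> MockRecipe:
    """Volumes putting the same number of marker copies from every member
    into the mix (the balanced mock community)."""
    if len(members) < 2:
        raise ValueError("a mock community needs at least 2 members")
    if target_copies_per_member <= 0:
        raise ValueError("target_copies_per_member must be positive")
    volumes: dict[str, float] = {}
    for m in members:
        cpul = marker_copies_per_microliter(m, mass_per_bp)
        if cpul <= 0 or not math.isfinite(cpul):
            raise ValueError(f"member {m.name!r}: non-positive copies per uL")
        volumes[m.name] = target_copies_per_member / cpul
    n = len(members)
    return MockRecipe(
        volumes=volumes,
        expected_copy_fraction={m.name: 1.0 / n for m in members},
        total_copies=target_copies_per_member * n,
    )


def unbalanced_volumes(
    members: Sequence[MockMember],
    target_fractions: Mapping[str, float],
    total_copies: float = 1e8,
    mass_per_bp: float = MASS_PER_BP_NG,
) -> MockRecipe:
    """Volumes realizing arbitrary expected copy proportions."""
    if set(target_fractions) != {m.name for m in members}:
        raise ValueError("target_fractions must cover exactly the member names")
    s = sum(target_fractions.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"target fractions sum to {s}, not 1")
    if any(f <= 0 for f in target_fractions.values()):
        raise ValueError("zero/negative target fraction: omit the member instead")
    volumes = {
        m.name: total_copies * target_fractions[m.name]
        / marker_copies_per_microliter(m, mass_per_bp)
        for m in members
    }
    return MockRecipe(
        volumes=volumes,
        expected_copy_fraction=dict(target_fractions),
        total_copies=total_copies,
    )


@dataclass
class ComparisonReport:
    log2_ratio: dict[str, float]
    l1_distance: float
    undetected: list[str]
    harmonized_observed: dict[str, float] = field(default_factory=dict)
    harmonized_expected: dict[str, float] = field(default_factory=dict)


def compare_observed_expected(
    observed: Mapping[str, float],
    expected: Mapping[str, float],
    pseudo_fraction: float = 1e-6,
) -> ComparisonReport:
    """Observed read fractions vs expected copy fractions.

    Observed taxa absent from the expected universe are pooled into
    ``other``.  Log2 ratios use ``pseudo_fraction`` for zeros; the L1
    distance over the harmonized universe lies in [0, 2]; ``undetected``
    lists expected taxa with zero observed fraction.
    """
    s_exp = sum(expected.values())
    if abs(s_exp - 1.0) > 1e-9:
        raise ValueError(f"expected fractions sum to {s_exp}, not 1")
    obs: dict[str, float] = {t: 0.0 for t in expected}
    obs["other"] = 0.0
    for t, f in observed.items():
        if t in expected:
            obs[t] += f
        else:
            obs["other"] += f
    exp = {**{t: float(f) for t, f in expected.items()}, "other": 0.0}

    ratios = {
        t: math.log2(max(obs[t], pseudo_fraction) / max(exp[t], pseudo_fraction))
        for t in exp
    }
    l1 = sum(abs(obs[t] - exp[t]) for t in exp)
    undetected = [t for t in expected if obs[t] == 0.0]
    return ComparisonReport(
        log2_ratio=ratios,
        l1_distance=l1,
        undetected=undetected,
        harmonized_observed=obs,
        harmonized_expected=exp,
    )
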