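"""Clamp candidate enumeration, filtering, scoring and ranking.

The design algorithm walks host-conserved blocks of the alignment profile,
emits every window of the allowed lengths on both strands, annotates each
with the guideline attributes —

(i)   annealing/melting temperature above that of the PCR primers,
(ii)  Tm above the extension temperature,
(iii) length between 12 and 21 bases,
(iv)  no self-complementary stretches,
(v)   purine content below 50% with no purine run longer than four —

scores every candidate by its mismatch count against each microbial row
(a microbial gap under the clamp is the strongest possible mismatch), and
ranks by the minimum-over-microbes mismatch count, breaking ties toward the
80 degC Tm target.  Constraints default to soft (violations reported, not
fatal): several field-proven published clamps bend the guidelines, so hard
enforcement would reject working designs.  Blocking-primer design reuses
the same conserved blocks but targets a Tm offset above the PCR primers
instead of the compositional criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .alignment_profile import (
    ConservationProfile,
    column_to_host_coordinate,
    host_conserved_blocks,
)
from .seq_core import (
    GAP,
    Oligo,
    OligoKind,
    Role,
    SequenceRecord,
    iupac_match,
    max_purine_run,
    purine_fraction,
    reverse_complement,
    self_complementary_stretch,
)
from .thermo import ThermoConfig, tm_dna_nn, tm_pna

logger = logging.getLogger(__name__)

__all__ = [
    "DesignConstraints",
    "PrimerPair",
    "ClampCandidate",
    "BlockingPrimerDesign",
    "BlockingPrimerResult",
    "enumerate_pna_candidates",
    "score_candidates",
    "rank_candidates",
    "design_pna",
    "design_blocking_primers",
]

Strand = Literal["same_as_host_reference", "reverse_complement"]


@dataclass(frozen=True)
class DesignConstraints:
    """Guideline thresholds for PNA candidates.

    ``constraint_mode='soft'`` keeps every window and lists breaches in
    ``violations``; ``'hard'`` drops any window that breaches a criterion.
    ``mismatch_aggregate`` chooses whether a candidate's divergence score is
    the minimum or the mean over microbial rows (minimum matches the
    "at least five SNPs to every microbial sequence" reading).
    """

    min_len: int = 12
    max_len: int = 21
    max_purine_fraction: float = 0.50
    max_purine_run: int = 4
    self_comp_k: int = 4
    min_tm_margin_over_primers: float = 0.0
    require_tm_above_extension: bool = True
    min_microbe_mismatches: int = 5
    constraint_mode: Literal["hard", "soft"] = "soft"
    min_conservation: float = 1.0
    mismatch_aggregate: Literal["min", "mean"] = "min"

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if min(self.min_len, self.max_purine_run, self.self_comp_k,
               self.min_microbe_mismatches) <= 0 or self.max_purine_fraction <= 0:
            raise ValueError("constraint thresholds must be positive")
        if self.constraint_mode not in ("hard", "soft"):
            raise ValueError("constraint_mode must be 'hard' or 'soft'")


@dataclass(frozen=True)
class PrimerPair:
    forward: Oligo
    reverse: Oligo


@dataclass
class ClampCandidate:
    """A candidate clamp oligomer, reported 5'->3' as synthesized."""

    sequence: str
    alignment_interval: tuple[int, int]
    strand: Strand
    tm_pna: float
    purine_fraction: float
    max_purine_run: int
    self_comp_len: int
    violations: list[str] = field(default_factory=list)
    host_coordinates: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_microbe_mismatches: dict[str, int] = field(default_factory=dict)
    min_microbe_mismatches: int | None = None
    mismatch_score: float | None = None

    def as_oligo(self, name: str) -> Oligo:
        return Oligo(name=name, sequence=self.sequence, kind=OligoKind.PNA,
                     tm_estimate=self.tm_pna)


@dataclass
class BlockingPrimerDesign:
    oligo: Oligo
    strategy: Literal["competitive", "elongation_arrest"]
    length_class: Literal["short", "long"]
    alignment_interval: tuple[int, int]
    strand: Strand
    target_tm: float
    achieved_tm: float
    overlapped_primer: str | None = None

    def __post_init__(self) -> None:
        if self.strategy == "competitive" and self.overlapped_primer is None:
            raise ValueError("competitive design must name the overlapped primer")


@dataclass
class BlockingPrimerResult:
    """Outcome wrapper: either a design or an explicit reason why none exists."""

    design: BlockingPrimerDesign | None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.design is not None


def _criterion_violations(
    seq: str,
    n: int,
    tm: float,
    constraints: DesignConstraints,
    thermo: ThermoConfig,
    primer_tm: float,
) -> list[str]:
    v: list[str] = []
    if not (constraints.min_len <= n <= constraints.max_len):
        v.append("length")
    # "lower than 50%" is strict: exactly at threshold counts as a breach
    if purine_fraction(seq) >= constraints.max_purine_fraction:
        v.append("purine_fraction")
    if max_purine_run(seq) > constraints.max_purine_run:
        v.append("purine_run")
    if self_complementary_stretch(seq, constraints.self_comp_k)[1]:
        v.append("self_complementary")
    if tm <= primer_tm + constraints.min_tm_margin_over_primers:
        v.append("tm_not_above_primers")
    if constraints.require_tm_above_extension and tm <= thermo.extension_temperature:
        v.append("tm_not_above_extension")
    return v


def enumerate_pna_candidates(
    profile: ConservationProfile,
    constraints: DesignConstraints = DesignConstraints(),
    thermo: ThermoConfig = ThermoConfig(),
    primer_pair: PrimerPair | None = None,
) -> list[ClampCandidate]:
    """Emit annotated candidate windows from all host-conserved blocks.

    Both strands are generated per window; in hard mode only windows passing
    every compositional and Tm criterion survive.  Windows whose host
    consensus contains a degenerate base are skipped with a logged reason.
    Returns an unscored, unranked list (see :func:`score_candidates`,
    :func:`rank_candidates`).
    """
    primer_tm = float("-inf")
    if primer_pair is not None:
        primer_tm = max(
            tm_dna_nn(primer_pair.forward.sequence, thermo),
            tm_dna_nn(primer_pair.reverse.sequence, thermo),
        )

    blocks = host_conserved_blocks(
        profile, min_conservation=constraints.min_conservation,
        min_len=constraints.min_len,
    )
    candidates: list[ClampCandidate] = []
    for b_start, b_end in blocks:
        for start in range(b_start, b_end - constraints.min_len + 1):
            for n in range(constraints.min_len, constraints.max_len + 1):
                end = start + n
                if end > b_end:
                    break
                window = "".join(profile.host_consensus[start:end])
                if any(ch not in "ACGT" for ch in window):
                    logger.debug(
                        "window [%d,%d) skipped: degenerate host consensus", start, end
                    )
                    continue
                for strand, seq in (
                    ("same_as_host_reference", window),
                    ("reverse_complement", reverse_complement(window)),
                ):
                    tm = tm_pna(seq, thermo) if 8 <= n <= 30 else float("nan")
                    viol = _criterion_violations(
                        seq, n, tm, constraints, thermo, primer_tm
                    )
                    if constraints.constraint_mode == "hard" and viol:
                        continue
                    cand = ClampCandidate(
                        sequence=seq,
                        alignment_interval=(start, end),
                        strand=strand,  # type: ignore[arg-type]
                        tm_pna=tm,
                        purine_fraction=purine_fraction(seq),
                        max_purine_run=max_purine_run(seq),
                        self_comp_len=self_complementary_stretch(
                            seq, constraints.self_comp_k
                        )[0],
                        violations=viol,
                    )
                    if profile.alignment is not None:
                        for rec in profile.alignment.by_role(Role.HOST):
                            s = column_to_host_coordinate(profile.alignment, rec.id, start)
                            e = column_to_host_coordinate(profile.alignment, rec.id, end - 1)
                            if s is not None and e is not None:
                                cand.host_coordinates[rec.id] = (s, e + 1)
                    candidates.append(cand)
    return candidates


def count_clamp_microbe_mismatches(
    consensus_window: str, microbe_window: str
) -> int:
    """Positions where the clamp's host consensus fails to IUPAC-match the
    microbial residue; a microbial gap counts as a mismatch (a clamp over a
    host-specific insertion cannot bind the microbe at all)."""
    if len(consensus_window) != len(microbe_window):
        raise ValueError("windows differ in length")
    n = 0
    for a, b in zip(consensus_window, microbe_window):
        if b == GAP or not iupac_match(a, b):
            n += 1
    return n


def score_candidates(
    candidates: Iterable[ClampCandidate],
    microbes: Sequence[SequenceRecord],
    profile: ConservationProfile,
    constraints: DesignConstraints = DesignConstraints(),
) -> list[ClampCandidate]:
    """Populate per-microbe and aggregate mismatch counts.

    Mismatches are counted in alignment-column space against the host
    consensus under the window; the count is strand-invariant because
    complementing both bases preserves IUPAC set intersection.
    """
    microbes = list(microbes)
    for m in microbes:
        if len(m) != profile.n_columns:
            raise ValueError(
                f"microbe {m.id!r} length {len(m)} does not match "
                f"alignment width {profile.n_columns}"
            )
    out = []
    for cand in candidates:
        s, e = cand.alignment_interval
        cons = "".join(profile.host_consensus[s:e])
        per = {
            m.id: count_clamp_microbe_mismatches(cons, m.residues[s:e])
            for m in microbes
        }
        cand.per_microbe_mismatches = per
        cand.min_microbe_mismatches = min(per.values()) if per else 0
        if constraints.mismatch_aggregate == "mean":
            cand.mismatch_score = sum(per.values()) / len(per) if per else 0.0
        else:
            cand.mismatch_score = float(cand.min_microbe_mismatches)
        out.append(cand)
    return out


_STRAND_ORDER = {"same_as_host_reference": 0, "reverse_complement": 1}


def rank_candidates(
    candidates: Sequence[ClampCandidate],
    thermo: ThermoConfig = ThermoConfig(),
) -> list[ClampCandidate]:
    """Total deterministic order: most microbe-divergent first.

    Key: (1) mismatch score descending, (2) |tm - target| ascending,
    (3) fewer violations, (4) leftmost start, same-strand before reverse.
    """
    def key(c: ClampCandidate):
        score = c.mismatch_score if c.mismatch_score is not None else 0.0
        tm_dist = abs(c.tm_pna - thermo.pna_target_tm)
        return (
            -score,
            tm_dist,
            len(c.violations),
            c.alignment_interval[0],
            _STRAND_ORDER[c.strand],
            c.alignment_interval[1],
        )

    return sorted(candidates, key=key)


def design_pna(
    profile: ConservationProfile,
    constraints: DesignConstraints = DesignConstraints(),
    thermo: ThermoConfig = ThermoConfig(),
    primer_pair: PrimerPair | None = None,
) -> list[ClampCandidate]:
    """Full pipeline: enumerate, score against the profile's microbial rows,
    apply the mismatch threshold (hard mode only), and rank."""
    if profile.alignment is None:
        raise ValueError("design_pna needs a profile built from an alignment")
    cands = enumerate_pna_candidates(profile, constraints, thermo, primer_pair)
    microbes = profile.alignment.by_role(Role.MICROBE)
    cands = score_candidates(cands, microbes, profile, constraints)
    for c in cands:
        if (c.min_microbe_mismatches or 0) < constraints.min_microbe_mismatches:
            c.violations.append("microbe_mismatches")
    if constraints.constraint_mode == "hard":
        cands = [c for c in cands if "microbe_mismatches" not in c.violations]
    return rank_candidates(cands, thermo)


# ---------------------------------------------------------------------------
# Blocking primers


def _find_primer_columns(
    profile: ConservationProfile, primer: Oligo
) -> tuple[tuple[int, int], str] | None:
    """Locate a primer's binding interval in alignment-column space on the
    host consensus (gap columns excluded); returns (interval, strand)."""
    cols = [j for j in range(profile.n_columns)
            if profile.host_consensus[j] != GAP and profile.host_gap_fraction[j] == 0.0]
    ref = "".join(profile.host_consensus[j] for j in cols)
    # local import avoids a module cycle (insilico_pcr uses seq_core only)
    from .insilico_pcr import find_primer_sites

    template = SequenceRecord(id="_host_consensus", residues=ref, role=Role.HOST)
    hits = find_primer_sites(template, primer, max_mismatch=0,
                             three_prime_window=5, three_prime_max=0)
    if not hits:
        return None
    h = hits[0]
    return (cols[h.interval[0]], cols[h.interval[1] - 1] + 1), h.strand


def _grow_to_tm(
    profile: ConservationProfile,
    block: tuple[int, int],
    seed: tuple[int, int],
    target_tm: float,
    thermo: ThermoConfig,
) -> tuple[tuple[int, int], float]:
    """Extend a seed interval along the host consensus, alternating ends,
    until the DNA/DNA Tm reaches the target or the conserved block ends."""
    s, e = seed

    def tm_of(a: int, b: int) -> float:
        seq = "".join(profile.host_consensus[a:b])
        if any(ch not in "ACGT" for ch in seq) or b - a < 8:
            return float("-inf")
        return tm_dna_nn(seq, thermo)

    tm = tm_of(s, e)
    grow_right = True
    while tm < target_tm:
        if grow_right and e < block[1]:
            e += 1
        elif s > block[0]:
            s -= 1
        elif e < block[1]:
            e += 1
        else:
            break
        grow_right = not grow_right
        tm = tm_of(s, e)
    return (s, e), tm


def design_blocking_primers(
    profile: ConservationProfile,
    primer_pair: PrimerPair,
    strategy: Literal["competitive", "elongation_arrest"],
    length_class: Literal["short", "long"] = "short",
    thermo: ThermoConfig = ThermoConfig(),
    *,
    short_delta: float = 5.0,
    long_delta: float = 15.0,
    min_conservation: float = 1.0,
    primer_names: tuple[str, str] | None = None,
) -> BlockingPrimerResult:
    """Design a C3-spacer blocking primer on the host consensus.

    Competitive designs overlap a PCR primer's binding site (out-competing
    it on host templates); elongation-arrest designs sit strictly between
    the two primer sites.  The oligomer targets a Tm of (primer Tm + 5) degC
    for the short class or (+15) for the long class, grown base by base
    along the conserved block; the long-class oligo is by construction an
    extension of the short-class one at the same locus.
    """
    delta = short_delta if length_class == "short" else long_delta
    names = primer_names or (primer_pair.forward.name, primer_pair.reverse.name)

    fwd_loc = _find_primer_columns(profile, primer_pair.forward)
    rev_loc = _find_primer_columns(profile, primer_pair.reverse)
    if fwd_loc is None or rev_loc is None:
        return BlockingPrimerResult(
            None, "primer pair does not bind the host consensus")
    fwd_iv, _ = fwd_loc
    rev_iv, _ = rev_loc
    if fwd_iv[0] > rev_iv[0]:
        fwd_iv, rev_iv = rev_iv, fwd_iv
        names = (names[1], names[0])

    blocks = host_conserved_blocks(profile, min_conservation=min_conservation,
                                   min_len=12)
    if strategy == "competitive":
        best = None  # (overlap, block, primer_iv, primer_idx)
        for iv, idx in ((fwd_iv, 0), (rev_iv, 1)):
            for blk in blocks:
                ov = min(blk[1], iv[1]) - max(blk[0], iv[0])
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, blk, iv, idx)
        if best is None:
            return BlockingPrimerResult(
                None, "no host-conserved block overlaps a primer binding site")
        _, blk, p_iv, p_idx = best
        seed = (max(blk[0], p_iv[0]), min(blk[1], p_iv[1]))
        if seed[1] - seed[0] < 8:
            seed = (seed[0], min(blk[1], seed[0] + 12))
        overlapped = names[p_idx]
        primer = (primer_pair.forward, primer_pair.reverse)[p_idx]
        base_tm = tm_dna_nn(primer.sequence, thermo)
        strand: Strand = "reverse_complement" if p_idx == 1 else "same_as_host_reference"
    else:
        inner = (fwd_iv[1], rev_iv[0])
        clipped = [(max(b[0], inner[0]), min(b[1], inner[1])) for b in blocks]
        inner_blocks = [b for b in clipped if b[1] - b[0] >= 12]
        if not inner_blocks:
            return BlockingPrimerResult(
                None, "no host-conserved block strictly between the primer sites")
        blk = max(inner_blocks, key=lambda b: b[1] - b[0])
        mid = (blk[0] + blk[1]) // 2
        seed = (max(blk[0], mid - 6), min(blk[1], mid + 6))
        overlapped = None
        base_tm = max(tm_dna_nn(primer_pair.forward.sequence, thermo),
                      tm_dna_nn(primer_pair.reverse.sequence, thermo))
        strand = "same_as_host_reference"

    target = base_tm + delta
    interval, achieved = _grow_to_tm(profile, blk, seed, target, thermo)
    seq = "".join(profile.host_consensus[interval[0]:interval[1]])
    if any(ch not in "ACGT" for ch in seq):
        return BlockingPrimerResult(
            None, "host consensus is degenerate over the only usable block")
    if strand == "reverse_complement":
        seq = reverse_complement(seq)
    oligo = Oligo(
        name=f"BL_{strategy}_{length_class}",
        sequence=seq,
        kind=OligoKind.BLOCKING_PRIMER,
        three_prime_block=True,
        tm_estimate=achieved,
    )
    return BlockingPrimerResult(BlockingPrimerDesign(
        oligo=oligo,
        strategy=strategy,
        length_class=length_class,
        alignment_interval=interval,
        strand=strand,
        target_tm=target,
        achieved_tm=achieved,
        overlapped_primer=overlapped,
    ))
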