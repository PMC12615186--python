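"""In-silico PCR: degenerate primer site scanning, amplicon prediction, and
clamp blocking outcomes.

Primer hits are IUPAC-aware exhaustive scans of both strands with separate
overall and 3'-terminal mismatch budgets (extension is exquisitely
sensitive to 3' mismatches).  Clamp blocking is a binary call: an amplicon
is blocked when the clamp finds an alignment inside the product within
``block_max_mismatch`` (default 0 — a single mismatch is taken to abolish
PNA clamping).  Composition prediction is deterministic weight bookkeeping
over amplifiable templates; no kinetic/efficiency simulation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .clamp_design import ClampCandidate
from .seq_core import Oligo, Role, SequenceRecord, iupac_match, reverse_complement

__all__ = [
    "PrimerHit",
    "AmpliconPrediction",
    "CompositionResult",
    "find_primer_sites",
    "predict_amplicons",
    "best_clamp_alignment",
    "predict_clamp_effect",
    "predict_composition",
]


@dataclass(frozen=True)
class PrimerHit:
    template_id: str
    strand: Literal["+", "-"]
    interval: tuple[int, int]  # 0-based half-open on the template plus strand
    mismatch_count: int
    three_prime_mismatch: bool


@dataclass
class AmpliconPrediction:
    template_id: str
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    product_interval: tuple[int, int]
    product_length: int
    product_seq: str = field(repr=False, default="")
    clamp_hits: list[tuple[str, tuple[int, int], int]] = field(default_factory=list)
    predicted_outcome: Literal["amplifiable", "blocked", "no_product"] = "amplifiable"


def _mismatch_profile(primer: str, window: str) -> list[int]:
    """Per-position mismatch indicator, indexed along the primer 5'->3'."""
    return [0 if iupac_match(p, w) else 1 for p, w in zip(primer, window)]


def find_primer_sites(
    template: SequenceRecord,
    primer: Oligo,
    max_mismatch: int = 2,
    three_prime_window: int = 5,
    three_prime_max: int = 0,
) -> list[PrimerHit]:
    """Scan both strands of an ungapped template for primer binding sites.

    A hit is rejected if its total mismatches exceed ``max_mismatch`` or if
    mismatches within the primer's 3'-terminal ``three_prime_window`` bases
    exceed ``three_prime_max``.
    """
    seq = template.residues
    if "-" in seq:
        raise ValueError("find_primer_sites requires an ungapped template")
    p = primer.sequence
    L = len(p)
    hits: list[PrimerHit] = []
    if L > len(seq):
        return hits
    rc = reverse_complement(p)
    for i in range(len(seq) - L + 1):
        window = seq[i:i + L]
        # plus strand: primer 3' end is the window's right edge
        mm = _mismatch_profile(p, window)
        total = sum(mm)
        tail = sum(mm[L - three_prime_window:]) if three_prime_window else 0
        if total <= max_mismatch and tail <= three_prime_max:
            hits.append(PrimerHit(template.id, "+", (i, i + L), total,
                                  three_prime_mismatch=tail > 0))
        # minus strand: compare revcomp(primer); primer 3' end maps to the
        # window's left edge
        mm = _mismatch_profile(rc, window)
        total = sum(mm)
        tail = sum(mm[:three_prime_window]) if three_prime_window else 0
        if total <= max_mismatch and tail <= three_prime_max:
            hits.append(PrimerHit(template.id, "-", (i, i + L), total,
                                  three_prime_mismatch=tail > 0))
    return hits


def predict_amplicons(
    template: SequenceRecord,
    forward: Oligo,
    reverse: Oligo,
    max_product_len: int = 5000,
    max_mismatch: int = 2,
    three_prime_window: int = 5,
    three_prime_max: int = 0,
) -> list[AmpliconPrediction]:
    """Pair every plus-strand forward hit with every downstream minus-strand
    reverse hit within ``max_product_len``.

    Product length runs from the forward primer's 5' end to the reverse
    primer's 5' end inclusive, i.e. both primers are part of the product.
    """
    kw = dict(max_mismatch=max_mismatch, three_prime_window=three_prime_window,
              three_prime_max=three_prime_max)
    f_hits = [h for h in find_primer_sites(template, forward, **kw) if h.strand == "+"]
    r_hits = [h for h in find_primer_sites(template, reverse, **kw) if h.strand == "-"]
    out: list[AmpliconPrediction] = []
    for fh in f_hits:
        for rh in r_hits:
            if rh.interval[0] < fh.interval[1]:
                continue  # reverse site upstream of / overlapping forward site
            length = rh.interval[1] - fh.interval[0]
            if length > max_product_len:
                continue
            out.append(AmpliconPrediction(
                template_id=template.id,
                forward_hit=fh,
                reverse_hit=rh,
                product_interval=(fh.interval[0], rh.interval[1]),
                product_length=length,
                product_seq=template.residues[fh.interval[0]:rh.interval[1]],
            ))
    return out


def best_clamp_alignment(product_seq: str, clamp_seq: str) -> tuple[int, tuple[int, int]] | None:
    """Best ungapped alignment of the clamp against either strand of the
    product: (mismatch count, product interval), or None if the clamp is
    longer than the product."""
    L = len(clamp_seq)
    if L > len(product_seq):
        return None
    best: tuple[int, tuple[int, int]] | None = None
    for probe in (clamp_seq, reverse_complement(clamp_seq)):
        for i in range(len(product_seq) - L + 1):
            mm = sum(_mismatch_profile(probe, product_seq[i:i + L]))
            if best is None or mm < best[0]:
                best = (mm, (i, i + L))
    return best


def predict_clamp_effect(
    amplicon: AmpliconPrediction,
    clamp: ClampCandidate | Oligo,
    block_max_mismatch: int = 0,
) -> Literal["amplifiable", "blocked"]:
    """Blocked iff the clamp aligns somewhere inside the product (either
    strand) within ``block_max_mismatch`` mismatches."""
    clamp_seq = clamp.sequence
    name = clamp.name if isinstance(clamp, Oligo) else "clamp"
    hit = best_clamp_alignment(amplicon.product_seq, clamp_seq)
    if hit is not None:
        mm, (s, e) = hit
        off = amplicon.product_interval[0]
        amplicon.clamp_hits.append((name, (s + off, e + off), mm))
        if mm <= block_max_mismatch:
            amplicon.predicted_outcome = "blocked"
            return "blocked"
    if amplicon.predicted_outcome != "blocked":
        amplicon.predicted_outcome = "amplifiable"
    return amplicon.predicted_outcome


@dataclass
class CompositionResult:
    role_fractions: dict[str, float]
    per_template: dict[str, str]  # template id -> outcome
    all_blocked: bool = False


def predict_composition(
    templates: Sequence[SequenceRecord],
    weights: Mapping[str, float],
    forward: Oligo,
    reverse: Oligo,
    clamps: Sequence[Oligo | ClampCandidate] = (),
    block_max_mismatch: int = 0,
    **pcr_kwargs,
) -> CompositionResult:
    """Expected pool composition by role over amplifiable templates.

    ``weights`` are copy weights per template id (>= 0, not all zero).
    A template is amplifiable when at least one predicted amplicon escapes
    every clamp.  Fractions are over amplifiable weight only and sum to 1;
    if everything is blocked an empty composition is returned with a flag.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    if not any(w > 0 for w in weights.values()):
        raise ValueError("weights must not all be zero")

    outcomes: dict[str, str] = {}
    role_weight: dict[str, float] = {}
    for t in templates:
        amps = predict_amplicons(t, forward, reverse, **pcr_kwargs)
        if not amps:
            outcomes[t.id] = "no_product"
            continue
        template_ok = False
        for amp in amps:
            amp_blocked = False
            for clamp in clamps:
                if predict_clamp_effect(amp, clamp, block_max_mismatch) == "blocked":
                    amp_blocked = True
                    break
            if not amp_blocked:
                template_ok = True
        outcomes[t.id] = "amplifiable" if template_ok else "blocked"
        if template_ok:
            role = t.role.value if isinstance(t.role, Role) else str(t.role)
            role_weight[role] = role_weight.get(role, 0.0) + float(weights.get(t.id, 0.0))

    total = sum(role_weight.values())
    if total <= 0:
        return CompositionResult({}, outcomes, all_blocked=True)
    return CompositionResult(
        {r: w / total for r, w in role_weight.items()}, outcomes
    )
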