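"""Synthetic host/microbe sequence panels with known ground truth.

The generator emulates the structure clamp design exploits in real
organellar loci:

* a host locus that may carry a long insertion (default 320 bp) absent from
  every microbial homolog — the alignment shows it as a gapped column block
  in microbial rows, and host amplicons come out exactly that much longer;
* a planted clamp site that is 100% conserved across host rows, divergent
  from every microbial row by at least a requested mismatch count, and
  compliant with the compositional design guidelines (pyrimidine-rich, no
  long purine runs, no self-complementary stretch);
* PCR primer binding sites embedded exactly once per template so every
  template yields exactly one predicted amplicon;
* background divergence: independent per-site substitutions in host rows
  (small, making conservation non-trivial) and microbial rows (larger).

Panels are emitted pre-columnized (the generator, like the design tool,
never aligns) together with a ground-truth record each consuming module can
re-verify — the fixture is its own oracle.  All randomness flows from one
integer seed through a single numpy Generator; identical seeds give
byte-identical panels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seq_core import (
    GAP,
    Oligo,
    Role,
    SequenceRecord,
    max_purine_run,
    purine_fraction,
    reverse_complement,
    self_complementary_stretch,
)
from . import wheat_panel

__all__ = ["FixtureSpec", "PanelTruth", "simulate_panel", "simulate_labeled_counts"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic panel.

    ``locus_length`` counts alignment columns (insertion included).  The
    planted site defaults to just downstream of the forward primer; the
    insertion sits midway between the planted site and the reverse primer.
    """

    seed: int = 1
    host_n: int = 4
    microbe_n: int = 10
    locus_length: int = 800
    insertion_length: int = 320
    insertion_position: int | None = None
    planted_position: int | None = None
    planted_length: int = 17
    planted_min_mismatches: int = 5
    per_site_microbe_divergence: float = 0.10
    host_divergence: float = 0.02
    forward_primer: str = wheat_panel.PRIMERS["799F"].sequence
    reverse_primer: str = wheat_panel.PRIMERS["1193R"].sequence
    primer_margin: int = 2

    def __post_init__(self) -> None:
        for p in (self.per_site_microbe_divergence, self.host_divergence):
            if not (0.0 <= p <= 1.0):
                raise ValueError("divergence probabilities must lie in [0, 1]")
        if self.host_n < 1 or self.microbe_n < 1:
            raise ValueError("need at least one host and one microbe")
        if self.insertion_length < 0 or self.planted_length <= 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class PanelTruth:
    planted_columns: tuple[int, int]
    clamp_sequence: str
    insertion_columns: tuple[int, int]
    forward_primer_columns: tuple[int, int]
    reverse_primer_columns: tuple[int, int]
    forward_primer_concrete: str
    reverse_primer_concrete: str
    min_mismatches_to_microbes: int
    roles: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _resolve_degenerate(rng: np.random.Generator, seq: str) -> str:
    from .seq_core import IUPAC_SETS

    return "".join(
        ch if ch in "ACGT" else sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))]
        for ch in seq
    )


def _compliant_site(rng: np.random.Generator, length: int,
                    max_tries: int = 500) -> str:
    """Pyrimidine-leaning random sequence passing the compositional
    guidelines (purine fraction < 0.5, purine run <= 4, no 4+
    self-complementary stretch)."""
    probs = np.array([0.15, 0.35, 0.15, 0.35])  # A C G T
    for _ in range(max_tries):
        seq = "".join(rng.choice(_BASES, size=length, p=probs))
        if (purine_fraction(seq) < 0.5 and max_purine_run(seq) <= 4
                and not self_complementary_stretch(seq, 4)[1]):
            return seq
    raise RuntimeError("could not sample a guideline-compliant planted site")


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float,
            protected: np.ndarray) -> None:
    """In-place iid substitutions (to a different base) outside protected
    columns."""
    if rate <= 0:
        return
    hit = (rng.random(arr.size) < rate) & ~protected
    for j in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[j]]
        arr[j] = choices[rng.integers(3)]


def _layout(spec: FixtureSpec, fwd: str, rev: str) -> dict[str, tuple[int, int]]:
    L = spec.locus_length
    m = spec.primer_margin
    fwd_iv = (m, m + len(fwd))
    rev_iv = (L - m - len(rev), L - m)
    planted_start = (spec.planted_position if spec.planted_position is not None
                     else fwd_iv[1] + 3)
    planted_iv = (planted_start, planted_start + spec.planted_length)
    if spec.insertion_length > 0:
        ins_start = (spec.insertion_position if spec.insertion_position is not None
                     else (planted_iv[1] + rev_iv[0] - spec.insertion_length) // 2)
        ins_iv = (ins_start, ins_start + spec.insertion_length)
    else:
        ins_iv = (planted_iv[1], planted_iv[1])

    ivs = {"fwd": fwd_iv, "planted": planted_iv, "ins": ins_iv, "rev": rev_iv}
    order = [fwd_iv, planted_iv, ins_iv, rev_iv]
    prev_end = 0
    for iv in order:
        if iv[0] < prev_end or iv[1] > L:
            raise ValueError(
                f"infeasible fixture spec: features {ivs} do not fit in {L} columns"
            )
        prev_end = max(prev_end, iv[1])
    return ivs


def _count_occurrences(template: str, primer: str) -> int:
    """Occurrences of a degenerate primer (either strand, IUPAC-aware,
    zero mismatches)."""
    from .seq_core import iupac_match

    n = 0
    for probe in (primer, reverse_complement(primer)):
        L = len(probe)
        for i in range(len(template) - L + 1):
            if all(iupac_match(p, t) for p, t in zip(probe, template[i:i + L])):
                n += 1
    return n


def simulate_panel(spec: FixtureSpec) -> tuple[list[SequenceRecord], PanelTruth]:
    """Generate an aligned host+microbe panel with ground truth.

    Host rows carry no gaps; microbial rows are gapped across the insertion
    block.  Primer sites and the planted site are protected from background
    mutation; each microbe receives exactly ``planted_min_mismatches``
    forced substitutions inside the planted site (background divergence
    never touches it, so the guarantee is ">=").
    """
    rng = np.random.default_rng(spec.seed)
    for attempt in range(20):
        records, truth = _simulate_once(spec, rng)
        ok = all(
            _count_occurrences(r.degapped().residues, p) == 1
            for r in records
            for p in (spec.forward_primer, spec.reverse_primer)
        )
        if ok:
            return records, truth
    raise RuntimeError("could not embed primer sites exactly once (20 attempts)")


def _simulate_once(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[SequenceRecord], PanelTruth]:
    fwd = _resolve_degenerate(rng, spec.forward_primer)
    rev = _resolve_degenerate(rng, spec.reverse_primer)
    ivs = _layout(spec, fwd, rev)
    L = spec.locus_length

    ancestor = rng.choice(_BASES, size=L)
    ancestor[ivs["fwd"][0]:ivs["fwd"][1]] = list(fwd)
    ancestor[ivs["rev"][0]:ivs["rev"][1]] = list(reverse_complement(rev))
    clamp_site = _compliant_site(rng, spec.planted_length)
    ancestor[ivs["planted"][0]:ivs["planted"][1]] = list(clamp_site)

    protected = np.zeros(L, dtype=bool)
    for key in ("fwd", "rev", "planted"):
        protected[ivs[key][0]:ivs[key][1]] = True

    records: list[SequenceRecord] = []
    for h in range(spec.host_n):
        row = ancestor.copy()
        _mutate(rng, row, spec.host_divergence, protected)
        records.append(SequenceRecord(
            id=f"host_{h:02d}", residues="".join(row), role=Role.HOST, aligned=True,
        ))

    p_s, p_e = ivs["planted"]
    for m in range(spec.microbe_n):
        row = ancestor.copy()
        # microbial rows lack the host insertion
        row_mut_protected = protected.copy()
        _mutate(rng, row, spec.per_site_microbe_divergence, row_mut_protected)
        # force the requested divergence at the planted site
        positions = rng.choice(
            np.arange(p_s, p_e), size=spec.planted_min_mismatches, replace=False
        )
        for j in positions:
            choices = [b for b in "ACGT" if b != row[j]]
            row[j] = choices[rng.integers(3)]
        row[ivs["ins"][0]:ivs["ins"][1]] = GAP
        records.append(SequenceRecord(
            id=f"microbe_{m:02d}", residues="".join(row), role=Role.MICROBE,
            aligned=True,
        ))

    truth = PanelTruth(
        planted_columns=ivs["planted"],
        clamp_sequence=clamp_site,
        insertion_columns=ivs["ins"],
        forward_primer_columns=ivs["fwd"],
        reverse_primer_columns=ivs["rev"],
        forward_primer_concrete=fwd,
        reverse_primer_concrete=rev,
        min_mismatches_to_microbes=spec.planted_min_mismatches,
        roles={r.id: r.role.value for r in records},
    )
    return records, truth


def simulate_labeled_counts(
    host_fraction: float,
    total_reads: int,
    taxon_profile: dict[str, float],
    seed: int = 1,
) -> "pd.DataFrame":
    """Multinomial read-count table over one host bin plus microbial taxa.

    ``taxon_profile`` gives relative microbial proportions (normalized
    internally); the host bin receives ``host_fraction`` of the probability
    mass.  Reproducible by seed.
    """
    import pandas as pd

    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not (0.0 <= host_fraction <= 1.0):
        raise ValueError("host_fraction must lie in [0, 1]")
    taxa = list(taxon_profile)
    weights = np.array([taxon_profile[t] for t in taxa], dtype=float)
    if host_fraction < 1.0:
        if weights.sum() <= 0:
            raise ValueError("taxon profile must have positive mass")
        weights = weights / weights.sum() * (1.0 - host_fraction)
    else:
        weights = np.zeros_like(weights)
    probs = np.concatenate([[host_fraction], weights])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total_reads, probs)
    rows = [{"taxon": "host", "role": "host", "count": int(draws[0])}]
    rows += [
        {"taxon": t, "role": "microbe", "count": int(c)}
        for t, c in zip(taxa, draws[1:])
    ]
    return pd.DataFrame(rows)
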