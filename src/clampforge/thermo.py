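"""Melting-temperature models for primer and clamp duplexes.

Two estimators matter for clamp design:

* ``tm_dna_nn`` — nearest-neighbor DNA/DNA Tm (enthalpy/entropy sum with
  salt and strand-concentration terms) under a named published parameter
  set; used for PCR primers and blocking primers.
* ``tm_pna`` — a sequence-based PNA/DNA correlation, affine in the DNA/DNA
  nearest-neighbor Tm, the pyrimidine fraction and the length.  With the
  default coefficients it reproduces the qualitative fact that a PNA/DNA
  duplex melts higher than the corresponding DNA/DNA duplex for the
  pyrimidine-rich oligomers clamp design favours.

Design aims for a clamp Tm well above the 72 degC extension step, as close
to 80 degC as practical; both predicates are evaluated as margins rather
than collapsed into one number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import mean

from Bio.SeqUtils import MeltingTemp as _mt

from .seq_core import expand_degenerate, purine_fraction

__all__ = ["ThermoConfig", "tm_wallace", "tm_dna_nn", "tm_pna", "NN_TABLES"]

#: Named nearest-neighbor parameter sets (Biopython tables).
NN_TABLES = {
    "santalucia1997_unified": _mt.DNA_NN3,  # Allawi & SantaLucia 1997
    "santalucia2004": _mt.DNA_NN4,
    "breslauer1986": _mt.DNA_NN1,
}


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic settings shared across the toolkit.

    monovalent_salt and oligo_concentration are molar; temperatures degC.
    ``degenerate_mode`` picks how a degenerate primer's expansions are
    aggregated: ``max`` (most stable variant — governs blocking feasibility),
    ``min`` or ``mean``.
    """

    nn_parameter_set: str = "santalucia1997_unified"
    monovalent_salt: float = 0.05
    oligo_concentration: float = 250e-9
    pna_coefficients: tuple[float, float, float, float] = (20.79, 0.83, -26.13, 0.44)
    extension_temperature: float = 72.0
    pna_target_tm: float = 80.0
    degenerate_mode: str = "max"

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.oligo_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.extension_temperature >= self.pna_target_tm:
            raise ValueError("extension temperature must lie below the PNA target Tm")
        if self.nn_parameter_set not in NN_TABLES:
            raise ValueError(
                f"unknown NN parameter set {self.nn_parameter_set!r}; "
                f"choose from {sorted(NN_TABLES)}"
            )
        if self.degenerate_mode not in ("max", "min", "mean"):
            raise ValueError("degenerate_mode must be max, min or mean")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, indent=2, sort_keys=True)


DEFAULT_THERMO = ThermoConfig()


def tm_wallace(seq: str) -> float:
    """Wallace rule 2(A+T) + 4(G+C); quick fallback, degC."""
    purine_fraction(seq)  # validation only: ungapped, non-degenerate
    at = sum(ch in "AT" for ch in seq.upper())
    return 2.0 * at + 4.0 * (len(seq) - at)


def _tm_nn_concrete(seq: str, config: ThermoConfig) -> float:
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=NN_TABLES[config.nn_parameter_set],
            Na=config.monovalent_salt * 1000.0,  # mM
            dnac1=config.oligo_concentration * 1e9,  # nM
            dnac2=0.0,
            saltcorr=5,
        )
    )


def tm_dna_nn(seq: str, config: ThermoConfig = DEFAULT_THERMO) -> float:
    """Nearest-neighbor DNA/DNA Tm in degC.

    Degenerate IUPAC bases are resolved by enumerating concrete expansions
    and aggregating per ``config.degenerate_mode`` (default: the most stable
    expansion, which governs whether the strongest variant still anneals).
    """
    if len(seq.replace("-", "")) != len(seq):
        raise ValueError("tm_dna_nn requires an ungapped sequence")
    if len(seq) < 8:
        raise ValueError("nearest-neighbor Tm is unreliable below 8 nt")
    values = [_tm_nn_concrete(s, config) for s in expand_degenerate(seq)]
    if config.degenerate_mode == "max":
        return max(values)
    if config.degenerate_mode == "min":
        return min(values)
    return float(mean(values))


def tm_pna(seq: str, config: ThermoConfig = DEFAULT_THERMO) -> float:
    """PNA/DNA duplex Tm from the sequence-based correlation.

    ``c0 + c1*Tm_NN(seq) + c2*f_pyrimidine + c3*length`` with configurable
    coefficients.  The underlying nearest-neighbor model needs >= 8 nt, so
    that is the effective minimum length; maximum 30 nt.
    """
    n = len(seq)
    if not (8 <= n <= 30):
        raise ValueError("tm_pna supports lengths 8-30 nt")
    f_pyr = 1.0 - purine_fraction(seq)  # validates non-degenerate, ungapped
    c0, c1, c2, c3 = config.pna_coefficients
    return c0 + c1 * tm_dna_nn(seq, config) + c2 * f_pyr + c3 * n
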