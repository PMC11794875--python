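"""Monoisotopic adduct m/z, ppm mass error, and Eyring rate calculators.

These back the desk-verifiable chemistry statements of the analysis: HRMS
confirmation of compound identities via calculated [M+H]+ / [M-H]- m/z and
the relative mass error in ppm, and the transition-state-theory (Eyring)
rate implied by an activation free energy.

Conventions fixed here:

* Monoisotopic masses of the most abundant isotope (CODATA/AME values, u):
  C 12 exactly, H 1.00782503207, N 14.0030740048, O 15.9949146196,
  S 31.97207100, P 30.97376163.
* Protonated/deprotonated adducts add or subtract the mass of a *proton*
  (1.007276467 u), i.e. the electron mass is accounted for, not the neutral
  hydrogen atom mass.
* Printed values are rounded half-up at the conventional precision
  (4 decimals for m/z, 1 decimal for ppm); full precision is available via
  ``precision=None``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import ParameterError, ParseError

MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

PROTON_MASS = 1.007276467

#: Boltzmann constant, J/K (CODATA, exact)
K_B = 1.380649e-23
#: Planck constant, J*s (CODATA, exact)
PLANCK_H = 6.62607015e-34
#: Molar gas constant, J/(mol*K)
R_GAS = 8.31446
#: Thermochemical calorie, J
CAL_TO_J = 4.184

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

ADDUCTS = ("[M+H]+", "[M-H]-", "M")


@dataclass(frozen=True)
class FormulaSpec:
    """A molecular formula as an element -> count map plus net charge."""

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise ParameterError(f"element {element!r} not in the mass table")
            if not isinstance(n, int) or n <= 0:
                raise ParameterError(f"count for {element} must be a positive integer")

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())


def parse_formula(text: str) -> FormulaSpec:
    """Parse a Hill-notation-like formula string, e.g. ``"C13H18N2O3"``.

    An omitted count means 1.  Repeated element symbols are summed.
    Raises :class:`ParseError` naming the character position on any symbol
    outside the built-in mass table or malformed token.
    """
    if not text or not text.strip():
        raise ParseError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ParseError(f"malformed formula token at position {pos} in {text!r}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ParseError(f"unknown element {element!r} at position {pos} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return FormulaSpec(counts=counts)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mono_mz(formula: FormulaSpec | str, adduct: str = "M", precision: int | None = 4) -> float:
    """Monoisotopic m/z of ``formula`` for a supported adduct.

    ``"[M+H]+"`` adds one proton mass, ``"[M-H]-"`` subtracts one, ``"M"``
    returns the neutral monoisotopic mass.  Rounded half-up to ``precision``
    decimals (default 4, the precision HRMS values are conventionally
    printed at); pass ``precision=None`` for the full-precision value.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if adduct not in ADDUCTS:
        raise ParameterError(f"unsupported adduct {adduct!r}; expected one of {ADDUCTS}")
    mass = formula.monoisotopic_mass
    if adduct == "[M+H]+":
        mass += PROTON_MASS
    elif adduct == "[M-H]-":
        mass -= PROTON_MASS
    return _round_half_up(mass, precision) if precision is not None else mass


def ppm_error(observed: float, calculated: float, precision: int | None = 1) -> float:
    """Relative mass error (observed - calculated) / calculated * 1e6, in ppm."""
    if calculated <= 0:
        raise ParameterError("calculated m/z must be positive")
    ppm = (observed - calculated) / calculated * 1e6
    return _round_half_up(ppm, precision) if precision is not None else ppm


@dataclass(frozen=True)
class RateInput:
    """Activation free energy (kcal/mol) and absolute temperature (K)."""

    dg_activation_kcal: float
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise ParameterError("temperature must be positive (kelvin)")


def tst_rate(inp: RateInput) -> float:
    """First-order rate constant from the Eyring equation, s^-1.

    k = (k_B * T / h) * exp(-dG'/(R*T)) with transmission coefficient 1.
    """
    dg_j_per_mol = inp.dg_activation_kcal * 1000.0 * CAL_TO_J
    prefactor = K_B * inp.temperature_k / PLANCK_H
    return prefactor * math.exp(-dg_j_per_mol / (R_GAS * inp.temperature_k))
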