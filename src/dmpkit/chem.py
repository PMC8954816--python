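"""Exact monoisotopic mass arithmetic for small-molecule metabolite work.

Everything downstream (biotransformation annotation, fragment localization,
theoretical m/z tables) is built on four primitives: a molecular-formula
parser, monoisotopic mass summation, protonated-adduct m/z and signed ppm
error.  Atomic masses are pinned constants so that results are
bit-reproducible across environments; reported m/z values round half-up to
4 decimal places (the convention of high-resolution qTOF metabolite tables)
while internal arithmetic keeps full double precision.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "DmpkError",
    "FormulaError",
    "ChainError",
    "ValidationError",
    "ComputationError",
    "ElementalFormula",
    "AdductSpec",
    "M_PLUS_H",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "formula_shift",
    "round_half_up",
]

#: Monoisotopic atomic masses (Da) of the elements this package handles.
#: Pinned to >=6 decimal places; carbon-12 is exactly 12 by definition.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass of a proton (Da), i.e. the hydrogen atom minus one electron.
#: Used for [M+H]+ so that theoretical m/z is electron-corrected.
PROTON_MASS = 1.00727646


class DmpkError(Exception):
    """Base class for all errors raised by this package."""


class FormulaError(DmpkError, ValueError):
    """A molecular-formula string or element count is invalid."""


class ChainError(DmpkError, ValueError):
    """A biotransformation is impossible on the given scaffold."""


class ValidationError(DmpkError, ValueError):
    """Input data or parameters violate a precondition."""


class ComputationError(DmpkError, RuntimeError):
    """A computation has no defined result (e.g. no admissible root)."""


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


_HILL_RANK = {"C": 0, "H": 1}


def _hill_key(symbol: str) -> tuple[int, str]:
    # Hill convention: carbon, hydrogen, then the rest alphabetically.
    return (_HILL_RANK.get(symbol, 2), symbol)


class ElementalFormula(Mapping):
    """Immutable element -> count map with Hill-ordered string rendering.

    Counts must be non-negative; zero-count elements are dropped, so two
    formulas are equal iff their maps are equal.  Instances are hashable and
    usable as dict keys.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None) -> None:
        cleaned: dict[str, int] = {}
        for element, count in dict(counts or {}).items():
            count = int(count)
            if count < 0:
                raise FormulaError(
                    f"negative count for element {element!r}: {count}"
                )
            if count:
                cleaned[element] = cleaned.get(element, 0) + count
        self._counts = {k: cleaned[k] for k in sorted(cleaned, key=_hill_key)}
        self._hash = hash(tuple(self._counts.items()))

    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"ElementalFormula({self._counts!r})"

    def __str__(self) -> str:
        return self.to_string()

    def to_string(self) -> str:
        """Render in Hill order, omitting counts of one (e.g. ``C16H23NO2``)."""
        return "".join(
            f"{el}{n}" if n != 1 else el for el, n in self._counts.items()
        )


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular-formula string into an :class:`ElementalFormula`.

    Underscores and whitespace are stripped first, so published renderings
    such as ``C_16_H_23_NO_2_`` parse identically to ``C16H23NO2``.  An
    element symbol with no trailing digits has an implicit count of one.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    cleaned = re.sub(r"[\s_]+", "", text)
    if not cleaned:
        raise FormulaError(f"empty formula string: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        match = _TOKEN.match(cleaned, pos)
        if match is None:
            raise FormulaError(
                f"unparseable token {cleaned[pos:pos + 4]!r} at position {pos}"
                f" in formula {text!r}"
            )
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASSES:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {text!r}"
            )
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da: sum of count x atomic mass."""
    total = 0.0
    for element, count in formula.items():
        try:
            total += count * MONOISOTOPIC_MASSES[element]
        except KeyError:
            raise FormulaError(
                f"no monoisotopic mass tabulated for element {element!r}"
            ) from None
    return total


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: how many protons are attached and the charge."""

    name: str
    proton_count: int
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValidationError(f"adduct {self.name!r} must have nonzero charge")


#: The protonated molecule observed in positive-mode electrospray.
M_PLUS_H = AdductSpec("[M+H]+", proton_count=1, charge=1)


def adduct_mz(formula: Mapping[str, int], adduct: AdductSpec = M_PLUS_H) -> float:
    """Theoretical m/z of ``formula`` under ``adduct`` (full precision).

    m/z = (M + n_H+ * m_proton) / |z|.  Round with :func:`round_half_up`
    when reporting at 4 decimal places.
    """
    return (
        monoisotopic_mass(formula) + adduct.proton_count * PROTON_MASS
    ) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValidationError(
            f"theoretical m/z must be positive, got {theoretical}"
        )
    return (observed - theoretical) / theoretical * 1e6


def formula_shift(
    formula: Mapping[str, int], delta: Mapping[str, int]
) -> ElementalFormula:
    """Apply a signed element delta (a biotransformation) to a formula.

    Raises :class:`ChainError` if any resulting count would be negative,
    which signals a transformation that is impossible on this scaffold.
    """
    merged = dict(formula)
    for element, change in delta.items():
        new = merged.get(element, 0) + change
        if new < 0:
            raise ChainError(
                f"transformation impossible on this scaffold: element "
                f"{element} count would be {new}"
            )
        merged[element] = new
    return ElementalFormula(merged)
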