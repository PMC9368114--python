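"""Elemental-formula arithmetic and peak annotation.

Monoisotopic masses, adduct m/z values and ppm mass errors for the
singly-charged adducts seen in DART spectra of insect powders, plus
annotation of observed peaks against the bundled marker compound table.

Reported m/z values are rounded half-up to 4 decimals and ppm errors to
1 decimal, matching the conventional presentation of high-resolution data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

from .constants import ADDUCTS, ATOMIC_MASS

__all__ = [
    "FormulaError",
    "AdductSpec",
    "CompoundRecord",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_peak",
    "load_marker_table",
]


class FormulaError(ValueError):
    """Raised for malformed elemental formulas or unknown adducts."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Parameters
    ----------
    text:
        Formula such as ``"C5H9NO2"``; each element symbol is optionally
        followed by an integer count (absent count means 1).

    Returns
    -------
    dict mapping element symbol to a positive count.

    Raises
    ------
    FormulaError
        For an empty string, an unknown element symbol, an explicit zero
        count, or trailing garbage.
    """
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:match.start()]!r} in formula {text!r}"
            )
        symbol, digits = match.group(1), match.group(2)
        if symbol not in ATOMIC_MASS:
            raise FormulaError(f"unknown element {symbol!r} in formula {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {symbol!r} in formula {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in formula {text!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Serialize element counts back to Hill notation (C, H, then A-Z)."""
    if not counts:
        raise FormulaError("empty element counts")
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic neutral mass (Da) of an element-count mapping."""
    if not counts:
        raise FormulaError("empty element counts")
    try:
        return sum(ATOMIC_MASS[e] * n for e, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"unknown element {exc.args[0]!r}") from exc


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AdductSpec:
    """A singly-charged ionization adduct."""

    name: str
    mass_delta: float
    charge_sign: int

    @classmethod
    def from_name(cls, name: str) -> "AdductSpec":
        try:
            delta, sign = ADDUCTS[name]
        except KeyError:
            supported = ", ".join(sorted(ADDUCTS))
            raise FormulaError(
                f"unknown adduct {name!r}; supported adducts: {supported}"
            ) from None
        return cls(name=name, mass_delta=delta, charge_sign=sign)

    @property
    def polarity(self) -> str:
        return "pos" if self.charge_sign > 0 else "neg"


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly-charged adduct of a neutral, rounded to 4 decimals."""
    if neutral_mass <= 0:
        raise FormulaError(f"neutral mass must be positive, got {neutral_mass}")
    spec = adduct if isinstance(adduct, AdductSpec) else AdductSpec.from_name(adduct)
    return round_half_up(neutral_mass + spec.mass_delta, 4)


def ppm_error(observed: float, theoretical: float, decimals: int | None = 1) -> float:
    """Relative mass error (observed - theoretical)/theoretical in ppm.

    By default rounded half-up to 1 decimal, the resolution-independent
    accuracy figure conventionally reported alongside high-resolution
    assignments; pass ``decimals=None`` for the unrounded value.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    value = (observed - theoretical) / theoretical * 1e6
    return value if decimals is None else round_half_up(value, decimals)


@dataclass(frozen=True)
class CompoundRecord:
    """One annotated marker ion: neutral formula + adduct + target species.

    ``status`` is "ok" when ``theoretical_mz`` agrees with the value
    recomputed from the formula and adduct to 4 decimals, else "flagged"
    (the row is retained for annotation/simulation but excluded from
    exact-arithmetic guarantees).
    """

    name: str
    formula: dict[str, int] = field(hash=False)
    adduct: AdductSpec
    theoretical_mz: float
    species: str
    block: str
    status: str = "ok"

    @property
    def polarity(self) -> str:
        return self.adduct.polarity

    @property
    def computed_mz(self) -> float:
        return adduct_mz(monoisotopic_mass(self.formula), self.adduct)


def load_marker_table(path=None) -> list[CompoundRecord]:
    """Load the bundled (or a user-supplied) marker compound table.

    The CSV needs columns name, formula, adduct, species, block,
    theoretical_mz. Each row's theoretical m/z is checked against the
    value recomputed from its formula and adduct; mismatching rows are
    kept but flagged rather than silently accepted.
    """
    import csv

    if path is None:
        source = resources.files("insectprint.data").joinpath("marker_ions.csv")
        fh = source.open("r", encoding="utf-8")
    else:
        fh = open(path, "r", encoding="utf-8")
    records = []
    with fh:
        for row in csv.DictReader(fh):
            formula = parse_formula(row["formula"])
            adduct = AdductSpec.from_name(row["adduct"])
            printed = float(row["theoretical_mz"])
            computed = adduct_mz(monoisotopic_mass(formula), adduct)
            status = "ok" if abs(computed - printed) < 5e-5 else "flagged"
            records.append(
                CompoundRecord(
                    name=row["name"],
                    formula=formula,
                    adduct=adduct,
                    theoretical_mz=printed,
                    species=row["species"],
                    block=row["block"],
                    status=status,
                )
            )
    return records


def annotate_peak(
    mz: float,
    polarity: str,
    tol_ppm: float = 5.0,
    table: list[CompoundRecord] | None = None,
) -> list[tuple[CompoundRecord, float]]:
    """Match an observed m/z against a compound table.

    Returns (record, ppm_error) pairs for records of matching polarity
    within ``tol_ppm``, sorted by absolute mass error (ties broken by
    record name so the result is independent of table row order). An
    empty list means no assignment, which is not an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if polarity not in ("pos", "neg"):
        raise ValueError(f"polarity must be 'pos' or 'neg', got {polarity!r}")
    if table is None:
        table = load_marker_table()
    if not table:
        raise ValueError("annotation table is empty")
    hits = []
    for rec in table:
        if rec.polarity != polarity:
            continue
        err = ppm_error(mz, rec.theoretical_mz)
        if abs(err) <= tol_ppm:
            hits.append((rec, err))
    hits.sort(key=lambda h: (abs(h[1]), h[0].name, h[0].block))
    return hits
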