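"""Sum formulas, isotope tables and natural-abundance isotope patterns.

A compound measured by GC-APCI-MS is described by the sum formula of the
*derivatized* molecule (silylation adds C and Si) together with ``n_bio``,
the number of carbon atoms of biological origin that a tracer such as
[U-13C]glucose can label.  At quadrupole-TOF resolution (~35,000) isotopic
fine structure is not resolved, so isotope patterns are computed on an
integer nominal-mass-shift axis with a spacing of 1.003355 Da (the
12C/13C mass gap).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FormulaError",
    "PatternTruncationError",
    "SumFormula",
    "IsotopeTable",
    "default_isotope_table",
    "parse_formula",
    "monoisotopic_mass",
    "isotopologue_mass",
    "natural_pattern",
    "CARBON_MASS_GAP",
]

#: Mass difference between 13C and 12C in Da; used as the nominal-shift spacing.
CARBON_MASS_GAP = 1.003355

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed or unsupported sum formula."""


class PatternTruncationError(ValueError):
    """Requested pattern length cannot hold the required isotope mass."""


@dataclass(frozen=True)
class SumFormula:
    """Element composition of a derivatized molecule.

    Parameters
    ----------
    elements
        Mapping of element symbol to a non-negative atom count.
    n_bio
        Number of biological carbon atoms (labelable by the tracer);
        must not exceed the total carbon count.
    """

    elements: Mapping[str, int]
    n_bio: int = 0

    def __post_init__(self) -> None:
        elems = {e: int(c) for e, c in self.elements.items() if c != 0}
        for e, c in elems.items():
            if c < 0:
                raise FormulaError(f"negative count for element {e!r}")
        if self.n_bio < 0:
            raise FormulaError("n_bio must be non-negative")
        if self.n_bio > elems.get("C", 0):
            raise FormulaError(
                f"n_bio={self.n_bio} exceeds carbon count {elems.get('C', 0)}"
            )
        object.__setattr__(self, "elements", elems)

    @classmethod
    def parse(cls, text: str, n_bio: int = 0) -> "SumFormula":
        return parse_formula(text, n_bio)

    def __str__(self) -> str:
        return format_formula(self.elements)

    def __add__(self, delta: Mapping[str, int]) -> "SumFormula":
        """Apply an element-count delta (e.g. a fragment's formula change)."""
        out = dict(self.elements)
        for e, d in delta.items():
            out[e] = out.get(e, 0) + d
            if out[e] < 0:
                raise FormulaError(
                    f"delta removes more {e} atoms than present ({self})"
                )
        return SumFormula(out, n_bio=self.n_bio)

    def __sub__(self, delta: Mapping[str, int]) -> "SumFormula":
        return self + {e: -d for e, d in delta.items()}


def parse_formula(text: str, n_bio: int = 0) -> SumFormula:
    """Parse a Hill-notation sum formula such as ``"C6H12O6"``.

    Repeated element tokens are summed.  Unknown element symbols (anything
    outside the default isotope table) raise :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    supported = default_isotope_table().elements
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula token at {text[pos:]!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in supported:
            raise FormulaError(f"unknown element {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise FormulaError(f"malformed formula token at {text[pos:]!r}")
    return SumFormula(counts, n_bio=n_bio)


def format_formula(elements: Mapping[str, int]) -> str:
    """Serialize element counts in Hill order (C, H, then alphabetical)."""
    elems = {e: c for e, c in elements.items() if c}
    order: list[str] = []
    if "C" in elems:
        order.append("C")
        if "H" in elems:
            order.append("H")
    order.extend(sorted(e for e in elems if e not in order))
    return "".join(f"{e}{elems[e] if elems[e] != 1 else ''}" for e in order)


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope data on the nominal-shift axis.

    ``isotopes`` maps an element symbol to a tuple of
    ``(shift, exact_mass, abundance)`` triples; abundances per element sum
    to one.  The shipped default reflects the values relevant for silylated
    metabolites: 13C at 1.07% and 28/29/30-Si at 92.2/4.7/3.1%.
    """

    isotopes: Mapping[str, tuple[tuple[int, float, float], ...]]

    def __post_init__(self) -> None:
        for e, iso in self.isotopes.items():
            total = sum(a for _, _, a in iso)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {e} sum to {total}, not 1")
            if any(s < 0 or a < 0 for s, _, a in iso):
                raise ValueError(f"invalid shift/abundance for {e}")

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.isotopes)

    def monoisotopic_mass(self, element: str) -> float:
        iso = self.isotopes[element]
        return max(iso, key=lambda t: t[2])[1]

    def shift_distribution(self, element: str) -> np.ndarray:
        """Abundance vector indexed by nominal shift for one atom."""
        iso = self.isotopes[element]
        out = np.zeros(max(s for s, _, _ in iso) + 1)
        for s, _, a in iso:
            out[s] += a
        return out

    def with_abundance(self, element: str, shift: int, abundance: float) -> "IsotopeTable":
        """Return a copy with one isotope's abundance replaced.

        The element's most abundant (shift-0) isotope absorbs the change so
        abundances still sum to one; used e.g. to switch 13C between the
        1.07% default and the rounded 1.1% convention.
        """
        iso = list(self.isotopes[element])
        idx = {s: i for i, (s, _, _) in enumerate(iso)}
        if shift not in idx or shift == 0:
            raise ValueError(f"no minor isotope at shift {shift} for {element}")
        old = iso[idx[shift]]
        delta = abundance - old[2]
        s0, m0, a0 = iso[idx[0]]
        iso[idx[shift]] = (old[0], old[1], abundance)
        iso[idx[0]] = (s0, m0, a0 - delta)
        new = dict(self.isotopes)
        new[element] = tuple(iso)
        return IsotopeTable(new)

    def without_minor_isotopes(self, elements: Iterable[str]) -> "IsotopeTable":
        """Collapse the listed elements to their monoisotopic form.

        2H, 15N, 17O/18O and 33S/34S contribute little next to C and Si in
        silylated analytes; this toggle lets results be computed with those
        contributions neglected entirely.
        """
        new = dict(self.isotopes)
        for e in elements:
            mono = max(self.isotopes[e], key=lambda t: t[2])
            new[e] = ((0, mono[1], 1.0),)
        return IsotopeTable(new)


def _load_default_table() -> IsotopeTable:
    iso: dict[str, list[tuple[int, float, float]]] = {}
    ref = resources.files("midfit.data").joinpath("isotopes.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            iso.setdefault(row["element"], []).append(
                (int(row["shift"]), float(row["mass"]), float(row["abundance"]))
            )
    return IsotopeTable({e: tuple(sorted(v)) for e, v in iso.items()})


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """The isotope table shipped with the package (see ``data/isotopes.tsv``)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _load_default_table()
    return _DEFAULT_TABLE


def monoisotopic_mass(f: SumFormula, table: IsotopeTable | None = None) -> float:
    """Sum of most-abundant-isotope exact masses, in Da."""
    table = table or default_isotope_table()
    return sum(c * table.monoisotopic_mass(e) for e, c in f.elements.items())


def isotopologue_mass(f: SumFormula, i: int, table: IsotopeTable | None = None) -> float:
    """Exact mass of isotopologue Mi: the monoisotopic mass plus ``i`` carbon gaps."""
    return monoisotopic_mass(f, table) + i * CARBON_MASS_GAP


def _self_convolve(dist: np.ndarray, count: int) -> np.ndarray:
    """``count``-fold convolution of a single-atom shift distribution."""
    result = np.array([1.0])
    base = dist
    while count:
        if count & 1:
            result = np.convolve(result, base)
        count >>= 1
        if count:
            base = np.convolve(base, base)
    return result


def natural_pattern(
    f: SumFormula,
    exclude_bio_carbons: int = 0,
    table: IsotopeTable | None = None,
    max_shift: int | None = None,
    tail_tol: float | None = 1e-6,
) -> np.ndarray:
    """Natural-abundance isotope pattern on the nominal-shift axis.

    The pattern is the discrete convolution of the per-atom isotope shift
    distributions over all atoms *except* ``exclude_bio_carbons`` biological
    carbons — those are fixed as 13C under the labelling hypothesis and only
    shift the pattern's base position, which is bookkept by the caller.

    Parameters
    ----------
    f
        Sum formula of the (derivatized) species.
    exclude_bio_carbons
        Number of biological carbons assumed 13C-labeled; 0..``f.n_bio``.
    max_shift
        Highest shift kept; defaults to ``f.n_bio + 4``.  The truncated
        pattern is renormalized to sum one.
    tail_tol
        If the truncated tail mass exceeds this, raise
        :class:`PatternTruncationError`; pass ``None`` to truncate silently.

    Returns
    -------
    numpy.ndarray of length ``max_shift + 1`` summing to one.
    """
    table = table or default_isotope_table()
    if not 0 <= exclude_bio_carbons <= f.n_bio:
        raise ValueError(
            f"exclude_bio_carbons={exclude_bio_carbons} outside 0..{f.n_bio}"
        )
    if max_shift is None:
        max_shift = f.n_bio + 4
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")

    pattern = np.array([1.0])
    for e, c in f.elements.items():
        if e == "C":
            c -= exclude_bio_carbons
        if c == 0:
            continue
        pattern = np.convolve(pattern, _self_convolve(table.shift_distribution(e), c))

    tail = float(pattern[max_shift + 1 :].sum())
    if tail_tol is not None and tail > tail_tol:
        raise PatternTruncationError(
            f"max_shift={max_shift} drops {tail:.3e} of the pattern mass"
        )
    out = np.zeros(max_shift + 1)
    head = pattern[: max_shift + 1]
    out[: head.size] = head
    return out / out.sum()
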