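"""Shared fixtures and independent brute-force oracles.

The pattern oracle enumerates isotope placements per element with exact
multinomial weights — a deliberately different algorithm from the
binary-exponentiation convolution used by the package.
"""

from __future__ import annotations

import itertools
from math import comb, prod

import numpy as np
import pytest

from midfit.formula import (
    IsotopeTable,
    SumFormula,
    default_isotope_table,
    parse_formula,
)


def _compositions(total: int, parts: int):
    """All tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def _multinomial(total: int, parts: tuple[int, ...]) -> int:
    out, left = 1, total
    for p in parts:
        out *= comb(left, p)
        left -= p
    return out


def brute_force_pattern(
    elements: dict[str, int],
    table: IsotopeTable | None = None,
    max_shift: int | None = None,
) -> np.ndarray:
    """Isotope pattern by exhaustive enumeration of isotope count vectors."""
    table = table or default_isotope_table()
    dist = {0: 1.0}
    for e, count in elements.items():
        if count == 0:
            continue
        iso = table.isotopes[e]
        shifts = [s for s, _, _ in iso]
        abund = [a for _, _, a in iso]
        edist: dict[int, float] = {}
        for parts in _compositions(count, len(iso)):
            p = _multinomial(count, parts) * prod(a**k for a, k in zip(abund, parts))
            s = sum(sh * k for sh, k in zip(shifts, parts))
            edist[s] = edist.get(s, 0.0) + p
        new: dict[int, float] = {}
        for s1, p1 in dist.items():
            for s2, p2 in edist.items():
                new[s1 + s2] = new.get(s1 + s2, 0.0) + p1 * p2
        dist = new
    top = max(dist) if max_shift is None else max_shift
    out = np.zeros(top + 1)
    for s, p in dist.items():
        if s <= top:
            out[s] = p
    return out / out.sum()


@pytest.fixture(scope="session")
def glucose() -> SumFormula:
    return parse_formula("C6H12O6", 6)


@pytest.fixture(scope="session")
def glucose_tms() -> SumFormula:
    """Glucose with five trimethylsilyl groups (the GC-ready derivative)."""
    return parse_formula("C21H52O6Si5", 6)


@pytest.fixture(scope="session")
def lactic_tms() -> SumFormula:
    """Lactic acid with two trimethylsilyl groups, three biological carbons."""
    return parse_formula("C9H22O3Si2", 3)
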