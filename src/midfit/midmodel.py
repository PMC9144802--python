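"""Fragment definitions and reconstruction of superimposed spectra.

Soft APCI ionization of a silylated metabolite produces a mixture of ion
species: mostly [M+H]+, with proton/hydrogen losses ([M]+, [M-H]+) and,
for carbonic acids, a water-adduct/methane-loss species [M+H3O-CH4]+ that
falls into the M+2 bin of [M+H]+ at qTOF resolution.  The measured
intensity vector (rawMID) is therefore an overlay of the compound's label
distribution (corMID), shifted per fragment and blurred by natural isotope
abundance.  This module builds that forward model: recMID(corMID, r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formula import (
    IsotopeTable,
    SumFormula,
    default_isotope_table,
    natural_pattern,
)

__all__ = [
    "Fragment",
    "BUILTIN_FRAGMENTS",
    "fragment_by_name",
    "Axis",
    "default_axis",
    "SpectrumVector",
    "check_simplex",
    "fragment_matrix",
    "reconstruct",
]

SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class Fragment:
    """One in-source ion species.

    ``offset`` is the integer nominal-mass shift of the species' M0 peak
    relative to [M+H]+; ``delta`` is its element-count change relative to
    [M+H]+.  For [M+H3O-CH4]+ the lost CH4 carbon is a silylation methyl,
    not biological carbon, so the label axis is unaffected.
    """

    name: str
    offset: int
    delta: Mapping[str, int] = field(default_factory=dict)

    def ion_formula(self, molecule: SumFormula) -> SumFormula:
        """Elemental composition of this species for the given molecule.

        If the fragment removes derivatization carbon from a molecule that
        has none to spare (an underivatized formula), the labelable count
        is clamped to the carbons that remain.
        """
        counts = dict(molecule.elements)
        counts["H"] = counts.get("H", 0) + 1
        for e, d in self.delta.items():
            counts[e] = counts.get(e, 0) + d
            if counts[e] < 0:
                raise ValueError(
                    f"fragment {self.name} removes more {e} than {molecule} has"
                )
        return SumFormula(counts, n_bio=min(molecule.n_bio, counts.get("C", 0)))


BUILTIN_FRAGMENTS: tuple[Fragment, ...] = (
    Fragment("[M-H]+", -2, {"H": -2}),
    Fragment("[M]+", -1, {"H": -1}),
    Fragment("[M+H]+", 0, {}),
    Fragment("[M+H3O-CH4]+", +2, {"C": -1, "H": -2, "O": +1}),
)


def fragment_by_name(name: str, fragments: Sequence[Fragment] = BUILTIN_FRAGMENTS) -> Fragment:
    for frag in fragments:
        if frag.name == name:
            return frag
    raise KeyError(f"unknown fragment {name!r}")


@dataclass(frozen=True)
class Axis:
    """Consecutive nominal-mass positions, ``start`` relative to [M+H]+."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("axis length must be >= 1")

    @property
    def stop(self) -> int:
        return self.start + self.length - 1

    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


def default_axis(n: int) -> Axis:
    """Axis from [M-H]+ to [M+H]+ + n + 2, covering all built-in fragments."""
    return Axis(-2, n + 5)


@dataclass(frozen=True)
class SpectrumVector:
    """Intensities at consecutive nominal positions (rawMID / recMID)."""

    values: np.ndarray
    start_offset: int = -2

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("spectrum must be a non-empty 1-d vector")
        object.__setattr__(self, "values", vals)

    @property
    def axis(self) -> Axis:
        return Axis(self.start_offset, self.values.size)


def check_simplex(vec: np.ndarray, name: str = "vector", tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Validate entries in [0, 1] and unit sum; returns the array."""
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise ValueError(f"{name} must be 1-d")
    if np.any(vec < -tol) or np.any(vec > 1 + tol):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if abs(vec.sum() - 1.0) > tol:
        raise ValueError(f"{name} must sum to 1 (got {vec.sum()!r})")
    return vec


def fragment_matrix(
    f: SumFormula,
    n: int,
    fragment: Fragment,
    axis: Axis,
    apply_abundance: bool = True,
    table: IsotopeTable | None = None,
    natural_in_unlabeled: bool = True,
) -> np.ndarray:
    """Column-stochastic matrix mapping corMID to this fragment's spectrum.

    Column ``j`` holds the natural-abundance pattern of isotopologue Mj of
    the fragment, based at axis position ``offset + j``.  With
    ``apply_abundance=False`` columns are unit vectors (the idealized
    textbook picture).  ``natural_in_unlabeled=False`` suppresses natural
    13C on the remaining biological carbons of labeled isotopologues, i.e.
    every column uses the fully-excluded pattern.

    Each column is renormalized over the axis so the matrix conserves
    intensity even when a pattern tail is clipped at the axis end.
    """
    table = table or default_isotope_table()
    if n < 0:
        raise ValueError("n must be >= 0")
    ion = fragment.ion_formula(f) if apply_abundance else None
    A = np.zeros((axis.length, n + 1))
    for j in range(n + 1):
        base = fragment.offset + j
        if base < axis.start or base > axis.stop:
            raise ValueError(
                f"fragment {fragment.name} isotopologue M{j} at position {base} "
                f"outside axis [{axis.start}, {axis.stop}]"
            )
        room = axis.stop - base
        if apply_abundance:
            excl = n if natural_in_unlabeled is False else j
            pat = natural_pattern(
                ion, exclude_bio_carbons=min(excl, ion.n_bio),
                table=table, max_shift=room, tail_tol=None,
            )
        else:
            pat = np.zeros(room + 1)
            pat[0] = 1.0
        A[base - axis.start : base - axis.start + pat.size, j] = pat
    return A


def reconstruct(
    mid: np.ndarray,
    n: int,
    r: np.ndarray,
    f: SumFormula,
    fragments: Sequence[Fragment] = BUILTIN_FRAGMENTS,
    axis: Axis | None = None,
    apply_abundance: bool = True,
    table: IsotopeTable | None = None,
    natural_in_unlabeled: bool = True,
) -> SpectrumVector:
    """Forward model: superimpose fragment-shifted label distributions.

    recMID = sum_f r_f * A_f @ corMID, where A_f is
    :func:`fragment_matrix` for fragment ``f``.  Because every A_f is
    column-stochastic and ``mid`` and ``r`` are simplex vectors, the result
    sums to one and is linear in both ``mid`` and ``r``.
    """
    axis = axis or default_axis(n)
    mid = check_simplex(mid, "corMID")
    if mid.size != n + 1:
        raise ValueError(f"corMID must have n+1={n + 1} entries, got {mid.size}")
    r = check_simplex(r, "fragment vector r")
    if r.size != len(fragments):
        raise ValueError(f"r must have {len(fragments)} entries, got {r.size}")
    rec = np.zeros(axis.length)
    for frag, weight in zip(fragments, r):
        if weight == 0.0:
            continue
        A = fragment_matrix(
            f, n, frag, axis, apply_abundance=apply_abundance,
            table=table, natural_in_unlabeled=natural_in_unlabeled,
        )
        rec += weight * (A @ mid)
    return SpectrumVector(rec / rec.sum(), start_offset=axis.start)
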