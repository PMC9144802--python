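"""Synthetic rawMID generation for testing every fitting path end to end.

The generator runs the forward model (fragment superposition plus natural
abundance) and perturbs it with a simple detector-noise model: lognormal
multiplicative noise per mass position (given as a coefficient of
variation) plus a uniform additive baseline floor.  Replicates share the
true fragment distribution, mirroring the observation that in-source
fragmentation is stable within a measurement series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fit import as_fragment_vector
from .formula import IsotopeTable, SumFormula
from .midmodel import (
    BUILTIN_FRAGMENTS,
    Axis,
    Fragment,
    SpectrumVector,
    check_simplex,
    default_axis,
    reconstruct,
)

__all__ = ["SimSpec", "simulate_rawmid"]


@dataclass
class SimSpec:
    """Ground truth and noise model for one simulated compound.

    noise_cv
        Coefficient of variation of the multiplicative lognormal noise,
        default 2% — a typical run-to-run intensity scatter for well
        integrated GC-APCI peaks.
    noise_floor
        Scale of the uniform additive baseline relative to the total
        signal, default 1e-4.
    """

    formula: SumFormula
    cormid: Sequence[float]
    r: Mapping[str, float] | Sequence[float]
    n: int | None = None
    noise_cv: float = 0.02
    noise_floor: float = 1e-4
    n_replicates: int = 1
    seed: int | None = None
    fragments: tuple[Fragment, ...] = BUILTIN_FRAGMENTS
    axis: Axis | None = None
    apply_abundance: bool = True
    isotope_table: IsotopeTable | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n is None:
            self.n = self.formula.n_bio
        self.cormid = check_simplex(np.asarray(self.cormid, dtype=float), "corMID")
        if self.cormid.size != self.n + 1:
            raise ValueError(f"corMID must have n+1={self.n + 1} entries")
        self.r = as_fragment_vector(self.r, self.fragments)


def simulate_rawmid(spec: SimSpec) -> list[SpectrumVector]:
    """Simulate ``n_replicates`` rawMID vectors for one compound.

    Each replicate is the noiseless reconstruction times lognormal noise
    (unit mean, CV ``noise_cv``) plus a uniform baseline, clipped at zero
    and normalized to unit sum.  A given seed fixes the entire stream.
    """
    axis = spec.axis or default_axis(spec.n)
    clean = reconstruct(
        spec.cormid,
        spec.n,
        spec.r,
        spec.formula,
        fragments=spec.fragments,
        axis=axis,
        apply_abundance=spec.apply_abundance,
        table=spec.isotope_table,
    ).values
    rng = np.random.default_rng(spec.seed)
    out = []
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    for _ in range(spec.n_replicates):
        vals = clean.copy()
        if spec.noise_cv > 0:
            vals = vals * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=vals.size)
        if spec.noise_floor > 0:
            vals = vals + spec.noise_floor * rng.uniform(0.0, 1.0, size=vals.size)
        vals = np.clip(vals, 0.0, None)
        out.append(SpectrumVector(vals / vals.sum(), start_offset=axis.start))
    return out
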