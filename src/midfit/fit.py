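"""Greedy nested grid-search estimation of corMID and the fragment vector.

The estimator minimizes the residual sum of squares

    err = sum_i (rawMID_i - recMID_i)^2

over the simplex-constrained label distribution corMID (length n+1) and
fragment distribution r (one entry per configured in-source species).  The
search is a deterministic pattern search: a coarse simplex grid (step 0.5)
seeds the solution, then candidate moves around the incumbent are tested
with a step size that shrinks whenever no move improves, down to
``step_min``.  When both corMID and r are free the search is nested —
every corMID hypothesis is scored with its own best-fitting r.

Superimposed spectra can be genuinely ambiguous (e.g. a pure M1 signal
seen through [M]+ is indistinguishable from a pure M0 signal seen through
[M+H]+).  Fixing either vector makes the problem uniquely solvable; when
both are free, an optional penalty inflates err for solutions with little
[M+H]+, and exact ties are broken toward the largest [M+H]+ share.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formula import IsotopeTable, SumFormula
from .midmodel import (
    BUILTIN_FRAGMENTS,
    Axis,
    Fragment,
    SpectrumVector,
    check_simplex,
    fragment_matrix,
)

__all__ = [
    "FitError",
    "FitOptions",
    "FitResult",
    "residual",
    "simplex_grid",
    "as_fragment_vector",
    "fit_cormid",
]


class FitError(ValueError):
    """Invalid input to, or failure of, the corMID fit."""


def residual(raw: SpectrumVector | np.ndarray, rec: SpectrumVector | np.ndarray) -> float:
    """Residual sum of squares between two spectra on a common axis."""
    if isinstance(raw, SpectrumVector) and isinstance(rec, SpectrumVector):
        if raw.start_offset != rec.start_offset or raw.values.size != rec.values.size:
            raise FitError("spectra are not on a common axis")
    a = raw.values if isinstance(raw, SpectrumVector) else np.asarray(raw, dtype=float)
    b = rec.values if isinstance(rec, SpectrumVector) else np.asarray(rec, dtype=float)
    if a.shape != b.shape:
        raise FitError("spectra are not on a common axis")
    d = a - b
    return float(d @ d)


def simplex_grid(dim: int, step: float) -> np.ndarray:
    """All vectors with entries that are multiples of ``step`` summing to 1.

    ``step`` must divide 1.  For ``dim=3, step=0.5`` this is the classic
    six-vector seed set {1,0,0}, {0,1,0}, {0,0,1}, {.5,.5,0}, {.5,0,.5},
    {0,.5,.5}.  Rows are in a fixed deterministic order.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    q = round(1.0 / step)
    if q < 1 or abs(1.0 / step - q) > 1e-9:
        raise ValueError(f"step={step} must divide 1")
    rows = []
    for bars in itertools.combinations(range(q + dim - 1), dim - 1):
        prev = -1
        row = []
        for b in (*bars, q + dim - 1):
            row.append(b - prev - 1)
            prev = b
        rows.append(row)
    return np.asarray(rows, dtype=float) / q


def as_fragment_vector(
    value: Mapping[str, float] | Sequence[float] | np.ndarray,
    fragments: Sequence[Fragment] = BUILTIN_FRAGMENTS,
) -> np.ndarray:
    """Coerce a dict keyed by fragment name (or a sequence) to a simplex vector."""
    if isinstance(value, Mapping):
        names = [fr.name for fr in fragments]
        for key in value:
            if key not in names:
                raise FitError(f"unknown fragment {key!r}; expected one of {names}")
        vec = np.array([float(value.get(nm, 0.0)) for nm in names])
    else:
        vec = np.asarray(value, dtype=float)
        if vec.size != len(fragments):
            raise FitError(
                f"fragment vector has {vec.size} entries for {len(fragments)} fragments"
            )
    return check_simplex(vec, "fragment vector r")


@dataclass
class FitOptions:
    """Tuning knobs of the estimator.

    fixed_r / fixed_mid
        Hold one side of the problem fixed (mutually exclusive); the other
        is then uniquely determined by the data.
    penalty
        λ ≥ 0; scores candidates by ``err * (1 + λ·(1 − r_[M+H]+))`` so
        [M+H]+-poor solutions are disfavored.  Off (0) by default.
    step_init, step_shrink, step_min
        Grid-refinement schedule; the final round uses exactly ``step_min``.
    fragments
        In-source species considered; restrict e.g. to drop the acid-only
        [M+H3O-CH4]+ species and shrink the search space.
    n_starts
        Number of coarse-grid candidates refined independently in the
        joint search (guards against local minima; deterministic).
    """

    fixed_r: Mapping[str, float] | Sequence[float] | None = None
    fixed_mid: Sequence[float] | None = None
    penalty: float = 0.0
    step_init: float = 0.5
    step_shrink: float = 0.5
    step_min: float = 1e-3
    fragments: tuple[Fragment, ...] = BUILTIN_FRAGMENTS
    apply_abundance: bool = True
    natural_in_unlabeled: bool = True
    n_starts: int = 3
    tie_tol: float = 1e-12
    ambiguity_tol: float = 1e-9
    isotope_table: IsotopeTable | None = None

    def __post_init__(self) -> None:
        if self.fixed_r is not None and self.fixed_mid is not None:
            raise FitError("fixed_r and fixed_mid are mutually exclusive")
        if self.penalty < 0:
            raise FitError("penalty must be >= 0")
        if not (0 < self.step_shrink < 1):
            raise FitError("step_shrink must be in (0, 1)")
        if not (0 < self.step_min <= self.step_init):
            raise FitError("need 0 < step_min <= step_init")
        offsets = [fr.offset for fr in self.fragments]
        if len(set(offsets)) != len(offsets):
            raise FitError("fragment offsets must be unique")


@dataclass(frozen=True)
class FitResult:
    """Outcome of :func:`fit_cormid`."""

    cormid: np.ndarray
    r: np.ndarray
    fragments: tuple[Fragment, ...]
    err: float
    recmid: SpectrumVector
    n_iterations: int
    ambiguity_flag: bool

    @property
    def r_dict(self) -> dict[str, float]:
        return {fr.name: float(v) for fr, v in zip(self.fragments, self.r)}

    @property
    def m0(self) -> float:
        return float(self.cormid[0])


def _step_schedule(opts: FitOptions) -> list[float]:
    steps: list[float] = []
    s = opts.step_init * opts.step_shrink
    while s > opts.step_min * (1 + 1e-12):
        steps.append(s)
        s *= opts.step_shrink
    steps.append(opts.step_min)
    return steps


def _neighbors(x: np.ndarray, step: float) -> np.ndarray:
    """Incumbent plus per-coordinate ± moves (renormalized) and pairwise
    mass transfers, deduplicated in a fixed order."""
    cands: dict[tuple, np.ndarray] = {tuple(np.round(x, 12)): x}

    def add(v: np.ndarray) -> None:
        cands.setdefault(tuple(np.round(v, 12)), v)

    d = x.size
    for i in range(d):
        up = x.copy()
        up[i] = min(up[i] + step, 1.0)
        add(up / up.sum())
        if x[i] > 0:
            dn = x.copy()
            dn[i] = max(dn[i] - step, 0.0)
            s = dn.sum()
            if s > 0:
                add(dn / s)
    for i in range(d):
        for j in range(d):
            if i == j or x[j] <= 0:
                continue
            t = min(step, x[j])
            tr = x.copy()
            tr[j] -= t
            tr[i] = min(tr[i] + t, 1.0)
            add(tr)
    return np.array(list(cands.values()))


def _select(pen: np.ndarray, rmh: np.ndarray | None, tie_tol: float) -> int:
    """Lowest penalized err; ties broken toward the largest [M+H]+ share,
    then toward the earliest candidate (deterministic)."""
    best = float(pen.min())
    idx = np.flatnonzero(pen <= best + tie_tol)
    if rmh is not None and idx.size > 1:
        sub = rmh[idx]
        idx = idx[sub >= sub.max() - 1e-12]
    return int(idx[0])


def fit_cormid(
    raw: SpectrumVector,
    f: SumFormula,
    n: int | None = None,
    opts: FitOptions | None = None,
) -> FitResult:
    """Estimate corMID (and, unless fixed, the fragment vector r) from rawMID.

    The raw spectrum is preprocessed by clipping negative intensities to
    zero and normalizing to unit sum; ``err`` always refers to that scale.
    """
    opts = opts or FitOptions()
    if n is None:
        n = f.n_bio
    if n < 0:
        raise FitError("n must be >= 0")
    vals = np.asarray(raw.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FitError("rawMID contains non-finite intensities")
    if vals.size < n + 1:
        raise FitError(f"rawMID has {vals.size} entries; need at least n+1={n + 1}")
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise FitError("rawMID is all zero")
    y = vals / total

    frags = tuple(opts.fragments)
    axis = raw.axis
    mats = [
        fragment_matrix(
            f, n, fr, axis,
            apply_abundance=opts.apply_abundance,
            table=opts.isotope_table,
            natural_in_unlabeled=opts.natural_in_unlabeled,
        )
        for fr in frags
    ]
    k = len(frags)
    mh = next((i for i, fr in enumerate(frags) if fr.name == "[M+H]+"), None)
    lam = opts.penalty
    tie = opts.tie_tol
    n_rounds = 0

    def penalize(errs: np.ndarray, rvecs: np.ndarray) -> np.ndarray:
        if lam > 0 and mh is not None:
            return errs * (1.0 + lam * (1.0 - rvecs[:, mh]))
        return errs

    fixed_r = None if opts.fixed_r is None else as_fragment_vector(opts.fixed_r, frags)
    fixed_mid = None
    if opts.fixed_mid is not None:
        fixed_mid = check_simplex(np.asarray(opts.fixed_mid, dtype=float), "corMID")
        if fixed_mid.size != n + 1:
            raise FitError(f"fixed_mid must have n+1={n + 1} entries")

    # ---- inner problem: best r for a given corMID hypothesis -------------
    def best_r(mid: np.ndarray) -> tuple[np.ndarray, float, float, int]:
        nonlocal n_rounds
        cols = np.column_stack([A @ mid for A in mats])  # axis × k

        def obj(R: np.ndarray) -> np.ndarray:
            d = y[None, :] - R @ cols.T
            return np.einsum("ij,ij->i", d, d)

        if fixed_r is not None:
            e = float(obj(fixed_r[None])[0])
            n_rounds += 1
            return fixed_r, e, float(penalize(np.array([e]), fixed_r[None])[0]), 1

        pool = simplex_grid(k, opts.step_init)
        errs = obj(pool)
        pens = penalize(errs, pool)
        n_rounds += 1
        ties = int(np.sum(pens <= pens.min() + opts.ambiguity_tol))
        i = _select(pens, pool[:, mh] if mh is not None else None, tie)
        x, cur_err, cur_pen = pool[i], float(errs[i]), float(pens[i])
        for step in _step_schedule(opts):
            for _ in range(200):
                cands = _neighbors(x, step)
                errs = obj(cands)
                pens = penalize(errs, cands)
                n_rounds += 1
                j = _select(pens, cands[:, mh] if mh is not None else None, tie)
                moved = False
                if pens[j] < cur_pen - tie:
                    moved = True
                elif pens[j] <= cur_pen + tie and mh is not None:
                    if cands[j, mh] > x[mh] + 1e-12:
                        moved = True
                if not moved:
                    break
                x, cur_err, cur_pen = cands[j], float(errs[j]), float(pens[j])
        return x, cur_err, cur_pen, ties

    # ---- fixed-mid mode: only r is searched ------------------------------
    if fixed_mid is not None:
        r, err, _, ties = best_r(fixed_mid)
        return _finalize(y, fixed_mid, r, frags, mats, axis, n_rounds, ties >= 2)

    # ---- fixed-r mode: only corMID is searched (fully vectorized) --------
    if fixed_r is not None:
        B = sum(w * A for w, A in zip(fixed_r, mats))

        def obj_m(Ms: np.ndarray) -> np.ndarray:
            d = y[None, :] - Ms @ B.T
            return np.einsum("ij,ij->i", d, d)

        pool = simplex_grid(n + 1, opts.step_init)
        errs = obj_m(pool)
        n_rounds += 1
        ties = int(np.sum(errs <= errs.min() + opts.ambiguity_tol))
        order = np.argsort(errs, kind="stable")[: opts.n_starts]
        best_x, best_err = None, np.inf
        for i0 in order:
            x, cur = pool[i0], float(errs[i0])
            for step in _step_schedule(opts):
                for _ in range(200):
                    cands = _neighbors(x, step)
                    e = obj_m(cands)
                    n_rounds += 1
                    j = int(np.argmin(e))
                    if e[j] < cur - tie:
                        x, cur = cands[j], float(e[j])
                    else:
                        break
            if cur < best_err - tie:
                best_x, best_err = x, cur
        return _finalize(y, best_x, fixed_r, frags, mats, axis, n_rounds, ties >= 2)

    # ---- joint mode: nested search, corMID outer, r inner ----------------
    cache: dict[tuple, tuple[np.ndarray, float, float]] = {}

    def eval_mid(mid: np.ndarray) -> tuple[np.ndarray, float, float]:
        key = tuple(np.round(mid, 12))
        hit = cache.get(key)
        if hit is None:
            r, err, pen, _ = best_r(mid)
            hit = (r, err, pen)
            cache[key] = hit
        return hit

    pool = simplex_grid(n + 1, opts.step_init)
    coarse = [eval_mid(m) for m in pool]
    pens = np.array([c[2] for c in coarse])
    rmhs = (
        np.array([c[0][mh] for c in coarse]) if mh is not None else None
    )
    ties = int(np.sum(pens <= pens.min() + opts.ambiguity_tol))
    order = sorted(
        range(len(pool)),
        key=lambda i: (pens[i], -(rmhs[i] if rmhs is not None else 0.0), i),
    )[: opts.n_starts]

    best_tuple = None  # (pen, -rmh) for comparison
    best_state = None  # (mid, r, err)
    for i0 in order:
        x = pool[i0]
        r, err, pen = coarse[i0]
        for step in _step_schedule(opts):
            for _ in range(200):
                cands = _neighbors(x, step)
                evals = [eval_mid(c) for c in cands]
                cpens = np.array([e[2] for e in evals])
                crmh = (
                    np.array([e[0][mh] for e in evals]) if mh is not None else None
                )
                j = _select(cpens, crmh, tie)
                moved = False
                if cpens[j] < pen - tie:
                    moved = True
                elif cpens[j] <= pen + tie and mh is not None:
                    if evals[j][0][mh] > r[mh] + 1e-12:
                        moved = True
                if not moved:
                    break
                x, (r, err, pen) = cands[j], evals[j]
        # Degenerate spectra admit whole families of near-exact solutions
        # (label shifted up, fragments shifted down).  Residual differences
        # below the search resolution (~step_min^2) cannot rank such
        # branches meaningfully, so within that tolerance the start with
        # the larger [M+H]+ share wins — the dominant species in practice.
        sel_tol = max(tie, opts.step_min**2)
        cand_key = (pen, -(r[mh] if mh is not None else 0.0))
        better = best_tuple is None or cand_key[0] < best_tuple[0] - sel_tol
        if not better and best_tuple is not None:
            better = cand_key[0] <= best_tuple[0] + sel_tol and cand_key[1] < best_tuple[1] - 1e-12
        if better:
            best_tuple, best_state = cand_key, (x, r, err)
    mid, r, _ = best_state
    return _finalize(y, mid, r, frags, mats, axis, n_rounds, ties >= 2)


def _finalize(
    y: np.ndarray,
    mid: np.ndarray,
    r: np.ndarray,
    frags: tuple[Fragment, ...],
    mats: list[np.ndarray],
    axis: Axis,
    n_rounds: int,
    ambiguous: bool,
) -> FitResult:
    rec = sum(w * (A @ mid) for w, A in zip(r, mats))
    rec = rec / rec.sum()
    err = residual(y, rec)
    return FitResult(
        cormid=np.clip(mid, 0.0, 1.0),
        r=np.clip(r, 0.0, 1.0),
        fragments=frags,
        err=err,
        recmid=SpectrumVector(rec, start_offset=axis.start),
        n_iterations=n_rounds,
        ambiguity_flag=ambiguous,
    )
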