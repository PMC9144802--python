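"""Delimited-table input/output and the two-stage calibration workflow.

The on-disk format is a wide delimited table (comma or tab, by file
suffix) with one row per nominal-mass position of one compound:

    compound,formula,n_bio,offset,S1,S2,...
    Gln,C20H49N2O3Si3,5,-2,12.1,10.9,...
    Gln,C20H49N2O3Si3,5,-1,...

``offset`` is the position relative to [M+H]+ and must be consecutive
within a compound; the remaining columns are per-sample intensities.

The two-stage workflow mirrors routine tracer studies: on unlabeled
control samples the label distribution is known (M0 = 100%), so the
fragment distribution r can be estimated per compound; the per-compound
median r is then held fixed while corMIDs are fitted in labeled samples.
A QC flag marks compounds whose controls do not correct to M0 >= 95%
when fitted freely — in practice a sign of spectral impurity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fit import FitError, FitOptions, FitResult, fit_cormid
from .formula import FormulaError, SumFormula, parse_formula
from .midmodel import BUILTIN_FRAGMENTS, Fragment, SpectrumVector

__all__ = [
    "TableError",
    "IntensityTable",
    "read_table",
    "write_table",
    "Calibration",
    "correct_table",
    "calibrate",
    "calibrate_then_correct",
    "write_results",
    "M0_QC_THRESHOLD",
]

logger = logging.getLogger("midfit")

META_COLUMNS = ["compound", "formula", "n_bio", "offset"]

#: Controls whose freely fitted M0 falls below this fraction are flagged.
M0_QC_THRESHOLD = 0.95


class TableError(ValueError):
    """Malformed intensity or result table."""


@dataclass(frozen=True)
class IntensityTable:
    """Per-compound intensity matrices (mass positions × samples)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _validate(self.data))

    @property
    def samples(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.data["compound"]))

    def formula_of(self, compound: str) -> SumFormula:
        block = self._block(compound)
        return parse_formula(
            str(block["formula"].iloc[0]), int(block["n_bio"].iloc[0])
        )

    def spectrum(self, compound: str, sample: str) -> SpectrumVector:
        block = self._block(compound)
        if sample not in self.samples:
            raise TableError(f"unknown sample {sample!r}")
        return SpectrumVector(
            block[sample].to_numpy(dtype=float),
            start_offset=int(block["offset"].iloc[0]),
        )

    def _block(self, compound: str) -> pd.DataFrame:
        block = self.data[self.data["compound"] == compound]
        if block.empty:
            raise TableError(f"unknown compound {compound!r}")
        return block.sort_values("offset")

    @classmethod
    def from_spectra(
        cls,
        compound: str,
        formula: SumFormula,
        spectra: Sequence[SpectrumVector],
        sample_names: Sequence[str] | None = None,
    ) -> "IntensityTable":
        if sample_names is None:
            sample_names = [f"S{i + 1}" for i in range(len(spectra))]
        first = spectra[0]
        rows = {
            "compound": compound,
            "formula": str(formula),
            "n_bio": formula.n_bio,
            "offset": first.axis.positions(),
        }
        frame = pd.DataFrame(rows)
        for name, sv in zip(sample_names, spectra):
            if sv.start_offset != first.start_offset or sv.values.size != first.values.size:
                raise TableError("all replicates must share one axis")
            frame[name] = sv.values
        return cls(frame)

    def merged_with(self, other: "IntensityTable") -> "IntensityTable":
        if self.samples != other.samples:
            raise TableError("tables have different sample sets")
        return IntensityTable(
            pd.concat([self.data, other.data], ignore_index=True)
        )


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise TableError(f"missing required columns: {missing}")
    frame = frame.reset_index(drop=True).copy()
    samples = [c for c in frame.columns if c not in META_COLUMNS]
    if not samples:
        raise TableError("table has no sample columns")
    if len(set(samples)) != len(samples):
        raise TableError("sample labels must be unique")
    for col in samples:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise TableError(f"non-numeric intensity in column {col!r}: {exc}") from exc
    for compound, block in frame.groupby("compound", sort=False):
        offsets = np.sort(block["offset"].to_numpy(dtype=int))
        if not np.array_equal(offsets, np.arange(offsets[0], offsets[0] + offsets.size)):
            raise TableError(f"offsets for {compound!r} are not consecutive")
        if block["formula"].nunique() != 1 or block["n_bio"].nunique() != 1:
            raise TableError(f"inconsistent formula/n_bio for {compound!r}")
        try:
            parse_formula(str(block["formula"].iloc[0]), int(block["n_bio"].iloc[0]))
        except FormulaError as exc:
            raise TableError(str(exc)) from exc
    return frame


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_table(path: str | Path, sep: str | None = None) -> IntensityTable:
    """Read a delimited intensity table; delimiter inferred from the suffix."""
    path = Path(path)
    sep = sep or _sep_for(path)
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise TableError(f"cannot parse {path}: {exc}") from exc
    header = path.read_text().splitlines()[0].split(sep)
    if len(set(header)) != len(header):
        raise TableError("duplicate column names in header")
    return IntensityTable(frame)


def write_table(table: IntensityTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=sep or _sep_for(path), index=False)


# ---------------------------------------------------------------------------
# fitting workflows


def _result_row(
    compound: str,
    sample: str,
    res: FitResult,
    qc_flag: bool | None = None,
) -> dict:
    row: dict = {
        "compound": compound,
        "sample": sample,
        "err": res.err,
        "n_iterations": res.n_iterations,
        "ambiguity_flag": res.ambiguity_flag,
        "qc_flag": qc_flag,
    }
    for name, val in res.r_dict.items():
        row[f"r_{name}"] = 100.0 * val
    for i, val in enumerate(res.cormid):
        row[f"M{i}"] = 100.0 * float(val)
    return row


def correct_table(table: IntensityTable, opts: FitOptions | None = None) -> pd.DataFrame:
    """Fit every compound × sample of one table; corMID/r in percent."""
    opts = opts or FitOptions()
    rows = []
    for compound in table.compounds:
        f = table.formula_of(compound)
        for sample in table.samples:
            res = fit_cormid(table.spectrum(compound, sample), f, opts=opts)
            logger.info(
                "%s/%s: err=%.3g iterations=%d ambiguous=%s",
                compound, sample, res.err, res.n_iterations, res.ambiguity_flag,
            )
            rows.append(_result_row(compound, sample, res))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Calibration:
    """Stage-1 output: per-compound fragment distributions from controls."""

    per_sample: pd.DataFrame
    fragment_vectors: dict[str, np.ndarray]
    qc_flags: dict[str, bool]
    fragments: tuple[Fragment, ...]


def calibrate(
    controls: IntensityTable,
    opts: FitOptions | None = None,
    aggregate: str = "median",
) -> Calibration:
    """Estimate per-compound fragment distributions from unlabeled controls.

    Each control spectrum is fitted twice: freely (corMID and r), whose
    M0 estimate feeds the impurity QC flag, and with the label
    distribution fixed at M0 = 100%, which yields the r estimate.  Per
    compound, r is aggregated over control samples (median by default,
    mean via ``aggregate="mean"``) and renormalized.
    """
    opts = opts or FitOptions()
    if aggregate not in {"median", "mean"}:
        raise ValueError("aggregate must be 'median' or 'mean'")
    frags = tuple(opts.fragments)
    rows = []
    vectors: dict[str, np.ndarray] = {}
    qc: dict[str, bool] = {}
    for compound in controls.compounds:
        f = controls.formula_of(compound)
        n = f.n_bio
        unlabeled = np.zeros(n + 1)
        unlabeled[0] = 1.0
        r_samples = []
        m0_free = []
        for sample in controls.samples:
            spec = controls.spectrum(compound, sample)
            free = fit_cormid(spec, f, opts=dataclasses.replace(
                opts, fixed_r=None, fixed_mid=None))
            m0_free.append(free.m0)
            fixed = fit_cormid(spec, f, opts=dataclasses.replace(
                opts, fixed_r=None, fixed_mid=unlabeled))
            r_samples.append(fixed.r)
            rows.append({
                "compound": compound,
                "sample": sample,
                "m0_free": 100.0 * free.m0,
                **{f"r_{fr.name}": 100.0 * v for fr, v in zip(frags, fixed.r)},
            })
        agg = np.median if aggregate == "median" else np.mean
        r_vec = agg(np.vstack(r_samples), axis=0)
        r_vec = r_vec / r_vec.sum()
        vectors[compound] = r_vec
        qc[compound] = bool(min(m0_free) < M0_QC_THRESHOLD)
        logger.info(
            "calibrated %s: r=%s qc_flag=%s", compound,
            np.round(r_vec, 4).tolist(), qc[compound],
        )
    return Calibration(pd.DataFrame(rows), vectors, qc, frags)


def calibrate_then_correct(
    controls: IntensityTable,
    labeled: IntensityTable,
    opts: FitOptions | None = None,
    aggregate: str = "median",
) -> pd.DataFrame:
    """Two-stage workflow: estimate r on controls, then fit corMID on
    labeled samples with r fixed at the per-compound aggregate."""
    opts = opts or FitOptions()
    missing = [c for c in labeled.compounds if c not in controls.compounds]
    if missing:
        raise TableError(f"compounds missing from controls: {missing}")
    cal = calibrate(controls, opts, aggregate=aggregate)
    rows = []
    for compound in labeled.compounds:
        f = labeled.formula_of(compound)
        stage2 = dataclasses.replace(
            opts, fixed_r=cal.fragment_vectors[compound], fixed_mid=None
        )
        for sample in labeled.samples:
            res = fit_cormid(labeled.spectrum(compound, sample), f, opts=stage2)
            rows.append(_result_row(compound, sample, res, cal.qc_flags[compound]))
    return pd.DataFrame(rows)


def write_results(results: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a result table; percentages rounded to two decimals."""
    path = Path(path)
    out = results.copy()
    for col in out.columns:
        if col.startswith(("M", "r_")) or col == "m0_free":
            out[col] = out[col].round(2)
    out.to_csv(path, sep=sep or _sep_for(path), index=False)
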