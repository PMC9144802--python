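"""Nested grid-search estimator: residual, seed grids, and fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midfit.fit import (
    FitError,
    FitOptions,
    as_fragment_vector,
    fit_cormid,
    residual,
    simplex_grid,
)
from midfit.formula import SumFormula, natural_pattern, parse_formula
from midfit.midmodel import (
    BUILTIN_FRAGMENTS,
    Axis,
    SpectrumVector,
    default_axis,
    reconstruct,
)
from midfit.simulate import SimSpec, simulate_rawmid

MH_ONLY = {"[M+H]+": 1.0}


class TestResidual:
    def test_equal_vectors(self):
        assert residual(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0

    def test_closed_form(self):
        assert residual(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 2.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=8))
    def test_matches_elementwise_oracle(self, vals):
        a = np.array(vals)
        b = a[::-1].copy()
        oracle = sum((x - y) ** 2 for x, y in zip(a, b))
        assert residual(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_axis_mismatch(self):
        with pytest.raises(FitError):
            residual(SpectrumVector(np.ones(3) / 3, -2),
                     SpectrumVector(np.ones(3) / 3, -1))
        with pytest.raises(FitError):
            residual(np.ones(3) / 3, np.ones(4) / 4)


class TestSimplexGrid:
    def test_printed_seed_set(self):
        got = {tuple(v) for v in simplex_grid(3, 0.5)}
        assert got == {
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5),
        }

    def test_dim_two_step_one(self):
        assert {tuple(v) for v in simplex_grid(2, 1.0)} == {(1, 0), (0, 1)}

    def test_stars_and_bars_count(self):
        # compositions of 4 quarters into 4 bins: C(7,3) = 35
        assert simplex_grid(4, 0.25).shape == (35, 4)

    def test_rows_are_simplex(self):
        grid = simplex_grid(5, 0.25)
        assert grid.sum(axis=1) == pytest.approx(np.ones(len(grid)))
        assert grid.min() >= 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            simplex_grid(0, 0.5)
        with pytest.raises(ValueError):
            simplex_grid(3, 0.3)


class TestFragmentVectorCoercion:
    def test_dict_and_sequence(self):
        v = as_fragment_vector({"[M-H]+": 0.1, "[M+H]+": 0.9})
        assert v == pytest.approx([0.1, 0, 0.9, 0])
        assert as_fragment_vector([0, 0, 1, 0]) == pytest.approx([0, 0, 1, 0])

    def test_errors(self):
        with pytest.raises(FitError):
            as_fragment_vector({"[M+2H]+": 1.0})
        with pytest.raises(ValueError):
            as_fragment_vector({"[M+H]+": 0.5})  # does not sum to 1


class TestFixedRFits:
    def test_mislabeled_glucose_worked_example(self, glucose):
        """Fully labeled glucose with 10% [M-H]+, corrected assuming pure
        [M+H]+, lands on M4 = 10% and M6 = 90%."""
        spec = SimSpec(glucose, [0, 0, 0, 0, 0, 0, 1],
                       {"[M-H]+": 0.10, "[M+H]+": 0.90},
                       noise_cv=0, noise_floor=0, apply_abundance=False)
        raw = simulate_rawmid(spec)[0]
        res = fit_cormid(raw, glucose,
                         opts=FitOptions(fixed_r=MH_ONLY, apply_abundance=False))
        assert res.cormid[4] == pytest.approx(0.10, abs=1e-3)
        assert res.cormid[6] == pytest.approx(0.90, abs=1e-3)
        assert res.cormid[[0, 1, 2, 3, 5]] == pytest.approx(0, abs=1e-3)

    def test_natural_pattern_corrects_to_pure_m0(self, glucose_tms):
        """An unlabeled spectrum must correct to M0 = 100%."""
        pat = natural_pattern(glucose_tms)
        raw = SpectrumVector(np.r_[0.0, 0.0, pat], start_offset=-2)
        res = fit_cormid(raw, glucose_tms, opts=FitOptions(fixed_r=MH_ONLY))
        assert res.m0 == pytest.approx(1.0, abs=5e-3)

    def test_single_fragment_identity_is_exact(self):
        """Abundance off, pure [M+H]+: the embedded raw is the unique
        solution and the search recovers it to the final step."""
        f = SumFormula({"C": 4, "H": 8, "O": 4}, 4)
        mid = np.array([0.05, 0.2, 0.15, 0.25, 0.35])
        raw = reconstruct(mid, 4, np.array([0, 0, 1.0, 0]), f, apply_abundance=False)
        res = fit_cormid(raw, f, opts=FitOptions(fixed_r=MH_ONLY, apply_abundance=False))
        assert np.abs(res.cormid - mid).max() <= 1e-3

    def test_stored_err_matches_recomputation(self, lactic_tms):
        spec = SimSpec(lactic_tms, [0.3, 0.1, 0.2, 0.4],
                       {"[M]+": 0.3, "[M+H]+": 0.7}, noise_cv=0.05, seed=7)
        raw = simulate_rawmid(spec)[0]
        res = fit_cormid(raw, lactic_tms, opts=FitOptions(fixed_r={"[M]+": 0.3, "[M+H]+": 0.7}))
        y = np.clip(raw.values, 0, None)
        y = y / y.sum()
        assert res.err == pytest.approx(residual(y, res.recmid.values), abs=1e-12)

    def test_never_regresses_from_coarse_grid(self, lactic_tms):
        spec = SimSpec(lactic_tms, [0.25, 0.25, 0.25, 0.25],
                       {"[M]+": 0.5, "[M+H]+": 0.5}, noise_cv=0.1, seed=3)
        raw = simulate_rawmid(spec)[0]
        r = as_fragment_vector({"[M]+": 0.5, "[M+H]+": 0.5})
        res = fit_cormid(raw, lactic_tms, opts=FitOptions(fixed_r=r))
        y = np.clip(raw.values, 0, None)
        y = y / y.sum()
        for mid in simplex_grid(4, 0.5):
            rec = reconstruct(mid, 3, r, lactic_tms)
            assert res.err <= residual(y, rec.values) + 1e-12


class TestFixedMidFits:
    def test_recovers_fragment_vector(self, lactic_tms):
        truth = {"[M-H]+": 0.1, "[M]+": 0.45, "[M+H]+": 0.45}
        mid = np.zeros(4)
        mid[0] = 1.0
        spec = SimSpec(lactic_tms, mid, truth, noise_cv=0, noise_floor=0)
        raw = simulate_rawmid(spec)[0]
        res = fit_cormid(raw, lactic_tms, opts=FitOptions(fixed_mid=mid))
        assert res.r == pytest.approx(as_fragment_vector(truth), abs=1e-3)
        assert res.cormid is not None and res.m0 == 1.0


class TestJointFit:
    def test_degenerate_pair_resolved_toward_mh(self):
        """Both explanations of a single peak have err 0; the penalty /
        tie-break must return the [M+H]+ one."""
        f = SumFormula({"C": 2, "H": 4, "O": 2}, 2)
        raw = reconstruct(np.array([0.0, 1.0, 0.0]), 2,
                          np.array([0, 1.0, 0, 0]), f, apply_abundance=False)
        res = fit_cormid(raw, f, opts=FitOptions(penalty=1.0, apply_abundance=False))
        assert res.cormid == pytest.approx([1, 0, 0], abs=1e-9)
        assert res.r_dict["[M+H]+"] == pytest.approx(1.0, abs=1e-9)
        assert res.ambiguity_flag

    def test_deterministic(self, lactic_tms):
        spec = SimSpec(lactic_tms, [0.2, 0.2, 0.3, 0.3],
                       {"[M]+": 0.4, "[M+H]+": 0.6}, noise_cv=0.03, seed=11)
        raw = simulate_rawmid(spec)[0]
        a = fit_cormid(raw, lactic_tms)
        b = fit_cormid(raw, lactic_tms)
        assert np.array_equal(a.cormid, b.cormid)
        assert np.array_equal(a.r, b.r)
        assert a.err == b.err and a.n_iterations == b.n_iterations

    def test_matches_exhaustive_grid_oracle(self):
        """Nested search attains the global minimum found by exhaustive
        enumeration on a fine simplex grid (two-fragment case)."""
        f = SumFormula({"C": 8, "H": 20, "O": 2, "Si": 2}, 2)
        frags = tuple(fr for fr in BUILTIN_FRAGMENTS if fr.name in ("[M]+", "[M+H]+"))
        true_mid = np.array([0.15, 0.25, 0.6])
        true_r = np.array([0.35, 0.65])
        raw = reconstruct(true_mid, 2, true_r, f, fragments=frags)
        y = raw.values / raw.values.sum()

        from midfit.midmodel import fragment_matrix

        mats = [fragment_matrix(f, 2, fr, raw.axis) for fr in frags]
        projected = [simplex_grid(3, 0.01) @ A.T for A in mats]
        best = np.inf
        for r in simplex_grid(2, 0.01):
            rec = r[0] * projected[0] + r[1] * projected[1]
            best = min(best, (((y[None, :] - rec) ** 2).sum(axis=1)).min())

        res = fit_cormid(raw, f, opts=FitOptions(fragments=frags, step_min=1e-5))
        assert res.err <= best + 1e-9

    def test_noiseless_grid_truth_recovered(self, lactic_tms):
        """(corMID, r) drawn on a 0.05 grid: joint fit reproduces the raw
        spectrum, and the fixed-r fit pins corMID to the truth."""
        true_mid = np.array([0.35, 0.0, 0.45, 0.2])
        true_r = {"[M-H]+": 0.05, "[M]+": 0.25, "[M+H]+": 0.70}
        spec = SimSpec(lactic_tms, true_mid, true_r, noise_cv=0, noise_floor=0)
        raw = simulate_rawmid(spec)[0]
        joint = fit_cormid(raw, lactic_tms, opts=FitOptions(step_min=1e-4))
        assert joint.err < 1e-8
        fixed = fit_cormid(raw, lactic_tms, opts=FitOptions(fixed_r=true_r))
        assert np.abs(fixed.cormid - true_mid).max() <= 0.01

    def test_parameter_recovery_fixed_r(self):
        """Median worst-coordinate error over noiseless sims stays below
        half the final grid step."""
        rng = np.random.default_rng(42)
        formulas = [
            parse_formula("C12H30O4Si2", 3),
            parse_formula("C17H40O5Si3", 4),
        ]
        devs = []
        for i in range(30):
            f = formulas[i % 2]
            n = f.n_bio
            mid = rng.multinomial(20, np.ones(n + 1) / (n + 1)) / 20.0
            r = rng.multinomial(20, [0.1, 0.2, 0.6, 0.1]) / 20.0
            raw = simulate_rawmid(SimSpec(f, mid, r, noise_cv=0, noise_floor=0))[0]
            res = fit_cormid(raw, f, opts=FitOptions(fixed_r=r))
            devs.append(np.abs(res.cormid - mid).max())
        opts = FitOptions()
        assert np.median(devs) <= opts.step_min / 2


class TestErrors:
    def test_bad_raw(self, glucose):
        with pytest.raises(FitError):
            fit_cormid(SpectrumVector(np.zeros(11), -2), glucose)
        with pytest.raises(FitError):
            fit_cormid(SpectrumVector(np.r_[np.nan, np.ones(10)], -2), glucose)
        with pytest.raises(FitError):
            fit_cormid(SpectrumVector(np.ones(4) / 4, -2), glucose)  # < n+1

    def test_bad_options(self):
        with pytest.raises(FitError):
            FitOptions(fixed_r=MH_ONLY, fixed_mid=[1.0, 0.0])
        with pytest.raises(FitError):
            FitOptions(penalty=-1.0)
        with pytest.raises(FitError):
            FitOptions(step_min=0.9, step_init=0.5)
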