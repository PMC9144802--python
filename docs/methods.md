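# Methods

## Forward model

A compound is described by the sum formula of its derivatized form and by
`n_bio`, the count of biological (labelable) carbons. Isotope patterns are
computed at nominal-mass resolution: all isotopes are binned by integer
mass shift with an axis spacing of 1.003355 Da (the ¹²C/¹³C gap). This is
the appropriate abstraction for quadrupole-TOF instruments (R ≈ 35,000),
where isotopic fine structure — e.g. the ~30 mDa gap between
[M+H₃O−CH₄]⁺ and the M+2 isotopologue of [M+H]⁺ — is not resolved.
Resolved fine-structure computation (FT-ICR class instruments) is out of
scope; at that resolution the species separate and this correction is not
needed.

The pattern of a formula is the convolution of per-atom isotope shift
distributions (binary exponentiation of the single-atom distribution per
element). For isotopologue Mj, exactly j biological carbons are fixed as
¹³C and excluded from the convolution; by default the *remaining*
biological carbons still carry natural ¹³C (the standard
correction-matrix convention; `natural_in_unlabeled=False` reproduces
idealized textbook patterns). Patterns are truncated at
`max_shift = n_bio + 4` by default and renormalized; a truncation that
drops more than `tail_tol` (10⁻⁶) of the mass raises an error unless the
caller opts out.

### Isotope table

Shipped as an editable TSV (`midfit/data/isotopes.tsv`): per element, the
nominal shift, exact mass and abundance of each isotope. Defaults: ¹³C at
0.0107 (switchable, e.g. to the rounded 0.011 convention, via
`IsotopeTable.with_abundance`), Si at 0.922/0.047/0.031, plus ²H, ¹⁵N,
¹⁷O/¹⁸O and ³³S/³⁴S. The minor isotopes of H, N, O and S contribute little
next to C and Si in silylated analytes and can be collapsed per element
with `without_minor_isotopes`; all guarantees hold either way.

### Fragments

Built-in species, offsets relative to [M+H]⁺ and element deltas:

| species          | offset | delta vs [M+H]⁺ |
|------------------|--------|------------------|
| [M-H]⁺           | −2     | −H₂              |
| [M]⁺             | −1     | −H               |
| [M+H]⁺           | 0      | —                |
| [M+H₃O−CH₄]⁺     | +2     | +H₂O −CH₄        |

The carbon lost with CH₄ is taken to be a silylation methyl, not
biological carbon, so the label axis of the water-adduct species is
unchanged; its abundance pattern simply uses one derivatization carbon
fewer. For underivatized formulas with no carbon to spare the labelable
count is clamped to the carbons remaining. User-defined `Fragment` objects
(name, offset, delta) extend or replace the built-in set, e.g. for ESI
adducts.

Each fragment matrix column is renormalized over the measurement axis, so
the forward model is column-stochastic: any valid (corMID, r) produces a
unit-sum spectrum, and the model is exactly linear in both arguments. The
default axis runs from −2 (the [M-H]⁺ M0 position) to n+2, length n+5.

## Estimator

The residual is `err = Σ(rawMID − recMID)²` after preprocessing rawMID by
clipping negative intensities to zero and normalizing to unit sum (a scale
convention; peak-relative scaling is for display only). The search is a
deterministic simplex pattern search:

* **Seed:** the full simplex grid at step 0.5 (for a 3-vector: the six
  canonical seeds {1,0,0}, {0,1,0}, {0,0,1}, {.5,.5,0}, {.5,0,.5},
  {0,.5,.5}).
* **Moves:** per-coordinate ±step (clipped to [0,1], renormalized) plus
  pairwise mass transfers `x + step·(eᵢ − eⱼ)`. Transfers stay on the
  constraint surface exactly and are what make convergence near simplex
  edges reliable; coordinate moves alone stall there.
* **Schedule:** moves are accepted while they lower the (penalized)
  residual by more than 10⁻¹²; when none does, the step is halved. The
  final round uses exactly `step_min` (default 10⁻³), so the returned
  optimum is resolved to roughly `step_min/2` per coordinate for
  well-conditioned problems.
* **Nesting:** with both vectors free, every corMID candidate is scored by
  an inner full search over r (vectorized; results memoized per corMID).
  The top `n_starts = 3` coarse-grid candidates are refined independently
  and the best endpoint wins — cheap insurance against the multi-modal
  landscapes that superimposed spectra produce.

With `fixed_r` the model collapses to a single matrix `B = Σ rₖAₖ` and the
corMID search is fully vectorized; with `fixed_mid` only the inner search
runs. Either restriction makes the minimum unique.

### Ambiguity, ties and the penalty

A pure-M1 signal seen through [M]⁺ and a pure-M0 signal seen through
[M+H]⁺ produce *identical* spectra; more generally a continuum of
(label shifted up, fragments shifted down) solutions can explain a
spectrum almost exactly. Three mechanisms address this:

* the `ambiguity_flag` is set when ≥2 coarse-grid candidates tie within
  10⁻⁹, so downstream code can see that the solution is not unique;
* the optional penalty multiplies err by `1 + λ·(1 − r₍M+H₎)` (λ = 0 by
  default), disfavoring [M+H]⁺-poor solutions — most compounds form
  predominantly [M+H]⁺;
* exact ties (≤10⁻¹² during the search) and, between independently refined
  starts, residual differences below the search resolution (`step_min²`,
  ~10⁻⁶ at defaults — differences a step-limited search cannot rank
  meaningfully) are broken toward the larger [M+H]⁺ share. This keeps the
  estimator deterministic and returns the conventional branch for clean
  unlabeled spectra without affecting genuinely distinguishable solutions.

The robust practice remains the two-stage workflow: estimate r on
unlabeled controls with corMID fixed at M0 = 100%, aggregate per compound
(median by default over replicates — fragment formation is stable within
a measurement series), then fit labeled samples with r fixed. The QC flag
marks compounds for which any control's *free* fit yields M0 < 95%; in
library screening such spectra almost always turn out impure. Impurity
handling beyond this flag (baseline modeling, deconvolution of co-eluting
signals) is out of scope.

## Synthetic data

`simulate_rawmid` draws replicates as
`reconstruct(corMID, n, r) × lognormal(CV) + uniform·floor`, clipped at
zero and renormalized. Defaults: multiplicative CV 2% (typical run-to-run
scatter of well-integrated GC-APCI peak areas) and additive floor 10⁻⁴ of
the total signal. A seed fixes the full stream. The generator emulates
integrated isotopologue intensities only — no chromatographic peak
shapes, scan-level noise, detector saturation, co-eluting background or
tracer impurity. Passing round-trip tests therefore demonstrates the
correctness of the correction arithmetic and the search, not robustness
to those real-data effects; tracer-purity correction in particular is
deliberately left to dedicated upstream tools.

## Numerical choices and test scales

* Simplex validation tolerance 10⁻⁹; per-element abundance sums checked to
  10⁻⁹.
* `step_min = 10⁻³` by default balances runtime against the ~5·10⁻⁴
  coordinate resolution appropriate for percent-scale reporting;
  convergence-sensitive checks (exhaustive-oracle equivalence,
  noiseless round trips) use 10⁻⁵–10⁻⁴.
* Exhaustive-oracle comparisons run at n ≤ 3 with two fragments on a 0.01
  grid; parameter-recovery statistics use 100 noiseless simulations over
  3–6-carbon silylated formulas; workflow tests use 2–3 compounds × 3
  samples. These sizes exercise every code path while keeping the default
  suite fast.
* Results tables report percentages to two decimals.
* Degenerate inputs: all-zero or non-finite spectra, axes shorter than
  n+1, fragments whose isotopologues fall off the axis, and
  over-truncated patterns all raise typed errors rather than returning
  silently wrong output.

## Known limitations

* The grid search is the method; no gradient or QP solver is used even
  where the fixed-r subproblem would admit one. This preserves exact
  reproducibility of the search path at a small accuracy cost bounded by
  `step_min`.
* Joint estimation on degenerate spectra returns the [M+H]⁺-preferred
  branch; if a compound genuinely fragments with little [M+H]⁺ *and* is
  partially labeled, only calibration on controls gives a trustworthy
  answer.
* Nominal-mass binning ignores sub-mDa mass defects; instruments that
  resolve them need no such correction.
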