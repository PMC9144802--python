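# midfit

Correction of **superimposed mass isotopologue distributions** (MIDs) in
GC-APCI-MS ¹³C tracer experiments.

## The problem

In metabolic flux studies a labeled precursor (typically [U-¹³C]glucose or
glutamine) is fed to cells and its incorporation into metabolites is read
off the mass isotopologue distribution M0…Mn of each compound, where *n* is
the number of biological carbon atoms. Before any flux interpretation the
measured intensities must be corrected for natural isotope abundance —
¹³C at ≈1.1%, and for silylated analytes the large ²⁸/²⁹/³⁰Si contribution
(92.2/4.7/3.1%) of the derivatization groups.

Atmospheric-pressure chemical ionization adds a second complication: the
soft source produces several ion species of the same analyte —
[M+H]⁺ alongside the proton/hydrogen-loss species [M]⁺ and [M-H]⁺ and, for
carbonic acids, the water-adduct/methane-loss species [M+H₃O−CH₄]⁺ which at
qTOF resolution (R ≈ 35,000) falls into the M+2 bin of [M+H]⁺. The measured
vector (**rawMID**) is therefore an overlay of the same label distribution
shifted by −2, −1, 0 and +2 nominal mass units. Ignoring a 10% [M-H]⁺
share of a fully labeled 6-carbon compound, for example, masquerades as a
spurious 10% M4 isotopologue.

## The model

Let **corMID** ∈ Δⁿ be the label distribution (ΣMi = 1) and
**r** ∈ Δᵏ the fragment distribution over the k configured ion species
(Σrₖ = 1). The forward model is

    recMID = Σₖ rₖ · Aₖ · corMID

where column *j* of Aₖ places the natural-abundance isotope pattern of
isotopologue Mj of species *k* (computed by convolution over all atoms
except the *j* ¹³C-labeled biological carbons) at nominal position
offsetₖ + j. The estimator minimizes

    err = Σᵢ (rawMIDᵢ − recMIDᵢ)²

over the simplex by a deterministic nested grid search: a coarse step-0.5
simplex grid seeds the solution and candidate moves around the incumbent
are tested with a shrinking step, each corMID hypothesis being scored with
its own best-fitting r. Fixing either vector makes the problem uniquely
solvable; joint estimation can be ambiguous, and ties are broken toward
the [M+H]⁺-dominated solution (optionally enforced by a penalty
`err · (1 + λ·(1 − r₍M+H₎))`).

The recommended two-stage workflow for tracer studies:

1. **calibrate** — on unlabeled control samples, fix corMID at M0 = 100%
   and estimate r per compound (median over replicates). Controls whose
   *free* fit gives M0 < 95% are QC-flagged as spectrally impure.
2. **correct** — fit corMID in labeled samples with r held at the
   calibrated value.

## Worked example

```python
import numpy as np
from midfit import SimSpec, FitOptions, simulate_rawmid, fit_cormid, parse_formula

glucose = parse_formula("C6H12O6", n_bio=6)

# fully labeled glucose forming 10% [M-H]+ / 90% [M+H]+ (idealized spectrum)
raw = simulate_rawmid(SimSpec(glucose, [0, 0, 0, 0, 0, 0, 1],
                              {"[M-H]+": 0.10, "[M+H]+": 0.90},
                              noise_cv=0, noise_floor=0,
                              apply_abundance=False))[0]

# correct it under the (wrong) assumption of pure [M+H]+ formation
res = fit_cormid(raw, glucose,
                 opts=FitOptions(fixed_r={"[M+H]+": 1.0}, apply_abundance=False))
print(np.round(100 * res.cormid, 2))
```

prints

```
[ 0.  0.  0.  0. 10.  0. 90.]
```

— the unaccounted [M-H]⁺ share resurfaces as a spurious 10% M4, exactly
the artifact this package exists to remove. Re-fitting the same spectrum
jointly (no `fixed_r`) recovers M6 = 100% with r = {10% [M-H]⁺, 90% [M+H]⁺}.

A file-based round trip with the CLI:

```
midfit simulate --formula C9H22O3Si2 --nbio 3 --cormid 1,0,0,0 \
    --r "[M]+=0.3,[M+H]+=0.7" --replicates 3 --seed 7 -o controls.csv
midfit simulate --formula C9H22O3Si2 --nbio 3 --cormid 0,0,0,1 \
    --r "[M]+=0.3,[M+H]+=0.7" --replicates 3 --seed 8 -o labeled.csv
midfit flux controls.csv labeled.csv -o results.csv
```

`results.csv` reports corMID and r per compound × sample in percent
(two decimals), together with the residual, an ambiguity flag and the
control QC flag.

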