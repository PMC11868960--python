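# isofinger

Regioisomer identification and quantitation from partial-deuterium
isotopic fingerprints in LC-MS data.

## The problem

Late-stage C–H functionalization of a drug-like molecule usually yields a
mixture of regioisomers — products with the same molecular formula that
differ only in which position reacted. Telling them apart normally means
chromatographic separation, isolation, and NMR of every peak, which does
not scale to high-throughput experimentation and biases selectivity data
sets toward major products.

`isofinger` implements a mass-spectral alternative. Each candidate
reactive site of the substrate is labeled with a *different* partial
level of deuterium (say site A = 25% D, B = 50% D, C = 75% D), measured
by ¹H NMR of the starting material. A reaction that consumes site A
removes A's label from the product but keeps B's and C's, so every
regioisomer carries a distinct isotopologue distribution — an *isotopic
fingerprint* readable on any unit-resolution (single-quadrupole) LC-MS:

* separated LC peaks are identified by matching their observed pattern
  against the predicted fingerprints (no isolation, no standards);
* unseparated mixtures are quantified by direct injection and spectral
  deconvolution (no chromatography at all);
* mixing the labeled substrate with unlabeled material at varying
  fractions and extrapolating the observed selectivity recovers the
  inherent protio selectivity and competitive kinetic isotope effects.

## The model

**Fingerprints.** For a candidate product that retains labeled sites with
deuterium fractions d₁…dₙ, the number of deuteriums follows the
Poisson–binomial distribution over independent Bernoulli sites, computed
exactly by iterative convolution of the vectors [1−dᵢ, dᵢ]. Convolving
with the natural-abundance envelope of the product formula (¹³C, ⁸¹Br, …,
by exact per-element polynomial convolution) gives the predicted
unit-mass pattern **a**ⱼ over nominal shifts 0…K.

**Deconvolution.** The observed isotopologue vector **y** of an
unseparated mixture satisfies **y** ≈ **A w**, where column j of **A** is
candidate j's fingerprint and **w** the isomer weights. `isofinger`
solves this by OLS and falls back to NNLS whenever OLS returns negative
weights (negative percent contributions are physically meaningless),
reporting normalized fractions, residual norm and the condition number of
**A**.

**Kinetic isotope effects.** A site with labeling d and competitive KIE
= kH/kD reacts at a factor 1 − d(1 − 1/KIE) of its protio rate, so at
labeled-substrate fraction χ the observed ratio against an unlabeled
reference site is linear in x = dχ:

    R(χ) = r₀ (1 − dχ(1 − 1/KIE)),   KIE = r₀ / (r₀ + slope)

The intercept r₀ is the protio selectivity; standard errors propagate to
the KIE by the delta method. An exact 2ⁿ-state kinetic simulator
(closed-form first-order depletion of every labeling state) provides
finite-conversion oracles and the residual-substrate pattern drift that
flags a KIE in the first place.

## Worked example

Methyl nicotinate labeled at C2/C4/C6 with 30/64/94% D, coupled with a
p-tolyl radical (net formula change +C7H6). Predict the fingerprints,
simulate a direct-injection spectrum of a known mixture, and deconvolve:

```python
import numpy as np
from isofinger import (Formula, LabelingScheme, Substrate, make_candidate,
                       build_design_matrix, MixtureModel, simulate_spectrum,
                       extract_vector, NoiseModel)

sub = Substrate(Formula.parse("C7H7NO2"),
                LabelingScheme.from_dict({"C2": 0.30, "C4": 0.64, "C6": 0.94}),
                name="methyl-nicotinate")
cands = [make_candidate(sub, s, "+C7H6", name=f"{s}-aryl") for s in ("C2", "C4", "C6")]
cands.append(make_candidate(sub, None, "+C7H6", name="RPh"))   # unlabeled-site product
dm = build_design_matrix(cands)

truth = np.array([0.45, 0.25, 0.20, 0.10])
spec = simulate_spectrum(cands, truth, noise=NoiseModel(0.02, 1.0, seed=7))
y = extract_vector(spec, cands[0].ion_mz(), dm.window)
print(MixtureModel(y, dm).fit().summary())
```

Output:

```
Regioisomer mixture deconvolution
  method: ols
  residual norm: 1.227e-04   cond(A): 11.8
  candidate              raw weight   fraction
  C2-aryl                   0.44663     0.4467
  C4-aryl                   0.26015     0.2602
  C6-aryl                   0.19944     0.1995
  RPh                       0.09367     0.0937
```

The four product fractions are recovered to about a percent from one
noisy spectrum with no separation: the C2 product is identified as the
major isomer (44.7% vs 45% true), and the RPh row quantifies reaction at
unlabeled positions — always include such a candidate when reaction can
occur away from the labeled sites. With the labels removed the four
columns of **A** would be identical and the problem unsolvable; the
distinct 30/64/94% levels are what make `cond(A)` small.

A KIE fit works the same way from a dilution table:

```python
from isofinger import DilutionSeries, fit_dilution_series
chis = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
ratios = 2.16 * (1 - 0.88 * chis * (1 - 1 / 1.80))   # a noiseless series
print(fit_dilution_series(DilutionSeries(chis, ratios), d=0.88).summary())
# -> r0 = 2.1600, KIE (kH/kD) = 1.8000
```

## Command line

Every workflow is also a subcommand driven by one YAML config (see
`isofinger.config` for the schema):

```bash
isofinger predict  --config run.yaml --out patterns.csv
isofinger deconv   --config run.yaml --out ratios.csv  well_A1.csv well_A2.csv
isofinger assign   --config run.yaml --out assign.csv  peak1.csv peak2.csv
isofinger kie      --series dilution.csv --d 0.88 --out fit.json
isofinger simulate --out plate_dir --seed 1
```

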