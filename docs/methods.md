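# Methods

This note documents the models implemented in `isofinger`, the defaults
and why they were chosen, the numerical choices, and the limits of what
the synthetic test bed can show.

## Label statistics

A labeling scheme assigns each reactive site an independent deuterium
incorporation fraction d ∈ [0, 1], as determined by ¹H NMR integration of
the starting material (`incorporation_from_nmr`: d = 1 − observed
integral / expected protons, clamped to [0, 1] with a warning beyond
0.02). Site independence is an assumption: deuteration chemistry that
correlates sites (e.g. a mechanism exchanging two positions together)
would violate the Poisson–binomial model, and nothing in MS data at unit
resolution can detect that.

The deuterium count of a product that retains sites d₁…dₙ is
Poisson–binomial, computed by iterative convolution of [1−dᵢ, dᵢ] —
exact, O(n²), and validated against 2ⁿ enumeration to 1e-12. Its mean is
Σdᵢ, and raising any dᵢ raises the mean: the monotonicity that makes
fingerprints orderable by mass.

## Natural-abundance envelopes and unit-mass binning

Isotope envelopes are computed from an embedded table (C, H, N, O, F, Si,
P, S, Cl, Br, I; IUPAC representative abundances) by per-element
polynomial convolution, binned by *nominal* mass shift. Two deliberate
simplifications:

* **Deuterium's natural abundance (0.0115%) is neglected** — only
  declared labels contribute D. The omission is orders of magnitude below
  the multiplicative noise floor of the data this method targets.
* **¹³C (+1.00336 Da) and H→D (+1.00628 Da) are lumped into the same +1
  bin.** Unit-resolution (single-quadrupole) instruments cannot resolve
  the 2.9 mDa difference; extraction bins are centered on the ¹³C spacing
  with a default ±0.3 Da tolerance that absorbs the drift over any
  practical window. High-resolution fine structure is out of scope.

Distributions are truncated to a window 0…K (default: retained label
count + 3 bins for the ¹³C/heavy-halogen tail) and renormalized. Bromine
and chlorine put real mass in the +2/+4 bins, which is why the window is
not simply the label count.

## Deconvolution

The observed vector is normalized to unit sum before regression; the
columns of the design matrix are unit-sum by construction, so absolute
intensity carries no information — only pattern shape does. OLS runs
first; if any weight falls below −1e-9 (a tolerance, so floating-point
negatives do not trigger spurious fallbacks) the solver reruns NNLS
(`scipy.optimize.nnls`) and sets a fallback flag. Rank-deficient designs
are rejected under OLS with a pointer to NNLS.

Equal ionization response across regioisomers is assumed by default —
measured isomer-to-isomer differences are small (order 1.2–1.5×) because
regioisomers share molecular volume and charge distribution — with an
optional per-candidate response-factor override for sensitivity analysis
(weights are divided by the factors before normalizing).

Peak assignment uses cosine similarity between the normalized observed
vector and each predicted pattern, tie-broken by least-squares residual;
cosine is the standard scale-free spectral-match score. Assignments whose
top two scores differ by less than 0.02 are flagged ambiguous — that
margin is also what the design-matrix condition-number warning (> 1e6)
guards against: two candidates with near-identical retained labelings
cannot be distinguished by any metric.

When reaction can occur away from the labeled sites (e.g. on an aryl
substituent), a `consumed_site=None` candidate retaining every label must
be included or that signal is misattributed; the CLI warns when such a
candidate is absent.

## Kinetics and KIE extraction

The exact simulator enumerates all 2ⁿ labeling states of an n-site
substrate (n ≤ 16). State s has probability Πdᵢ^sᵢ(1−dᵢ)^(1−sᵢ) and
depletes first-order at rate K(s) = Σⱼ kⱼ(sⱼ), with kⱼ(D) = kⱼᴴ/KIEⱼ.
Closed-form exponential integrals give cumulative per-site product and
the surviving-state label distribution at any conversion; the reaction
time matching a target conversion is solved by root-finding
(`scipy.optimize.brentq`, xtol 1e-12) on total surviving mass, which is
monotone in time. Mass is conserved identically (the per-site integrals
telescope), making the simulator a machine-precision oracle.

In the conversion → 0 limit the per-site flux is kⱼᴴ(1 − dⱼ(1 − 1/KIEⱼ)),
which is the fitting model used throughout:

* `fit_dilution_series` regresses R = r₀ + slope·(dχ) and reports
  r₀ (intercept), KIE = r₀/(r₀ + slope), with OLS/WLS standard errors
  propagated to the KIE by the delta method. Ratio response (probed site
  over an unlabeled reference site) is the default because the reference
  site's rate is χ-independent, making the ratio exactly linear in dχ.
* Two or more labeled positions are fit independently, each site's ratio
  against the d = 0 reference; this multi-site construction is this
  package's own and is validated by round trip through the exact
  simulator (noiseless recovery to 1e-6).
* `correct_fractions_for_kie` divides observed fractions by
  1 − dᵢ(1 − 1/KIEᵢ) and renormalizes. For competitive KIE < 3 that
  factor stays within [1/3, 1], which is why the correction is often
  negligible at low conversion.
* `detect_kie` flags |Δ mean mass shift| of residual substrate vs the
  initial label distribution above 0.02 shift units. The threshold is a
  practical default: drift grows with conversion and with d(1 − 1/KIE),
  so weak effects at low conversion sit below it by design — absence of a
  flag is not absence of a KIE.

The fit assumes the differential (low-conversion) regime. At finite
conversion the surviving substrate is already label-enriched and ratios
curve; conversion-resolved (Rayleigh-type) fitting is out of scope, and
the simulator exists precisely to quantify that regime error. Inverse
KIEs (< 1) are fit and flagged, not rejected. Estimates of KIE − 1 become
noise-dominated as KIE → 1; the test suite measures this scatter rather
than hiding it.

## Synthetic data: what it emulates and what it does not

`simulate_spectrum` places peaks at the protonated product's monoisotopic
m/z plus unit-mass bins, intensities proportional to the fraction- and
response-weighted candidate patterns, with Gaussian multiplicative noise
(default relative σ = 0.02) plus an additive floor (default σ = 1 count
on a default total of 1e5), clipped at zero. The defaults produce
deconvolution scatter of the order seen between orthogonal quantitation
methods on real plates; they are stated assumptions, not fits to any
instrument, since replicate variance is not published for this chemistry.
The plate generator mirrors a 24-well layout — six labeling schemes on a
methyl nicotinate scaffold with levels around 30/64/94%, four aryl
radical reagents, triplicate injection — with Dirichlet-distributed truth
fractions under a fixed seed.

Not emulated: chromatographic peak shapes and retention behavior, adduct
and fragment ions, charge states above 1, detector saturation,
ion-suppression matrix effects, and correlated (non-independent) site
labeling. Passing tests therefore demonstrate the correctness of the
inference given centroided, protonated, unit-resolution data — not
robustness to every failure mode of real LC-MS acquisition.

## Problem sizes and evaluation protocol

Stochastic checks use 100–1000 seeded trials (assignment accuracy,
random-system recovery) and 200-trial noise ensembles; these sizes give
negligible Monte-Carlo error relative to the margins tested. Mixture
quantitation under noise is evaluated per measurement as in the plate
protocol: triplicate injections averaged into one isotopologue vector per
sample before deconvolution. Single-injection error on the didactic
25/50/75 three-site system is intrinsically ~1.7× higher (the pseudo-
inverse amplifies per-bin noise by the design's conditioning), a floor no
solver can beat; the realistic 30/64/94 labeling is well-conditioned
enough to pass the same bar per single injection.

## Numerical conventions

* All probability vectors are validated to sum to 1 ± 1e-9; convolution
  is exact polynomial multiplication (vectors are tiny; no FFT).
* Shift 0 denotes the fully protio, all-lightest-isotope protonated ion;
  display conventions that start counting at "M+1" map onto internal
  shifts 0…K.
* Degenerate inputs fail loudly: zero total intensity, empty candidate
  lists, rank-deficient OLS, nonpositive fitted intercepts, correction
  factors ≤ 0, conversion ≥ 1, and overlapping extraction bins are all
  explicit errors rather than silent results.
* `DilutionSeries` requires ≥ 2 distinct χ; with exactly 2 points the fit
  is exact and standard errors are reported as NaN (zero degrees of
  freedom).
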