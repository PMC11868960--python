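"""Synthetic instrument data: mixture spectra, labeled kinetics, dilution
series and whole microscale plates.

This module is the test bed standing in for LC-MS hardware.  It emulates
unit-resolution centroided spectra of protonated ions (peaks at the
monoisotopic m/z plus unit-mass bins), regioisomer mixing with optional
per-isomer response factors, multiplicative + additive detector noise,
and KIE-driven kinetic fractionation of partially labeled substrates.

The kinetics simulator is exact, not stochastic: with n labeled sites the
substrate population is a mixture of 2^n isotopologue states, each
depleting first-order at a rate summed over its sites (deuterated sites
react slower by their KIE).  Closed-form exponential integrals give the
cumulative product fractions and the surviving-state label distribution
at any conversion, which makes it a machine-precision oracle for the
differential-regime fitting model in :mod:`isofinger.kie`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize

from .chem import CandidateProduct, Formula, LabelingScheme, Substrate, make_candidate
from .elements import C13_SPACING
from .isotopes import MassShiftDistribution, predict_pattern
from .kie import DilutionSeries
from .spectra import CentroidSpectrum


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: relative multiplicative sigma + additive counts sigma."""

    mult_sigma: float = 0.02
    add_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mult_sigma < 0 or self.add_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, intensities: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = intensities * (1.0 + self.mult_sigma * rng.standard_normal(intensities.shape))
        out = out + self.add_sigma * rng.standard_normal(intensities.shape)
        return np.clip(out, 0.0, None)


ZERO_NOISE = NoiseModel(0.0, 0.0, 0)


def simulate_spectrum(
    candidates: list[CandidateProduct],
    fractions: np.ndarray,
    noise: NoiseModel = ZERO_NOISE,
    rng: np.random.Generator | None = None,
    total_intensity: float = 1e5,
    response_factors: np.ndarray | None = None,
    K: int | None = None,
) -> CentroidSpectrum:
    """Centroided spectrum of a regioisomer mixture (inverse of deconvolution).

    Peak k sits at the product base m/z + k * 1.00336 with intensity
    proportional to sum_j f_j * rf_j * pattern_j[k], perturbed by the
    noise model.  All candidates must share one product formula (true for
    regioisomers of the same transformation).  Pass an explicit ``rng``
    to draw several replicates from one stream; otherwise the noise
    model's seed is used.
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (len(candidates),) or np.any(f < 0) or not np.isclose(f.sum(), 1.0, atol=1e-9):
        raise ValueError("fractions must be nonnegative, one per candidate, summing to 1")
    base = candidates[0].ion_mz()
    if any(abs(c.ion_mz() - base) > 1e-6 for c in candidates):
        raise ValueError("candidates in one mixture spectrum must share the product formula")
    rf = np.ones(len(candidates)) if response_factors is None else np.asarray(response_factors, float)
    if K is None:
        K = max(len(c.retained_sites()) for c in candidates) + 3
    intensity = np.zeros(K + 1)
    for fj, rfj, cand in zip(f, rf, candidates):
        intensity += fj * rfj * predict_pattern(cand, K).probs
    intensity *= total_intensity
    if rng is None:
        rng = noise.rng()
    intensity = noise.apply(intensity, rng)
    mz = base + np.arange(K + 1) * C13_SPACING
    return CentroidSpectrum(mz, intensity)


@dataclass(frozen=True)
class KineticSystem:
    """First-order site competition on a partially labeled substrate.

    ``k_h[j]`` is the protio rate constant of site j (arbitrary units),
    ``kies[j]`` its kH/kD; deuterated copies of site j react at
    ``k_h[j] / kies[j]``.  ``conversion`` is the target overall fraction
    of substrate consumed.
    """

    scheme: LabelingScheme
    k_h: tuple[float, ...]
    kies: tuple[float, ...]
    conversion: float

    def __post_init__(self) -> None:
        n = len(self.scheme)
        if n > 16:
            raise ValueError("at most 16 labeled sites (2^n state enumeration)")
        if len(self.k_h) != n or len(self.kies) != n:
            raise ValueError("k_h and kies must align with the labeling scheme")
        if any(k <= 0 for k in self.k_h) or any(k <= 0 for k in self.kies):
            raise ValueError("rates and KIEs must be positive")
        if not (0.0 <= self.conversion < 1.0):
            raise ValueError("conversion must lie in [0, 1)")


@dataclass(frozen=True)
class KineticsResult:
    """Exact finite-conversion outcome of a :class:`KineticSystem`."""

    site_fractions: dict[str, float]      # cumulative product fractions by site
    residual_pattern: MassShiftDistribution  # label-count distribution of survivors
    residual_mass: float                  # surviving substrate fraction
    time: float


def simulate_kinetics(sys: KineticSystem) -> KineticsResult:
    """Enumerate all 2^n labeling states and integrate their depletion.

    State s occurs with probability prod_j d_j^{s_j} (1-d_j)^{1-s_j} and
    depletes at total rate K(s) = sum_j k_j(s_j).  The reaction time is
    solved (bisection to 1e-12) so the overall conversion matches the
    target; product at site j accumulates P(s) * k_j(s)/K(s) *
    (1 - exp(-K(s) t)) in closed form, and the residual pattern is the
    deuterium-count distribution of the surviving states.
    """
    ds = np.array(sys.scheme.fractions)
    kh = np.array(sys.k_h)
    kie = np.array(sys.kies)
    n = len(ds)
    states = np.array(list(itertools.product((0, 1), repeat=n)), dtype=float).reshape(2**n, n)
    probs = np.prod(np.where(states == 1, ds, 1.0 - ds), axis=1)
    site_rates = np.where(states == 1, kh / kie, kh)      # (2^n, n)
    total_rates = site_rates.sum(axis=1)

    if sys.conversion == 0.0:
        t = 0.0
    else:
        def surviving(t: float) -> float:
            return float(np.dot(probs, np.exp(-total_rates * t)))

        target = 1.0 - sys.conversion
        hi = 1.0
        while surviving(hi) > target:
            hi *= 2.0
        t = scipy.optimize.brentq(lambda x: surviving(x) - target, 0.0, hi, xtol=1e-12, rtol=1e-15)

    depleted = probs * (1.0 - np.exp(-total_rates * t))   # fraction of each state consumed
    per_site = (site_rates / total_rates[:, None]) * depleted[:, None]
    site_totals = per_site.sum(axis=0)
    converted = site_totals.sum()
    if converted > 0:
        site_fracs = site_totals / converted
    else:
        # conversion -> 0 limit: fractions follow the instantaneous rates
        rates0 = (site_rates * probs[:, None]).sum(axis=0)
        site_fracs = rates0 / rates0.sum()

    surviving_w = probs * np.exp(-total_rates * t)
    residual_mass = float(surviving_w.sum())
    counts = states.sum(axis=1).astype(int)
    pattern = np.zeros(n + 1)
    np.add.at(pattern, counts, surviving_w)
    residual = MassShiftDistribution.from_weights(pattern)
    return KineticsResult(
        site_fractions=dict(zip(sys.scheme.site_ids, site_fracs)),
        residual_pattern=residual,
        residual_mass=residual_mass,
        time=float(t),
    )


def simulate_dilution(
    r0s: dict[str, float],
    ds: dict[str, float],
    kies: dict[str, float],
    chis,
    noise_sigma: float = 0.0,
    seed: int = 0,
    reference_site: str | None = None,
    conversion: float = 1e-6,
) -> DilutionSeries:
    """Dilution experiment: labeled substrate mixed with unlabeled material.

    At labeled fraction chi every site's effective labeling is d*chi; each
    point runs the exact kinetics simulator at low conversion (default
    1e-6, the differential regime of the fitting model).  ``r0s`` are the
    protio rate constants by site; the reported ratio is probed site /
    reference site (the first d = 0 site by default, or the last site).
    Multiplicative Gaussian noise of relative size ``noise_sigma`` is
    applied to the ratios, seeded.
    """
    sites = list(r0s)
    if set(sites) != set(ds) or set(sites) != set(kies):
        raise ValueError("r0s, ds and kies must cover the same sites")
    if reference_site is None:
        unlabeled = [s for s in sites if ds[s] == 0.0]
        reference_site = unlabeled[0] if unlabeled else sites[-1]
    probed = [s for s in sites if s != reference_site]
    rng = np.random.default_rng(seed)
    chis = np.asarray(chis, dtype=float)
    if np.any((chis < 0) | (chis > 1)):
        raise ValueError("chi values must lie in [0, 1]")
    rows = []
    for chi in chis:
        scheme = LabelingScheme.from_dict({s: ds[s] * chi for s in sites})
        sys = KineticSystem(
            scheme, tuple(r0s[s] for s in sites), tuple(kies[s] for s in sites), conversion
        )
        rows.append(simulate_kinetics(sys).site_fractions)
    frac = pd.DataFrame(rows)
    ratios = frac[probed[0]].to_numpy() / frac[reference_site].to_numpy()
    if noise_sigma > 0:
        ratios = ratios * (1.0 + noise_sigma * rng.standard_normal(ratios.shape))
    return DilutionSeries(chis, ratios, fractions=frac)


# ---------------------------------------------------------------------------
# plate simulation

_PLATE_SCAFFOLD = "C7H7NO2"  # 3-carbomethoxypyridine scaffold
# six labeling schemes around the ~30/64/94% levels used for the plate substrates
_PLATE_SCHEMES = [
    {"C2": 0.30, "C4": 0.64, "C6": 0.94},
    {"C2": 0.25, "C4": 0.55, "C6": 0.85},
    {"C2": 0.35, "C4": 0.70, "C6": 0.90},
    {"C2": 0.20, "C4": 0.50, "C6": 0.80},
    {"C2": 0.40, "C4": 0.65, "C6": 0.88},
    {"C2": 0.28, "C4": 0.60, "C6": 0.92},
]
# four electronically diverse aryl radicals: net formula change of ArH - H2
_PLATE_REAGENTS = {
    "p-tolyl": "+C7H6",
    "phenyl": "+C6H4",
    "4-F-phenyl": "+C6H3F",
    "4-MeO-phenyl": "+C7H6O",
}


@dataclass(frozen=True)
class PlateResult:
    """Simulated microscale plate: spectra per well/replicate plus the truth table."""

    spectra: dict[tuple[str, int], CentroidSpectrum]
    truth: pd.DataFrame
    candidates: dict[str, list[CandidateProduct]] = field(repr=False, default_factory=dict)

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def write(self, out_dir: str | Path) -> None:
        """CSV tree: one spectrum per well/replicate plus truth.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (well, rep), spec in self.spectra.items():
            d = out / well
            d.mkdir(exist_ok=True)
            spec.to_csv(d / f"rep{rep}.csv")
        self.truth.to_csv(out / "truth.csv", index=False)


def default_plate_substrates() -> list[Substrate]:
    """Six partially labeled 3-substituted pyridine substrates."""
    return [
        Substrate(
            Formula.parse(_PLATE_SCAFFOLD),
            LabelingScheme.from_dict(scheme),
            name=f"S{i + 1}",
        )
        for i, scheme in enumerate(_PLATE_SCHEMES)
    ]


def plate_candidates(substrate: Substrate, delta: str) -> list[CandidateProduct]:
    """Site-consuming candidates plus the unlabeled-site (RPh-type) catch-all."""
    cands = [
        make_candidate(substrate, site, delta, name=site)
        for site in substrate.scheme.site_ids
    ]
    cands.append(make_candidate(substrate, None, delta, name="RPh"))
    return cands


def simulate_plate(
    substrates: list[Substrate] | None = None,
    reagents: dict[str, str] | None = None,
    replicates: int = 3,
    truth_fractions: dict[str, np.ndarray] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
) -> PlateResult:
    """Simulate a full microscale coupling plate analyzed by direct injection.

    Defaults mirror a 24-well layout: 6 labeled substrates (rows of the
    truth table) x 4 aryl-radical reagents, each well measured in
    triplicate -> 72 spectra and 24 truth rows.  Truth fractions default
    to a seeded flat Dirichlet draw over each well's candidates; pass
    ``truth_fractions`` (well id -> fraction vector) to pin them.
    """
    substrates = substrates if substrates is not None else default_plate_substrates()
    reagents = reagents if reagents is not None else dict(_PLATE_REAGENTS)
    if seed is not None:
        noise = NoiseModel(noise.mult_sigma, noise.add_sigma, seed)
    rng = noise.rng()
    spectra: dict[tuple[str, int], CentroidSpectrum] = {}
    cand_map: dict[str, list[CandidateProduct]] = {}
    rows = []
    for si, sub in enumerate(substrates):
        for ri, (reagent, delta) in enumerate(reagents.items()):
            well = f"{chr(ord('A') + si)}{ri + 1}"
            cands = plate_candidates(sub, delta)
            cand_map[well] = cands
            if truth_fractions is not None and well in truth_fractions:
                f = np.asarray(truth_fractions[well], dtype=float)
            else:
                f = rng.dirichlet(np.ones(len(cands)))
            row = {"well": well, "substrate": sub.name, "reagent": reagent}
            row.update({f"f_{c.name}": fv for c, fv in zip(cands, f)})
            rows.append(row)
            for rep in range(1, replicates + 1):
                spectra[(well, rep)] = simulate_spectrum(cands, f, noise=noise, rng=rng)
    return PlateResult(spectra, pd.DataFrame(rows), cand_map)
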