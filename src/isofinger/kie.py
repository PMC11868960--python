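"""Competitive kinetic isotope effects from dilution series.

With partially labeled material, a primary KIE suppresses reaction at the
deuterated fraction of a site, so the observed regioisomer ratio is
biased away from the inherent protio selectivity.  Mixing labeled with
unlabeled substrate at labeled fraction chi dilutes the effective
labeling of every site to d*chi.  Under first-order site competition at
low conversion the observed ratio of a probed site (labeling d, isotope
effect KIE = kH/kD) against an unlabeled reference site is linear in the
effective labeling::

    R(chi) = r0 * (1 - d*chi*(1 - 1/KIE))

so a straight-line fit in x = d*chi recovers the protio selectivity r0
as the intercept and the KIE from the slope, KIE = r0 / (r0 + slope).
At KIE > 1 the slope is negative; KIE < 1 (inverse effect) is permitted
and flagged.  Standard errors propagate to the KIE by the delta method.

A KIE also leaves a signature in the *residual substrate*: slow-reacting
deuterated molecules survive preferentially, so the residual isotope
pattern drifts heavy.  :func:`detect_kie` quantifies that drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopes import MassShiftDistribution
from .spectra import ObservedVector

#: mean-shift drift (in nominal mass units) above which a KIE is flagged
KIE_DETECT_THRESHOLD = 0.02


class KIEFitError(ValueError):
    """Degenerate or inconsistent dilution-series input."""


@dataclass(frozen=True)
class DilutionSeries:
    """Observed product ratios (or site fractions) vs labeled-substrate fraction chi.

    ``ratio`` is the regression response: probed-site / reference-site
    product ratio at each chi.  ``fractions`` optionally carries the full
    per-site fraction table (one column per site) for multi-site fits.
    ``sigma`` holds optional per-point ratio uncertainties.
    """

    chi: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray | None = None
    fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        if chi.shape != ratio.shape or chi.ndim != 1:
            raise KIEFitError("chi and ratio must be 1-D arrays of equal length")
        if np.any((chi < 0) | (chi > 1)):
            raise KIEFitError("labeled fractions chi must lie in [0, 1]")
        if len(np.unique(chi)) != chi.size:
            raise KIEFitError("chi values must be distinct")
        if np.any(ratio <= 0):
            raise KIEFitError("ratios must be positive")
        object.__setattr__(self, "chi", chi)
        object.__setattr__(self, "ratio", ratio)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != chi.shape or np.any(s <= 0):
                raise KIEFitError("sigma must be positive, one per point")
            object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.chi.size

    @classmethod
    def from_csv(cls, path: str | Path, ratio_column: str = "ratio") -> "DilutionSeries":
        """Read columns ``chi`` and ``ratio`` (plus optional ``sigma`` and
        per-site fraction columns) from a CSV file."""
        df = pd.read_csv(path)
        if "chi" not in df.columns:
            raise KIEFitError(f"{path}: missing required column 'chi'")
        if ratio_column not in df.columns:
            raise KIEFitError(f"{path}: missing response column {ratio_column!r}")
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        frac_cols = [c for c in df.columns if c not in ("chi", ratio_column, "sigma")]
        fractions = df[frac_cols] if frac_cols else None
        return cls(df["chi"].to_numpy(), df[ratio_column].to_numpy(), sigma, fractions)


@dataclass(frozen=True)
class KIEFitResult:
    """Dilution-extrapolation fit: protio selectivity and competitive KIE."""

    r0: float            # intercept: inherent protio regioselectivity ratio
    slope: float         # d(ratio)/d(d*chi)
    kie: float           # kH/kD at the probed site
    se_r0: float
    se_slope: float
    se_kie: float
    n_points: int
    resid_norm: float
    r_squared: float
    d: float             # site labeling fraction used as the x-scale
    inverse: bool        # kie < 1

    def summary(self) -> str:
        lines = [
            "Dilution-series competitive KIE fit",
            f"  n = {self.n_points} points, site labeling d = {self.d:.3f}",
            f"  protio selectivity r0 = {self.r0:.4f} +- {self.se_r0:.4f}",
            f"  slope               = {self.slope:.4f} +- {self.se_slope:.4f}",
            f"  KIE (kH/kD)         = {self.kie:.4f} +- {self.se_kie:.4f}"
            + ("  [inverse]" if self.inverse else ""),
            f"  residual norm {self.resid_norm:.3e}   R^2 = {self.r_squared:.5f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "r0": self.r0, "slope": self.slope, "kie": self.kie,
            "se_r0": self.se_r0, "se_slope": self.se_slope, "se_kie": self.se_kie,
            "n_points": self.n_points, "resid_norm": self.resid_norm,
            "r_squared": self.r_squared, "d": self.d, "inverse": self.inverse,
        }

    def predict(self, chi: np.ndarray) -> np.ndarray:
        return self.r0 + self.slope * self.d * np.asarray(chi, dtype=float)

    def plot(self, series: DilutionSeries | None = None, ax=None):
        """Observed ratios vs chi with the fitted extrapolation line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, 50)
        ax.plot(grid, self.predict(grid), "-", label=f"fit: r0={self.r0:.2f}, KIE={self.kie:.2f}")
        if series is not None:
            ax.plot(series.chi, series.ratio, "o", label="observed")
        ax.set_xlabel("labeled substrate fraction $\\chi$")
        ax.set_ylabel("product ratio R")
        ax.legend()
        return ax


class DilutionKIEModel:
    """Linear dilution-extrapolation model; ``fit()`` returns :class:`KIEFitResult`.

    Weighted least squares is used when the series carries per-point
    uncertainties, unweighted otherwise.
    """

    def __init__(self, series: DilutionSeries, d: float) -> None:
        if not (0.0 < d <= 1.0):
            raise KIEFitError(f"site deuterium fraction d must be in (0, 1], got {d}")
        if len(series) < 2:
            raise KIEFitError("need >= 2 distinct chi points to fit a line")
        self.series = series
        self.d = float(d)

    def fit(self) -> KIEFitResult:
        s = self.series
        x = self.d * s.chi
        X = np.column_stack([np.ones_like(x), x])
        if s.sigma is not None:
            w = 1.0 / s.sigma
            Xw, yw = X * w[:, None], s.ratio * w
        else:
            Xw, yw = X, s.ratio
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        r0, slope = float(beta[0]), float(beta[1])
        if r0 <= 0:
            raise KIEFitError(f"nonpositive fitted intercept r0 = {r0:.4g}")
        resid = s.ratio - X @ beta
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        n = len(s)
        if s.sigma is not None:
            cov = xtx_inv  # known per-point variances
        elif n > 2:
            cov = xtx_inv * float(resid @ resid) / (n - 2)
        else:
            cov = np.full((2, 2), np.nan)
        kie = r0 / (r0 + slope)
        if kie <= 0:
            raise KIEFitError(
                f"fitted slope {slope:.4g} implies nonpositive KIE; "
                "the linear dilution model does not describe these data"
            )
        # delta method: kie = r0/(r0+slope)
        grad = np.array([slope, -r0]) / (r0 + slope) ** 2
        se_kie = float(np.sqrt(grad @ cov @ grad)) if np.all(np.isfinite(cov)) else np.nan
        ss_tot = float(np.sum((s.ratio - s.ratio.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        return KIEFitResult(
            r0=r0, slope=slope, kie=float(kie),
            se_r0=float(np.sqrt(cov[0, 0])), se_slope=float(np.sqrt(cov[1, 1])),
            se_kie=se_kie, n_points=n, resid_norm=float(np.linalg.norm(resid)),
            r_squared=r2, d=self.d, inverse=bool(kie < 1.0),
        )


def fit_dilution_series(series: DilutionSeries, d: float) -> KIEFitResult:
    """One-call wrapper: ``DilutionKIEModel(series, d).fit()``."""
    return DilutionKIEModel(series, d).fit()


def fit_multisite_dilution(
    chis: np.ndarray,
    fractions: pd.DataFrame,
    ds: dict[str, float],
    reference_site: str | None = None,
) -> dict[str, KIEFitResult]:
    """Fit one KIE per labeled site from a multi-site dilution table.

    ``fractions`` has one column of product site fractions per site;
    ``ds`` maps site -> labeling fraction.  Each labeled site's ratio
    against the (unlabeled, d = 0) reference site is fit independently
    with the single-site model — valid because the reference site's rate
    is chi-independent.  The reference defaults to the first d = 0 site.
    """
    if reference_site is None:
        unlabeled = [s for s, dv in ds.items() if dv == 0.0]
        if not unlabeled:
            raise KIEFitError("no unlabeled (d = 0) reference site available")
        reference_site = unlabeled[0]
    if reference_site not in fractions.columns:
        raise KIEFitError(f"reference site {reference_site!r} missing from fraction table")
    out: dict[str, KIEFitResult] = {}
    ref = fractions[reference_site].to_numpy()
    for site, dv in ds.items():
        if site == reference_site or dv == 0.0:
            continue
        series = DilutionSeries(np.asarray(chis, float), fractions[site].to_numpy() / ref)
        out[site] = fit_dilution_series(series, dv)
    return out


def detect_kie(
    residual: ObservedVector | MassShiftDistribution,
    initial: MassShiftDistribution,
    threshold: float = KIE_DETECT_THRESHOLD,
) -> tuple[float, bool]:
    """Flag a KIE from drift of the residual-substrate isotope pattern.

    The statistic is |mean mass shift(residual) - mean mass shift(initial)|
    over a shared window; slow-reacting deuterated molecules accumulate in
    the residual, pushing its mean shift up, so any drift beyond the
    threshold (default 0.02 shift units) flags an isotope effect at a
    labeled position.
    """
    if isinstance(residual, MassShiftDistribution):
        rn = residual.probs
    else:
        rn = residual.normalized()
    if rn.size != len(initial):
        raise KIEFitError(
            f"window mismatch: residual has {rn.size} bins, initial {len(initial)}"
        )
    stat = float(abs(np.dot(np.arange(rn.size), rn) - initial.mean_shift()))
    return stat, stat > threshold


def correct_fractions_for_kie(
    observed_fractions: np.ndarray,
    ds: np.ndarray,
    kies: np.ndarray,
) -> np.ndarray:
    """Remove label-induced kinetic bias from observed site fractions.

    At a site with labeling d and isotope effect KIE the reactive flux is
    attenuated by ``1 - d*(1 - 1/KIE)`` relative to protio material; the
    inherent protio fractions are the observed ones divided by that
    factor and renormalized.  For competitive KIE < 3 the factor stays
    within [1/3, 1], which is why the correction is often negligible at
    low conversion.
    """
    f = np.asarray(observed_fractions, dtype=float)
    d = np.asarray(ds, dtype=float)
    k = np.asarray(kies, dtype=float)
    if not (f.shape == d.shape == k.shape):
        raise KIEFitError("fractions, ds and KIEs must be aligned")
    if np.any(k <= 0):
        raise KIEFitError("KIEs must be positive")
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise KIEFitError("observed fractions must sum to 1")
    factors = 1.0 - d * (1.0 - 1.0 / k)
    if np.any(factors <= 0):
        raise KIEFitError("correction factor <= 0; model invalid for these (d, KIE)")
    corrected = f / factors
    return corrected / corrected.sum()
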