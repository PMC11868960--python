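"""Spectral deconvolution of regioisomer mixtures and peak assignment.

The observed isotopologue vector of an *unseparated* product mixture is a
nonnegative combination of the candidate fingerprints::

    y ~= A w,   A[:, j] = predicted pattern of candidate j

Solving for w by linear regression gives the regioisomer ratios without
chromatographic separation.  Ordinary least squares (OLS) is tried first;
negative percent contributions are physically nonsensical, so when OLS
returns a negative weight the solver falls back to non-negative least
squares (NNLS) and flags it.

The fitting surface follows the statsmodels convention: build a
:class:`MixtureModel` from an observed vector and a design matrix, call
``fit()``, get a :class:`MixtureResults` with weights, normalized
fractions, residual diagnostics and a ``summary()`` table.  The
:func:`deconvolve` function is the one-call wrapper.

For *separated* peaks, :func:`assign_pattern` ranks candidates by cosine
similarity between the observed and predicted fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .chem import CandidateProduct
from .isotopes import DEFAULT_EXTRA_BINS, predict_pattern
from .spectra import ObservedVector

#: condition number above which near-identical labeling is flagged
COND_WARN_THRESHOLD = 1e6

#: OLS weights below this are treated as genuinely negative (auto fallback)
NEGATIVE_WEIGHT_TOL = -1e-9

#: top-two cosine scores closer than this flag an ambiguous assignment
AMBIGUITY_MARGIN = 0.02


class DeconvolutionError(ValueError):
    """Ill-posed or inconsistent deconvolution input."""


@dataclass(frozen=True)
class DesignMatrix:
    """Candidate fingerprint matrix: one unit-sum column per candidate."""

    A: np.ndarray
    names: tuple[str, ...]
    window: int

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[1] < 1:
            raise DeconvolutionError("design matrix must be 2-D with >= 1 column")
        if A.shape[1] != len(self.names):
            raise DeconvolutionError("one name per candidate column required")
        sums = A.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DeconvolutionError(f"columns must each sum to 1 (got {sums})")
        object.__setattr__(self, "A", A)

    @property
    def n_candidates(self) -> int:
        return self.A.shape[1]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A))


def build_design_matrix(
    candidates: list[CandidateProduct],
    K: int | None = None,
    include_envelope: bool = True,
) -> DesignMatrix:
    """Predict every candidate fingerprint over a shared window.

    All candidates must share the same parent substrate (one mixture, one
    labeling scheme).  Warns when the condition number exceeds 1e6 —
    near-identical retained labelings make the weights ill-determined.
    """
    if not candidates:
        raise DeconvolutionError("at least one candidate required")
    parent = candidates[0].parent
    if any(c.parent != parent for c in candidates[1:]):
        raise DeconvolutionError("all candidates must share the same parent substrate")
    if K is None:
        K = max(len(c.retained_sites()) for c in candidates) + DEFAULT_EXTRA_BINS
    cols = [predict_pattern(c, K, include_envelope=include_envelope).probs for c in candidates]
    dm = DesignMatrix(np.column_stack(cols), tuple(c.name for c in candidates), K)
    cond = dm.condition_number()
    if cond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"design matrix condition number {cond:.3g} > {COND_WARN_THRESHOLD:.0e}: "
            "candidate labelings are nearly indistinguishable",
            stacklevel=2,
        )
    return dm


class MixtureModel:
    """Linear unmixing model: observed isotopologue vector on candidate fingerprints.

    Parameters
    ----------
    y
        Observed intensity vector (an :class:`ObservedVector` or plain
        array over the same window as the design matrix).  Normalized to
        unit sum before regression — absolute intensity carries no
        information about the ratios.
    design
        :class:`DesignMatrix` of predicted candidate patterns.
    response_factors
        Optional per-candidate relative ionization responses.  Raw
        regression weights are divided by these before normalizing, for
        sensitivity analysis; by default equal response is assumed
        (measured isomer-to-isomer differences are typically small,
        ~1.2-1.5x).
    """

    def __init__(
        self,
        y: ObservedVector | np.ndarray,
        design: DesignMatrix,
        response_factors: np.ndarray | None = None,
    ) -> None:
        yv = y.y if isinstance(y, ObservedVector) else np.asarray(y, dtype=float)
        if yv.size != design.A.shape[0]:
            raise DeconvolutionError(
                f"observed window length {yv.size} != design window {design.A.shape[0]}"
            )
        total = yv.sum()
        if total <= 0:
            raise DeconvolutionError("zero total intensity; nothing to deconvolve")
        self.y = yv / total
        self.design = design
        if response_factors is not None:
            rf = np.asarray(response_factors, dtype=float)
            if rf.shape != (design.n_candidates,) or np.any(rf <= 0):
                raise DeconvolutionError("response_factors must be positive, one per candidate")
            self.response_factors = rf
        else:
            self.response_factors = None

    def fit(self, method: str = "auto") -> "MixtureResults":
        """Solve for candidate weights.

        ``method`` is ``"ols"``, ``"nnls"`` or ``"auto"`` (OLS first,
        NNLS rerun + fallback flag if any OLS weight is negative).
        """
        if method not in ("auto", "ols", "nnls"):
            raise DeconvolutionError(f"unknown method {method!r}")
        A = self.design.A
        fallback = False
        if method in ("auto", "ols"):
            rank = np.linalg.matrix_rank(A)
            if rank < self.design.n_candidates:
                raise DeconvolutionError(
                    "design matrix is rank-deficient under OLS; use method='nnls'"
                )
            w, *_ = np.linalg.lstsq(A, self.y, rcond=None)
            used = "ols"
            if method == "auto" and np.any(w < NEGATIVE_WEIGHT_TOL):
                w, _ = scipy.optimize.nnls(A, self.y)
                used, fallback = "nnls", True
        else:
            w, _ = scipy.optimize.nnls(A, self.y)
            used = "nnls"
        resid = self.y - A @ w
        corrected = w / self.response_factors if self.response_factors is not None else w
        total = corrected.sum()
        if total <= 0:
            raise DeconvolutionError("all fitted weights are zero; cannot form fractions")
        return MixtureResults(
            weights=w,
            fractions=corrected / total,
            names=self.design.names,
            method=used,
            fallback=fallback,
            resid_norm=float(np.linalg.norm(resid)),
            condition_number=self.design.condition_number(),
            observed=self.y,
            design=self.design,
        )


@dataclass(frozen=True)
class MixtureResults:
    """Fitted regioisomer weights with residual diagnostics."""

    weights: np.ndarray
    fractions: np.ndarray
    names: tuple[str, ...]
    method: str
    fallback: bool
    resid_norm: float
    condition_number: float
    observed: np.ndarray
    design: DesignMatrix

    def __post_init__(self) -> None:
        if self.method == "nnls" and np.any(self.weights < 0):
            raise DeconvolutionError("NNLS produced negative weights")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": list(self.names),
                "raw_weight": self.weights,
                "fraction": self.fractions,
                "method": self.method,
                "resid_norm": self.resid_norm,
                "fallback": self.fallback,
            }
        )

    def summary(self) -> str:
        lines = [
            "Regioisomer mixture deconvolution",
            f"  method: {self.method}" + ("  (OLS->NNLS fallback)" if self.fallback else ""),
            f"  residual norm: {self.resid_norm:.3e}   cond(A): {self.condition_number:.3g}",
            f"  {'candidate':<20} {'raw weight':>12} {'fraction':>10}",
        ]
        for name, w, f in zip(self.names, self.weights, self.fractions):
            lines.append(f"  {name:<20} {w:>12.5f} {f:>10.4f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Bar plot of observed vs reconstructed isotopologue intensities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(self.observed.size)
        ax.bar(k - 0.2, self.observed, width=0.4, label="observed")
        ax.bar(k + 0.2, self.design.A @ self.weights, width=0.4, label="fit")
        ax.set_xlabel("nominal mass shift")
        ax.set_ylabel("normalized intensity")
        ax.legend()
        return ax


def deconvolve(
    y: ObservedVector | np.ndarray,
    A: DesignMatrix,
    method: str = "auto",
    response_factors: np.ndarray | None = None,
) -> MixtureResults:
    """One-call wrapper: ``MixtureModel(y, A).fit(method)``."""
    return MixtureModel(y, A, response_factors=response_factors).fit(method)


@dataclass(frozen=True)
class AssignmentResult:
    """Ranked candidate assignments for one separated LC peak."""

    ranking: tuple[tuple[str, float, float], ...]  # (candidate, cosine, residual)
    ambiguous: bool = field(default=False)

    @property
    def best(self) -> str:
        return self.ranking[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["candidate", "score", "residual"])


def assign_pattern(
    y: ObservedVector | np.ndarray,
    candidates: list[CandidateProduct],
    include_envelope: bool = True,
) -> AssignmentResult:
    """Identify which candidate a separated peak's fingerprint matches.

    Similarity is the cosine between the normalized observed vector and
    each predicted pattern (scale-free, the standard spectral-match
    score); ties are broken by the smaller least-squares residual.  The
    result is flagged ambiguous when the top two scores differ by < 0.02.
    """
    if not candidates:
        raise DeconvolutionError("empty candidate list")
    yv = y.y if isinstance(y, ObservedVector) else np.asarray(y, dtype=float)
    total = yv.sum()
    if total <= 0:
        raise DeconvolutionError("zero total intensity; nothing to assign")
    yn = yv / total
    K = yv.size - 1
    rows = []
    for c in candidates:
        p = predict_pattern(c, K, include_envelope=include_envelope).probs
        cos = float(np.dot(yn, p) / (np.linalg.norm(yn) * np.linalg.norm(p)))
        resid = float(np.linalg.norm(yn - p))
        rows.append((c.name, cos, resid))
    rows.sort(key=lambda r: (-r[1], r[2]))
    ambiguous = len(rows) > 1 and (rows[0][1] - rows[1][1]) < AMBIGUITY_MARGIN
    return AssignmentResult(tuple(rows), ambiguous)
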