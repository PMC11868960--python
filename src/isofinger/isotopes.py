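"""Mass-shift isotopologue distributions: the isotopic fingerprints.

Two independent sources contribute to the unit-mass isotope pattern of a
product ion:

* the *label* component — the number of deuteriums retained from the
  partially labeled sites follows a Poisson-binomial distribution over
  the independent per-site incorporation fractions; and
* the *natural-abundance* component — the 13C/15N/18O/81Br... envelope of
  the product formula.

Both are probability vectors over nominal mass shift k relative to the
all-protio, all-lightest-isotope ion, and the observable fingerprint is
their discrete convolution.  At unit resolution the 13C (+1.00336 Da) and
H-to-D (+1.00628 Da) shifts fall in the same nominal bin, which is exactly
the regime of the single-quadrupole data this method targets.

All distributions are computed by exact polynomial convolution — the
vectors are tiny, and exactness lets tests pin results to 1e-12 against
brute-force enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .chem import CandidateProduct, Formula
from .elements import ABUNDANCE

#: extra window bins beyond the retained label count, for the 13C/Br tail
DEFAULT_EXTRA_BINS = 3


@dataclass(frozen=True)
class MassShiftDistribution:
    """Probability vector over nominal mass shifts 0..K (unit-mass bins).

    Shift 0 is the fully protio, all-lightest-isotope protonated ion; the
    common "M+1 ... M+5" display labels map onto internal shifts 0..4.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probability vector must be a nonempty 1-D array")
        if np.any(p < -1e-15):
            raise ValueError("probabilities must be nonnegative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))

    @classmethod
    def from_weights(cls, w: Iterable[float]) -> "MassShiftDistribution":
        """Normalize arbitrary nonnegative weights into a distribution."""
        w = np.asarray(list(w), dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("weights sum to zero; cannot normalize")
        return cls(w / total)

    def __len__(self) -> int:
        return self.probs.size

    @property
    def window(self) -> int:
        """Largest shift index K."""
        return self.probs.size - 1

    def mean_shift(self) -> float:
        """Expected nominal mass shift, E[k]."""
        return float(np.dot(np.arange(self.probs.size), self.probs))

    def truncated(self, K: int) -> "MassShiftDistribution":
        """Truncate to shifts 0..K and renormalize the retained mass."""
        if K < 0:
            raise ValueError("window K must be >= 0")
        p = self.probs[: K + 1]
        if p.size < K + 1:
            p = np.pad(p, (0, K + 1 - p.size))
        return MassShiftDistribution.from_weights(p)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"shift": np.arange(self.probs.size), "probability": self.probs}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MassShiftDistribution":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(np.asarray(df["probability"], dtype=float))


def label_count_distribution(ds: Sequence[float]) -> MassShiftDistribution:
    """Poisson-binomial distribution of the retained deuterium count.

    ``p[k]`` is the probability that exactly k of the independent sites
    carry D, computed by iterative convolution of per-site Bernoulli
    vectors ``[1-d, d]``.  Length is ``len(ds) + 1``; an empty site list
    gives the point mass [1.0].
    """
    p = np.array([1.0])
    for d in ds:
        if not (0.0 <= d <= 1.0):
            raise ValueError(f"deuterium fraction must be in [0,1], got {d}")
        p = np.convolve(p, [1.0 - d, d])
    return MassShiftDistribution(p / p.sum())


def natural_envelope(formula: Formula, K: int | None = None) -> MassShiftDistribution:
    """Unit-mass-binned natural-abundance isotope envelope of a formula.

    Computed by per-element polynomial convolution of the embedded
    abundance vectors; optionally truncated to shifts 0..K and
    renormalized.  Hydrogen contributes nothing (deliberate-label-only
    deuterium model).
    """
    p = np.array([1.0])
    for sym, n in formula.counts.items():
        vec = np.asarray(ABUNDANCE[sym], dtype=float)
        for _ in range(n):
            p = np.convolve(p, vec)
    dist = MassShiftDistribution(p / p.sum())
    return dist if K is None else dist.truncated(K)


def convolve_shift(
    a: MassShiftDistribution, b: MassShiftDistribution, K: int | None = None
) -> MassShiftDistribution:
    """Discrete convolution of two shift distributions, truncated to 0..K."""
    p = np.convolve(a.probs, b.probs)
    dist = MassShiftDistribution.from_weights(p)
    return dist if K is None else dist.truncated(K)


def predict_pattern(
    candidate: CandidateProduct,
    K: int | None = None,
    include_envelope: bool = True,
) -> MassShiftDistribution:
    """Predicted isotopic fingerprint of one candidate product ion.

    The Poisson-binomial label distribution over the candidate's retained
    sites, convolved with the natural-abundance envelope of the product
    formula (set ``include_envelope=False`` for the labels-only pattern).
    This is one column of the deconvolution design matrix.

    Default window: retained label count + 3 extra bins for the 13C/Br
    tail.
    """
    labels = label_count_distribution(candidate.retained_fractions())
    if K is None:
        K = labels.window + DEFAULT_EXTRA_BINS
    if K < len(candidate.retained_sites()):
        raise ValueError(
            f"window K={K} shorter than the {len(candidate.retained_sites())} retained labeled sites"
        )
    if not include_envelope:
        return labels.truncated(K)
    env = natural_envelope(candidate.formula)
    return convolve_shift(labels, env, K)


def incorporation_from_nmr(observed_integral: float, expected_protons: float) -> float:
    """Per-site deuterium fraction from a 1H NMR integral.

    The site resonance is integrated against a non-labeled reference;
    d = 1 - observed/expected, clamped to [0, 1].  Values outside [0, 1]
    by more than 0.02 trigger a warning (integration or referencing
    problem).
    """
    if expected_protons <= 0:
        raise ValueError("expected_protons must be positive")
    if observed_integral < 0:
        raise ValueError("observed_integral must be >= 0")
    d = 1.0 - observed_integral / expected_protons
    if d < -0.02 or d > 1.02:
        warnings.warn(
            f"NMR-derived deuterium fraction {d:.3f} outside [0,1] by >0.02; "
            "check integration reference",
            stacklevel=2,
        )
    return float(min(1.0, max(0.0, d)))
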