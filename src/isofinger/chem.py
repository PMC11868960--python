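"""Molecular formulas, labeled substrates and candidate regioisomeric products.

The chemistry model is deliberately minimal: a substrate is a molecular
formula plus a list of *labeled sites*, each carrying the deuterium
incorporation fraction measured by 1H NMR of the starting material.  No
structure or SMILES awareness is needed — the isotopic-fingerprint method
only uses per-site incorporation fractions.

A :class:`CandidateProduct` is one column of the eventual design matrix:
"the reaction consumed site X (or no labeled site at all) and changed the
formula by delta".  Consuming a site removes its label from the product;
a ``consumed_site=None`` candidate models reaction at an unlabeled
position and retains every label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .elements import KNOWN_ELEMENTS, MONOISOTOPIC_MASS, PROTON_MASS


class FormulaError(ValueError):
    """Malformed or chemically impossible formula input."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_DELTA_SEG = re.compile(r"([+-]?)((?:[A-Z][a-z]?\d*)+)")


def parse_formula(text: str) -> "Formula":
    """Parse a Hill-notation formula string such as ``"C7H7NO2"``.

    Raises :class:`FormulaError` on empty input, unknown element symbols,
    or text that does not match the element-count grammar.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula(counts)


def parse_delta(text: str) -> dict[str, int]:
    """Parse a signed formula delta such as ``"+C7H6"`` or ``"+Br-H"``.

    Returns signed element counts; segments without an explicit sign are
    added.  ``"C7H6"`` == ``"+C7H6"``; ``"Br-H"`` means add one Br,
    remove one H (net change of an aromatic bromination).
    """
    if not text or not text.strip():
        raise FormulaError("empty delta string")
    text = text.replace(" ", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _DELTA_SEG.match(text, pos)
        if not m or m.start() != pos:
            raise FormulaError(f"malformed delta {text!r} at position {pos}")
        sign = -1 if m.group(1) == "-" else 1
        for sym, cnt in parse_formula(m.group(2)).counts.items():
            counts[sym] = counts.get(sym, 0) + sign * cnt
        pos = m.end()
    return {k: v for k, v in counts.items() if v != 0}


@dataclass(frozen=True)
class Formula:
    """Element counts of a neutral molecule; immutable.

    Counts must be nonnegative and every element must exist in the
    embedded isotope table.
    """

    counts: dict[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in KNOWN_ELEMENTS:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"negative or non-integer count for {sym}: {n}")
            if n:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __add__(self, other: "Formula | dict[str, int]") -> "Formula":
        delta = other.counts if isinstance(other, Formula) else other
        return self.apply_delta(delta)

    def apply_delta(self, delta: dict[str, int]) -> "Formula":
        """Add signed element counts; negative resulting counts are rejected."""
        out = dict(self.counts)
        for sym, n in delta.items():
            new = out.get(sym, 0) + n
            if new < 0:
                raise FormulaError(
                    f"delta removes more {sym} than present "
                    f"({out.get(sym, 0)} {sym} in {self.hill()}, delta {n:+d})"
                )
            out[sym] = new
        return Formula(out)

    def hill(self) -> str:
        """Canonical Hill-notation serialization (C, H, then alphabetical)."""
        parts = []
        order = [s for s in ("C", "H") if s in self.counts]
        order += sorted(s for s in self.counts if s not in ("C", "H"))
        for sym in order:
            n = self.counts[sym]
            parts.append(sym + (str(n) if n != 1 else ""))
        return "".join(parts)

    def monoisotopic_mass(self) -> float:
        """Mass of the all-lightest-isotope, all-protio neutral molecule, Da."""
        return sum(MONOISOTOPIC_MASS[s] * n for s, n in self.counts.items())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Formula({self.hill()!r})"


@dataclass(frozen=True)
class LabeledSite:
    """One partially deuterated position: identifier and D fraction d in [0, 1]."""

    site: str
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"deuterium fraction for site {self.site!r} must be in [0,1], got {self.d}")


@dataclass(frozen=True)
class LabelingScheme:
    """Ordered, statistically independent labeled sites with unique identifiers."""

    sites: tuple[LabeledSite, ...]

    def __post_init__(self) -> None:
        sites = tuple(
            s if isinstance(s, LabeledSite) else LabeledSite(*s) for s in self.sites
        )
        ids = [s.site for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site identifiers in labeling scheme: {ids}")
        object.__setattr__(self, "sites", sites)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "LabelingScheme":
        return cls(tuple(LabeledSite(k, v) for k, v in d.items()))

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site for s in self.sites)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(s.d for s in self.sites)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class Substrate:
    """A labeled starting material: formula + labeling scheme + adduct convention.

    Only protonation ([M+H]+, charge 1) is implemented; the adduct field is
    a hook for other conventions.  ``monoisotopic_mass``, when given
    explicitly, must agree with the formula to 1e-4 Da.
    """

    formula: Formula
    scheme: LabelingScheme
    adduct: str = "[M+H]+"
    charge: int = 1
    monoisotopic_mass: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.scheme) > self.formula["H"]:
            raise ValueError(
                f"{len(self.scheme)} labeled sites exceed the hydrogen count "
                f"({self.formula['H']}) of {self.formula.hill()}"
            )
        if self.adduct not in ("[M+H]+", "M+H"):
            raise ValueError(f"unsupported adduct {self.adduct!r}; only [M+H]+ is implemented")
        if self.charge != 1:
            raise ValueError("only charge 1 is implemented")
        computed = self.formula.monoisotopic_mass()
        if self.monoisotopic_mass is None:
            object.__setattr__(self, "monoisotopic_mass", computed)
        elif abs(self.monoisotopic_mass - computed) > 1e-4:
            raise ValueError(
                f"declared monoisotopic mass {self.monoisotopic_mass} differs from "
                f"formula mass {computed:.5f} by more than 1e-4 Da"
            )

    def ion_mz(self) -> float:
        """m/z of the all-protio, all-lightest-isotope protonated ion."""
        return self.formula.monoisotopic_mass() + PROTON_MASS


@dataclass(frozen=True)
class CandidateProduct:
    """One possible regioisomeric product: which labeled site was consumed
    and how the transformation changed the formula.

    ``consumed_site=None`` models reaction at an unlabeled position: all
    labels are retained.  Including such a candidate in the design matrix
    is best practice whenever reaction can occur away from the labeled
    sites (e.g. on an aryl substituent).
    """

    parent: Substrate
    consumed_site: str | None
    delta: dict[str, int] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.consumed_site is not None and self.consumed_site not in self.parent.scheme.site_ids:
            raise ValueError(
                f"consumed site {self.consumed_site!r} not in labeling scheme "
                f"{self.parent.scheme.site_ids}"
            )
        # validates nonnegative resulting counts eagerly
        object.__setattr__(self, "_formula", self.parent.formula.apply_delta(self.delta))
        if not self.name:
            object.__setattr__(self, "name", self.consumed_site or "unlabeled-site")

    @property
    def formula(self) -> Formula:
        return self._formula  # type: ignore[attr-defined]

    def retained_sites(self) -> tuple[LabeledSite, ...]:
        return tuple(s for s in self.parent.scheme.sites if s.site != self.consumed_site)

    def retained_fractions(self) -> tuple[float, ...]:
        return tuple(s.d for s in self.retained_sites())

    def ion_mz(self) -> float:
        """m/z of the product's fully protio monoisotopic [M+H]+ ion."""
        return self.formula.monoisotopic_mass() + PROTON_MASS


def make_candidate(
    substrate: Substrate,
    consumed_site: str | None,
    delta: dict[str, int] | str,
    name: str = "",
) -> CandidateProduct:
    """Construct a candidate product; ``delta`` may be a signed-formula string."""
    if isinstance(delta, str):
        delta = parse_delta(delta)
    return CandidateProduct(substrate, consumed_site, delta, name)
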