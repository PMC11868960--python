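"""Embedded element isotope data (IUPAC 2021 representative values).

The table covers the elements that occur in the substrates and
functionalization reagents this package targets (organic scaffolds plus
halogenation/cyanation chemistry).  Abundance vectors are indexed by
*nominal* mass shift relative to the lightest isotope, matching the
unit-mass binning used throughout: ``ABUNDANCE["Br"][2]`` is the 81Br
probability sitting in the +2 bin.

Deuterium's natural abundance (0.0115%) is deliberately omitted from the
hydrogen vector: only user-declared labels contribute D, and the natural
level is far below unit-resolution instrument precision.
"""

from __future__ import annotations

# monoisotopic mass of the lightest (principal) isotope, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "Si": 27.9769265327,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "I": 126.904468,
}

# natural-abundance probability by nominal mass shift (sums to 1)
ABUNDANCE: dict[str, tuple[float, ...]] = {
    "H": (1.0,),  # 2H neglected; see module docstring
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "Si": (0.92223, 0.04685, 0.03092),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Cl": (0.7576, 0.0, 0.2424),
    "Br": (0.5069, 0.0, 0.4931),
    "I": (1.0,),
}

#: mass of a proton (charge carrier for [M+H]+), Da
PROTON_MASS = 1.00727646688

#: 13C - 12C spacing, Da; the nominal +1 bin center spacing
C13_SPACING = 1.00335484

#: 2H - 1H spacing, Da; lumped into the same +1 bin at unit resolution
D_H_SPACING = 1.00627675

KNOWN_ELEMENTS = frozenset(MONOISOTOPIC_MASS)
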