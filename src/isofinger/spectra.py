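"""Centroided-spectrum ingestion and isotopologue-vector extraction.

A :class:`CentroidSpectrum` is a sorted list of (m/z, intensity) peaks
from CSV ("mz,intensity", header optional) or mzML (centroided scans via
pyteomics).  :func:`extract_vector` pulls the observed intensity vector
y[0..K] for a target ion by summing intensities in unit-mass bins spaced
by the 13C shift; at the default 0.3 Da tolerance the slightly wider
H-to-D spacing lands in the same bin, matching unit-resolution data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import C13_SPACING


class SpectrumError(ValueError):
    """Unreadable, empty, or inconsistent spectrum input."""


@dataclass(frozen=True)
class CentroidSpectrum:
    """Peak-picked mass spectrum: m/z strictly increasing, intensities >= 0."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise SpectrumError("m/z and intensity arrays must be 1-D and equal length")
        if np.any(inten < 0):
            raise SpectrumError("negative intensities")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            # merge exact duplicates rather than reject
            uniq, inv = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, inten)
            mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.mz.size

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(path, index=False)


@dataclass(frozen=True)
class ObservedVector:
    """Observed isotopologue intensities aligned to mass-shift bins 0..K."""

    y: np.ndarray
    base_mz: float
    tol: float

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if np.any(y < 0):
            raise SpectrumError("observed intensities must be >= 0")
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.y.size

    @property
    def total(self) -> float:
        return float(self.y.sum())

    def normalized(self) -> np.ndarray:
        """Unit-sum copy of the intensity vector."""
        if self.total <= 0:
            raise SpectrumError("zero total intensity; cannot normalize")
        return self.y / self.total


def _load_csv(path: Path) -> CentroidSpectrum:
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise SpectrumError(f"unreadable spectrum CSV {path}: {exc}") from exc
    # header optional: drop a non-numeric first row
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] < 2 or len(df) == 0:
        raise SpectrumError(f"spectrum CSV {path} must have two columns mz,intensity")
    return CentroidSpectrum(
        df.iloc[:, 0].astype(float).to_numpy(), df.iloc[:, 1].astype(float).to_numpy()
    )


_NS = "{http://psi.hupo.org/ms/mzml}"
# controlled-vocabulary accessions needed to decode binary data arrays
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    import base64
    import struct
    import zlib

    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    kind = _ACC_MZ_ARRAY if _ACC_MZ_ARRAY in accs else (
        _ACC_INT_ARRAY if _ACC_INT_ARRAY in accs else None
    )
    binary = bda.find(f"{_NS}binary")
    raw = base64.b64decode((binary.text or "").encode())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    width, code = (4, "f") if _ACC_F32 in accs else (8, "d")
    values = np.array(struct.unpack(f"<{len(raw) // width}{code}", raw), dtype=float)
    return kind, values


def _load_mzml(
    path: Path,
    scan_index: int | None,
    rt_window: tuple[float, float] | None,
    allow_profile: bool,
) -> CentroidSpectrum:
    # minimal HUPO-PSI mzML reader: centroided spectra, 32/64-bit float
    # arrays, zlib or no compression (no installed mzML parser is usable
    # in this stack, so the subset this package needs is implemented here)
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SpectrumError(f"unreadable mzML {path}: {exc}") from exc
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for i, spectrum in enumerate(tree.iter(f"{_NS}spectrum")):
        if scan_index is not None and i != scan_index:
            continue
        if rt_window is not None:
            rt = None
            for cv in spectrum.iter(f"{_NS}cvParam"):
                if cv.get("accession") == _ACC_SCAN_START:
                    rt = float(cv.get("value"))
            if rt is None or not (rt_window[0] <= rt <= rt_window[1]):
                continue
        own_accs = {
            cv.get("accession")
            for cv in spectrum.findall(f"{_NS}cvParam")
        }
        if _ACC_PROFILE in own_accs and not allow_profile:
            raise SpectrumError(
                f"scan {i} in {path} is profile data; centroid it upstream or "
                "pass allow_profile=True to take the raw points as centroids"
            )
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{_NS}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind is not None:
                arrays[kind] = values
        if _ACC_MZ_ARRAY not in arrays or _ACC_INT_ARRAY not in arrays:
            raise SpectrumError(f"scan {i} in {path} lacks m/z or intensity arrays")
        mzs.append(arrays[_ACC_MZ_ARRAY])
        intens.append(arrays[_ACC_INT_ARRAY])
        if scan_index is not None:
            break
    if not mzs:
        raise SpectrumError(f"no matching scan in {path} (index={scan_index}, rt={rt_window})")
    return CentroidSpectrum(np.concatenate(mzs), np.concatenate(intens))


def load_spectrum(
    path,
    format: str | None = None,
    scan_index: int | None = None,
    rt_window: tuple[float, float] | None = None,
    allow_profile: bool = False,
) -> CentroidSpectrum:
    """Load a centroided spectrum from CSV or mzML.

    Parameters
    ----------
    path
        Input file. Format inferred from the suffix unless given.
    format
        ``"csv"`` or ``"mzml"``.
    scan_index, rt_window
        mzML scan selector: a 0-based scan index, or an inclusive
        retention-time window (same unit as the file) whose scans are
        summed. One of the two is required for multi-scan files; with
        neither, all scans are summed.
    allow_profile
        Accept profile-mode mzML scans as-is (otherwise rejected).
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumError(f"spectrum file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        spec = _load_csv(path)
    elif fmt == "mzml":
        spec = _load_mzml(path, scan_index, rt_window, allow_profile)
    else:
        raise SpectrumError(f"unsupported spectrum format {fmt!r} (csv or mzml)")
    if len(spec) == 0:
        raise SpectrumError(f"empty spectrum in {path}")
    return spec


def extract_vector(
    spec: CentroidSpectrum, base_mz: float, K: int, tol: float = 0.3
) -> ObservedVector:
    """Extract the observed isotopologue vector y[0..K] for a target ion.

    Bin k collects all intensity within ``base_mz + k*1.00336 +- tol``.
    Bin centers use the 13C spacing; the default 0.3 Da tolerance absorbs
    the 2.9 mDa/bin drift of pure-D shifts over windows of practical
    length.  Missing bins are zero.
    """
    if base_mz <= 0:
        raise SpectrumError("base_mz must be positive")
    if not (0.0 < tol < 0.5):
        raise SpectrumError(f"tolerance must be in (0, 0.5) Da, got {tol}")
    if 2 * tol >= C13_SPACING:
        raise SpectrumError(f"tolerance {tol} makes adjacent unit-mass bins overlap")
    centers = base_mz + np.arange(K + 1) * C13_SPACING
    y = np.zeros(K + 1)
    for k, c in enumerate(centers):
        mask = np.abs(spec.mz - c) <= tol
        y[k] = spec.intensity[mask].sum()
    return ObservedVector(y, base_mz, tol)
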