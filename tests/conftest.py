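import base64
import itertools
import struct

import numpy as np
import pytest

from isofinger import (
    Formula,
    LabelingScheme,
    Substrate,
    make_candidate,
)

# --- shared model systems ------------------------------------------------


@pytest.fixture
def toy_substrate():
    """Carbon-free three-site toy: labels 25/50/75%, no natural envelope."""
    return Substrate(
        Formula({"H": 3}),
        LabelingScheme.from_dict({"A": 0.25, "B": 0.50, "C": 0.75}),
        name="toy",
    )


@pytest.fixture
def toy_candidates(toy_substrate):
    return [make_candidate(toy_substrate, s, {}, name=s) for s in ("A", "B", "C")]


@pytest.fixture
def nicotinate():
    """Methyl nicotinate scaffold, three reactive ring sites labeled ~30/64/94%."""
    return Substrate(
        Formula.parse("C7H7NO2"),
        LabelingScheme.from_dict({"C2": 0.30, "C4": 0.64, "C6": 0.94}),
        name="methyl-nicotinate",
    )


@pytest.fixture
def nicotinate_candidates(nicotinate):
    cands = [make_candidate(nicotinate, s, "+C7H6", name=s) for s in ("C2", "C4", "C6")]
    cands.append(make_candidate(nicotinate, None, "+C7H6", name="RPh"))
    return cands


# --- independent oracles -------------------------------------------------


def brute_force_label_dist(ds):
    """2^n enumeration of the deuterium-count distribution; independent of
    the iterative-convolution implementation."""
    n = len(ds)
    p = np.zeros(n + 1)
    for state in itertools.product((0, 1), repeat=n):
        prob = 1.0
        for s, d in zip(state, ds):
            prob *= d if s else (1.0 - d)
        p[sum(state)] += prob
    return p


def brute_force_convolve(a, b):
    """Direct double-sum convolution."""
    out = np.zeros(len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


# --- minimal mzML writer -------------------------------------------------

_MZML_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
{spectra}
    </spectrumList>
  </run>
</mzML>
"""

_SPECTRUM_TEMPLATE = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{npeaks}">
        <cvParam cvRef="MS" accession="MS:{mode_acc}" name="{mode_name}" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""


def _b64(values):
    return base64.b64encode(struct.pack("<%dd" % len(values), *values)).decode()


def write_mzml(path, scans, profile=False):
    """Write a minimal centroided (or profile) mzML file.

    ``scans`` is a list of (rt_minutes, mz_array, intensity_array).
    """
    mode_acc, mode_name = ("1000128", "profile spectrum") if profile else ("1000127", "centroid spectrum")
    blocks = []
    for i, (rt, mz, inten) in enumerate(scans):
        mz_b64, int_b64 = _b64(list(mz)), _b64(list(inten))
        blocks.append(
            _SPECTRUM_TEMPLATE.format(
                index=i, npeaks=len(mz), rt=rt, mode_acc=mode_acc, mode_name=mode_name,
                mz_len=len(mz_b64), int_len=len(int_b64), mz_b64=mz_b64, int_b64=int_b64,
            )
        )
    path.write_text(_MZML_TEMPLATE.format(count=len(scans), spectra="\n".join(blocks)))
    return path
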