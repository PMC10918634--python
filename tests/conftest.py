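"""Shared fixtures: reference databases and an independent mzML writer."""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path

import numpy as np
import pytest

from zoomsid.refdb import fixture_contaminants, fixture_reference_db

_SPECTRUM_TEMPLATE = """
    <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{mz_len}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="{mz_comp}" name="compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{mz_b64}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{int_len}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="{int_comp}" name="compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{int_b64}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""

_DOC_TEMPLATE = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">{body}
    </spectrumList>
  </run>
</mzML>"""


def write_minimal_mzml(path: Path, spectra, compress: bool = False) -> None:
    """Write a minimal standalone mzML file (independent of the package).

    ``spectra`` is a sequence of (mz, intensity) array pairs, encoded as
    little-endian 64-bit floats, base64, optionally zlib-compressed.
    """
    comp_acc = "MS:1000574" if compress else "MS:1000576"
    chunks = []
    for i, (mz, inten) in enumerate(spectra):

        def encode(arr):
            raw = struct.pack(f"<{len(arr)}d", *[float(v) for v in arr])
            if compress:
                raw = zlib.compress(raw)
            return base64.b64encode(raw).decode()

        mz_b64, int_b64 = encode(mz), encode(inten)
        chunks.append(
            _SPECTRUM_TEMPLATE.format(
                index=i,
                scan=i + 1,
                n=len(mz),
                mz_b64=mz_b64,
                int_b64=int_b64,
                mz_len=len(mz_b64),
                int_len=len(int_b64),
                mz_comp=comp_acc,
                int_comp=comp_acc,
            )
        )
    Path(path).write_text(_DOC_TEMPLATE.format(count=len(spectra), body="".join(chunks)))


@pytest.fixture(scope="session")
def mzml_writer():
    return write_minimal_mzml


@pytest.fixture(scope="session")
def full_db():
    return fixture_reference_db()


@pytest.fixture(scope="session")
def africa_db():
    return fixture_reference_db("africa")


@pytest.fixture(scope="session")
def eurasia_db():
    return fixture_reference_db("eurasia")


@pytest.fixture(scope="session")
def contaminants():
    return fixture_contaminants()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
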