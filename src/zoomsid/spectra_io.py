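"""Reading raw spectra, grouping technical replicates, writing peak lists.

Supported input formats are mzML (self-contained reader for the
profile/peak-array subset of the standard) and two-column delimited text
(m/z, intensity). MALDI peptide-mass-fingerprint spectra are assumed
singly charged throughout, so the m/z axis is read as a mass axis in Da.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_REPLICATE_PATTERN = r"^(?P<sample>.+)_(?P<replicate>\d+)$"


class SpectrumFormatError(ValueError):
    """Raised when an input file cannot be parsed as a spectrum."""


class EmptyInputError(ValueError):
    """Raised when a file parses but contains no spectra."""


@dataclass
class RawSpectrum:
    """One technical replicate's continuous (m/z, intensity) profile.

    ``mz`` is strictly ascending, in Da (singly-charged assumption);
    ``intensity`` is non-negative and the same length.
    """

    sample_id: str
    replicate_index: int
    mz: np.ndarray
    intensity: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 1:
            raise ValueError("spectrum must contain at least one point")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    def replace_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        """Return a copy of this spectrum with a new intensity array."""
        return RawSpectrum(
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
            mz=self.mz.copy(),
            intensity=np.asarray(intensity, dtype=float),
            source_path=self.source_path,
        )


@dataclass
class ReplicateGroup:
    """Technical replicates (typically a triplicate) of one sample."""

    sample_id: str
    replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for rep in self.replicates:
            if rep.sample_id != self.sample_id:
                raise ValueError(
                    f"replicate sample_id {rep.sample_id!r} does not match group {self.sample_id!r}"
                )
        indices = [rep.replicate_index for rep in self.replicates]
        if len(set(indices)) != len(indices):
            raise ValueError(f"duplicate replicate indices in group {self.sample_id!r}: {indices}")

    def __len__(self) -> int:
        return len(self.replicates)


def _sort_and_dedupe(mz: np.ndarray, intensity: np.ndarray, origin: str) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z (warn if input unsorted); duplicate m/z keep max intensity."""
    order = np.argsort(mz, kind="stable")
    if not np.array_equal(order, np.arange(mz.size)):
        logger.warning("m/z values in %s were not ascending; sorting", origin)
        mz, intensity = mz[order], intensity[order]
    if mz.size > 1 and np.any(np.diff(mz) == 0):
        uniq, inverse = np.unique(mz, return_inverse=True)
        best = np.full(uniq.size, -np.inf)
        np.maximum.at(best, inverse, intensity)
        logger.warning("duplicate m/z values in %s; keeping max intensity", origin)
        mz, intensity = uniq, best
    return mz, intensity


# PSI-MS controlled-vocabulary accessions used when decoding binary arrays.
_CV_MZ_ARRAY = "MS:1000514"
_CV_INTENSITY_ARRAY = "MS:1000515"
_CV_FLOAT64 = "MS:1000523"
_CV_FLOAT32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"
_CV_NO_COMPRESSION = "MS:1000576"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(node: ElementTree.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, values)."""
    kind = None
    dtype = "d"
    compressed = False
    payload = ""
    for child in node.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc in (_CV_MZ_ARRAY, _CV_INTENSITY_ARRAY):
                kind = acc
            elif acc == _CV_FLOAT32:
                dtype = "f"
            elif acc == _CV_FLOAT64:
                dtype = "d"
            elif acc == _CV_ZLIB:
                compressed = True
            elif acc == _CV_NO_COMPRESSION:
                compressed = False
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    count = len(raw) // struct.calcsize(dtype)
    return kind, np.array(struct.unpack(f"<{count}{dtype}", raw), dtype=float)


def read_mzml(path: str | Path) -> list[RawSpectrum]:
    """Read every spectrum from an mzML file.

    A self-contained reader for the parts of mzML that MALDI peak
    exports use: ``<spectrum>`` elements with base64-encoded 32/64-bit
    float m/z and intensity arrays, optionally zlib-compressed. Each
    spectrum becomes one :class:`RawSpectrum`; the sample id defaults to
    the file stem and the replicate index to the 1-based position in the
    file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[RawSpectrum] = []
    try:
        tree = ElementTree.parse(path)
        root = tree.getroot()
        if _localname(root.tag) not in ("mzML", "indexedmzML"):
            raise SpectrumFormatError(f"{path}: root element {_localname(root.tag)!r} is not mzML")
        for i, spec_node in enumerate(
            (n for n in root.iter() if _localname(n.tag) == "spectrum"), start=1
        ):
            mz = inten = None
            for arr_node in (n for n in spec_node.iter() if _localname(n.tag) == "binaryDataArray"):
                kind, values = _decode_binary_array(arr_node)
                if kind == _CV_MZ_ARRAY:
                    mz = values
                elif kind == _CV_INTENSITY_ARRAY:
                    inten = values
            if mz is None or inten is None:
                raise SpectrumFormatError(f"{path}: spectrum #{i} lacks m/z or intensity array")
            if mz.size != inten.size:
                raise SpectrumFormatError(f"{path}: spectrum #{i} has mismatched array lengths")
            mz, inten = _sort_and_dedupe(mz, inten, f"{path.name}#{i}")
            spectra.append(
                RawSpectrum(
                    sample_id=path.stem,
                    replicate_index=i,
                    mz=mz,
                    intensity=np.clip(inten, 0.0, None),
                    source_path=str(path),
                )
            )
    except (FileNotFoundError, EmptyInputError, SpectrumFormatError):
        raise
    except Exception as exc:  # malformed XML, bad base64, ...
        raise SpectrumFormatError(f"cannot parse {path} as mzML: {exc}") from exc
    if not spectra:
        raise EmptyInputError(f"no spectra found in {path}")
    return spectra


def read_xy_text(path: str | Path, delimiter: str | None = None) -> RawSpectrum:
    """Read a two-column (m/z, intensity) text spectrum.

    Lines starting with ``#`` are comments. ``delimiter=None`` splits on
    any whitespace; pass e.g. ``","`` for CSV exports.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(delimiter)
            parts = [p for p in parts if p != ""]
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {stripped!r}")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric value in {stripped!r}") from exc
    if not mzs:
        raise SpectrumFormatError(f"{path}: no data rows")
    mz, inten = _sort_and_dedupe(np.array(mzs), np.array(intens), path.name)
    stem = path.stem
    match = re.match(DEFAULT_REPLICATE_PATTERN, stem)
    sample_id, rep_idx = (match.group("sample"), int(match.group("replicate"))) if match else (stem, 1)
    return RawSpectrum(
        sample_id=sample_id,
        replicate_index=rep_idx,
        mz=mz,
        intensity=np.clip(inten, 0.0, None),
        source_path=str(path),
    )


def group_replicates(
    spectra: Sequence[RawSpectrum],
    id_rule: str = DEFAULT_REPLICATE_PATTERN,
    use_names: bool = True,
) -> list[ReplicateGroup]:
    """Partition spectra into per-sample replicate groups.

    ``id_rule`` is a regular expression with ``sample`` and ``replicate``
    named groups (or two positional groups), applied to the file-name stem
    when ``use_names`` is true, otherwise to the stored ``sample_id``.
    Every input spectrum lands in exactly one group; single-replicate
    groups are allowed but logged.
    """
    pattern = re.compile(id_rule)
    if pattern.groups < 2 and not ("sample" in pattern.groupindex and "replicate" in pattern.groupindex):
        raise ValueError("id_rule must capture a sample id and a replicate index (two groups)")

    groups: dict[str, list[RawSpectrum]] = {}
    for spec in spectra:
        key_source = Path(spec.source_path).stem if (use_names and spec.source_path) else spec.sample_id
        match = pattern.match(key_source)
        if match:
            if "sample" in pattern.groupindex:
                sample_id = match.group("sample")
                rep_idx = int(match.group("replicate"))
            else:
                sample_id = match.group(1)
                rep_idx = int(match.group(2))
        else:
            sample_id, rep_idx = key_source, spec.replicate_index
        spec = RawSpectrum(
            sample_id=sample_id,
            replicate_index=rep_idx,
            mz=spec.mz,
            intensity=spec.intensity,
            source_path=spec.source_path,
        )
        groups.setdefault(sample_id, []).append(spec)

    if spectra and not groups:
        raise ValueError(f"id_rule {id_rule!r} matched no spectra")

    out: list[ReplicateGroup] = []
    for sample_id in sorted(groups):
        members = sorted(groups[sample_id], key=lambda s: s.replicate_index)
        if len(members) == 1:
            logger.warning("sample %s has a single replicate", sample_id)
        out.append(ReplicateGroup(sample_id=sample_id, replicates=members))
    return out


def write_peaks_csv(path: str | Path, peak_lists: Iterable) -> None:
    """Write one or more peak lists as CSV (``sample_id,mz,intensity,snr``)."""
    import pandas as pd

    frames = []
    for peaks in peak_lists:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": peaks.sample_id,
                    "mz": peaks.mz,
                    "intensity": peaks.intensity,
                    "snr": peaks.snr,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else None
    if table is None:
        raise ValueError("no peak lists to write")
    table.to_csv(path, index=False, float_format="%.6f")


def read_peaks_csv(path: str | Path) -> list:
    """Read peak lists written by :func:`write_peaks_csv`, one per sample."""
    import pandas as pd

    from zoomsid.preprocess import PeakList

    table = pd.read_csv(path)
    required = {"sample_id", "mz", "intensity", "snr"}
    if not required.issubset(table.columns):
        raise SpectrumFormatError(f"{path}: missing columns {sorted(required - set(table.columns))}")
    out = []
    for sample_id, sub in table.groupby("sample_id", sort=True):
        sub = sub.sort_values("mz")
        out.append(
            PeakList(
                sample_id=str(sample_id),
                mz=sub["mz"].to_numpy(float),
                intensity=sub["intensity"].to_numpy(float),
                snr=sub["snr"].to_numpy(float),
            )
        )
    return out
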