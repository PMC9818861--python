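"""Reading and writing centroided MS1 runs in mzXML.

Reading goes through :mod:`pyteomics.mzxml`. Writing is implemented here
directly (pyteomics has no mzXML writer): scans are serialized with 32-bit
network-byte-order m/z–intensity pairs, uncompressed — the most interoperable
mzXML dialect.

Only centroid data is handled; profile-mode spectra are neither detected nor
converted.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from pyteomics import mzxml as _pyt_mzxml

from .errors import EmptyRunError, MzXMLParseError

_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


@dataclass
class CentroidScan:
    """One centroided scan: parallel m/z and intensity arrays.

    ``mz`` is strictly increasing; intensities are non-negative and aligned
    with ``mz``. ``retention_time`` is in seconds.
    """

    scan_index: int
    retention_time: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly increasing within a scan")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.retention_time < 0:
            raise ValueError("retention time must be >= 0")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def total_ion_current(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RawRun:
    """One sample measurement: MS1 scans in acquisition (retention-time) order."""

    sample_id: str
    run_index: int
    scans: list[CentroidScan] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scans must be sorted by retention time")

    @property
    def n_scans(self) -> int:
        return len(self.scans)


def read_ms1_run(path: str | Path, sample_id: str, run_index: int) -> RawRun:
    """Read an mzXML file, keeping only MS1 scans.

    MS2+ scans are silently dropped; the retained scans keep their
    acquisition order and get contiguous 0-based ``scan_index`` values.

    Raises
    ------
    MzXMLParseError
        If the file is missing or not well-formed mzXML.
    EmptyRunError
        If the file contains no MS1 scans.
    """
    path = Path(path)
    scans: list[CentroidScan] = []
    try:
        with _pyt_mzxml.read(str(path)) as reader:
            for entry in reader:
                if int(entry.get("msLevel", 0)) != 1:
                    continue
                rt_minutes = float(entry["retentionTime"])  # pyteomics: minutes
                mz = np.asarray(entry["m/z array"], dtype=np.float64)
                inten = np.asarray(entry["intensity array"], dtype=np.float64)
                order = np.argsort(mz, kind="stable")
                mz, inten = mz[order], inten[order]
                if mz.size > 1:
                    # merge centroids that collide after float round-trip
                    uniq, inverse = np.unique(mz, return_inverse=True)
                    if uniq.size < mz.size:
                        summed = np.zeros(uniq.size)
                        np.add.at(summed, inverse, inten)
                        mz, inten = uniq, summed
                scans.append(
                    CentroidScan(
                        scan_index=len(scans),
                        retention_time=rt_minutes * 60.0,
                        ms_level=1,
                        mz=mz,
                        intensity=inten,
                    )
                )
    except (OSError, etree.XMLSyntaxError, Exception) as exc:
        if isinstance(exc, EmptyRunError):
            raise
        raise MzXMLParseError(f"cannot parse mzXML file {path}: {exc}") from exc
    if not scans:
        raise EmptyRunError(f"no MS1 scans in {path}")
    scans.sort(key=lambda s: s.retention_time)
    for i, scan in enumerate(scans):
        scan.scan_index = i
    return RawRun(sample_id=sample_id, run_index=run_index, scans=scans)


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray) -> str:
    pairs = np.empty(2 * mz.size, dtype=">f4")
    pairs[0::2] = mz.astype(">f4")
    pairs[1::2] = intensity.astype(">f4")
    return base64.b64encode(pairs.tobytes()).decode("ascii")


def write_mzxml(run: RawRun, path: str | Path) -> Path:
    """Write a run as mzXML 3.2 (32-bit float pairs, network byte order, no zlib)."""
    if run.n_scans == 0:
        raise EmptyRunError(f"refusing to write empty run {run.sample_id!r}")
    path = Path(path)
    root = etree.Element(f"{{{_MZXML_NS}}}mzXML", nsmap={None: _MZXML_NS})
    ms_run = etree.SubElement(root, f"{{{_MZXML_NS}}}msRun")
    ms_run.set("scanCount", str(run.n_scans))
    for scan in run.scans:
        el = etree.SubElement(ms_run, f"{{{_MZXML_NS}}}scan")
        el.set("num", str(scan.scan_index + 1))
        el.set("msLevel", str(scan.ms_level))
        el.set("peaksCount", str(scan.n_peaks))
        el.set("retentionTime", f"PT{scan.retention_time:.6f}S")
        peaks = etree.SubElement(el, f"{{{_MZXML_NS}}}peaks")
        peaks.set("compressionType", "none")
        peaks.set("compressedLen", "0")
        peaks.set("precision", "32")
        peaks.set("byteOrder", "network")
        peaks.set("contentType", "m/z-int")
        peaks.text = _encode_peaks(scan.mz, scan.intensity)
    tree = etree.ElementTree(root)
    try:
        tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1", pretty_print=True)
    except OSError as exc:
        raise OSError(f"cannot write mzXML to {path}: {exc}") from exc
    return path
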