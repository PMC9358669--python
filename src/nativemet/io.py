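"""Readers/writers for mzML, MGF, feature CSV and GraphML, plus the
in-memory run model.

Retention time is minutes everywhere inside the package; second-valued
fields (mzML scan start time in seconds, MGF ``RTINSECONDS``) are converted
on ingest.  mzML support is limited to centroided, positive-mode spectra.
Reading goes through :mod:`pyteomics`; the mzML writer emits a minimal but
standard-conformant document (64-bit uncompressed binary arrays with the
usual PSI-MS controlled-vocabulary terms) that round-trips through any
compliant reader.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "Run",
    "read_mzml",
    "write_mzml",
    "read_mgf",
    "write_mgf",
    "read_feature_csv",
    "write_feature_csv",
    "write_graphml",
    "read_graphml",
]


class MSIOError(ValueError):
    """Raised for malformed or unsupported input files."""


@dataclass
class Spectrum:
    """One centroided scan.

    peaks are stored as parallel numpy arrays sorted by m/z; ``precursor``
    is an ``(m/z, charge)`` tuple for MS2 scans (charge may be None).
    """

    scan_id: str
    rt: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor: tuple[float, int | None] | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise MSIOError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise MSIOError("negative intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.ms_level not in (1, 2):
            raise MSIOError(f"unsupported ms_level {self.ms_level}")
        if self.ms_level == 2 and self.precursor is None:
            raise MSIOError(f"MS2 scan {self.scan_id!r} lacks a precursor")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Run:
    """A sequence of spectra ordered by retention time plus metadata."""

    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def rt_span(self) -> tuple[float, float]:
        return (self.spectra[0].rt, self.spectra[-1].rt) if self.spectra else (0.0, 0.0)


# ---------------------------------------------------------------------------
# mzML

def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack("<%dd" % len(values), *map(float, values))
    ).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a Run as minimal centroided mzML (64-bit, uncompressed)."""
    path = Path(path)
    run_id = escape(str(run.metadata.get("description", "nativemet_run")), {'"': "&quot;"})
    parts = [_MZML_HEADER.format(run_id=run_id, count=len(run.spectra))]
    for idx, s in enumerate(run.spectra):
        parts.append(
            f'      <spectrum index="{idx}" id="{escape(s.scan_id, {chr(34): "&quot;"})}" '
            f'defaultArrayLength="{s.n_peaks}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>\n'
            '        <scanList count="1">\n'
            '          <scan>\n'
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{s.rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
        )
        if s.precursor is not None:
            pmz, pz = s.precursor
            charge = (
                f'                <cvParam cvRef="MS" accession="MS:1000041" '
                f'name="charge state" value="{pz}"/>\n'
                if pz is not None
                else ""
            )
            parts.append(
                '        <precursorList count="1">\n'
                "          <precursor>\n"
                '            <selectedIonList count="1">\n'
                "              <selectedIon>\n"
                f'                <cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{pmz:.6f}"/>\n'
                f"{charge}"
                "              </selectedIon>\n"
                "            </selectedIonList>\n"
                "          </precursor>\n"
                "        </precursorList>\n"
            )
        mz_b64 = _encode_array(s.mz)
        int_b64 = _encode_array(s.intensity)
        parts.append(
            '        <binaryDataArrayList count="2">\n'
            f'          <binaryDataArray encodedLength="{len(mz_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>\n'
            f"            <binary>{mz_b64}</binary>\n"
            "          </binaryDataArray>\n"
            f'          <binaryDataArray encodedLength="{len(int_b64)}">\n'
            '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>\n'
            f"            <binary>{int_b64}</binary>\n"
            "          </binaryDataArray>\n"
            "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))


def _cv_params(element) -> dict[str, dict]:
    """Accession -> attribute dict for the direct cvParam children."""
    out = {}
    for child in element:
        if etree.QName(child).localname == "cvParam":
            out[child.get("accession")] = dict(child.attrib)
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    raw = None
    for child in bda:
        if etree.QName(child).localname == "binary":
            raw = base64.b64decode(child.text or "")
    if raw is None:
        raise MSIOError("binaryDataArray lacks <binary> content")
    if "MS:1000574" in params:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem) -> Spectrum:
    params = _cv_params(elem)
    if "MS:1000128" in params:
        raise MSIOError(
            f"profile-mode spectrum {elem.get('id')!r}; centroid the data first"
        )
    ms_level = int(params.get("MS:1000511", {}).get("value", 1))
    rt = 0.0
    precursor = None
    mz = intens = None
    for child in elem:
        name = etree.QName(child).localname
        if name == "scanList":
            for scan in child:
                if etree.QName(scan).localname != "scan":
                    continue
                sp = _cv_params(scan)
                if "MS:1000016" in sp:
                    attr = sp["MS:1000016"]
                    rt = float(attr["value"])
                    if "second" in attr.get("unitName", "minute"):
                        rt /= 60.0
        elif name == "precursorList":
            for prec in child:
                for sub in prec:
                    if etree.QName(sub).localname != "selectedIonList":
                        continue
                    for ion in sub:
                        ip = _cv_params(ion)
                        if "MS:1000744" in ip:
                            charge = ip.get("MS:1000041", {}).get("value")
                            precursor = (
                                float(ip["MS:1000744"]["value"]),
                                int(charge) if charge is not None else None,
                            )
        elif name == "binaryDataArrayList":
            for bda in child:
                if etree.QName(bda).localname != "binaryDataArray":
                    continue
                bp = _cv_params(bda)
                values = _decode_binary_array(bda)
                if "MS:1000514" in bp:
                    mz = values
                elif "MS:1000515" in bp:
                    intens = values
    if mz is None or intens is None:
        raise MSIOError(f"spectrum {elem.get('id')!r} lacks m/z or intensity array")
    return Spectrum(
        scan_id=str(elem.get("id")),
        rt=rt,
        ms_level=ms_level,
        mz=mz,
        intensity=intens,
        precursor=precursor,
    )


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file into a Run (RT converted to minutes).

    Understands the standard PSI-MS vocabulary for scan time, ms level,
    selected-ion precursors and 32/64-bit (optionally zlib-compressed)
    binary arrays; profile-mode spectra are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise MSIOError(f"no such file: {path}")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MSIOError(f"not a readable mzML file: {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname == "indexedmzML":
        root = next(c for c in root if etree.QName(c).localname == "mzML")
    if etree.QName(root).localname != "mzML":
        raise MSIOError(f"not an mzML document: {path}")
    spectra = [
        _parse_mzml_spectrum(elem)
        for elem in root.iter()
        if etree.QName(elem).localname == "spectrum"
    ]
    if not spectra:
        raise MSIOError(f"empty run: {path} contains no spectra")
    return Run(spectra=spectra, metadata={"path": str(path)})


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MS/MS spectra from an MGF file (RTINSECONDS -> minutes)."""
    path = Path(path)
    if not path.exists():
        raise MSIOError(f"no such file: {path}")
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise MSIOError(f"MGF spectrum {i} lacks PEPMASS")
            pepmass = float(params["pepmass"][0])
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            spectra.append(
                Spectrum(
                    scan_id=str(params.get("title", f"mgf_scan_{i}")),
                    rt=rt,
                    ms_level=2,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    precursor=(pepmass, charge),
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write MS2 spectra to MGF (precursor as PEPMASS, RT in seconds)."""
    entries = []
    for s in spectra:
        if s.ms_level != 2 or s.precursor is None:
            raise MSIOError(f"spectrum {s.scan_id!r} is not an MS2 scan with precursor")
        params = {
            "TITLE": s.scan_id,
            "PEPMASS": s.precursor[0],
            "RTINSECONDS": s.rt * 60.0,
        }
        if s.precursor[1] is not None:
            params["CHARGE"] = s.precursor[1]
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Feature CSV (two dialects)

#: MZmine-style export header -> native column names.
MZMINE_COLUMNS = {
    "row ID": "feature_id",
    "row m/z": "mass_value",
    "row retention time": "rt_apex",
}

NATIVE_COLUMNS = [
    "feature_id",
    "kind",
    "mass_value",
    "rt_apex",
    "rt_start",
    "rt_end",
    "apex_intensity",
    "area",
]


def read_feature_csv(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read a feature table CSV in the native or MZmine-like dialect.

    The dialect is detected from the header unless given explicitly; an
    unrecognizable header is an error rather than a guess.
    """
    path = Path(path)
    if not path.exists():
        raise MSIOError(f"no such file: {path}")
    df = pd.read_csv(path)
    header = set(df.columns)
    if dialect == "auto":
        if set(NATIVE_COLUMNS[:4]).issubset(header):
            dialect = "native"
        elif set(MZMINE_COLUMNS).issubset(header):
            dialect = "mzmine"
        else:
            raise MSIOError(
                f"cannot detect feature-table dialect from columns {sorted(header)}"
            )
    if dialect == "native":
        missing = [c for c in NATIVE_COLUMNS[:4] if c not in header]
        if missing:
            raise MSIOError(f"feature CSV missing required column(s): {missing}")
        return df
    if dialect == "mzmine":
        missing = [c for c in MZMINE_COLUMNS if c not in header]
        if missing:
            raise MSIOError(f"MZmine feature CSV missing required column(s): {missing}")
        out = df.rename(columns=MZMINE_COLUMNS)
        area_cols = [c for c in df.columns if c.strip().lower().endswith("area")]
        out["area"] = df[area_cols[0]] if area_cols else np.nan
        out["kind"] = "metabolite"
        keep = ["feature_id", "kind", "mass_value", "rt_apex", "area"]
        return out[keep]
    raise MSIOError(f"unknown feature CSV dialect {dialect!r}")


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table in the native dialect (stable column order)."""
    cols = [c for c in NATIVE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols, float_format="%.6f")


# ---------------------------------------------------------------------------
# GraphML

def write_graphml(network, path: str | Path) -> None:
    """Write a molecular network (or plain networkx graph) to GraphML."""
    import networkx as nx

    g = network.graph if isinstance(getattr(network, "graph", None), nx.Graph) else network
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path):
    import networkx as nx

    return nx.read_graphml(str(path))


def _spectrum_dict_equal(a: Spectrum, b: Spectrum, tol: float = 1e-6) -> bool:
    return (
        a.ms_level == b.ms_level
        and abs(a.rt - b.rt) < tol
        and a.n_peaks == b.n_peaks
        and np.allclose(a.mz, b.mz, atol=tol)
        and np.allclose(a.intensity, b.intensity, rtol=1e-9)
    )
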