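"""Readers and writers for the formats the pipeline touches.

mzML is the interchange format for runs: read with a compact parser of
the mzML 1.1 controlled vocabulary (centroid/profile, scan times with
units, optionally zlib-compressed 32/64-bit base64 arrays) and written
as a minimal mzML 1.1.0 document with uncompressed 64-bit arrays.
Compound libraries and sample sheets are TSV, result tables CSV, and a
compact JSON-lines format (one spectrum per line) serves as the diffable
internal fixture format.
"""

from __future__ import annotations

import base64
import hashlib
import json
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemmass import Adduct, Formula, parse_formula

__all__ = [
    "Spectrum",
    "Run",
    "CompoundEntry",
    "SampleSheet",
    "read_mzml",
    "write_mzml",
    "read_jsonl",
    "write_jsonl",
    "read_compound_library",
    "default_bile_acid_library",
    "read_sample_sheet",
    "write_results",
]

#: class tags whose adduct must be acetate (choline lipids ionize as acetate adducts)
_CHOLINE_CLASSES = {"LPL-headgroup-PC", "LPL-headgroup-O-PC"}


@dataclass
class Spectrum:
    """One centroided scan. ``aif`` marks fragment-level scans acquired
    without precursor isolation (all-ion fragmentation)."""

    ms_level: int
    rt: float  # minutes
    mz_array: np.ndarray
    intensity_array: np.ndarray
    aif: bool = False

    def __post_init__(self) -> None:
        self.mz_array = np.asarray(self.mz_array, dtype=float)
        self.intensity_array = np.asarray(self.intensity_array, dtype=float)
        if self.mz_array.shape != self.intensity_array.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if self.mz_array.size > 1 and not np.all(np.diff(self.mz_array) > 0):
            raise ValueError("m/z array must be strictly ascending")
        if np.any(self.intensity_array < 0):
            raise ValueError("negative intensities")
        if self.ms_level == 2:
            self.aif = True


@dataclass
class Run:
    """Time-ordered spectra plus acquisition metadata."""

    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)
        self.metadata.setdefault("polarity", "negative")
        self.metadata.setdefault("ms1_range", (370.0, 700.0))

    def scans(self, ms_level: int) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == ms_level]


@dataclass
class CompoundEntry:
    """One library record: identity, composition, adduct and quant wiring."""

    name: str
    class_tag: str  # "+"-joined tags, e.g. "taurine-conjugate+sulfate"
    neutral_formula: Formula
    adduct: str = Adduct.DEPROTONATED
    expected_rt: float | None = None
    rt_source: str = "standard"  # standard | predicted
    internal_standard_ref: str | None = None
    is_internal_standard: bool = False
    nominal_is_concentration: float | None = None  # µM

    def __post_init__(self) -> None:
        tags = set(self.class_tag.split("+"))
        if tags & _CHOLINE_CLASSES and self.adduct != Adduct.ACETATE:
            raise ValueError(
                f"{self.name}: choline lipids must use the acetate adduct"
            )
        if self.adduct == Adduct.ACETATE and not tags & _CHOLINE_CLASSES:
            raise ValueError(
                f"{self.name}: acetate adduct reserved for choline lipids"
            )


class SampleSheet:
    """Run-level design table: role, nominal concentrations, spike stage,
    day and replicate indices."""

    ROLES = {"blank", "calibrant", "QC", "study"}

    def __init__(self, frame: pd.DataFrame):
        required = {"run_id", "role"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(frame["role"]) - self.ROLES
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)

    def rows(self, role: str | None = None) -> pd.DataFrame:
        if role is None:
            return self.frame
        return self.frame[self.frame["role"] == role]


# --------------------------------------------------------------------------
# mzML
# --------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _decode_binary(bda: ET.Element, default_length: int) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit."""
    import zlib

    accessions = {
        c.get("accession") for c in bda.iter(f"{{{_MZML_NS}}}cvParam")
    }
    text = bda.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if arr.size != default_length:
        raise ValueError("binary array length mismatch")
    return arr


def read_mzml(path: str | Path) -> Run:
    """Read a centroided negative-mode mzML file into a :class:`Run`.

    Parses the mzML 1.1 vocabulary directly (ms level, scan start time
    with unit handling, base64 binary arrays with optional zlib, 32- or
    64-bit floats). Profile-mode spectra are rejected; fragment-level
    scans without a precursor isolation window are flagged as AIF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra = []
    ns = f"{{{_MZML_NS}}}"
    for _, el in ET.iterparse(str(path), events=("end",)):
        if el.tag != f"{ns}spectrum":
            continue
        params = {
            c.get("accession"): c
            for c in el.iter(f"{ns}cvParam")
        }
        if "MS:1000128" in params:
            raise ValueError("profile-mode data not supported; centroid first")
        ms_level = int(params["MS:1000511"].get("value", 1)) if "MS:1000511" in params else 1
        rt_param = params.get("MS:1000016")
        rt = float(rt_param.get("value")) if rt_param is not None else 0.0
        unit = (rt_param.get("unitName") or "minute") if rt_param is not None else "minute"
        if "second" in unit:
            rt /= 60.0
        has_isolation = el.find(f"{ns}precursorList") is not None
        arrays: dict[str, np.ndarray] = {}
        length = int(el.get("defaultArrayLength", 0))
        for bda in el.iter(f"{ns}binaryDataArray"):
            accs = {c.get("accession") for c in bda.iter(f"{ns}cvParam")}
            data = _decode_binary(bda, length)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        spectra.append(
            Spectrum(
                ms_level=ms_level,
                rt=rt,
                mz_array=arrays.get("mz", np.array([])),
                intensity_array=arrays.get("intensity", np.array([])),
                aif=ms_level == 2 and not has_isolation,
            )
        )
        el.clear()
    if not any(s.ms_level == 1 for s in spectra):
        raise ValueError("no MS1 scans in run")
    return Run(spectra=spectra)


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{array.size}d", *array)).decode()


def write_mzml(run: Run, path: str | Path) -> Path:
    """Write a Run as a minimal centroided mzML 1.1.0 document."""
    path = Path(path)
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    ET.SubElement(root, "cvList", count="1")
    spec_list = ET.SubElement(
        ET.SubElement(root, "run", id=str(run.metadata.get("run_id", "run"))),
        "spectrumList",
        count=str(len(run.spectra)),
    )

    def cv(parent, accession, name, value="", unit=None):
        attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
        if unit:
            attrs.update(
                unitCvRef="UO", unitAccession=unit[0], unitName=unit[1]
            )
        ET.SubElement(parent, "cvParam", **attrs)

    for i, s in enumerate(run.spectra):
        el = ET.SubElement(
            spec_list,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(s.mz_array.size),
        )
        cv(el, "MS:1000511", "ms level", str(s.ms_level))
        cv(el, "MS:1000127", "centroid spectrum")
        cv(el, "MS:1000129", "negative scan")
        scans = ET.SubElement(ET.SubElement(el, "scanList", count="1"), "scan")
        cv(
            scans,
            "MS:1000016",
            "scan start time",
            repr(s.rt),
            unit=("UO:0000031", "minute"),
        )
        bal = ET.SubElement(el, "binaryDataArrayList", count="2")
        for arr, acc, name in (
            (s.mz_array, "MS:1000514", "m/z array"),
            (s.intensity_array, "MS:1000515", "intensity array"),
        ):
            encoded = _b64(arr)
            bda = ET.SubElement(bal, "binaryDataArray", encodedLength=str(len(encoded)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")
    return path


# --------------------------------------------------------------------------
# JSON-lines fixture format
# --------------------------------------------------------------------------

def write_jsonl(run: Run, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        meta = dict(run.metadata)
        meta["ms1_range"] = list(meta.get("ms1_range", (370.0, 700.0)))
        fh.write(json.dumps({"run_metadata": meta}) + "\n")
        for s in run.spectra:
            fh.write(
                json.dumps(
                    {
                        "ms_level": s.ms_level,
                        "rt": s.rt,
                        "aif": s.aif,
                        "mz": [round(x, 6) for x in s.mz_array.tolist()],
                        "intensity": [round(x, 4) for x in s.intensity_array.tolist()],
                    }
                )
                + "\n"
            )
    return path


def read_jsonl(path: str | Path) -> Run:
    spectra, metadata = [], {}
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            if "run_metadata" in obj:
                metadata = obj["run_metadata"]
                if "ms1_range" in metadata:
                    metadata["ms1_range"] = tuple(metadata["ms1_range"])
                continue
            spectra.append(
                Spectrum(
                    ms_level=obj["ms_level"],
                    rt=obj["rt"],
                    mz_array=np.array(obj["mz"]),
                    intensity_array=np.array(obj["intensity"]),
                    aif=obj.get("aif", obj["ms_level"] == 2),
                )
            )
    return Run(spectra=spectra, metadata=metadata)


def read_run(path: str | Path) -> Run:
    """Dispatch on extension: .mzML or .jsonl."""
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path)
    return read_jsonl(path)


# --------------------------------------------------------------------------
# Libraries, sample sheets, results
# --------------------------------------------------------------------------

_LIB_COLUMNS = ["name", "class_tag", "formula", "adduct"]


def read_compound_library(path: str | Path) -> list[CompoundEntry]:
    """Read a TSV compound library; validates formulas, adduct legality and
    internal-standard references."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_LIB_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"library missing columns: {sorted(missing)}")
    if frame["name"].duplicated().any():
        dupes = frame["name"][frame["name"].duplicated()].tolist()
        raise ValueError(f"duplicate compound names: {dupes}")
    entries = []
    for _, row in frame.iterrows():
        def _opt(col, cast=float):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return cast(v)

        entries.append(
            CompoundEntry(
                name=str(row["name"]),
                class_tag=str(row["class_tag"]),
                neutral_formula=parse_formula(str(row["formula"])),
                adduct=str(row["adduct"]),
                expected_rt=_opt("expected_rt"),
                rt_source=str(row.get("rt_source", "standard") or "standard"),
                internal_standard_ref=_opt("internal_standard_ref", str),
                is_internal_standard=bool(_opt("is_internal_standard", int) or 0),
                nominal_is_concentration=_opt("nominal_is_concentration"),
            )
        )
    names = {e.name for e in entries}
    for e in entries:
        if e.internal_standard_ref and e.internal_standard_ref not in names:
            raise ValueError(
                f"{e.name}: internal standard {e.internal_standard_ref!r} "
                "not in library"
            )
    return entries


def default_bile_acid_library() -> list[CompoundEntry]:
    """The shipped bile-acid panel (quantified analytes + deuterated IS)."""
    import importlib.resources

    ref = importlib.resources.files("aifquant.data").joinpath("bile_acids.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_compound_library(p)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", comment="#"))


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, config: dict | None = None
) -> list[Path]:
    """Write result tables as CSV (4 significant digits for floats, missing
    as empty cells) plus a run-log with tool version and config hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.4g", na_rep="")
        written.append(p)
    config_blob = json.dumps(config or {}, sort_keys=True).encode()
    log = {
        "tool": "aifquant",
        "version": __version__,
        "config_hash": hashlib.sha256(config_blob).hexdigest()[:16],
        "tables": [p.name for p in written],
    }
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    written.append(log_path)
    return written
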