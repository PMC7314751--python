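"""Readers and writers for the formats the toolkit touches.

Internal tables are tab-separated text with fixed headers so fixtures are
diffable and nothing binary is required for testing:

* peak table   — one row per centroid peak per scan event,
* feature table — one row per reproducible m/z feature,
* compound DB  — id, name, formula, monoisotopic mass, class,
* range config — JSON listing ordered [low, high) scan ranges per
  polarity plus the per-injection grouping.

Centroided MS1 spectra are read from mzXML through pyteomics; mzML is
handled by a small built-in reader covering the subset this toolkit
consumes (centroided MS1 arrays with scan-window, polarity and
ion-injection-time metadata).  A minimal mzML *writer* is included only
to produce small test fixtures.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from .ranges import ScanRangeSet, plan_injections
from .simulate import ScanEvent

__all__ = [
    "PEAK_COLUMNS",
    "FEATURE_COLUMNS",
    "peak_table_from_events",
    "write_peaks",
    "read_peaks",
    "read_spectra",
    "write_ranges",
    "read_ranges",
    "write_features",
    "read_features",
    "read_compound_db",
    "write_compound_db",
    "write_minimal_mzml",
]

PEAK_COLUMNS = (
    "sample",
    "injection",
    "blank",
    "polarity",
    "range_id",
    "range_low",
    "range_high",
    "mz",
    "intensity",
    "injection_time_ms",
)

FEATURE_COLUMNS = (
    "ref_mz",
    "median_intensity",
    "presence",
    "snr",
    "rsd_pct",
    "max_blank",
)

#: m/z serialized at 6 decimals (sub-0.01 ppm at m/z 100, below measurement
#: error); intensities and times at 4.
_FLOAT_FORMATS = {"mz": "%.6f", "ref_mz": "%.6f"}


def peak_table_from_events(
    events: Sequence[ScanEvent], sample: str = "sample"
) -> pd.DataFrame:
    """Flatten simulated scan events into the internal peak table."""
    range_ids = {}
    rows = []
    for ev in events:
        key = (ev.range_low, ev.range_high)
        if key not in range_ids:
            range_ids[key] = len(range_ids)
        for mz, inten in zip(ev.mz, ev.intensity):
            rows.append(
                (
                    sample,
                    ev.injection_id,
                    ev.blank,
                    ev.polarity,
                    range_ids[key],
                    ev.range_low,
                    ev.range_high,
                    float(mz),
                    float(inten),
                    ev.injection_time_ms,
                )
            )
    return pd.DataFrame(rows, columns=list(PEAK_COLUMNS))


def _round_floats(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            decimals = 6 if col in _FLOAT_FORMATS else 4
            out[col] = out[col].round(decimals)
    return out


def write_peaks(peaks: pd.DataFrame, path) -> None:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table lacks columns {missing}")
    _round_floats(peaks[list(PEAK_COLUMNS)]).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a peak table, lacks columns {missing}")
    df["blank"] = df["blank"].astype(bool)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    _round_floats(features).to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "ref_mz" not in df.columns:
        raise ValueError(f"{path}: not a feature table (no ref_mz column)")
    return df


# ---------------------------------------------------------------------------
# range configuration JSON


def write_ranges(ranges: ScanRangeSet, path, max_per_injection: int = 8) -> None:
    """Serialize a scan-range set to the operator-facing JSON document.

    Overlap cannot occur for a boundary-encoded set, but the document is
    validated on write anyway so hand-edited files are caught on re-read.
    """
    doc = {
        "polarity": ranges.polarity,
        "ranges": [[low, high] for low, high in ranges.ranges],
        "counts": None if ranges.counts is None else [float(c) for c in ranges.counts],
        "injection_groups": plan_injections(ranges, max_per_injection),
    }
    _validate_range_doc(doc)
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _validate_range_doc(doc: dict) -> None:
    rs = doc["ranges"]
    if not rs:
        raise ValueError("range config holds no ranges")
    for (lo1, hi1), (lo2, hi2) in zip(rs, rs[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping ranges [{lo1},{hi1}) and [{lo2},{hi2})")
    for lo, hi in rs:
        if not lo < hi:
            raise ValueError(f"invalid range [{lo},{hi})")


def read_ranges(path) -> ScanRangeSet:
    doc = json.loads(Path(path).read_text())
    _validate_range_doc(doc)
    rs = doc["ranges"]
    for (_, hi1), (lo2, _) in zip(rs, rs[1:]):
        if hi1 != lo2:
            raise ValueError("range config is not contiguous")
    boundaries = np.array([rs[0][0]] + [hi for _, hi in rs], dtype=float)
    counts = doc.get("counts")
    return ScanRangeSet(
        boundaries=boundaries,
        polarity=doc.get("polarity", "negative"),
        counts=None if counts is None else np.asarray(counts, dtype=float),
    )


# ---------------------------------------------------------------------------
# compound database


def read_compound_db(path) -> pd.DataFrame:
    """Read a compound table (id, name, formula, monoisotopic_mass, class).

    Either ``formula`` or ``monoisotopic_mass`` must be present per row; a
    missing mass is computed from the formula, and when both are given
    they must agree to 1e-4 Da.
    """
    db = pd.read_csv(path, sep="\t")
    required = {"id", "name"}
    if not required.issubset(db.columns):
        raise ValueError(f"{path}: compound DB needs columns {sorted(required)}")
    if "monoisotopic_mass" not in db.columns:
        db["monoisotopic_mass"] = np.nan
    if "formula" not in db.columns:
        db["formula"] = None
    masses = []
    for _, row in db.iterrows():
        mass = row["monoisotopic_mass"]
        formula = row["formula"]
        has_formula = isinstance(formula, str) and formula.strip()
        if has_formula:
            computed = chem.formula_mass(formula)
            if pd.notna(mass):
                if abs(mass - computed) > 1e-4:
                    raise ValueError(
                        f"compound {row['id']}: stated mass {mass} differs from "
                        f"formula mass {computed:.5f} by more than 1e-4 Da"
                    )
            else:
                mass = computed
        if pd.isna(mass) or mass <= 0:
            raise ValueError(f"compound {row['id']}: no usable monoisotopic mass")
        masses.append(float(mass))
    db["monoisotopic_mass"] = masses
    if "class" not in db.columns:
        db["class"] = ""
    return db


def write_compound_db(db: pd.DataFrame, path) -> None:
    db.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mzML / mzXML reading


def read_spectra(path) -> pd.DataFrame:
    """Read centroided MS1 spectra from mzML or mzXML into a peak table.

    One row per centroid peak.  Scan-window metadata is mapped to a dense
    ``range_id``; a missing injection time is recorded as NaN, never zero.
    Peaks falling outside their spectrum's declared scan window are kept
    but flagged (``in_window = False``) with a warning.

    Raises on profile-mode spectra: centroid upstream (e.g. with
    ProteoWizard peak picking) before loading.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if not path.exists():
        raise FileNotFoundError(f"spectra file not found: {path}")
    if suffix == ".mzml":
        spectra = _iter_mzml(path)
    elif suffix == ".mzxml":
        spectra = _iter_mzxml(path)
    else:
        raise ValueError(f"unsupported spectra format {suffix!r} (want .mzML/.mzXML)")

    rows = []
    range_ids = {}
    n_outside = 0
    for idx, sp in enumerate(spectra):
        if sp["profile"]:
            raise ValueError(
                f"{path}: spectrum {idx} is profile mode; centroid before loading"
            )
        if sp["ms_level"] not in (None, 1):
            continue
        low, high = sp["window"]
        key = (low, high)
        if key not in range_ids:
            range_ids[key] = len(range_ids)
        for mz, inten in zip(sp["mz"], sp["intensity"]):
            in_window = True
            if low is not None and high is not None:
                in_window = low <= mz <= high
                n_outside += not in_window
            rows.append(
                (
                    path.stem,
                    sp["injection_id"] if sp["injection_id"] is not None else idx,
                    False,
                    sp["polarity"],
                    range_ids[key],
                    np.nan if low is None else low,
                    np.nan if high is None else high,
                    float(mz),
                    float(inten),
                    sp["injection_time_ms"],
                    in_window,
                )
            )
    if n_outside:
        warnings.warn(
            f"{path}: {n_outside} peak(s) outside their declared scan window",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=list(PEAK_COLUMNS) + ["in_window"])


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(b64_text: str, accessions: set) -> np.ndarray:
    """Decode an mzML <binary> payload (64/32-bit float, zlib or none)."""
    import zlib

    raw = base64.b64decode(b64_text.strip() or b"")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    itemsize, code = (4, "f") if "MS:1000521" in accessions else (8, "d")
    n = len(raw) // itemsize
    return np.array(struct.unpack("<%d%s" % (n, code), raw[: n * itemsize]))


def _iter_mzml(path):
    # Minimal namespace-agnostic mzML reader for centroided MS1 spectra
    # (m/z + intensity arrays, scan window, injection time, polarity, mode).
    import xml.etree.ElementTree as ET

    for _, elem in ET.iterparse(str(path)):
        if _local(elem.tag) != "spectrum":
            continue
        acc = {}  # accession -> value, spectrum + scan level
        for cv in elem.iter():
            if _local(cv.tag) == "cvParam":
                acc[cv.get("accession")] = cv.get("value")

        mz_arr = inten_arr = np.array([])
        for bda in elem.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            local_acc = {
                cv.get("accession")
                for cv in bda.iter()
                if _local(cv.tag) == "cvParam"
            }
            binary = next(
                (c for c in bda.iter() if _local(c.tag) == "binary"), None
            )
            values = _decode_binary(binary.text or "", local_acc) if binary is not None else np.array([])
            if "MS:1000514" in local_acc:
                mz_arr = values
            elif "MS:1000515" in local_acc:
                inten_arr = values

        window = (None, None)
        if "MS:1000501" in acc and "MS:1000500" in acc:
            window = (float(acc["MS:1000501"]), float(acc["MS:1000500"]))
        if "MS:1000129" in acc:
            polarity = "negative"
        elif "MS:1000130" in acc:
            polarity = "positive"
        else:
            polarity = "unknown"
        inj = acc.get("MS:1000927")
        level = acc.get("MS:1000511")
        yield {
            "mz": mz_arr,
            "intensity": inten_arr,
            "profile": "MS:1000128" in acc,
            "ms_level": int(level) if level is not None else None,
            "window": window,
            "polarity": polarity,
            "injection_time_ms": float(inj) if inj is not None else np.nan,
            "injection_id": None,
        }
        elem.clear()


def _iter_mzxml(path):
    from pyteomics import mzxml

    with mzxml.read(str(path)) as reader:
        for sp in reader:
            low = sp.get("lowMz", sp.get("startMz"))
            high = sp.get("highMz", sp.get("endMz"))
            yield {
                "mz": sp.get("m/z array", []),
                "intensity": sp.get("intensity array", []),
                "profile": sp.get("centroided") is False,
                "ms_level": sp.get("msLevel"),
                "window": (
                    float(low) if low is not None else None,
                    float(high) if high is not None else None,
                ),
                "polarity": {"-": "negative", "+": "positive"}.get(
                    sp.get("polarity"), "unknown"
                ),
                "injection_time_ms": np.nan,
                "injection_id": None,
            }


# ---------------------------------------------------------------------------
# minimal mzML writing (test fixtures only)


def _encode_array(values: np.ndarray) -> str:
    data = struct.pack("<%dd" % len(values), *np.asarray(values, dtype=float))
    return base64.b64encode(data).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="1">
  <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
 </cvList>
 <run id="run">
  <spectrumList count="{count}">
"""

_MZML_FOOTER = """  </spectrumList>
 </run>
</mzML>
"""


def write_minimal_mzml(events: Sequence[ScanEvent], path, centroided: bool = True) -> None:
    """Write scan events as a minimal centroided mzML file.

    Intended only for producing small, self-contained test fixtures; the
    output carries exactly the metadata :func:`read_spectra` consumes
    (mode, polarity, scan window, ion injection time, 64-bit uncompressed
    arrays).
    """
    mode_acc, mode_name = (
        ("MS:1000127", "centroid spectrum")
        if centroided
        else ("MS:1000128", "profile spectrum")
    )
    parts = [_MZML_HEADER.format(count=len(events))]
    for i, ev in enumerate(events):
        pol_acc, pol_name = (
            ("MS:1000129", "negative scan")
            if ev.polarity == "negative"
            else ("MS:1000130", "positive scan")
        )
        mz_b64 = _encode_array(ev.mz)
        int_b64 = _encode_array(ev.intensity)
        parts.append(
            f"""   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{ev.n_peaks}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>
    <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000927" name="ion injection time" value="{ev.injection_time_ms:.4f}" unitName="millisecond"/>
      <scanWindowList count="1">
       <scanWindow>
        <cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" value="{ev.range_low:.4f}" unitName="m/z"/>
        <cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" value="{ev.range_high:.4f}" unitName="m/z"/>
       </scanWindow>
      </scanWindowList>
     </scan>
    </scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len(mz_b64)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitName="m/z"/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len(int_b64)}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitName="number of detector counts"/>
      <binary>{int_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))
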