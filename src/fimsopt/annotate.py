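"""Putative accurate-mass annotation of reproducible m/z features.

Features are matched against a compound database by comparing the observed
m/z with the expected adduct m/z ([M+H]+ in positive mode, [M-H]- in
negative) within a ppm tolerance (default 5).  This is level-2 putative
annotation: isobaric compounds are never disambiguated — every hit within
tolerance is reported, sorted by absolute ppm error.  An optional
constant-ppm mass-accuracy shift (as measured from internal standards)
may be applied to the observed m/z before matching; default 0.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import adduct_mz, ADDUCTS

__all__ = ["DEFAULT_ADDUCTS", "annotate_features", "ANNOTATION_COLUMNS"]

DEFAULT_ADDUCTS = {"positive": ("[M+H]+",), "negative": ("[M-H]-",)}

ANNOTATION_COLUMNS = (
    "ref_mz",
    "compound_id",
    "compound_name",
    "compound_class",
    "adduct",
    "ppm_error",
)


def annotate_features(
    features: "pd.DataFrame | Sequence[float]",
    db: pd.DataFrame,
    polarity: str,
    tolerance_ppm: float = 5.0,
    adducts: Optional[Sequence[str]] = None,
    ppm_shift: float = 0.0,
) -> pd.DataFrame:
    """Match feature m/z values against a compound database.

    Parameters
    ----------
    features
        Feature table with a ``ref_mz`` column, or a bare sequence of m/z.
    db
        Compound table with ``id``, ``name``, ``monoisotopic_mass`` and
        optionally ``class`` columns (see ``msio.read_compound_db``).
    polarity
        ``"positive"`` or ``"negative"``; selects the default adduct.
    adducts
        Override the adduct list (names from ``chem.ADDUCTS``).
    ppm_shift
        Constant mass-accuracy correction applied to observed m/z before
        matching, in ppm (positive shifts observed m/z up).

    Returns
    -------
    DataFrame
        One row per (feature, compound, adduct) hit, plus one all-NaN row
        per unmatched feature, sorted by feature m/z then |ppm error|.
    """
    if polarity not in DEFAULT_ADDUCTS:
        raise ValueError(f"unknown polarity {polarity!r}")
    if len(db) == 0:
        raise ValueError("compound database is empty")
    adduct_names = tuple(adducts) if adducts is not None else DEFAULT_ADDUCTS[polarity]
    for name in adduct_names:
        if name not in ADDUCTS:
            raise KeyError(f"unknown adduct {name!r}")

    if isinstance(features, pd.DataFrame):
        mzs = features["ref_mz"].to_numpy(dtype=float)
    else:
        mzs = np.asarray(list(features), dtype=float)

    # expected ion m/z per (compound, adduct), sorted for window search
    exp_rows = []
    for name in adduct_names:
        for _, row in db.iterrows():
            exp_rows.append(
                (
                    adduct_mz(float(row["monoisotopic_mass"]), name),
                    row["id"],
                    row["name"],
                    row.get("class", ""),
                    name,
                )
            )
    exp_rows.sort(key=lambda r: r[0])
    exp_mz = np.array([r[0] for r in exp_rows])

    records = []
    for mz in mzs:
        corrected = mz * (1.0 + ppm_shift * 1e-6)
        half_width = corrected * tolerance_ppm * 1e-6
        lo = np.searchsorted(exp_mz, corrected - half_width, side="left")
        hi = np.searchsorted(exp_mz, corrected + half_width, side="right")
        hits = []
        for k in range(lo, hi):
            expected, cid, cname, cclass, adduct = exp_rows[k]
            ppm_error = (corrected - expected) / expected * 1e6
            if abs(ppm_error) <= tolerance_ppm:
                hits.append((float(mz), cid, cname, cclass, adduct, float(ppm_error)))
        if hits:
            hits.sort(key=lambda h: abs(h[-1]))
            records.extend(hits)
        else:
            records.append((float(mz), None, None, None, None, np.nan))
    return pd.DataFrame(records, columns=list(ANNOTATION_COLUMNS))
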