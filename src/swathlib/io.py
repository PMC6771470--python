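"""Reading and writing spectral libraries as transition-list TSV files.

Two dialects are supported:

* **peakview** — the PeakView/ProteinPilot SWATH-library export (columns
  ``Q1, Q3, RT_detected, protein_name, relative_intensity,
  stripped_sequence, modification_sequence, prec_z, frg_type, frg_z,
  frg_nr, score, decoy, shared, confidence``). Canonical RT unit is
  minutes.
* **openswath** — the OpenSWATH transition list (``PrecursorMz, ProductMz,
  Tr_recalibrated, ProteinName, PeptideSequence, FullUniModPeptideName,
  PrecursorCharge, LibraryIntensity, FragmentType, FragmentSeriesNumber,
  FragmentCharge``). ``Tr_recalibrated`` values (empirical RT or iRT) are
  passed through unchanged and flagged in ``dialect_meta`` — no iRT
  calibration is attempted.

One file row is one fragment ion; rows sharing an entry key
``(stripped_sequence, modified_sequence, precursor_charge)`` are grouped
into one :class:`~swathlib.model.PrecursorEntry`, preserving row order.
Decoy rows are read and flagged, never dropped. Inconsistent
precursor-level fields within one key are a hard error (they indicate a
corrupt export; libraries are merged at the library level, never by
averaging rows).

Column-name mappings are config-extensible: pass a custom mapping to
:func:`read_library` to absorb PeakView export variants.
"""

from __future__ import annotations

import csv
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .model import FragmentIon, PrecursorEntry, SpectralLibrary

PEAKVIEW_COLUMNS = [
    "Q1", "Q3", "RT_detected", "protein_name", "relative_intensity",
    "stripped_sequence", "modification_sequence", "prec_z", "frg_type",
    "frg_z", "frg_nr", "score", "decoy", "shared", "confidence",
]

OPENSWATH_COLUMNS = [
    "PrecursorMz", "ProductMz", "Tr_recalibrated", "ProteinName",
    "PeptideSequence", "FullUniModPeptideName", "PrecursorCharge",
    "LibraryIntensity", "FragmentType", "FragmentSeriesNumber",
    "FragmentCharge",
]

# Signature columns that identify a dialect.
_PEAKVIEW_SIGNATURE = {"Q1", "Q3", "stripped_sequence"}
_OPENSWATH_SIGNATURE = {"PrecursorMz", "ProductMz", "PeptideSequence"}

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", "", "nan"}


def detect_dialect(header_row: Sequence[str]) -> str:
    """Identify the library dialect from a header row.

    Returns ``"peakview"``, ``"openswath"`` or ``"unknown"``.
    """
    if not header_row:
        raise ValueError("empty header")
    cols = set(header_row)
    if _PEAKVIEW_SIGNATURE <= cols:
        return "peakview"
    if _OPENSWATH_SIGNATURE <= cols:
        return "openswath"
    return "unknown"


def _parse_flag(value) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot interpret flag value {value!r}")


def _require_columns(df: pd.DataFrame, required: Sequence[str]) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    # element-wise float() rather than pandas' fast parser: the latter is
    # not correctly rounded, which would break bit-exact round trips
    values = []
    for pos, raw in enumerate(df[col].tolist()):
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            raise ValueError(
                f"missing value in column {col!r} at file row {pos + 2}")
        try:
            values.append(float(raw))
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric value {raw!r} in column {col!r} at file "
                f"row {pos + 2}") from None
    return pd.Series(values, index=df.index)


def read_library(path, dialect: str = "auto", label: str = "",
                 column_map: Optional[Dict[str, str]] = None
                 ) -> SpectralLibrary:
    """Read a transition-list TSV into a :class:`SpectralLibrary`.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header row.
    dialect : {"auto", "peakview", "openswath"}
        ``"auto"`` detects from the header.
    label : str
        Provenance label attached to the library and seeded into each
        entry's ``sources`` set (defaults to the file stem).
    column_map : dict, optional
        Renames file columns to canonical dialect names before parsing,
        absorbing export variants (e.g. ``{"RT": "RT_detected"}``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    if column_map:
        df = df.rename(columns=column_map)
    if dialect == "auto":
        dialect = detect_dialect(list(df.columns))
    if dialect == "peakview":
        lib = _read_peakview(df)
    elif dialect == "openswath":
        lib = _read_openswath(df)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    lib.label = label or _stem(path)
    for entry in lib:
        entry.sources.add(lib.label)
    return lib


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def _check_consistent(group: pd.DataFrame, key, columns: Sequence[str]):
    for col in columns:
        values = group[col].unique()
        if len(values) > 1:
            raise ValueError(
                f"inconsistent precursor fields within key {key}: column "
                f"{col!r} has values {sorted(map(str, values))}"
            )


def _read_peakview(df: pd.DataFrame) -> SpectralLibrary:
    _require_columns(df, PEAKVIEW_COLUMNS)
    extra_cols = [c for c in df.columns if c not in PEAKVIEW_COLUMNS]
    q1 = _numeric(df, "Q1")
    q3 = _numeric(df, "Q3")
    rt = _numeric(df, "RT_detected")
    inten = _numeric(df, "relative_intensity")
    conf = _numeric(df, "confidence")
    prec_z = _numeric(df, "prec_z").astype(int)
    frg_z = _numeric(df, "frg_z").astype(int)
    frg_nr = _numeric(df, "frg_nr").astype(int)

    entries = []
    grouped = df.groupby(
        ["stripped_sequence", "modification_sequence", "prec_z"],
        sort=False)
    for (stripped, modified, _), group in grouped:
        idx = group.index
        key = (stripped, modified, int(prec_z[idx[0]]))
        _check_consistent(group, key,
                          ["Q1", "RT_detected", "protein_name", "confidence",
                           "decoy", "shared"])
        first = idx[0]
        fragments = [
            FragmentIon(mz=float(q3[i]),
                        relative_intensity=float(inten[i]),
                        series=str(df["frg_type"][i]),
                        ordinal=int(frg_nr[i]),
                        charge=int(frg_z[i]))
            for i in idx
        ]
        entries.append(PrecursorEntry(
            stripped_sequence=stripped,
            modified_sequence=modified,
            precursor_charge=key[2],
            precursor_mz=float(q1[first]),
            rt=float(rt[first]),
            protein=str(df["protein_name"][first]),
            confidence=float(conf[first]),
            is_decoy=_parse_flag(df["decoy"][first]),
            shared=_parse_flag(df["shared"][first]),
            fragments=fragments,
            extras={c: str(df[c][first]) for c in extra_cols},
        ))
    return SpectralLibrary(entries, dialect_meta={
        "dialect": "peakview",
        "columns": list(df.columns),
        "extra_columns": extra_cols,
        "rt_unit": "minutes",
    })


def _read_openswath(df: pd.DataFrame) -> SpectralLibrary:
    _require_columns(df, OPENSWATH_COLUMNS)
    q1 = _numeric(df, "PrecursorMz")
    q3 = _numeric(df, "ProductMz")
    rt = _numeric(df, "Tr_recalibrated")
    inten = _numeric(df, "LibraryIntensity")
    prec_z = _numeric(df, "PrecursorCharge").astype(int)
    frg_z = _numeric(df, "FragmentCharge").astype(int)
    frg_nr = _numeric(df, "FragmentSeriesNumber").astype(int)

    entries = []
    grouped = df.groupby(
        ["PeptideSequence", "FullUniModPeptideName", "PrecursorCharge"],
        sort=False)
    for (stripped, modified, _), group in grouped:
        idx = group.index
        key = (stripped, modified, int(prec_z[idx[0]]))
        _check_consistent(group, key,
                          ["PrecursorMz", "Tr_recalibrated", "ProteinName"])
        first = idx[0]
        fragments = [
            FragmentIon(mz=float(q3[i]),
                        relative_intensity=float(inten[i]),
                        series=str(df["FragmentType"][i]),
                        ordinal=int(frg_nr[i]),
                        charge=int(frg_z[i]))
            for i in idx
        ]
        entries.append(PrecursorEntry(
            stripped_sequence=stripped,
            modified_sequence=modified,
            precursor_charge=key[2],
            precursor_mz=float(q1[first]),
            rt=float(rt[first]),
            protein=str(df["ProteinName"][first]),
            confidence=1.0,  # dialect carries no identification score
            fragments=fragments,
        ))
    return SpectralLibrary(entries, dialect_meta={
        "dialect": "openswath",
        "columns": list(df.columns),
        "extra_columns": [],
        # Tr_recalibrated may be empirical minutes or iRT; passed through.
        "rt_unit": "as-is",
    })


def write_library(lib: SpectralLibrary, path, dialect: str = "peakview"
                  ) -> int:
    """Write ``lib`` as a transition-list TSV; returns rows written.

    One row per fragment ion. PeakView exports all canonical fields plus
    any entry-level extra columns; OpenSWATH exports the standard
    transition-list columns (decoy/shared/confidence have no column in
    that dialect and are not written). Modified sequences are written
    unchanged — no re-encoding between modification nomenclatures.
    """
    if dialect == "peakview":
        return _write_peakview(lib, path)
    if dialect == "openswath":
        return _write_openswath(lib, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _bool_str(flag: bool) -> str:
    return "TRUE" if flag else "FALSE"


def _write_rows(path, header: List[str], rows: List[List]) -> int:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
    return len(rows)


def _write_peakview(lib: SpectralLibrary, path) -> int:
    extra_cols: List[str] = []
    for entry in lib:
        for col in entry.extras:
            if col not in extra_cols:
                extra_cols.append(col)
    header = PEAKVIEW_COLUMNS + extra_cols
    rows = []
    for entry in lib:
        for frag in entry.fragments:
            row = [
                repr(entry.precursor_mz), repr(frag.mz), repr(entry.rt),
                entry.protein, repr(frag.relative_intensity),
                entry.stripped_sequence, entry.modified_sequence,
                entry.precursor_charge, frag.series, frag.charge,
                frag.ordinal, repr(entry.confidence),
                _bool_str(entry.is_decoy), _bool_str(entry.shared),
                repr(entry.confidence),
            ]
            row.extend(entry.extras.get(c, "") for c in extra_cols)
            rows.append(row)
    return _write_rows(path, header, rows)


def _write_openswath(lib: SpectralLibrary, path) -> int:
    rows = []
    for entry in lib:
        for frag in entry.fragments:
            rows.append([
                repr(entry.precursor_mz), repr(frag.mz), repr(entry.rt),
                entry.protein, entry.stripped_sequence,
                entry.modified_sequence, entry.precursor_charge,
                repr(frag.relative_intensity), frag.series, frag.ordinal,
                frag.charge,
            ])
    return _write_rows(path, OPENSWATH_COLUMNS, rows)
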