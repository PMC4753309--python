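"""Shared file I/O: CSV/TSV with ``#`` metadata comments, JSON, Newick.

All text formats are plain, diff-able and round-trip losslessly:
floats are written with 10 significant digits, column order is fixed,
and metadata rides in ``# key=value`` comment lines above the header.
Malformed rows are reported with their 1-based line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .colonization import CellCountObservation
from .community import AbundanceTable
from .geochem import ExtractionRecord
from .kinetics import TimeSeries
from .oxygen import Microprofile

__all__ = [
    "read_series", "write_series",
    "read_profile", "write_profile",
    "read_abundance", "write_abundance",
    "read_counts", "write_counts",
    "read_icp", "write_icp",
    "write_newick", "write_json_report",
]

_FLOAT_FMT = "{:.10g}"


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (float, np.floating, int, np.integer)):
        return _FLOAT_FMT.format(float(x))
    return str(x)


def _read_commented(path: str | Path, sep: str) -> tuple[dict, pd.DataFrame, int]:
    """Parse ``# key=value`` header comments plus the delimited body."""
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        elif line.strip():
            break
        else:
            body_start = i + 1
    from io import StringIO

    body = "\n".join(lines[body_start:])
    df = pd.read_csv(StringIO(body), sep=sep)
    return meta, df, body_start + 2  # 1-based line number of the first data row


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, column: str, first_data_line: int, path) -> np.ndarray:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + first_data_line
        raise ValueError(
            f"{path}: non-numeric value {df[column][bad.idxmax()]!r} "
            f"in column {column!r} at line {line}"
        )
    return converted.to_numpy(dtype=float)


# -- accretion / DNA series ------------------------------------------------

def write_series(series: TimeSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        if series.units:
            fh.write(f"# units={series.units}\n")
        fh.write("t_days,x,censored\n")
        for t, x, c in zip(series.t, series.x, series.censored):
            fh.write(f"{_fmt(t)},{_fmt(x)},{_fmt(c)}\n")


def read_series(path: str | Path) -> TimeSeries:
    meta, df, line0 = _read_commented(path, sep=",")
    _require_columns(df, ["t_days", "x"], path)
    t = _numeric(df, "t_days", line0, path)
    x = _numeric(df, "x", line0, path)
    censored = (
        df["censored"].astype(str).str.lower().isin(["true", "1"]).to_numpy()
        if "censored" in df.columns else None
    )
    return TimeSeries(t=t, x=x, censored=censored, units=meta.get("units", ""))


# -- O2 microprofiles ------------------------------------------------------

def write_profile(profile: Microprofile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# c_bulk_uM={_fmt(profile.C_bulk)}\n")
        if profile.temperature is not None:
            fh.write(f"# temperature_c={_fmt(profile.temperature)}\n")
        fh.write("z_um,c_uM\n")
        for z, c in zip(profile.z, profile.C):
            fh.write(f"{_fmt(z)},{_fmt(c)}\n")


def read_profile(path: str | Path) -> Microprofile:
    meta, df, line0 = _read_commented(path, sep=",")
    _require_columns(df, ["z_um", "c_uM"], path)
    z = _numeric(df, "z_um", line0, path)
    c = _numeric(df, "c_uM", line0, path)
    if "c_bulk_uM" not in meta:
        raise ValueError(f"{path}: missing '# c_bulk_uM=' metadata comment")
    temp = float(meta["temperature_c"]) if "temperature_c" in meta else None
    return Microprofile(z=z, C=c, C_bulk=float(meta["c_bulk_uM"]), temperature=temp)


# -- abundance tables ------------------------------------------------------

def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Taxon x sample TSV; copy numbers and mode ride in comments."""
    with open(path, "w") as fh:
        fh.write(f"# mode={table.mode}\n")
        for taxon, cn in table.copy_numbers.items():
            if cn != 1:
                fh.write(f"# copy_number:{taxon}={_fmt(cn)}\n")
        fh.write("taxon\t" + "\t".join(table.samples) + "\n")
        for taxon in table.taxa:
            row = "\t".join(_fmt(v) for v in table.values.loc[taxon])
            fh.write(f"{taxon}\t{row}\n")


def read_abundance(path: str | Path) -> AbundanceTable:
    meta, df, line0 = _read_commented(path, sep="\t")
    _require_columns(df, ["taxon"], path)
    sample_cols = [c for c in df.columns if c != "taxon"]
    dupes = pd.Index(sample_cols)
    if dupes.duplicated().any() or any(c.endswith(".1") for c in sample_cols):
        suspect = [c for c in sample_cols if c.endswith(".1")]
        raise ValueError(f"{path}: duplicate sample columns {suspect or list(dupes[dupes.duplicated()])}")
    values = df.set_index("taxon")[sample_cols]
    for col in sample_cols:
        values[col] = _numeric(df, col, line0, path)
    copy_numbers = pd.Series(1.0, index=values.index)
    for key, val in meta.items():
        if key.startswith("copy_number:"):
            copy_numbers[key.split(":", 1)[1]] = float(val)
    return AbundanceTable(values=values, mode=meta.get("mode", "counts"),
                         copy_numbers=copy_numbers)


# -- SEM count fields ------------------------------------------------------

def write_counts(observations: list[CellCountObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("t_days,field_id,field_area_cm2,morphotype,count\n")
        for obs in observations:
            for morph, n in sorted(obs.counts.items()):
                fh.write(f"{_fmt(obs.t)},{obs.field_id},{_fmt(obs.field_area)},"
                         f"{morph},{int(n)}\n")


def read_counts(path: str | Path) -> list[CellCountObservation]:
    _, df, line0 = _read_commented(path, sep=",")
    _require_columns(df, ["t_days", "field_id", "field_area_cm2", "morphotype", "count"], path)
    t = _numeric(df, "t_days", line0, path)
    area = _numeric(df, "field_area_cm2", line0, path)
    count = _numeric(df, "count", line0, path)
    out: dict[tuple, CellCountObservation] = {}
    for i in range(len(df)):
        key = (t[i], str(df["field_id"][i]))
        obs = out.get(key)
        if obs is None:
            obs = CellCountObservation(t=t[i], field_area=area[i],
                                       counts={}, field_id=str(df["field_id"][i]))
            out[key] = obs
        obs.counts[str(df["morphotype"][i])] = int(count[i])
    return list(out.values())


# -- ICP extraction tables -------------------------------------------------

def write_icp(records: list[ExtractionRecord], path: str | Path) -> None:
    """Long-format element concentrations, one row per (t, element)."""
    with open(path, "w") as fh:
        if records:
            fh.write(f"# extraction_volume_l={_fmt(records[0].extraction_volume)}\n")
            fh.write(f"# slide_area_cm2={_fmt(records[0].slide_area)}\n")
            if records[0].site:
                fh.write(f"# site={records[0].site}\n")
        fh.write("t_days,element,mg_per_L\n")
        for rec in records:
            for el in sorted(rec.concentrations):
                fh.write(f"{_fmt(rec.t)},{el},{_fmt(rec.concentrations[el])}\n")


def read_icp(path: str | Path) -> list[ExtractionRecord]:
    meta, df, line0 = _read_commented(path, sep=",")
    _require_columns(df, ["t_days", "element", "mg_per_L"], path)
    t = _numeric(df, "t_days", line0, path)
    conc = _numeric(df, "mg_per_L", line0, path)
    volume = float(meta.get("extraction_volume_l", 0.05))
    area = float(meta.get("slide_area_cm2", 18.75))
    site = meta.get("site", "")
    grouped: dict[float, dict[str, float]] = {}
    for i in range(len(df)):
        grouped.setdefault(t[i], {})[str(df["element"][i])] = conc[i]
    return [
        ExtractionRecord(t=tt, concentrations=els, extraction_volume=volume,
                         slide_area=area, site=site)
        for tt, els in sorted(grouped.items())
    ]


# -- misc ------------------------------------------------------------------

def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, numpy types coerced)."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=default) + "\n")
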