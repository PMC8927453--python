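"""Delimited-text I/O for curves, metadata, truth and property tables.

All files are tab-separated with a header row.  Floats are written with 17
significant digits so a write-read round trip reproduces every value to full
double precision.

Schemas
-------
curves:      sample_id, displacement_mm, force_N       (long format)
metadata:    sample_id, tissue, rate_mm_s, L0_mm, A0_mm2
truth:       sample_id, tissue, rate_mm_s, mu_MPa, gamma, rupture_strain, L0_mm, A0_mm2
properties:  see :data:`burnmech.mechanics.PROPERTY_COLUMNS`
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ParseError
from .mechanics import SpecimenGeometry, TensileRecord

_FLOAT_FMT = "%.17g"

CURVE_COLUMNS = ("sample_id", "displacement_mm", "force_N")
META_COLUMNS = ("sample_id", "tissue", "rate_mm_s", "L0_mm", "A0_mm2")


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty table", stacklevel=3)
        return pd.DataFrame(columns=list(required_columns))
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def write_curves(records: Iterable[TensileRecord], path) -> None:
    frames = [pd.DataFrame({"sample_id": rec.sample_id,
                            "displacement_mm": rec.displacement,
                            "force_N": rec.force}) for rec in records]
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=list(CURVE_COLUMNS)))
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_metadata(records: Iterable[TensileRecord], path) -> None:
    rows = [{"sample_id": rec.sample_id, "tissue": rec.tissue_label,
             "rate_mm_s": rec.loading_rate, "L0_mm": rec.geometry.L0,
             "A0_mm2": rec.geometry.A0} for rec in records]
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_study(records, truth: pd.DataFrame | None, out_dir) -> dict[str, Path]:
    """Write curves + metadata (+ optional ground truth) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = list(records)
    paths = {"curves": out_dir / "curves.tsv", "metadata": out_dir / "metadata.tsv"}
    write_curves(records, paths["curves"])
    write_metadata(records, paths["metadata"])
    if truth is not None:
        paths["truth"] = out_dir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False, float_format=_FLOAT_FMT)
    return paths


def read_curves(curves_path, metadata_path) -> list[TensileRecord]:
    """Reassemble TensileRecords from a curves file and its metadata file."""
    curves = _read_table(curves_path, CURVE_COLUMNS)
    meta = _read_table(metadata_path, META_COLUMNS)
    if curves.empty:
        return []
    meta = meta.set_index("sample_id")
    records = []
    for sid, grp in curves.groupby("sample_id", sort=False):
        if sid not in meta.index:
            raise ParseError(f"sample {sid!r} present in curves but not in metadata")
        m = meta.loc[sid]
        records.append(TensileRecord(
            sample_id=str(sid), tissue_label=str(m["tissue"]),
            loading_rate=float(m["rate_mm_s"]),
            geometry=SpecimenGeometry(L0=float(m["L0_mm"]), A0=float(m["A0_mm2"])),
            displacement=grp["displacement_mm"].to_numpy(dtype=float),
            force=grp["force_N"].to_numpy(dtype=float),
        ))
    return records


def write_properties(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_properties(path) -> pd.DataFrame:
    from .mechanics import PROPERTY_COLUMNS
    return _read_table(path, PROPERTY_COLUMNS)
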