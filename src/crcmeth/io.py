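"""Readers and writers for the pipeline's delimited-text formats.

Formats:

* beta matrix TSV — first column ``site_id``, remaining columns one per sample
* sample sheet TSV — ``sample_id, group``
* site annotation TSV — ``site_id, gene, region``
* qMSP plate CSV — long format ``sample_id,matrix,target,well,ct`` with the
  literal ``ND`` for undetected wells
* roster TSV — participant flags and derived analysis arm
* model JSON — intercept, per-marker coefficients, provenance
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, PlateFormatError
from .screening import BetaMatrix

ND = "ND"


def read_beta_matrix(beta_path, samples_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col=0)
    values.index.name = None
    sheet = read_sample_sheet(samples_path)
    return BetaMatrix(values, sheet)


def write_beta_matrix(m: BetaMatrix, beta_path, samples_path) -> None:
    out = m.values.copy()
    out.index.name = "site_id"
    out.to_csv(beta_path, sep="\t")
    sheet = m.sample_groups.rename("group").rename_axis("sample_id").reset_index()
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.Series:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(sheet.columns):
        raise InputError(f"sample sheet {path} needs columns sample_id, group")
    return sheet.set_index("sample_id")["group"]


def read_annotation(path) -> pd.Series:
    ann = pd.read_csv(path, sep="\t")
    if not {"site_id", "gene"} <= set(ann.columns):
        raise InputError(f"annotation {path} needs columns site_id, gene")
    return ann.set_index("site_id")["gene"].fillna("")


def write_annotation(truth: pd.DataFrame, path) -> None:
    ann = truth[["site_id", "gene"]].copy()
    ann["region"] = ""
    ann.to_csv(path, sep="\t", index=False)


def read_plate(path) -> pd.DataFrame:
    """Read a long-format plate CSV; ``ND`` wells become NaN Cts.

    Malformed Ct entries are reported with their 1-based file line number.
    """
    plate = pd.read_csv(path, dtype={"ct": str})
    required = {"sample_id", "matrix", "target", "well", "ct"}
    if not required <= set(plate.columns):
        raise PlateFormatError(f"plate {path} missing columns {sorted(required - set(plate.columns))}")
    plate["line"] = np.arange(2, len(plate) + 2)  # 1-based, after the header
    ct_str = plate["ct"].astype(str).str.strip()
    nd = ct_str.str.upper().eq(ND) | ct_str.eq("") | ct_str.str.lower().eq("nan")
    ct = pd.to_numeric(ct_str.where(~nd), errors="coerce")
    bad = (~nd) & ct.isna()
    if bad.any():
        line = int(plate.loc[bad, "line"].iloc[0])
        raise PlateFormatError(f"plate {path} line {line}: unparseable Ct {ct_str[bad].iloc[0]!r}")
    plate["ct"] = ct
    return plate


def write_plate(plate: pd.DataFrame, path) -> None:
    out = plate[["sample_id", "matrix", "target", "well", "ct"]].copy()
    out["ct"] = out["ct"].map(lambda c: ND if pd.isna(c) else f"{c:.4f}")
    out.to_csv(path, index=False)


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, sep="\t", index=False)


def read_roster(path) -> pd.DataFrame:
    roster = pd.read_csv(path, sep="\t")
    for c in roster.columns:
        if roster[c].dropna().isin([True, False]).all() and roster[c].dtype != bool:
            if c not in ("participant_id", "group", "analysis_arm"):
                roster[c] = roster[c].astype(bool)
    return roster
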