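"""qMSP Ct processing: well aggregation, reference QC, imputation, calling.

The rulebook, applied per sample:

1. **Reference QC** — a sample is invalid if the ACTB reference has
   Ct > 33 (or is undetected) in at least 2 of its 3 wells.
2. **Aggregation** — each target's mean Ct is taken over its detected wells
   when at least 2 of 3 detect; otherwise the target is undetected.
3. **Imputation** — on a QC-valid sample, an undetected target is assigned
   Ct 33 (flagged), so it scores as unmethylated under every positivity
   bound.
4. **Calling** — a marker is positive iff its mean Ct is strictly below the
   (matrix, marker) bound: 31 for cg13096260 and 32 for cg12993163 in
   stool, 25 for either marker in blood. Tissue samples are not called;
   they are summarised as delta-Ct = Ct(target) − Ct(ACTB), lower delta-Ct
   meaning higher methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, PlateFormatError

MARKERS = ("cg13096260", "cg12993163")
REFERENCE = "ACTB"

VALID = "valid"
INVALID = "invalid"
POSITIVE = "positive"
NEGATIVE = "negative"


def _is_undetected(ct) -> bool:
    return ct is None or (isinstance(ct, float) and math.isnan(ct))


@dataclass(frozen=True)
class CallThresholds:
    """Positivity bounds and QC/imputation constants.

    ``bounds`` maps (matrix, marker) to the strict upper Ct bound for a
    positive call; a ``(matrix, "*")`` entry acts as a wildcard for any
    marker in that matrix. Defaults follow the assay design: stool 31/32,
    blood 25 for both markers.
    """

    bounds: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("stool", "cg13096260"): 31.0,
            ("stool", "cg12993163"): 32.0,
            ("blood", "*"): 25.0,
        }
    )
    actb_fail_ct: float = 33.0
    impute_ct: float = 33.0
    min_detected_wells: int = 2

    def __post_init__(self) -> None:
        for key, b in self.bounds.items():
            if b >= self.impute_ct:
                raise ConfigError(f"positivity bound {key}={b} must be below impute_ct={self.impute_ct}")

    def bound_for(self, matrix: str, marker: str) -> float:
        try:
            return self.bounds[(matrix, marker)]
        except KeyError:
            try:
                return self.bounds[(matrix, "*")]
            except KeyError:
                raise ConfigError(f"no positivity bound for matrix={matrix!r}, marker={marker!r}") from None


def aggregate_wells(cts: Sequence[float | None], min_detected_wells: int = 2) -> tuple[float | None, int]:
    """Mean Ct over the detected wells of one (sample, target) triplicate.

    Returns ``(mean_ct, n_detected)``; the mean is None (undetected) when
    fewer than ``min_detected_wells`` of the 3 wells amplified.
    """
    if len(cts) != 3:
        raise PlateFormatError(f"expected exactly 3 wells, got {len(cts)}")
    detected = [float(c) for c in cts if not _is_undetected(c)]
    if len(detected) < min_detected_wells:
        return None, len(detected)
    return float(np.mean(detected)), len(detected)


def qc_reference(actb_cts: Sequence[float | None], actb_fail_ct: float = 33.0) -> str:
    """Reference-gene QC: invalid iff >= 2 of 3 ACTB wells exceed the bound.

    Undetected wells count as failing; Ct exactly at the bound passes
    (the rule is a strict inequality).
    """
    if len(actb_cts) != 3:
        raise PlateFormatError(f"expected exactly 3 ACTB wells, got {len(actb_cts)}")
    n_fail = sum(1 for c in actb_cts if _is_undetected(c) or float(c) > actb_fail_ct)
    return INVALID if n_fail >= 2 else VALID


def impute_undetected(
    mean_ct: float | None, qc_status: str, thresholds: CallThresholds | None = None
) -> tuple[float, bool]:
    """Assign the sentinel Ct (default 33) to an undetected target on a
    QC-valid sample. Returns ``(mean_ct, imputed_flag)``."""
    if qc_status != VALID:
        raise InputError("imputation applies only to QC-valid samples")
    thresholds = thresholds or CallThresholds()
    if mean_ct is None or (isinstance(mean_ct, float) and math.isnan(mean_ct)):
        return thresholds.impute_ct, True
    return float(mean_ct), False


def call_marker(
    mean_ct: float, matrix: str, marker: str, thresholds: CallThresholds | None = None
) -> str:
    """Positive iff mean Ct is strictly below the (matrix, marker) bound."""
    if not math.isfinite(mean_ct):
        raise InputError("call_marker requires a finite mean Ct")
    thresholds = thresholds or CallThresholds()
    return POSITIVE if mean_ct < thresholds.bound_for(matrix, marker) else NEGATIVE


def compute_delta_ct(target_mean_ct: float, actb_mean_ct: float) -> float:
    """Delta-Ct = Ct(target) − Ct(ACTB); lower values = higher methylation."""
    if not (math.isfinite(target_mean_ct) and math.isfinite(actb_mean_ct)):
        raise InputError("delta-Ct requires finite target and reference Cts")
    return float(target_mean_ct) - float(actb_mean_ct)


@dataclass
class PlateResult:
    """Outcome of processing a plate.

    calls : one row per (sample, marker) on QC-valid stool/blood samples:
        ``sample_id, matrix, group, marker, mean_ct, n_detected, imputed, call``
    delta_ct : one row per (tissue sample, marker): ``sample_id, group,
        target, delta_ct``
    invalid : QC-failed samples with reasons
    """

    calls: pd.DataFrame
    delta_ct: pd.DataFrame
    invalid: pd.DataFrame


def _triplicate(sub: pd.DataFrame, sid, target) -> list[float | None]:
    cts = [None if pd.isna(c) else float(c) for c in sub["ct"]]
    if len(cts) != 3:
        lines = sub["line"].tolist() if "line" in sub else []
        raise PlateFormatError(
            f"sample {sid!r} target {target!r}: expected 3 wells, got {len(cts)}"
            + (f" (lines {lines})" if lines else "")
        )
    for c in cts:
        if c is not None and not 0 < c < 40:
            raise PlateFormatError(f"sample {sid!r} target {target!r}: Ct {c} outside (0, 40)")
    return cts


def process_plate(
    plate: pd.DataFrame,
    thresholds: CallThresholds | None = None,
    sample_groups: pd.Series | None = None,
) -> PlateResult:
    """Run QC, aggregation, imputation and calling over a long-format plate.

    ``plate`` needs columns ``sample_id, matrix, target, well, ct`` (ct NaN
    for undetected wells). ``sample_groups`` optionally maps sample id to a
    clinical group carried through to the outputs. Processing is per-sample
    independent; tissue samples yield delta-Ct records instead of calls.
    """
    thresholds = thresholds or CallThresholds()
    required = {"sample_id", "matrix", "target", "well", "ct"}
    if not required <= set(plate.columns):
        raise PlateFormatError(f"plate missing columns {sorted(required - set(plate.columns))}")

    call_rows, dct_rows, invalid_rows = [], [], []
    for (sid, matrix), sub in plate.groupby(["sample_id", "matrix"], sort=True):
        group = "" if sample_groups is None else sample_groups.get(sid, "")
        by_target = {t: g for t, g in sub.groupby("target")}
        if REFERENCE not in by_target:
            raise PlateFormatError(f"sample {sid!r} has no {REFERENCE} wells")
        actb_cts = _triplicate(by_target[REFERENCE], sid, REFERENCE)
        if qc_reference(actb_cts, thresholds.actb_fail_ct) == INVALID:
            invalid_rows.append((sid, matrix, group, "reference gene QC failure"))
            continue
        actb_mean, _ = aggregate_wells(actb_cts, thresholds.min_detected_wells)
        markers = sorted(t for t in by_target if t != REFERENCE)
        for target in markers:
            cts = _triplicate(by_target[target], sid, target)
            mean_ct, n_det = aggregate_wells(cts, thresholds.min_detected_wells)
            mean_ct, imputed = impute_undetected(mean_ct, VALID, thresholds)
            if matrix == "tissue":
                if actb_mean is None:
                    invalid_rows.append((sid, matrix, group, "reference undetected"))
                    break
                dct_rows.append((sid, group, target, compute_delta_ct(mean_ct, actb_mean)))
            else:
                call = call_marker(mean_ct, matrix, target, thresholds)
                call_rows.append((sid, matrix, group, target, mean_ct, n_det, imputed, call))

    calls = pd.DataFrame(
        call_rows,
        columns=["sample_id", "matrix", "group", "marker", "mean_ct", "n_detected", "imputed", "call"],
    )
    delta_ct = pd.DataFrame(dct_rows, columns=["sample_id", "group", "target", "delta_ct"])
    invalid = pd.DataFrame(invalid_rows, columns=["sample_id", "matrix", "group", "reason"])
    return PlateResult(calls, delta_ct, invalid)
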