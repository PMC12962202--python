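"""ROI summaries, bias, and Bland-Altman-type agreement statistics.

Conventions: all SDs use the n-1 denominator; agreement coefficients (95%
limits of agreement, repeatability coefficient, reproducibility coefficient)
are 1.96 times the SD of the relevant paired differences.  ROI tables are
plain pandas DataFrames so they round-trip through CSV unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ROI

#: R2* (1/s) above which ROIs are excluded from PDFF analysis, per field
#: strength label: echo spacings at each field limit PDFF accuracy beyond
#: these rates.  The rule is strictly-greater: a summary exactly at the
#: threshold is retained.
R2STAR_EXCLUSION_S = {"1.5T": 276.0, "3T": 397.0}


def roi_summary(map_2d: np.ndarray, rois: list[ROI], map_id: str = "", method_tag: str = "") -> pd.DataFrame:
    """Per-ROI mean/SD table over finite voxels of ``map_2d``."""
    rows = []
    for roi in rois:
        vals = map_2d[roi.mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {roi.name!r} contains no finite voxels")
        rows.append(
            {
                "roi": roi.name,
                "pdff_nominal": roi.pdff_nominal,
                "t1w_nominal_ms": roi.t1w_nominal_ms,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_voxels": int(vals.size),
                "map_id": map_id,
                "method": method_tag,
            }
        )
    return pd.DataFrame(rows)


def bias_vs_reference(table: pd.DataFrame, reference_table: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI bias = measured mean - reference mean, joined on ROI id."""
    ref = reference_table.set_index("roi")["mean"]
    missing = set(table["roi"]) - set(ref.index)
    if missing:
        raise ValueError(f"reference table lacks ROIs: {sorted(missing)}")
    out = table.copy()
    out["reference"] = out["roi"].map(ref)
    out["bias"] = out["mean"] - out["reference"]
    return out


def group_reference_table(table: pd.DataFrame, ref_t1w_ms: float = 200.0) -> pd.DataFrame:
    """Reference convention for the vial phantom.

    Vials sharing a nominal PDFF were filled from one emulsion batch, so the
    vial whose water T1 is closest to the fat T1 (T1w = 200 ms), measured
    with a low-flip steady-state acquisition, serves as the reference for
    its whole PDFF group.  Returns a table with one reference mean per ROI.
    """
    ref_rows = table[table["t1w_nominal_ms"] == ref_t1w_ms]
    if ref_rows.empty:
        raise ValueError(f"no rows with t1w_nominal_ms == {ref_t1w_ms}")
    by_group = ref_rows.set_index("pdff_nominal")["mean"]
    out = table[["roi", "pdff_nominal"]].copy()
    out["mean"] = out["pdff_nominal"].map(by_group)
    return out


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of paired differences ``a - b``.

    ``coefficient = 1.96 * sd`` and ``kind`` tags the use: LoA (agreement
    between methods), RC (test-retest repeatability), RDC (between-field-
    strength reproducibility).
    """

    n: int
    mean_diff: float
    sd_diff: float
    kind: str

    @property
    def coefficient(self) -> float:
        return 1.96 * self.sd_diff

    @property
    def limits(self) -> tuple[float, float]:
        return (self.mean_diff - self.coefficient, self.mean_diff + self.coefficient)


def bland_altman(values_a, values_b, kind: str = "LoA") -> AgreementStats:
    """Agreement statistics for paired measurements ``a`` and ``b``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value vectors must be 1-D of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if kind not in ("LoA", "RC", "RDC"):
        raise ValueError("kind must be one of LoA, RC, RDC")
    diff = a - b
    return AgreementStats(n=a.size, mean_diff=float(diff.mean()),
                          sd_diff=float(diff.std(ddof=1)), kind=kind)


def voxelwise_sd(maps: list[np.ndarray]) -> np.ndarray:
    """Per-voxel SD (ddof=1) across repeated acquisitions of the same map."""
    if len(maps) < 2:
        raise ValueError("need at least two repetitions")
    stack = np.stack(maps)
    return np.nanstd(stack, axis=0, ddof=1)


def normalize_sd(table: pd.DataFrame, reference_method_table: pd.DataFrame) -> pd.DataFrame:
    """Normalize ROI SD summaries by the reference method's median ROI SD.

    Divides each ROI mean in ``table`` (summaries of a voxel-wise SD map) by
    the median of the reference method's ROI means on the same system,
    removing hardware-dependent noise scale differences between systems.
    """
    ref_median = float(reference_method_table["mean"].median())
    if ref_median <= 0:
        raise ValueError("reference median SD must be positive")
    out = table.copy()
    out["normalized"] = out["mean"] / ref_median
    return out


def r2star_exclude(table: pd.DataFrame, b0_label: str,
                   thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Drop rows whose summary R2* exceeds the field-strength threshold.

    Requires an ``r2star_mean`` column from the designated reference method.
    The rule is strictly greater-than, so summaries exactly at the threshold
    survive, and the operation is idempotent.
    """
    thresholds = thresholds if thresholds is not None else R2STAR_EXCLUSION_S
    if b0_label not in thresholds:
        raise ValueError(f"no R2* exclusion threshold configured for {b0_label!r}")
    if "r2star_mean" not in table.columns:
        raise ValueError("table must carry an 'r2star_mean' column")
    return table[table["r2star_mean"] <= thresholds[b0_label]].reset_index(drop=True)


def whole_liver_pdff(segment_table: pd.DataFrame) -> float:
    """Unweighted mean of the available segment summary values.

    After exclusion, the average runs over the remaining segments; with no
    segments surviving the measurement is flagged missing (NaN).
    """
    if len(segment_table) == 0:
        return float("nan")
    if len(segment_table) > 9:
        raise ValueError("at most nine liver segments expected")
    return float(segment_table["mean"].mean())
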