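"""Relative copy number from qPCR Ct replicates (calibrator ddCt method).

Each sample's mean target Ct is normalized to a reference gene (dCt),
referenced to a calibrator animal assumed to carry two copies (ddCt), and
converted to copy number as 2 * 2^(-ddCt) under perfect doubling.  A
censored target (no amplification) maps to copy number zero.  When no
two-copy calibrator exists, the modal copy level across assayed animals
can be re-anchored to two copies instead.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


class QpcrError(ValueError):
    pass


class CalibrationError(QpcrError):
    pass


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    target_ct: tuple[float, ...]   # NaN marks a censored replicate
    reference_ct: tuple[float, ...]
    assay: str = ""

    def __post_init__(self) -> None:
        if len(self.target_ct) < 1 or len(self.reference_ct) < 1:
            raise QpcrError("need at least one replicate")


@dataclass(frozen=True)
class DeltaCt:
    sample: str
    mean: float                     # +inf when all target replicates censored
    per_replicate: tuple[float, ...]


@dataclass(frozen=True)
class CopyNumberCall:
    sample: str
    delta_ct: float
    ddct: float
    copy_number: float
    rounded_cn: int
    min_max_range: tuple[float, float]


def delta_ct(m: CtMeasurement) -> DeltaCt:
    """Mean target Ct minus mean reference Ct, keeping per-replicate dCt.

    Censored replicates among valid ones are dropped with a warning; if
    every target replicate is censored, dCt is +inf (copy number zero).
    Per-replicate dCt pairs replicates index-wise when counts match,
    otherwise each target replicate is set against the reference mean.
    """
    tgt = np.asarray(m.target_ct, dtype=float)
    ref = np.asarray(m.reference_ct, dtype=float)
    ref_mean = float(np.nanmean(ref))
    valid = ~np.isnan(tgt)
    if not valid.any():
        return DeltaCt(sample=m.sample, mean=float("inf"), per_replicate=())
    if not valid.all():
        warnings.warn(
            f"{m.sample}: dropping {int((~valid).sum())} censored target replicate(s)",
            stacklevel=2,
        )
    if len(tgt) == len(ref):
        per = tuple(float(t - r) for t, r, ok in zip(tgt, ref, valid) if ok)
    else:
        per = tuple(float(t - ref_mean) for t in tgt[valid])
    return DeltaCt(
        sample=m.sample,
        mean=float(np.mean(tgt[valid]) - ref_mean),
        per_replicate=per,
    )


def copy_number(
    sample_dct: DeltaCt, calibrator_dct: DeltaCt, calibrator_cn: float = 2.0
) -> CopyNumberCall:
    """ddCt-based copy number: calibrator_cn * 2^(-ddCt)."""
    if np.isinf(calibrator_dct.mean):
        raise CalibrationError("calibrator target is censored; cannot calibrate")
    if np.isinf(sample_dct.mean):
        return CopyNumberCall(
            sample=sample_dct.sample,
            delta_ct=float("inf"),
            ddct=float("inf"),
            copy_number=0.0,
            rounded_cn=0,
            min_max_range=(0.0, 0.0),
        )
    ddct = sample_dct.mean - calibrator_dct.mean
    cn = calibrator_cn * 2.0 ** (-ddct)
    reps = np.array(sample_dct.per_replicate) - calibrator_dct.mean
    rng = (
        (float(calibrator_cn * 2.0 ** (-reps.max())), float(calibrator_cn * 2.0 ** (-reps.min())))
        if reps.size
        else (cn, cn)
    )
    return CopyNumberCall(
        sample=sample_dct.sample,
        delta_ct=sample_dct.mean,
        ddct=ddct,
        copy_number=cn,
        rounded_cn=max(0, round(cn)),
        min_max_range=rng,
    )


def mode_calibrate(calls: list[CopyNumberCall]) -> list[CopyNumberCall]:
    """Re-anchor relative copy levels so the modal rounded level becomes 2.

    Used when no external two-copy calibrator exists.  Raises on a
    multimodal tie, listing the tied levels.
    """
    if len(calls) < 3:
        raise CalibrationError("mode calibration needs at least 3 samples")
    counts = Counter(c.rounded_cn for c in calls)
    top = counts.most_common()
    modes = [lvl for lvl, n in top if n == top[0][1]]
    if len(modes) > 1:
        raise CalibrationError(f"tied modal copy levels: {sorted(modes)}")
    mode = modes[0]
    if mode == 0:
        raise CalibrationError("modal copy level is zero; cannot rescale")
    scale = 2.0 / mode
    shift = np.log2(mode / 2.0)  # equivalent ddct adjustment
    out = []
    for c in calls:
        cn = c.copy_number * scale
        out.append(
            replace(
                c,
                ddct=c.ddct + shift if np.isfinite(c.ddct) else c.ddct,
                copy_number=cn,
                rounded_cn=max(0, round(cn)),
                min_max_range=(c.min_max_range[0] * scale, c.min_max_range[1] * scale),
            )
        )
    return out


def measurements_from_table(df: pd.DataFrame) -> list[CtMeasurement]:
    """Parse a replicate table (sample, assay, target_ct_rep*, reference_ct_rep*)."""
    tgt_cols = sorted(c for c in df.columns if c.startswith("target_ct_rep"))
    ref_cols = sorted(c for c in df.columns if c.startswith("reference_ct_rep"))
    if not tgt_cols or not ref_cols:
        raise QpcrError("no replicate columns found")
    return [
        CtMeasurement(
            sample=str(r["sample"]),
            assay=str(r.get("assay", "")),
            target_ct=tuple(float(r[c]) for c in tgt_cols),
            reference_ct=tuple(float(r[c]) for c in ref_cols),
        )
        for _, r in df.iterrows()
    ]


def call_copy_numbers(
    measurements: list[CtMeasurement],
    calibrator: str | None = None,
    calibrator_cn: float = 2.0,
    mode_anchor: bool = False,
) -> list[CopyNumberCall]:
    """Full ddCt pipeline over a set of samples for one assay."""
    dcts = {m.sample: delta_ct(m) for m in measurements}
    if mode_anchor:
        zero = DeltaCt(sample="__origin__", mean=0.0, per_replicate=())
        raw = [copy_number(d, zero, calibrator_cn) for d in dcts.values()]
        return mode_calibrate(raw)
    if calibrator is None or calibrator not in dcts:
        raise CalibrationError("calibrator sample not found")
    cal = dcts[calibrator]
    return [
        copy_number(d, cal, calibrator_cn)
        for s, d in dcts.items()
        if s != calibrator
    ]
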