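"""Two-sample read-depth CNV detection over sliding windows.

Read starts from two samples are counted in half-overlapping sliding
windows; each window's count ratio is tested against equal copy number
with a Geary-Hinkley transform of the ratio of two Poisson variables, and
maximal runs of consecutive significant windows with a common sign of the
log2 ratio are merged into CNV calls.  Defaults follow the standard
read-depth configuration: p <= 0.001, |log2 ratio| >= 0.6, and at least
ten consecutive significant windows per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


class CnvCallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerConfig:
    p_threshold: float = 0.001
    log2_threshold: float = 0.6
    min_windows_required: int = 10
    window_multiplier: int = 2
    explicit_window_length: int | None = None

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.log2_threshold <= 0:
            raise CnvCallerError("thresholds must be positive")
        if self.min_windows_required < 1:
            raise CnvCallerError("min_windows_required must be >= 1")


@dataclass(frozen=True)
class CnvCall:
    id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    mean_log2_ratio: float
    combined_p: float
    n_windows: int
    direction: str  # "gain_in_A" | "gain_in_B"


def count_reads_in_windows(
    placements_a: dict[str, np.ndarray],
    placements_b: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    window_length: int,
    advance: int,
) -> pd.DataFrame:
    """Count read starts per sliding window.

    Windows are half-open [k*advance, k*advance + window_length) on 0-based
    coordinates; a trailing partial window is dropped.  Read positions are
    1-based on input; placements beyond the chromosome end are skipped with
    a logged warning.  Returns columns chrom, start, end, x, y.
    """
    if not (1 <= advance <= window_length):
        raise CnvCallerError("need window_length >= advance >= 1")
    frames = []
    for chrom, length in chrom_lengths.items():
        if length < window_length:
            continue
        n_win = (length - window_length) // advance + 1
        starts = np.arange(n_win, dtype=np.int64) * advance
        ends = starts + window_length
        cols = {}
        for name, placements in (("x", placements_a), ("y", placements_b)):
            pos = np.sort(np.asarray(placements.get(chrom, ()), dtype=np.int64)) - 1
            n_bad = int((pos < 0).sum() + (pos >= length).sum())
            if n_bad:
                logger.warning(
                    "%d read placement(s) beyond %s bounds skipped", n_bad, chrom
                )
                pos = pos[(pos >= 0) & (pos < length)]
            cols[name] = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "x": cols["x"], "y": cols["y"]}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def geary_hinkley_p(
    x: np.ndarray, y: np.ndarray, mu_x: float, mu_y: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p-value for x/y departing from its null ratio mu_x/mu_y.

    Treats t = (mu_y*z - mu_x) / sqrt(mu_y*z^2 + mu_x), z = x/y, as standard
    normal under the null that both counts are Poisson at their null means.
    y = 0 is handled by the z -> inf limit t -> sqrt(mu_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = x / y
        t = (mu_y * z - mu_x) / np.sqrt(mu_y * z * z + mu_x)
    t = np.where((y == 0) & (x > 0), np.sqrt(mu_y), t)
    t = np.where((y == 0) & (x == 0), 0.0, t)
    p = 2.0 * norm.sf(np.abs(t))
    return t, p


def window_ratio_test(
    x: int, y: int, total_a: float, total_b: float, n_windows: int
) -> tuple[float, float]:
    """(log2 ratio, p) for one window.

    ``total_a``/``total_b`` are the summed window counts of the track and
    ``n_windows`` its size, so the null per-window means are total/n.  The
    log2 ratio is log2((x/total_a)/(y/total_b)); it is +/-inf when exactly
    one count is zero and NaN when both are.
    """
    if total_a <= 0 or total_b <= 0:
        raise CnvCallerError("totals must be positive")
    mu_x = total_a / n_windows
    mu_y = total_b / n_windows
    _, p = geary_hinkley_p(np.array([x]), np.array([y]), mu_x, mu_y)
    if x == 0 and y == 0:
        return float("nan"), 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = float(
            np.log2(np.float64(x) / total_a) - np.log2(np.float64(y) / total_b)
        )
    return log2r, float(p[0])


def ratio_test_track(track: pd.DataFrame, cfg: CallerConfig | None = None) -> pd.DataFrame:
    """Add log2_ratio, p_value and significance flags to a window track.

    Null means are the track's own per-window averages; significance
    requires both p <= p_threshold and |log2 ratio| >= log2_threshold.
    Windows with both counts zero are non-significant with undefined ratio.
    """
    cfg = cfg or CallerConfig()
    out = track.copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    total_a, total_b = x.sum(), y.sum()
    if total_a <= 0 or total_b <= 0:
        raise CnvCallerError("each sample needs at least one counted read")
    n = len(out)
    _, p = geary_hinkley_p(x, y, total_a / n, total_b / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2((x / total_a) / (y / total_b))
    both_zero = (x == 0) & (y == 0)
    log2r = np.where(both_zero, np.nan, log2r)
    p = np.where(both_zero, 1.0, p)
    out["log2_ratio"] = log2r
    out["p_value"] = p
    with np.errstate(invalid="ignore"):
        out["significant"] = (
            (p <= cfg.p_threshold)
            & ~both_zero
            & (np.abs(log2r) >= cfg.log2_threshold)
        )
    return out


def auto_window_length(
    genome_length: int, total_a: int, total_b: int, cfg: CallerConfig | None = None
) -> int:
    """Smallest window (times the configured multiplier) at which a true
    |log2 ratio| of ``log2_threshold`` reaches the ``p_threshold`` critical
    point of the ratio test, given genome-scaled expected counts."""
    cfg = cfg or CallerConfig()
    if total_a <= 0 or total_b <= 0:
        raise CnvCallerError("totals must be positive")
    z_crit = norm.isf(cfg.p_threshold / 2.0)

    def min_t(length: int) -> float:
        mu_x = total_a * length / genome_length
        mu_y = total_b * length / genome_length
        r = 2.0 ** cfg.log2_threshold
        ts = []
        for z in (mu_x / mu_y * r, mu_x / mu_y / r):
            t = (mu_y * z - mu_x) / np.sqrt(mu_y * z * z + mu_x)
            ts.append(abs(t))
        return min(ts)

    lo, hi = 1, int(genome_length)
    if min_t(hi) < z_crit:
        raise CnvCallerError("no feasible window length up to the genome length")
    while lo < hi:
        mid = (lo + hi) // 2
        if min_t(mid) >= z_crit:
            hi = mid
        else:
            lo = mid + 1
    return cfg.window_multiplier * lo


def call_cnvs(stats: pd.DataFrame, cfg: CallerConfig | None = None) -> list[CnvCall]:
    """Merge runs of consecutive significant same-sign windows into calls.

    Input must be ordered by (chromosome, start); runs shorter than
    ``min_windows_required`` are discarded and mixed-sign runs split at the
    sign change.  combined_p is the minimum member p-value.
    """
    cfg = cfg or CallerConfig()
    calls: list[CnvCall] = []
    for chrom, sub in stats.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise CnvCallerError("window track must be sorted by start")
        sig = sub["significant"].to_numpy()
        log2r = sub["log2_ratio"].to_numpy()
        sign = np.sign(log2r)
        run: list[int] = []
        counter = 0

        def flush(run_idx: list[int]) -> None:
            nonlocal counter
            if len(run_idx) < cfg.min_windows_required:
                return
            counter += 1
            member = sub.iloc[run_idx]
            mean_l2 = float(member["log2_ratio"].mean())
            num = chrom[3:] if chrom.lower().startswith("chr") else chrom
            calls.append(
                CnvCall(
                    id=f"Chr{num}_CNV_{counter}",
                    chrom=chrom,
                    start=int(member["start"].iloc[0]),
                    end=int(member["end"].iloc[-1]),
                    mean_log2_ratio=mean_l2,
                    combined_p=float(member["p_value"].min()),
                    n_windows=len(run_idx),
                    direction="gain_in_A" if mean_l2 > 0 else "gain_in_B",
                )
            )

        for i in range(len(sub)):
            if sig[i] and (not run or sign[i] == sign[run[-1]]):
                run.append(i)
            else:
                flush(run)
                run = [i] if sig[i] else []
        flush(run)
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "mean_log2_ratio": c.mean_log2_ratio,
                "combined_p": c.combined_p,
                "n_windows": c.n_windows,
                "direction": c.direction,
            }
            for c in calls
        ],
        columns=[
            "id", "chrom", "start", "end", "mean_log2_ratio",
            "combined_p", "n_windows", "direction",
        ],
    )


def run_caller(
    placements_a: dict[str, np.ndarray],
    placements_b: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    cfg: CallerConfig | None = None,
) -> tuple[pd.DataFrame, list[CnvCall]]:
    """Count, test and call in one pass, sizing the window automatically
    unless ``cfg.explicit_window_length`` is set.  The sliding advance is
    half the window length."""
    cfg = cfg or CallerConfig()
    if cfg.explicit_window_length:
        window = cfg.explicit_window_length
    else:
        total_a = sum(len(v) for v in placements_a.values())
        total_b = sum(len(v) for v in placements_b.values())
        window = auto_window_length(
            sum(chrom_lengths.values()), total_a, total_b, cfg
        )
    advance = max(window // 2, 1)
    track = count_reads_in_windows(
        placements_a, placements_b, chrom_lengths, window, advance
    )
    stats = ratio_test_track(track, cfg)
    return stats, call_cnvs(stats, cfg)
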