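"""Periodogram-based undulation scoring of worm keypoint trajectories.

Tracked positions of seven body points (jaws, body1–body5, tail) are
quality-controlled by per-point annotation coverage, gap-filled by linear
interpolation, and scanned in non-overlapping 10-second windows.  A window
counts as undulation when any of the five trunk points (body1–body5) moves
within a bounded pixel range AND oscillates at a dominant frequency inside
the undulation band (0.5–1.5 Hz by default).  Window labels are aggregated
into an undulation-ratio time series, integrated into per-animal AUC values
over a circadian interval, and compared between groups with Shapiro–Wilk,
Wilcoxon signed-rank (paired) and Wilcoxon rank-sum (unpaired) tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "POINT_NAMES",
    "BODY_POINTS",
    "KeypointTrack",
    "WindowClassification",
    "UndulationSeries",
    "GroupComparison",
    "read_tracks_csv",
    "qc_tracks",
    "interpolate_missing",
    "classify_window",
    "classify_track",
    "undulation_ratio",
    "interval_auc",
    "compare_groups",
]

POINT_NAMES = ("jaws", "body1", "body2", "body3", "body4", "body5", "tail")
BODY_POINTS = ("body1", "body2", "body3", "body4", "body5")
_BODY_IDX = tuple(POINT_NAMES.index(p) for p in BODY_POINTS)


@dataclass
class KeypointTrack:
    """Per-frame positions of the 7 tracked points for one animal.

    ``x``, ``y``: float arrays of shape (n_frames, 7), ordered as
    ``POINT_NAMES``; ``present``: boolean array of the same shape flagging
    frames where the point was annotated.  ``t0_zt_hours`` anchors frame 0
    in zeitgeber time.
    """

    worm_id: str
    genotype: str
    fps: float
    x: np.ndarray
    y: np.ndarray
    present: np.ndarray
    t0_zt_hours: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name, arr in (("x", self.x), ("y", self.y), ("present", self.present)):
            if arr.ndim != 2 or arr.shape[1] != len(POINT_NAMES):
                raise ValueError(f"{name} must have shape (n_frames, 7)")
        if not (self.x.shape == self.y.shape == self.present.shape):
            raise ValueError("x, y and present must share one shape")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    def coverage(self) -> np.ndarray:
        """Fraction of frames annotated, per point."""
        return self.present.mean(axis=0)


@dataclass(frozen=True)
class WindowClassification:
    """Label and diagnostics for one 10-s window."""

    window_index: int
    start_time: float  # s from recording start
    dominant_frequency: dict  # point name -> Hz
    movement: dict  # point name -> px (peak-to-peak coordinate range)
    undulating: bool


@dataclass(frozen=True)
class UndulationSeries:
    """Fraction of undulating windows per time bin, for one animal."""

    worm_id: str
    bin_start: tuple[float, ...]  # s from recording start
    ratio: tuple[float, ...]
    bin_width: float  # s
    t0_zt_hours: float = 0.0

    def __post_init__(self) -> None:
        if any(not 0.0 <= r <= 1.0 for r in self.ratio):
            raise ValueError("ratios must lie in [0, 1]")
        if len(self.bin_start) != len(self.ratio):
            raise ValueError("bin_start and ratio must align")


@dataclass(frozen=True)
class GroupComparison:
    """One statistical test on per-animal AUC values."""

    test_name: str  # shapiro | wilcoxon_signed_rank | wilcoxon_rank_sum
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    n: tuple[int, ...]
    paired: bool
    significant: bool
    degenerate: bool = False


def read_tracks_csv(tracks_path, meta_path) -> list[KeypointTrack]:
    """Load the long-format track CSV plus its per-animal metadata JSON.

    CSV columns: worm_id, frame, point_name, x, y, present (0/1).
    Metadata JSON: worm_id -> {fps, genotype, t0_zt_hours}.
    """
    df = pd.read_csv(tracks_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    tracks = []
    for worm_id, grp in df.groupby("worm_id", sort=True):
        m = meta[str(worm_id)]
        n_frames = int(grp["frame"].max()) + 1
        x = np.zeros((n_frames, 7))
        y = np.zeros((n_frames, 7))
        present = np.zeros((n_frames, 7), dtype=bool)
        for p_idx, pname in enumerate(POINT_NAMES):
            sub = grp[grp["point_name"] == pname]
            fr = sub["frame"].to_numpy(dtype=int)
            x[fr, p_idx] = sub["x"].to_numpy()
            y[fr, p_idx] = sub["y"].to_numpy()
            present[fr, p_idx] = sub["present"].to_numpy(dtype=bool)
        tracks.append(
            KeypointTrack(
                worm_id=str(worm_id), genotype=m["genotype"], fps=float(m["fps"]),
                x=x, y=y, present=present,
                t0_zt_hours=float(m.get("t0_zt_hours", 0.0)),
            )
        )
    return tracks


def qc_tracks(
    tracks: Iterable[KeypointTrack], min_coverage: float = 0.9
) -> list[KeypointTrack]:
    """Keep animals whose every point is annotated in >= ``min_coverage`` of frames."""
    return [t for t in tracks if (t.coverage() >= min_coverage).all()]


def _fill_1d(values: np.ndarray, present: np.ndarray) -> np.ndarray:
    idx = np.nonzero(present)[0]
    if idx.size == 0:
        raise ValueError("a tracked point has no annotated frames")
    # np.interp extends with the nearest observed value beyond the ends
    return np.interp(np.arange(values.size), idx, values[idx])


def interpolate_missing(track: KeypointTrack) -> KeypointTrack:
    """Fill missing frames linearly; leading/trailing gaps take the nearest value."""
    x = track.x.copy()
    y = track.y.copy()
    for p in range(len(POINT_NAMES)):
        pres = track.present[:, p]
        if pres.all():
            continue
        x[:, p] = _fill_1d(x[:, p], pres)
        y[:, p] = _fill_1d(y[:, p], pres)
    return replace(
        track, x=x, y=y, present=np.ones_like(track.present, dtype=bool)
    )


def _dominant_frequency(coords: np.ndarray, fps: float) -> tuple[float, float]:
    """(dominant frequency, peak power) of a 1-D coordinate trace.

    Mean-removed periodogram, no taper; the DC bin is excluded from the
    peak search.
    """
    freqs, power = signal.periodogram(
        coords, fs=fps, detrend="constant", window="boxcar"
    )
    i = int(np.argmax(power[1:])) + 1
    return float(freqs[i]), float(power[i])


def classify_window(
    x: np.ndarray,
    y: np.ndarray,
    fps: float,
    freq_band: tuple[float, float] = (0.5, 1.5),
    move_band: tuple[float, float] = (0.5, 10.0),
    window_index: int = 0,
    start_time: float = 0.0,
    window_s: float = 10.0,
    movement_mode: str = "range",
) -> WindowClassification:
    """Score one 10-s window of the five trunk points.

    ``x``, ``y``: arrays of shape (n_frames, 5) for body1–body5.  For each
    point, the dominant frequency is taken from the coordinate axis with the
    larger periodogram peak, and the movement is the larger peak-to-peak
    coordinate range of the two axes (``movement_mode="pathlength"`` sums
    frame-to-frame displacements instead).  The window is undulating iff ANY
    point falls inside both bands (inclusive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    expected = int(round(window_s * fps))
    if x.shape[0] != expected or y.shape[0] != expected:
        raise ValueError(
            f"window must span exactly {window_s} s = {expected} frames at {fps} fps"
        )
    if x.shape[1] != len(BODY_POINTS) or y.shape[1] != len(BODY_POINTS):
        raise ValueError("window arrays must cover the 5 trunk points")
    if fps < 2.0 * freq_band[1]:
        raise ValueError("fps below the Nyquist bound for the frequency band")

    dom: dict[str, float] = {}
    move: dict[str, float] = {}
    undulating = False
    for j, pname in enumerate(BODY_POINTS):
        fx, px_pow = _dominant_frequency(x[:, j], fps)
        fy, py_pow = _dominant_frequency(y[:, j], fps)
        freq = fx if px_pow >= py_pow else fy
        if movement_mode == "range":
            mv = max(np.ptp(x[:, j]), np.ptp(y[:, j]))
        elif movement_mode == "pathlength":
            mv = float(np.hypot(np.diff(x[:, j]), np.diff(y[:, j])).sum())
        else:
            raise ValueError("movement_mode must be 'range' or 'pathlength'")
        dom[pname] = freq
        move[pname] = float(mv)
        if (
            move_band[0] <= mv <= move_band[1]
            and freq_band[0] <= freq <= freq_band[1]
        ):
            undulating = True
    return WindowClassification(
        window_index=window_index, start_time=start_time,
        dominant_frequency=dom, movement=move, undulating=undulating,
    )


def classify_track(
    track: KeypointTrack,
    freq_band: tuple[float, float] = (0.5, 1.5),
    move_band: tuple[float, float] = (0.5, 10.0),
    window_s: float = 10.0,
    movement_mode: str = "range",
) -> list[WindowClassification]:
    """Classify every complete non-overlapping 10-s window of one track."""
    if not track.present.all():
        track = interpolate_missing(track)
    wlen = int(round(window_s * track.fps))
    n_windows = track.n_frames // wlen
    out = []
    for w in range(n_windows):
        sl = slice(w * wlen, (w + 1) * wlen)
        out.append(
            classify_window(
                track.x[sl][:, _BODY_IDX], track.y[sl][:, _BODY_IDX], track.fps,
                freq_band=freq_band, move_band=move_band,
                window_index=w, start_time=w * wlen / track.fps,
                window_s=window_s, movement_mode=movement_mode,
            )
        )
    return out


def undulation_ratio(
    classifications: Sequence[WindowClassification],
    bin_width: float = 180.0,
    worm_id: str = "",
    t0_zt_hours: float = 0.0,
    window_s: float = 10.0,
) -> UndulationSeries:
    """Fraction of undulating windows per ``bin_width``-second bin.

    Bins are aligned to the recording start; bins containing no windows are
    omitted.  A window belongs to the bin containing its start time.
    """
    counts: dict[int, list[int]] = {}
    for c in classifications:
        b = int(c.start_time // bin_width)
        counts.setdefault(b, []).append(int(c.undulating))
    bins = sorted(counts)
    return UndulationSeries(
        worm_id=worm_id,
        bin_start=tuple(b * bin_width for b in bins),
        ratio=tuple(float(np.mean(counts[b])) for b in bins),
        bin_width=bin_width,
        t0_zt_hours=t0_zt_hours,
    )


def interval_auc(series: UndulationSeries, t_start: float, t_end: float) -> float:
    """Trapezoidal integral of the undulation ratio over [t_start, t_end] hours.

    Times are zeitgeber/circadian hours; the series is anchored at
    ``t0_zt_hours``.  Ratios are placed at bin midpoints, the piecewise-linear
    curve is extended with its edge values, and the integral is returned in
    ratio-hours.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    mid_h = (
        np.asarray(series.bin_start) + 0.5 * series.bin_width
    ) / 3600.0 + series.t0_zt_hours
    r = np.asarray(series.ratio, dtype=float)
    cover_lo = series.t0_zt_hours + np.asarray(series.bin_start).min() / 3600.0
    cover_hi = (
        series.t0_zt_hours
        + (np.asarray(series.bin_start).max() + series.bin_width) / 3600.0
    )
    if t_end <= cover_lo or t_start >= cover_hi:
        raise ValueError("requested interval does not overlap the series")
    # sample the piecewise-linear ratio curve on the clipped interval
    lo = max(t_start, cover_lo)
    hi = min(t_end, cover_hi)
    grid = np.unique(np.concatenate(([lo, hi], mid_h[(mid_h > lo) & (mid_h < hi)])))
    vals = np.interp(grid, mid_h, r)  # edge bins extend flat
    return float(np.trapezoid(vals, grid))


def compare_groups(
    auc_values: Mapping[tuple[str, str], Sequence[float]],
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Shapiro–Wilk per group, signed-rank within genotype, rank-sum between.

    ``auc_values`` maps (genotype, condition) to per-animal AUCs.  Paired
    signed-rank tests compare the two conditions of one genotype (matched
    animals, equal lengths required); rank-sum tests compare the two
    genotypes within one condition.
    """
    out: list[GroupComparison] = []
    keys = sorted(auc_values)
    for key in keys:
        vals = np.asarray(auc_values[key], dtype=float)
        if vals.size < 3:
            raise ValueError(f"group {key} needs at least 3 values")
        stat, p = stats.shapiro(vals)
        out.append(GroupComparison(
            test_name="shapiro", groups=(f"{key[0]}/{key[1]}",),
            statistic=float(stat), p_value=float(p), n=(vals.size,),
            paired=False, significant=p < alpha,
        ))
    genotypes = sorted({g for g, _ in keys})
    conditions = sorted({c for _, c in keys})
    for g in genotypes:  # paired: condition A vs B within genotype
        conds = [c for c in conditions if (g, c) in auc_values]
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a = np.asarray(auc_values[(g, conds[i])], dtype=float)
                b = np.asarray(auc_values[(g, conds[j])], dtype=float)
                if a.size != b.size:
                    raise ValueError(
                        f"paired comparison {g}: {conds[i]} vs {conds[j]} "
                        "requires equal-length matched vectors"
                    )
                diffs = a - b
                if np.all(diffs == 0):
                    out.append(GroupComparison(
                        test_name="wilcoxon_signed_rank",
                        groups=(f"{g}/{conds[i]}", f"{g}/{conds[j]}"),
                        statistic=float("nan"), p_value=1.0,
                        n=(a.size, b.size), paired=True,
                        significant=False, degenerate=True,
                    ))
                    continue
                stat, p = stats.wilcoxon(a, b)
                out.append(GroupComparison(
                    test_name="wilcoxon_signed_rank",
                    groups=(f"{g}/{conds[i]}", f"{g}/{conds[j]}"),
                    statistic=float(stat), p_value=float(p),
                    n=(a.size, b.size), paired=True, significant=p < alpha,
                ))
    for c in conditions:  # unpaired: genotype A vs B within condition
        gens = [g for g in genotypes if (g, c) in auc_values]
        for i in range(len(gens)):
            for j in range(i + 1, len(gens)):
                a = np.asarray(auc_values[(gens[i], c)], dtype=float)
                b = np.asarray(auc_values[(gens[j], c)], dtype=float)
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                out.append(GroupComparison(
                    test_name="wilcoxon_rank_sum",
                    groups=(f"{gens[i]}/{c}", f"{gens[j]}/{c}"),
                    statistic=float(stat), p_value=float(p),
                    n=(a.size, b.size), paired=False, significant=p < alpha,
                ))
    return out
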