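"""Kymograph construction and wave-feature extraction.

Quantifies the wavelike behaviour of expression patterns along the
anterior-posterior axis: kymographs (time x AP position), per-frame peak
detection linked into wave tracks, wave direction and speed, the spatial
trend of wave amplitude, and a static-like / dynamic-like classification of
enhancer activity. A static enhancer's activity wave gains strength as it
travels toward the anterior (where the speed regulator is low); a dynamic
enhancer's wave weakens anterior-ward. The AP convention is package-wide:
index 0 = anterior (see :mod:`wavegrn.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

from .grn_model import SimulationResult

__all__ = [
    "Kymograph",
    "WaveTrack",
    "WaveSummary",
    "extract_kymograph",
    "detect_wave_peaks",
    "classify_enhancer_dynamics",
    "count_stripes",
    "ap_intensity_profile",
    "deletion_phenotype_report",
]


@dataclass
class Kymograph:
    """Intensity over (time x AP position); position 0 = anterior.

    ``values`` may contain NaN where a position bin received no samples;
    missing bins are never imputed in stored data (peak detection
    interpolates on the fly).
    """

    values: np.ndarray
    times: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be 2-D (time x position)")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times length must match number of frames")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("time stamps must be monotone")

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_csv(self, path) -> None:
        """CSV matrix; header row = bin centers, first column = time."""
        df = pd.DataFrame(self.values, columns=[f"{c:g}" for c in self.bin_centers])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Kymograph":
        df = pd.read_csv(path)
        times = df.pop("time").to_numpy()
        centers = np.asarray([float(c) for c in df.columns])
        if len(centers) > 1:
            half = np.diff(centers).mean() / 2
        else:
            half = 0.5
        edges = np.concatenate([[centers[0] - half], centers + half])
        return cls(values=df.to_numpy(), times=times, bin_edges=edges)


@dataclass
class WaveTrack:
    """One wave crest followed over time: per-frame (time, position, amplitude)."""

    track_id: int
    times: np.ndarray
    positions: np.ndarray
    amplitudes: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class WaveSummary:
    """Direction, speed, amplitude trend and classification of one track."""

    direction: Literal["posterior_to_anterior", "anterior_to_posterior", "stationary"]
    mean_speed: float
    amplitude_slope: float
    classification: Literal["static_like", "dynamic_like", "ambiguous"]
    slope_threshold: float = field(default=float("nan"))


def extract_kymograph(
    source: SimulationResult | pd.DataFrame,
    species: str | None = None,
    *,
    intensity_column: str = "intensity",
    position_column: str = "x",
    time_column: str = "t",
    n_bins: int | None = None,
    extent: tuple[float, float] | None = None,
    aggregate: Literal["mean", "sum"] = "mean",
) -> Kymograph:
    """Build a kymograph from a simulation or from tracked-nucleus records.

    For a :class:`SimulationResult` the cells already form a 1-D AP row, so
    the kymograph is the (time x cell) slice of ``species`` verbatim. For
    tracked input (a DataFrame with time, AP position and intensity columns)
    intensities are binned by position per frame; bins with no samples are
    NaN, never zero.
    """
    if isinstance(source, SimulationResult):
        if species is None:
            raise ValueError("species is required for simulation input")
        vals = source.get(species)
        edges = np.arange(source.n_cells + 1, dtype=float) - 0.5
        return Kymograph(values=vals.copy(), times=source.times.copy(), bin_edges=edges)

    df = source
    if len(df) == 0:
        raise ValueError("empty tracked input")
    for col in (time_column, position_column, intensity_column):
        if col not in df.columns:
            raise ValueError(f"tracked input lacks column {col!r}")
    x = df[position_column].to_numpy(dtype=float)
    if n_bins is None:
        n_bins = 32
    lo, hi = extent if extent is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    times = np.unique(df[time_column].to_numpy())
    values = np.full((len(times), n_bins), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    binned = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    agg = df.assign(_bin=binned).groupby([time_column, "_bin"])[intensity_column]
    agg = agg.sum() if aggregate == "sum" else agg.mean()
    for (t, b), v in agg.items():
        values[t_index[t], int(b)] = v
    return Kymograph(values=values, times=times, bin_edges=edges)


def _frame_peaks(row: np.ndarray, min_prominence: float):
    """Local maxima of one frame; NaN gaps interpolated only for detection."""
    row = np.asarray(row, dtype=float)
    if np.all(np.isnan(row)):
        return np.empty(0, dtype=int), np.empty(0), np.empty(0)
    if np.any(np.isnan(row)):
        idx = np.arange(len(row))
        good = ~np.isnan(row)
        row = np.interp(idx, idx[good], row[good])
    peaks, props = find_peaks(row, prominence=min_prominence)
    return peaks, row[peaks], props["prominences"]


def detect_wave_peaks(
    kymo: Kymograph, min_prominence: float, max_link_distance: float
) -> list[WaveTrack]:
    """Detect per-frame intensity peaks and link them into wave tracks.

    Peaks in consecutive frames are linked greedily by distance: candidate
    (old peak, new peak) pairs within ``max_link_distance`` are accepted in
    order of increasing distance (ties broken by lower position index), each
    peak used at most once. Unlinked new peaks start new tracks.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    if kymo.values.shape[0] < 2:
        raise ValueError("kymograph needs at least 2 frames")

    centers = kymo.bin_centers
    open_tracks: dict[int, dict] = {}
    done: list[dict] = []
    next_id = 0
    for fi in range(kymo.values.shape[0]):
        pk, amp, prom = _frame_peaks(kymo.values[fi], min_prominence)
        pos = centers[pk]
        prev_ids = list(open_tracks)
        pairs = []
        for tid in prev_ids:
            p_old = open_tracks[tid]["positions"][-1]
            for j, p_new in enumerate(pos):
                d = abs(p_new - p_old)
                if d <= max_link_distance:
                    pairs.append((d, min(p_old, p_new), tid, j))
        pairs.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for d, _, tid, j in pairs:
            if tid in used_t or j in used_p:
                continue
            tr = open_tracks[tid]
            tr["times"].append(kymo.times[fi])
            tr["positions"].append(pos[j])
            tr["amplitudes"].append(amp[j])
            tr["prominences"].append(prom[j])
            used_t.add(tid)
            used_p.add(j)
        for tid in prev_ids:
            if tid not in used_t:
                done.append(open_tracks.pop(tid))
        for j in range(len(pos)):
            if j not in used_p:
                open_tracks[next_id] = {
                    "id": next_id,
                    "times": [kymo.times[fi]],
                    "positions": [pos[j]],
                    "amplitudes": [amp[j]],
                    "prominences": [prom[j]],
                }
                next_id += 1
    done.extend(open_tracks.values())
    done.sort(key=lambda tr: (tr["times"][0], tr["positions"][0]))
    return [
        WaveTrack(
            track_id=i,
            times=tr["times"],
            positions=tr["positions"],
            amplitudes=tr["amplitudes"],
            prominences=tr["prominences"],
        )
        for i, tr in enumerate(done)
    ]


def classify_enhancer_dynamics(
    track: WaveTrack,
    slope_threshold: float | None = None,
    *,
    axis_length: float | None = None,
) -> WaveSummary:
    """Classify one wave track as static-like, dynamic-like or ambiguous.

    The least-squares slope of amplitude versus AP position is the trend
    statistic. Under the anterior = 0 convention, a negative slope means the
    wave gains amplitude as it travels anterior-ward (the static-enhancer
    signature); a positive slope means it fades anterior-ward (the
    dynamic-enhancer signature). ``slope_threshold`` defaults to 5% of the
    track's amplitude range per full axis length (``axis_length`` falls back
    to the track's position span) — slopes smaller than that are ambiguous.
    Direction comes from net position drift over the track.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 records to classify a track")
    drift = track.positions[-1] - track.positions[0]
    pos_span = track.positions.max() - track.positions.min()
    if pos_span == 0:
        return WaveSummary(
            direction="stationary",
            mean_speed=0.0,
            amplitude_slope=float("nan"),
            classification="ambiguous",
        )
    direction = (
        "posterior_to_anterior"
        if drift < 0
        else "anterior_to_posterior"
        if drift > 0
        else "stationary"
    )
    dtime = track.times[-1] - track.times[0]
    mean_speed = abs(drift) / dtime if dtime > 0 else 0.0
    slope = linregress(track.positions, track.amplitudes).slope
    if slope_threshold is None:
        amp_range = track.amplitudes.max() - track.amplitudes.min()
        span = axis_length if axis_length is not None else pos_span
        slope_threshold = 0.05 * amp_range / span if span > 0 else 0.0
    if slope < -slope_threshold:
        cls = "static_like"
    elif slope > slope_threshold:
        cls = "dynamic_like"
    else:
        cls = "ambiguous"
    return WaveSummary(
        direction=direction,
        mean_speed=mean_speed,
        amplitude_slope=float(slope),
        classification=cls,
        slope_threshold=float(slope_threshold),
    )


def count_stripes(frame: Sequence[float], threshold: float) -> int:
    """Number of maximal contiguous runs above ``threshold`` in one frame."""
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    above = frame > threshold
    return int(np.sum(above[1:] & ~above[:-1]) + (1 if above.size and above[0] else 0))


def ap_intensity_profile(
    image: np.ndarray, axis: int = 0, mask: np.ndarray | None = None
) -> np.ndarray:
    """Sum a 2-D image along the dorsal-ventral axis to get an AP profile.

    ``axis`` is the axis summed over (0: rows, i.e. image columns become the
    AP positions). ``mask`` restricts the sum to a region of interest.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
        image = np.where(mask, image, 0.0)
    return image.sum(axis=axis)


def _contained_stripes(frame: np.ndarray, zone: np.ndarray, threshold: float) -> int:
    """Count above-threshold runs of ``frame`` lying entirely inside ``zone``.

    A stripe is a spatially localized expression band; an above-threshold run
    that continues past the zone boundary (e.g. the homogeneous ramp joining
    the posterior domain) is not an anterior stripe.
    """
    above = frame > threshold
    n = len(frame)
    count = 0
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if zone[i : j + 1].all():
                count += 1
            i = j + 1
        else:
            i += 1
    return count


def deletion_phenotype_report(
    intact: SimulationResult,
    deleted: SimulationResult,
    gene: int,
    *,
    anterior_R: float = 0.1,
    posterior_R: float = 0.9,
    stripe_threshold_frac: float = 0.1,
) -> dict:
    """Compare an enhancer-deletion run against the intact circuit.

    Reports, for gene ``gene`` (1-based): the number of stripes at the final
    frame in the anterior zone (cells with R < ``anterior_R``), whether and
    how strongly posterior cells (R > ``posterior_R``) keep oscillating
    through the last quarter of the run, and the ratio of the deleted run's
    maximum activity to the intact run's.
    """
    if gene not in (1, 2, 3):
        raise ValueError("gene must be 1, 2 or 3")
    if intact.n_cells != deleted.n_cells or not np.allclose(
        intact.profile.R, deleted.profile.R
    ):
        raise ValueError("intact and deleted runs must share grid and profile")
    name = f"G{gene}"
    gi = intact.get(name)
    gd = deleted.get(name)
    R = intact.profile.R
    intact_max = float(gi.max())
    deleted_max = float(gd.max())
    stripe_thr = stripe_threshold_frac * intact_max

    ant = R < anterior_R
    post = R > posterior_R
    final = gd[-1]
    anterior_stripes = _contained_stripes(final, ant, stripe_thr)
    q_start = int(0.75 * gd.shape[0])
    osc_counts = []
    if post.any():
        rng = gd.max() - gd.min()
        for c in np.nonzero(post)[0]:
            pk, _ = find_peaks(gd[q_start:, c], prominence=0.05 * rng if rng > 0 else None)
            osc_counts.append(len(pk))
    posterior_osc = int(np.median(osc_counts)) if osc_counts else 0
    return {
        "gene": name,
        "anterior_stripe_count": int(anterior_stripes),
        "posterior_oscillation_maxima": posterior_osc,
        "posterior_oscillation_persists": posterior_osc >= 1,
        "amplitude_ratio": (deleted_max / intact_max) if intact_max > 0 else float("nan"),
        "intact_max": intact_max,
        "deleted_max": deleted_max,
        "stripe_threshold": stripe_thr,
    }
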