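"""Synthetic ground-truth data generators for every pipeline stage.

Each generator is deterministic given (parameters, seed) and returns both
the data object and a machine-readable ground truth sufficient to score the
downstream operations without re-deriving anything:

- embryo-like MS2 movies (nuclei as Gaussian blobs advected by a slow flow,
  at most one transcription punctum per nucleus, intensity following a known
  activity field) for the imaging chain;
- site x sample accessibility matrices with group structure (2 time points x
  3 regions x 3 replicates by default), known differential sites and known
  cluster patterns;
- per-sample peak interval sets with boundary jitter and dropout for
  consensus merging;
- binned coverage tracks with spiked artifact bins for blacklist flagging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .accessibility import AccessibilityMatrix, CoverageTrack, GenomicInterval
from .grn_model import SimulationResult
from .ms2_imaging import MovieStack

__all__ = [
    "TravelingPulse",
    "SimulationActivity",
    "MovieGroundTruth",
    "MatrixGroundTruth",
    "gen_embryo_movie",
    "gen_accessibility_matrix",
    "gen_peak_sets",
    "gen_coverage_tracks",
]


# ---------------------------------------------------------------------------
# Activity sources for the movie generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TravelingPulse:
    """Parametric activity wave: a Gaussian pulse sweeping posterior->anterior.

    Evaluated on normalized coordinates (x in [0, 1] along AP with 0 =
    anterior, t in [0, 1] over the movie). The pulse center moves from
    ``x_start`` to ``x_end``; the local amplitude is linear in x, from
    ``amp_anterior`` at x=0 to ``amp_posterior`` at x=1, so
    ``amp_anterior > amp_posterior`` mimics a static enhancer's wave and the
    converse a dynamic enhancer's.
    """

    amp_anterior: float = 1.0
    amp_posterior: float = 0.3
    width: float = 0.15
    x_start: float = 0.9
    x_end: float = 0.1

    def __call__(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        c = self.x_start + (self.x_end - self.x_start) * t
        amp = self.amp_anterior + (self.amp_posterior - self.amp_anterior) * x
        return amp * np.exp(-((x - c) ** 2) / (2 * self.width**2))


@dataclass(frozen=True)
class SimulationActivity:
    """Activity field read from a simulated trajectory (one species).

    Normalized coordinates map onto the simulation grid (x -> cell index,
    t -> simulation time); values are scaled to a maximum of 1.
    """

    result: SimulationResult
    species: str

    def __call__(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        vals = self.result.get(self.species)
        vmax = vals.max()
        if vmax <= 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        times = self.result.times
        tt = np.asarray(t, dtype=float) * (times[-1] - times[0]) + times[0]
        cc = np.asarray(x, dtype=float) * (self.result.n_cells - 1)
        ti = np.clip(np.searchsorted(times, tt), 0, len(times) - 1)
        c0 = np.clip(np.floor(cc).astype(int), 0, self.result.n_cells - 1)
        c1 = np.clip(c0 + 1, 0, self.result.n_cells - 1)
        w = cc - c0
        return (vals[ti, c0] * (1 - w) + vals[ti, c1] * w) / vmax


# ---------------------------------------------------------------------------
# Embryo movie
# ---------------------------------------------------------------------------

@dataclass
class MovieGroundTruth:
    """Everything needed to score the imaging chain on a synthetic movie."""

    positions: np.ndarray  # (frames, n_nuclei, 2) = (y, x)
    z_positions: np.ndarray  # (n_nuclei,)
    activity: np.ndarray  # (frames, n_nuclei), normalized to [0, 1]
    spot_mask: np.ndarray  # (frames, n_nuclei) bool: punctum present
    spot_offsets: np.ndarray  # (n_nuclei, 3) fixed (z, y, x) offset of the punctum
    spot_peak: float
    nucleus_peak: float
    background: float
    noise_sigma: float
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return self.positions.shape[1]

    def spots_at(self, frame: int) -> np.ndarray:
        """(k, 4) array of true spot (z, y, x, nucleus) at one frame."""
        idx = np.nonzero(self.spot_mask[frame])[0]
        out = np.empty((len(idx), 4))
        for r, n in enumerate(idx):
            out[r, 0] = self.z_positions[n] + self.spot_offsets[n, 0]
            out[r, 1] = self.positions[frame, n, 0] + self.spot_offsets[n, 1]
            out[r, 2] = self.positions[frame, n, 1] + self.spot_offsets[n, 2]
            out[r, 3] = n
        return out

    def save_json(self, path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def gen_embryo_movie(
    activity_source: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    *,
    n_nuclei: int = 50,
    frames: int = 50,
    shape: tuple[int, int, int] = (20, 160, 320),  # (z, y, x)
    drift: tuple[float, float] = (0.05, 0.25),  # (y, x) px/frame affine drift
    walk_sigma: float = 0.15,  # random-walk step (px/frame)
    nucleus_sigma: float = 7.0,
    nucleus_sigma_z: float = 5.0,
    spot_sigma: float = 1.2,
    psf_sigma: float | None = None,
    nucleus_peak: float = 25.0,
    background: float = 10.0,
    snr: float = 8.0,
    spot_floor: float = 0.5,
    spot_on_threshold: float = 0.1,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[MovieStack, MovieGroundTruth]:
    """Render a synthetic MS2 movie with known ground truth.

    Nuclei are Gaussian blobs (weak diffuse nuclear marker) laid out on a
    jittered grid spanning the AP (x) axis and advected by an affine drift
    plus a per-nucleus random walk. A nucleus transcribes when its activity
    (from ``activity_source``, default a static-enhancer-like
    :class:`TravelingPulse`) exceeds ``spot_on_threshold``; it then carries
    exactly one punctum at a fixed sub-nuclear offset. Transcription sites
    are bursty on/off objects, so an "on" punctum never fades to nothing:
    its peak is ``snr * sigma_bg * (spot_floor + (1-spot_floor) * activity)``,
    where ``sigma_bg`` is the total background noise (Gaussian read noise of
    2% of the nucleus peak, plus shot noise when ``poisson_noise``); ``snr``
    is therefore the full-activity punctum peak over the background sigma.
    ``psf_sigma`` optionally blurs the noiseless image.

    The initial layout reserves room for the accumulated drift; nuclei whose
    random walk still reaches the border are clipped with a warning.
    """
    if n_nuclei < 1 or frames < 2:
        raise ValueError("need n_nuclei >= 1 and frames >= 2")
    rng = np.random.default_rng(seed)
    if activity_source is None:
        activity_source = TravelingPulse()
    nz, ny, nx = shape
    margin = 3 * nucleus_sigma

    # jittered grid layout spanning the AP axis, leaving room for the drift
    tot_dy, tot_dx = (frames - 1) * np.asarray(drift)
    x_lo, x_hi = margin - min(0.0, tot_dx), nx - margin - max(0.0, tot_dx)
    y_lo, y_hi = margin - min(0.0, tot_dy), ny - margin - max(0.0, tot_dy)
    n_cols = int(np.ceil(np.sqrt(n_nuclei * (x_hi - x_lo) / max(y_hi - y_lo, 1))))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    gx = np.linspace(x_lo, x_hi, n_cols)
    gy = np.linspace(y_lo, y_hi, n_rows)
    xx, yy = np.meshgrid(gx, gy)
    order = rng.permutation(n_rows * n_cols)[:n_nuclei]
    pos0 = np.stack([yy.ravel()[order], xx.ravel()[order]], axis=1)
    spacing = min(np.diff(gx).min() if n_cols > 1 else nx, np.diff(gy).min() if n_rows > 1 else ny)
    pos0 += rng.uniform(-0.15, 0.15, pos0.shape) * spacing
    z_pos = np.clip(rng.normal(nz / 2, 1.5, n_nuclei), 2, nz - 3)

    # flow: affine drift + random walk, cumulative
    steps = np.asarray(drift) + rng.normal(0.0, walk_sigma, (frames - 1, n_nuclei, 2))
    positions = np.empty((frames, n_nuclei, 2))
    positions[0] = pos0
    positions[1:] = pos0 + np.cumsum(steps, axis=0)
    lo = np.array([margin / 2, margin / 2])
    hi = np.array([ny - margin / 2, nx - margin / 2])
    if np.any(positions < lo) or np.any(positions > hi):
        import warnings

        warnings.warn("flow reaches the field border; nuclei clipped", stacklevel=2)
        positions = np.clip(positions, lo, hi)

    # activity on normalized coordinates (x -> AP, t -> movie progress)
    t_norm = np.repeat(np.linspace(0, 1, frames)[:, None], n_nuclei, axis=1)
    x_norm = positions[:, :, 1] / (nx - 1)
    activity = np.clip(activity_source(x_norm, t_norm), 0.0, None)
    spot_mask = activity > spot_on_threshold

    noise_sigma = 0.02 * nucleus_peak
    sigma_bg = np.sqrt(noise_sigma**2 + (background if poisson_noise else 0.0))
    spot_peak = snr * sigma_bg  # full-activity punctum peak over background
    spot_offsets = np.stack(
        [
            rng.uniform(-1.5, 1.5, n_nuclei),
            rng.uniform(-0.3, 0.3, n_nuclei) * nucleus_sigma,
            rng.uniform(-0.3, 0.3, n_nuclei) * nucleus_sigma,
        ],
        axis=1,
    )

    zg = np.arange(nz, dtype=float)
    movie = np.full((frames, nz, ny, nx), background, dtype=float)
    r_n = int(np.ceil(3 * nucleus_sigma))
    r_s = int(np.ceil(4 * spot_sigma))
    for f in range(frames):
        vol = movie[f]
        for n in range(n_nuclei):
            cy, cx = positions[f, n]
            cz = z_pos[n]
            _add_blob(
                vol, cz, cy, cx, nucleus_sigma_z, nucleus_sigma, nucleus_peak, r_n, zg
            )
            if spot_mask[f, n]:
                sz = cz + spot_offsets[n, 0]
                sy = cy + spot_offsets[n, 1]
                sx = cx + spot_offsets[n, 2]
                amp = spot_peak * (spot_floor + (1.0 - spot_floor) * activity[f, n])
                _add_blob(vol, sz, sy, sx, spot_sigma, spot_sigma, amp, r_s, zg)
    if psf_sigma:
        from scipy.ndimage import gaussian_filter

        for f in range(frames):
            movie[f] = gaussian_filter(movie[f], psf_sigma)
    if poisson_noise:
        movie = rng.poisson(np.clip(movie, 0, None)).astype(float)
    movie = np.clip(movie + rng.normal(0.0, noise_sigma, movie.shape), 0.0, None)

    truth = MovieGroundTruth(
        positions=positions,
        z_positions=z_pos,
        activity=activity,
        spot_mask=spot_mask,
        spot_offsets=spot_offsets,
        spot_peak=spot_peak,
        nucleus_peak=nucleus_peak,
        background=background,
        noise_sigma=noise_sigma,
        seed=seed,
        params={
            "n_nuclei": n_nuclei,
            "frames": frames,
            "shape": list(shape),
            "drift": list(drift),
            "walk_sigma": walk_sigma,
            "snr": snr,
            "spot_floor": spot_floor,
            "spot_sigma": spot_sigma,
            "spot_on_threshold": spot_on_threshold,
        },
    )
    return MovieStack(data=movie), truth


def _add_blob(vol, cz, cy, cx, sz, sxy, peak, radius, zg):
    nzv, nyv, nxv = vol.shape
    y0, y1 = max(0, int(cy - radius)), min(nyv, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(nxv, int(cx + radius) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    ys = np.arange(y0, y1, dtype=float)
    xs = np.arange(x0, x1, dtype=float)
    gy = np.exp(-((ys - cy) ** 2) / (2 * sxy**2))
    gx = np.exp(-((xs - cx) ** 2) / (2 * sxy**2))
    gz = np.exp(-((zg - cz) ** 2) / (2 * sz**2))
    vol[:, y0:y1, x0:x1] += peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


# ---------------------------------------------------------------------------
# Accessibility matrix
# ---------------------------------------------------------------------------

@dataclass
class MatrixGroundTruth:
    """Known structure of a synthetic accessibility matrix."""

    differential: np.ndarray  # (n_sites,) bool
    cluster_labels: np.ndarray  # (n_sites,) int, -1 for non-differential sites
    patterns: np.ndarray  # (n_clusters, n_groups) up/down multipliers (log scale)
    group_names: list[str]
    effect_size: float
    dispersion: float
    seed: int

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "differential": self.differential.tolist(),
                    "cluster_labels": self.cluster_labels.tolist(),
                    "patterns": self.patterns.tolist(),
                    "group_names": self.group_names,
                    "effect_size": self.effect_size,
                    "dispersion": self.dispersion,
                    "seed": self.seed,
                },
                fh,
            )


def gen_accessibility_matrix(
    n_sites: int = 1200,
    *,
    regions: Sequence[str] = ("a", "m", "p"),
    times: Sequence[str] = ("IT23", "IT26"),
    replicates: int = 3,
    frac_differential: float = 0.25,
    effect_size: float = 1.5,
    dispersion: float = 0.3,
    n_clusters: int = 6,
    seed: int = 0,
) -> tuple[AccessibilityMatrix, MatrixGroundTruth]:
    """Log-normal accessibility scores with known differential/cluster structure.

    The design is regions x times x replicates (3 x 2 x 3 = 18 samples by
    default). Each site gets a log-normal baseline; differential sites are
    assigned round-robin to one of ``n_clusters`` accessibility patterns
    (a distinct subset of the 6 region-time groups shifted up by
    ``effect_size`` on the natural-log scale). Replicate noise is
    log-normal with sigma ``dispersion``. Sites are laid out as
    non-overlapping 500 bp intervals on one scaffold.
    """
    if not 0.0 <= frac_differential <= 1.0:
        raise ValueError("frac_differential must lie in [0, 1]")
    if replicates < 1 or not regions or not times:
        raise ValueError("invalid design")
    rng = np.random.default_rng(seed)
    groups = [(r, t) for t in times for r in regions]
    n_groups = len(groups)
    if n_clusters > 2**n_groups - 2:
        raise ValueError("too many clusters for this design")
    n_samples = n_groups * replicates
    samples = pd.DataFrame(
        [
            {"region": r, "time": t, "replicate": k + 1}
            for (r, t) in groups
            for k in range(replicates)
        ]
    )
    n_diff = int(round(frac_differential * n_sites))
    differential = np.zeros(n_sites, dtype=bool)
    diff_idx = rng.choice(n_sites, size=n_diff, replace=False)
    differential[diff_idx] = True

    # distinct up-group patterns, one per cluster (never all-up / all-down)
    pattern_pool = [p for p in range(1, 2**n_groups - 1)]
    chosen = rng.choice(len(pattern_pool), size=n_clusters, replace=False)
    patterns = np.zeros((n_clusters, n_groups))
    for ci, pi in enumerate(chosen):
        bits = pattern_pool[pi]
        patterns[ci] = [(bits >> g) & 1 for g in range(n_groups)]

    cluster_labels = np.full(n_sites, -1)
    cluster_labels[diff_idx] = np.arange(n_diff) % n_clusters

    log_base = rng.normal(3.0, 1.0, n_sites)
    log_mu = np.repeat(log_base[:, None], n_samples, axis=1)
    group_of_sample = np.repeat(np.arange(n_groups), replicates)
    for si in diff_idx:
        log_mu[si] += effect_size * patterns[cluster_labels[si]][group_of_sample]
    scores = np.exp(log_mu + rng.normal(0.0, dispersion, (n_sites, n_samples)))

    sites = [GenomicInterval("LG1", 1000 * i, 1000 * i + 500, f"site_{i}") for i in range(n_sites)]
    matrix = AccessibilityMatrix(
        sites=sites, scores=scores, samples=samples, differential=differential
    )
    truth = MatrixGroundTruth(
        differential=differential,
        cluster_labels=cluster_labels,
        patterns=patterns,
        group_names=[f"{r}_{t}" for (r, t) in groups],
        effect_size=effect_size,
        dispersion=dispersion,
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Peak sets and coverage tracks
# ---------------------------------------------------------------------------

def gen_peak_sets(
    n_samples: int = 5,
    n_true_regions: int = 100,
    *,
    region_length: int = 400,
    spacing: int = 2000,
    jitter: int = 50,
    dropout: float = 0.2,
    chrom: str = "LG1",
    seed: int = 0,
) -> tuple[list[list[GenomicInterval]], dict]:
    """Per-sample peak calls around known true regions.

    Each true region is emitted in each sample with uniform boundary jitter
    (up to ``jitter`` bp per edge) unless dropped out (probability
    ``dropout``). Regions are spaced so jitter can never merge neighbors.
    The truth records, per region, which samples retained it and whether it
    has the >= 2-sample support required for consensus.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    if spacing <= region_length + 4 * jitter:
        raise ValueError("spacing too small: jittered neighbors could merge")
    rng = np.random.default_rng(seed)
    starts = spacing * np.arange(n_true_regions) + spacing // 2
    kept = rng.random((n_true_regions, n_samples)) >= dropout
    per_sample: list[list[GenomicInterval]] = [[] for _ in range(n_samples)]
    for ri, s0 in enumerate(starts):
        for si in range(n_samples):
            if not kept[ri, si]:
                continue
            a = int(s0 + rng.integers(-jitter, jitter + 1))
            b = int(s0 + region_length + rng.integers(-jitter, jitter + 1))
            per_sample[si].append(GenomicInterval(chrom, a, max(b, a + 1), f"r{ri}_s{si}"))
    support = kept.sum(axis=1)
    truth = {
        "starts": starts.tolist(),
        "region_length": region_length,
        "kept": kept.tolist(),
        "support": support.tolist(),
        "consensus_regions": [int(i) for i in np.nonzero(support >= 2)[0]],
        "seed": seed,
    }
    return per_sample, truth


def gen_coverage_tracks(
    n_libraries: int = 3,
    chrom_length: int = 100_000,
    *,
    bin_size: int = 50,
    spike_positions: Sequence[int] = (),
    spike_height: float = 200.0,
    background_mean: float = 1.0,
    background_noise: float = 0.0,
    chrom: str = "LG1",
    seed: int = 0,
) -> tuple[list[CoverageTrack], dict]:
    """Binned coverage tracks with artifact spikes at known bins.

    ``spike_positions`` are bin indices receiving ``spike_height`` in every
    library (on top of background). The truth lists the bins whose expected
    cross-library mean is >= 100, the blacklist rule's threshold.
    """
    n_bins = chrom_length // bin_size
    spikes = np.asarray(spike_positions, dtype=int)
    if np.any(spikes < 0) or np.any(spikes >= n_bins):
        raise ValueError("spike positions fall outside the chromosome")
    if spike_height <= background_mean:
        raise ValueError("spike_height must exceed the background")
    rng = np.random.default_rng(seed)
    tracks = []
    for li in range(n_libraries):
        vals = np.full(n_bins, background_mean)
        if background_noise > 0:
            vals = np.clip(vals + rng.normal(0.0, background_noise, n_bins), 0.0, None)
        vals[spikes] += spike_height
        tracks.append(CoverageTrack(values={chrom: vals}, bin_size=bin_size, library_id=f"lib{li}"))
    expected_mean = background_mean + spike_height
    truth = {
        "spiked_bins": sorted(int(b) for b in spikes),
        "expected_flagged": sorted(int(b) for b in spikes) if expected_mean >= 100 else [],
        "n_bins": n_bins,
        "seed": seed,
    }
    return tracks, truth
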