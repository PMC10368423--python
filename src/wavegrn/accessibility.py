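"""Chromatin-accessibility interval and score post-processing.

Post-processing rules for ATAC-seq-style data downstream of peak calling:
consensus-peak merging across samples, artifact ("blacklist") bin flagging
from binned coverage, selection of the most variable accessible sites,
k-means clustering of z-scored accessibility, the fractional site-overlap
predicate between enhancer-reporter constructs and accessible sites, and the
construct-activity x differential-accessibility association table.

All coordinates are BED-convention 0-based half-open. Differential flags are
inputs here (produced upstream by count-based tests, or by the synthetic
generator); no statistical testing is performed in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "AccessibilityMatrix",
    "AssociationTable",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "merge_consensus_peaks",
    "flag_blacklist_bins",
    "select_most_variable",
    "zscore_cluster",
    "construct_site_overlap",
    "association_analysis",
]


@dataclass(frozen=True)
class GenomicInterval:
    """BED-style 0-based half-open interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    metadata: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"need 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CoverageTrack:
    """Uniformly binned per-chromosome coverage for one library.

    ``values[chrom][i]`` is the signal of bin ``[i*bin_size, (i+1)*bin_size)``.
    """

    values: dict[str, np.ndarray]
    bin_size: int
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if np.any(v < 0):
                raise ValueError(f"negative coverage on {c}")


@dataclass
class AccessibilityMatrix:
    """Site x sample accessibility-score matrix with sample annotations.

    ``samples`` annotates each column with region (e.g. a/m/p), time point
    and replicate. Optional per-site ``differential`` flags mark sites called
    differentially accessible upstream.
    """

    sites: list[GenomicInterval]
    scores: np.ndarray
    samples: pd.DataFrame
    differential: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sites), len(self.samples)):
            raise ValueError("scores must be (n_sites x n_samples)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        required = {"region", "time", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample annotations must include {sorted(required)}")
        if self.differential is not None:
            self.differential = np.asarray(self.differential, dtype=bool)
            if self.differential.shape != (len(self.sites),):
                raise ValueError("differential flags must be per-site")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.scores,
            index=[f"{s.chrom}:{s.start}-{s.end}" for s in self.sites],
            columns=[
                f"{r.region}_{r.time}_rep{r.replicate}" for r in self.samples.itertuples()
            ],
        )
        if self.differential is not None:
            df["differential"] = self.differential
        df.to_csv(path)


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

def read_bed(path, sample_id: str | None = None) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else "."
            meta = (("sample", sample_id),) if sample_id is not None else ()
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name, meta)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bedgraph(path, bin_size: int, library_id: str = "") -> CoverageTrack:
    """Read a bedGraph whose records are aligned to ``bin_size`` bins."""
    values: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, val = line.split("\t")[:4]
            start, end = int(start), int(end)
            if start % bin_size or (end - start) != bin_size:
                raise ValueError(f"record [{start},{end}) not aligned to {bin_size} bp bins")
            values.setdefault(chrom, {})[start // bin_size] = float(val)
    dense = {}
    for chrom, bins in values.items():
        arr = np.zeros(max(bins) + 1)
        for b, v in bins.items():
            arr[b] = v
        dense[chrom] = arr
    return CoverageTrack(values=dense, bin_size=bin_size, library_id=library_id)


# ---------------------------------------------------------------------------
# Interval rules
# ---------------------------------------------------------------------------

def merge_consensus_peaks(
    per_sample_peaks: Sequence[Sequence[GenomicInterval]], min_support: int = 2
) -> list[GenomicInterval]:
    """Merge per-sample peak sets into supported consensus peaks.

    Peaks overlapping by at least 1 bp are merged transitively into their
    union span. A merged peak is kept only if its contributing peaks were
    called in at least ``min_support`` distinct samples.
    """
    tagged: list[tuple[GenomicInterval, int]] = []
    for si, peaks in enumerate(per_sample_peaks):
        for p in peaks:
            if not isinstance(p, GenomicInterval):
                raise TypeError("peaks must be GenomicInterval instances")
            tagged.append((p, si))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    merged: list[GenomicInterval] = []
    cur: list[int] | None = None
    cur_chrom = ""
    cur_samples: set[int] = set()

    def flush() -> None:
        if cur is not None and len(cur_samples) >= min_support:
            merged.append(GenomicInterval(cur_chrom, cur[0], cur[1]))

    for p, si in tagged:
        if cur is not None and p.chrom == cur_chrom and p.start < cur[1]:
            cur[1] = max(cur[1], p.end)
            cur_samples.add(si)
        else:
            flush()
            cur = [p.start, p.end]
            cur_chrom = p.chrom
            cur_samples = {si}
    flush()
    return merged


def flag_blacklist_bins(
    tracks: Sequence[CoverageTrack], threshold: float = 100.0
) -> list[GenomicInterval]:
    """Flag genome bins whose cross-library mean signal is >= ``threshold``.

    Adjacent flagged bins are merged into one blacklist interval. All tracks
    must share bin size; shorter chromosomes are zero-padded to the longest.
    """
    if not tracks:
        raise ValueError("need at least one coverage track")
    bin_size = tracks[0].bin_size
    if any(t.bin_size != bin_size for t in tracks):
        raise ValueError("all tracks must share the same bin size")
    chroms = sorted({c for t in tracks for c in t.values})
    out: list[GenomicInterval] = []
    for chrom in chroms:
        n = max(len(t.values.get(chrom, ())) for t in tracks)
        acc = np.zeros(n)
        for t in tracks:
            v = t.values.get(chrom)
            if v is not None:
                acc[: len(v)] += v
        mean = acc / len(tracks)
        flagged = mean >= threshold
        i = 0
        while i < n:
            if flagged[i]:
                j = i
                while j + 1 < n and flagged[j + 1]:
                    j += 1
                out.append(GenomicInterval(chrom, i * bin_size, (j + 1) * bin_size))
                i = j + 1
            else:
                i += 1
    return out


# ---------------------------------------------------------------------------
# Score-matrix rules
# ---------------------------------------------------------------------------

def select_most_variable(matrix: AccessibilityMatrix) -> np.ndarray:
    """Boolean mask of the "most variable accessible sites".

    A site qualifies if its mean accessibility score exceeds the median of
    all site means AND its standard deviation exceeds the 3rd quartile of
    all site standard deviations. Quantiles use linear interpolation between
    order statistics; standard deviations are sample SDs (ddof=1).
    """
    if matrix.n_sites < 4:
        raise ValueError("need at least 4 sites for quartile computation")
    if matrix.scores.shape[1] < 2:
        raise ValueError("standard deviation undefined with fewer than 2 samples")
    means = matrix.scores.mean(axis=1)
    sds = matrix.scores.std(axis=1, ddof=1)
    return (means > np.median(means)) & (sds > np.quantile(sds, 0.75))


def zscore_cluster(
    matrix: AccessibilityMatrix,
    k: int = 6,
    restarts: int = 1000,
    seed: int | None = None,
    site_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster sites on per-site z-scored accessibility with k-means.

    Each site's scores are z-scored across samples, then k-means is run with
    ``restarts`` random initializations, keeping the solution with the best
    (lowest) within-cluster sum of squares. Deterministic given ``seed``.
    Raises on any zero-variance site, naming it.
    """
    z = _zscore_rows(matrix.scores if site_mask is None else matrix.scores[site_mask])
    if k > z.shape[0]:
        raise ValueError("k cannot exceed the number of sites")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(z)


def kmeans_inertia(
    matrix: AccessibilityMatrix, k: int, restarts: int, seed: int | None = None
) -> float:
    """Best within-cluster sum of squares over ``restarts`` initializations."""
    from sklearn.cluster import KMeans

    z = _zscore_rows(matrix.scores)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(z)
    return float(km.inertia_)


def _zscore_rows(scores: np.ndarray) -> np.ndarray:
    sds = scores.std(axis=1, ddof=0)
    bad = np.nonzero(sds == 0)[0]
    if len(bad):
        raise ValueError(f"zero-variance site at row {bad[0]}; cannot z-score")
    return (scores - scores.mean(axis=1, keepdims=True)) / sds[:, None]


# ---------------------------------------------------------------------------
# Construct-site association
# ---------------------------------------------------------------------------

def construct_site_overlap(
    construct: GenomicInterval, site: GenomicInterval, min_site_fraction: float = 0.9
) -> bool:
    """True iff at least ``min_site_fraction`` of the *site* lies in the construct.

    The rule is asymmetric: the fraction is of the site's length, so a small
    site inside a large construct overlaps, while the converse need not.
    """
    return construct.overlap_bp(site) >= min_site_fraction * len(site)


@dataclass
class AssociationTable:
    """2x2 construct-activity x differential-accessibility association.

    Counts partition the constructs; percentages are rounded to 1 decimal.
    ``no_site_constructs`` lists constructs overlapping no site at all (they
    are counted in the non-differential class).
    """

    active_differential: int
    active_nondifferential: int
    inactive_differential: int
    inactive_nondifferential: int
    no_site_constructs: list[str] = field(default_factory=list)
    fisher_p: float | None = None

    @property
    def n_constructs(self) -> int:
        return (
            self.active_differential
            + self.active_nondifferential
            + self.inactive_differential
            + self.inactive_nondifferential
        )

    @property
    def percentages(self) -> dict[str, float]:
        n = self.n_constructs
        n_act = self.active_differential + self.active_nondifferential
        n_inact = n - n_act
        n_diff = self.active_differential + self.inactive_differential
        n_nondiff = n - n_diff

        def pct(num: int, den: int) -> float:
            return round(100.0 * num / den, 1) if den else float("nan")

        return {
            "active": pct(n_act, n),
            "inactive": pct(n_inact, n),
            "active_overlapping_differential": pct(self.active_differential, n_act),
            "inactive_overlapping_differential": pct(self.inactive_differential, n_inact),
            "differential_overlapping_active": pct(self.active_differential, n_diff),
            "nondifferential_overlapping_active": pct(self.active_nondifferential, n_nondiff),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "differential": [self.active_differential, self.inactive_differential],
                "non_differential": [
                    self.active_nondifferential,
                    self.inactive_nondifferential,
                ],
            },
            index=["active", "inactive"],
        )


def association_analysis(
    constructs: Sequence[tuple[GenomicInterval, bool]],
    sites: Sequence[tuple[GenomicInterval, bool]],
    *,
    min_site_fraction: float = 0.9,
    fisher: bool = False,
) -> AssociationTable:
    """Associate enhancer-construct activity with differential accessibility.

    Each construct is an (interval, active) pair; each site an (interval,
    differential) pair. A construct counts as "overlapping differential" iff
    the fractional-overlap rule holds for at least one differential site
    (mixed-flag overlaps resolve to the differential class). Constructs
    overlapping no site at all fall in the non-differential class and are
    listed in ``no_site_constructs``.
    """
    if not constructs:
        raise ValueError("need at least one construct")
    counts = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    orphans: list[str] = []
    for construct, active in constructs:
        hits = [
            diff
            for site, diff in sites
            if construct_site_overlap(construct, site, min_site_fraction)
        ]
        if not hits:
            orphans.append(
                construct.name
                if construct.name != "."
                else f"{construct.chrom}:{construct.start}-{construct.end}"
            )
        counts[(bool(active), any(hits))] += 1
    p = None
    if fisher:
        from scipy.stats import fisher_exact

        table = [
            [counts[(True, True)], counts[(True, False)]],
            [counts[(False, True)], counts[(False, False)]],
        ]
        p = float(fisher_exact(table)[1])
    return AssociationTable(
        active_differential=counts[(True, True)],
        active_nondifferential=counts[(True, False)],
        inactive_differential=counts[(False, True)],
        inactive_nondifferential=counts[(False, False)],
        no_site_constructs=orphans,
        fisher_p=p,
    )
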