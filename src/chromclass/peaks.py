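"""Peak detection, cross-sample matching, and feature-matrix assembly.

Peaks are strict local maxima of the baseline-corrected trace exceeding the
mu + 3*sigma noise threshold.  Apex retention times are then matched across
all traces of a study into a consistent registry, and the logged apex heights
become the samples x peaks feature matrix fed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .chromatogram import Chromatogram
from .preprocess import NoiseStats


@dataclass(frozen=True)
class DetectedPeak:
    """One above-threshold local maximum of a corrected trace."""

    rt_apex: float  # minutes
    height: float  # corrected (logged) intensity at the apex
    prominence: float = 0.0


@dataclass
class PeakRegistry:
    """Consistent peaks across a study.

    ``table`` has one row per registry peak: ``peak_id`` (1..P),
    ``consensus_rt`` (median apex RT, minutes, strictly increasing),
    ``rt_tolerance`` and ``presence_fraction``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        rts = self.table["consensus_rt"].to_numpy()
        if len(rts) > 1 and not np.all(np.diff(rts) > 0):
            raise ValueError("registry consensus RTs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def consensus_rts(self) -> np.ndarray:
        return self.table["consensus_rt"].to_numpy()

    @property
    def column_names(self) -> list[str]:
        return [f"peak_{int(i):02d}" for i in self.table["peak_id"]]


@dataclass
class FeatureMatrix:
    """Samples-by-peaks matrix of logged peak heights.

    ``values``: rows aligned with ``meta`` (one row per trace), columns are
    registry peaks.  ``imputed`` flags entries filled with the trace's
    detection floor because no detection matched the registry peak.
    """

    values: pd.DataFrame
    meta: pd.DataFrame  # sample_id, replicate_id, class_label
    imputed: pd.DataFrame
    registry: PeakRegistry | None = None

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta must have the same number of rows")
        if self.values.isna().any().any():
            raise ValueError("feature matrix may not contain missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.values.reset_index(drop=True)],
            axis=1,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = ["sample_id", "replicate_id", "class_label"]
        peak_cols = [c for c in df.columns if c.startswith("peak_")]
        values = df[peak_cols]
        return cls(
            values=values,
            meta=df[meta_cols],
            imputed=pd.DataFrame(False, index=values.index, columns=peak_cols),
        )


def detect_peaks(c: Chromatogram, stats: NoiseStats) -> list[DetectedPeak]:
    """All strict local maxima above the noise threshold, sorted by RT.

    Plateau maxima take the leftmost point of the plateau as apex.  The apex
    height is the corrected intensity at the maximum.
    """
    if c.stage_tag != "baseline_corrected":
        raise ValueError("peak detection expects a baseline-corrected trace")
    y = c.intensity
    idx, props = find_peaks(y, height=stats.threshold, plateau_size=1)
    apex = np.where(props["plateau_sizes"] > 1, props["left_edges"], idx)
    prominences = peak_prominences(y, idx)[0]
    return [
        DetectedPeak(rt_apex=float(c.rt[a]), height=float(y[a]), prominence=float(p))
        for a, p in zip(apex, prominences)
    ]


def match_peaks(
    all_detections: list[list[DetectedPeak]],
    rt_tol: float = 0.1,
    presence_threshold: float = 1.0,
) -> PeakRegistry:
    """Cluster apex RTs across traces into a consistent registry.

    Greedy support-weighted matching: repeatedly locate the RT window of
    half-width ``rt_tol`` containing apexes from the most traces, assign each
    trace's closest apex inside the window to a new cluster, remove those
    apexes, and continue while any window still reaches the presence
    requirement.  Clusters present in at least ``presence_threshold`` of the
    traces are kept; their consensus RT is the median member apex RT.

    Counting window support per *trace* (not per apex) makes the matcher
    robust to the occasional spurious noise apex that survives the
    mu + 3*sigma threshold.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    if not 0 < presence_threshold <= 1:
        raise ValueError("presence_threshold must be in (0, 1]")
    n_traces = len(all_detections)
    if n_traces < 1:
        raise ValueError("need at least one trace")

    rts = []
    trace_ids = []
    for i, dets in enumerate(all_detections):
        for d in dets:
            rts.append(d.rt_apex)
            trace_ids.append(i)
    rts = np.asarray(rts, dtype=float)
    trace_ids = np.asarray(trace_ids, dtype=int)
    order = np.argsort(rts, kind="stable")
    rts, trace_ids = rts[order], trace_ids[order]

    required = presence_threshold * n_traces - 1e-9
    alive = np.ones(rts.size, dtype=bool)
    clusters: list[tuple[float, int]] = []  # (consensus_rt, n_member_traces)

    while alive.any():
        r = rts[alive]
        t = trace_ids[alive]
        # distinct-trace support of the window centered at each alive apex
        lo = np.searchsorted(r, r - rt_tol, side="left")
        hi = np.searchsorted(r, r + rt_tol, side="right")
        support = np.array(
            [np.unique(t[a:b]).size for a, b in zip(lo, hi)], dtype=int
        )
        best = int(np.argmax(support))  # ties: lowest RT (sorted order)
        if support[best] < max(required, 1.0):
            break
        center = r[best]
        in_win = np.flatnonzero(np.abs(r - center) <= rt_tol)
        # one member per trace: the apex closest to the window center
        members: dict[int, int] = {}
        for j in in_win:
            tid = t[j]
            if tid not in members or abs(r[j] - center) < abs(r[members[tid]] - center):
                members[tid] = j
        member_local = np.fromiter(members.values(), dtype=int)
        consensus = float(np.median(r[member_local]))
        clusters.append((consensus, len(members)))
        alive_idx = np.flatnonzero(alive)
        alive[alive_idx[member_local]] = False

    kept = [
        (rt, n) for rt, n in clusters if n >= presence_threshold * n_traces - 1e-9
    ]
    kept.sort(key=lambda x: x[0])
    table = pd.DataFrame(
        {
            "peak_id": np.arange(1, len(kept) + 1),
            "consensus_rt": [rt for rt, _ in kept],
            "rt_tolerance": rt_tol,
            "presence_fraction": [n / n_traces for _, n in kept],
        }
    )
    return PeakRegistry(table=table)


def build_feature_matrix(
    all_detections: list[list[DetectedPeak]],
    thresholds: list[float],
    manifest: pd.DataFrame,
    registry: PeakRegistry,
) -> FeatureMatrix:
    """Assemble the traces x registry-peaks matrix of logged apex heights.

    For each trace and registry peak, the matched detection is the apex
    closest to the consensus RT within the registry tolerance; a trace with
    no match gets its own detection threshold (the detection floor) and an
    imputation flag.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if not (len(all_detections) == len(thresholds) == len(manifest)):
        raise ValueError("detections, thresholds, and manifest must align")
    cols = registry.column_names
    consensus = registry.consensus_rts
    tol = registry.table["rt_tolerance"].to_numpy()
    values = np.empty((len(all_detections), len(registry)))
    imputed = np.zeros_like(values, dtype=bool)
    for i, (dets, floor) in enumerate(zip(all_detections, thresholds)):
        det_rts = np.array([d.rt_apex for d in dets])
        for j, (c_rt, c_tol) in enumerate(zip(consensus, tol)):
            if det_rts.size:
                k = int(np.argmin(np.abs(det_rts - c_rt)))
                if abs(det_rts[k] - c_rt) <= c_tol:
                    values[i, j] = dets[k].height
                    continue
            values[i, j] = floor
            imputed[i, j] = True
    meta = manifest[["sample_id", "replicate_id", "class_label"]].reset_index(drop=True)
    return FeatureMatrix(
        values=pd.DataFrame(values, columns=cols),
        meta=meta,
        imputed=pd.DataFrame(imputed, columns=cols),
        registry=registry,
    )
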