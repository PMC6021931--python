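"""Synthetic HS-GC-MS study generator.

Emulates the statistical structure of a four-stage fruit-ripening essential-oil
study: 101 oils in classes of 11/27/36/27, each injected in triplicate, giving
303 total ion chromatograms.  Each trace carries 22 Gaussian peaks on a smooth
drifting baseline with additive Gaussian noise; one limonene-like peak towers
orders of magnitude over the rest, and per-compound class trajectories may be
increasing, decreasing, U-shaped, or flat across the four ripening stages —
mirroring the known non-monotone evolution of citrus volatiles (for example
β-pinene dips before rising again while myrcene rises then falls).

All intensities are in arbitrary units; peak heights are parameterized on the
log10 scale, where between-class differences, between-oil scatter, and
replicate scatter are additive effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatogram import Chromatogram, read_trace, write_trace

TRAJECTORY_KINDS = ("increasing", "decreasing", "u_shaped", "flat")

# Unit class-trajectory patterns over the four ripening stages; scaled by a
# per-study amplitude and the design's separability knob.
_TRAJECTORY_PATTERNS = {
    "increasing": np.array([-1.0, -1.0 / 3.0, 1.0 / 3.0, 1.0]),
    "decreasing": np.array([1.0, 1.0 / 3.0, -1.0 / 3.0, -1.0]),
    "u_shaped": np.array([1.0, -1.0, -1.0, 1.0]),
    "flat": np.zeros(4),
}

#: Log10 amplitude of the between-class trajectory at separability 1.
CLASS_EFFECT_AMPLITUDE = 0.25


@dataclass(frozen=True)
class PeakSpec:
    """Ground truth for one chromatographic peak.

    ``class_log_heights`` holds the mean log10 apex height per ripening class
    (before oil/replicate effects and the separability scaling).
    """

    peak_id: int
    retention_time: float  # minutes
    width: float  # Gaussian sigma, minutes
    class_log_heights: tuple[float, float, float, float]
    trajectory_kind: str = "flat"

    def __post_init__(self) -> None:
        if self.retention_time <= 0 or self.width <= 0:
            raise ValueError("retention_time and width must be positive")
        if len(self.class_log_heights) != 4 or not np.all(
            np.isfinite(self.class_log_heights)
        ):
            raise ValueError("class_log_heights must be 4 finite values")
        if self.trajectory_kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory_kind {self.trajectory_kind!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Size, noise, and scale parameters of a simulated study.

    Defaults reproduce the reference design: 101 oils in classes of
    11/27/36/27 measured in triplicate (303 traces) on a uniform RT grid of
    two points per second over 0.5–28 min.
    """

    class_sizes: tuple[int, ...] = (11, 27, 36, 27)
    replicates_per_sample: int = 3
    noise_sd: float = 2.0  # additive, raw intensity units
    baseline_amplitude: float = 30.0  # raw intensity units
    replicate_log_sd: float = 0.05  # within-oil replicate scatter (log10)
    eo_log_sd: float = 0.15  # between-oil scatter (log10)
    measurement_log_sd: float = 0.02  # per-peak height jitter (log10)
    separability: float = 1.0  # multiplier on between-class log differences
    rt_start: float = 0.5  # minutes
    rt_stop: float = 28.0  # minutes
    points_per_min: int = 120  # two scans per second
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.class_sizes):
            raise ValueError("invalid design: class sizes must be positive")
        if self.replicates_per_sample <= 0:
            raise ValueError("invalid design: replicates_per_sample must be positive")
        if self.noise_sd <= 0:
            raise ValueError("invalid design: noise_sd must be positive")
        if self.baseline_amplitude < 0:
            raise ValueError("invalid design: baseline_amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))

    @property
    def n_traces(self) -> int:
        return self.n_samples * self.replicates_per_sample

    def rt_grid(self) -> np.ndarray:
        n = int(round((self.rt_stop - self.rt_start) * self.points_per_min)) + 1
        return self.rt_start + np.arange(n) / self.points_per_min


# Retention times (minutes) of the 22 consistently detected peaks of the
# reference bitter-orange profile; peak 9 (10.45 min) is the limonene-like
# dominant peak.
REFERENCE_RETENTION_TIMES = (
    1.99, 5.17, 6.95, 8.27, 8.41, 8.83, 9.43, 9.92, 10.45, 11.30, 11.82,
    12.48, 13.28, 13.80, 15.64, 16.83, 18.16, 19.01, 21.66, 23.40, 25.70,
    26.07,
)

_LIMONENE_LIKE_ID = 9

# Base log10 heights (class-averaged); values span one decade so minor peaks
# exercise the detection threshold while staying well above it.
_BASE_LOG_HEIGHTS = (
    3.2, 2.7, 3.4, 3.1, 3.1, 3.3, 2.6, 2.8, 5.8, 3.0, 3.2,
    2.7, 2.9, 3.5, 2.6, 2.8, 3.0, 3.3, 3.1, 2.9, 2.6, 2.7,
)

# Peaks with no class trajectory (limonene-like included: in the reference
# study the dominant peak carried little ripening information).
_FLAT_IDS = frozenset({2, 5, 9, 12, 16, 21, 22})


def _default_kind(peak_id: int) -> str:
    if peak_id in _FLAT_IDS:
        return "flat"
    informative = [i for i in range(1, 23) if i not in _FLAT_IDS]
    cycle = ("increasing", "decreasing", "u_shaped")
    return cycle[informative.index(peak_id) % 3]


def default_peak_specs() -> list[PeakSpec]:
    """The 22-peak ground-truth registry of the default synthetic study.

    Widths grow slowly with retention time (0.05–0.14 min sigma) except for
    the closely eluting 8.27/8.41 min pair, which is kept narrow so both
    remain resolvable; 15 peaks carry a class trajectory and 7 (including the
    limonene-like giant) are flat.
    """
    specs = []
    for i, rt in enumerate(REFERENCE_RETENTION_TIMES, start=1):
        width = min(0.05 + 0.0035 * rt, 0.11)
        if i in (4, 5):  # closely eluting pair, keep resolvable
            width = 0.04
        kind = _default_kind(i)
        base = _BASE_LOG_HEIGHTS[i - 1]
        offsets = CLASS_EFFECT_AMPLITUDE * _TRAJECTORY_PATTERNS[kind]
        specs.append(
            PeakSpec(
                peak_id=i,
                retention_time=rt,
                width=width,
                class_log_heights=tuple(base + offsets),
                trajectory_kind=kind,
            )
        )
    return specs


def adjusted_class_log_heights(spec: PeakSpec, separability: float) -> np.ndarray:
    """Class log-heights with between-class differences scaled by ``separability``."""
    vals = np.asarray(spec.class_log_heights, dtype=float)
    return vals.mean() + separability * (vals - vals.mean())


def gaussian_signal(
    t: np.ndarray, centers, heights, widths
) -> np.ndarray:
    """Sum of Gaussian peaks evaluated on grid ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c, h, w in zip(np.atleast_1d(centers), np.atleast_1d(heights), np.atleast_1d(widths)):
        out += h * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def baseline_profile(t: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Smooth, strictly positive instrument baseline: linear drift plus one
    broad cosine, scaled by ``design.baseline_amplitude``."""
    x = (np.asarray(t, float) - design.rt_start) / (design.rt_stop - design.rt_start)
    return design.baseline_amplitude * (1.0 + 0.5 * x + 0.3 * np.cos(np.pi * x))


def simulate_chromatogram(
    specs: list[PeakSpec],
    class_index: int,
    eo_effect: float,
    replicate_effect: float,
    design: StudyDesign,
    rng: np.random.Generator,
) -> Chromatogram:
    """Render one raw trace for a sample of class ``class_index`` (1..4).

    Peak apex heights are ``10**(class_log_height + eo_effect +
    replicate_effect)``; the oil and replicate effects are global (they model
    extraction-yield and injection-volume variation, so they shift every peak
    of the trace by the same log amount).
    """
    if not 1 <= class_index <= 4:
        raise ValueError("class_index must be in 1..4")
    t = design.rt_grid()
    centers = [s.retention_time for s in specs]
    widths = [s.width for s in specs]
    heights = [
        10.0
        ** (
            adjusted_class_log_heights(s, design.separability)[class_index - 1]
            + eo_effect
            + replicate_effect
        )
        for s in specs
    ]
    intensity = (
        baseline_profile(t, design)
        + gaussian_signal(t, centers, heights, widths)
        + rng.normal(0.0, design.noise_sd, size=t.size)
    )
    return Chromatogram(rt=t, intensity=intensity, class_label=class_index)


def _sample_table(design: StudyDesign) -> pd.DataFrame:
    rows = []
    k = 0
    for cls, n in enumerate(design.class_sizes, start=1):
        for _ in range(n):
            k += 1
            rows.append({"sample_id": f"S{k:03d}", "class_label": cls})
    return pd.DataFrame(rows)


def simulate_study(
    specs: list[PeakSpec], design: StudyDesign, seed: int | None = None
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Simulate a full study: one trace per replicate of every oil.

    Returns the traces and a manifest with columns ``sample_id``,
    ``replicate_id``, ``class_label`` (one row per trace, aligned with the
    trace list).  The per-oil effect is shared by all replicates of an oil.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = _sample_table(design)
    traces: list[Chromatogram] = []
    manifest_rows = []
    for _, row in samples.iterrows():
        eo_effect = rng.normal(0.0, design.eo_log_sd)
        for rep in range(1, design.replicates_per_sample + 1):
            rep_effect = rng.normal(0.0, design.replicate_log_sd)
            c = simulate_chromatogram(
                specs, int(row.class_label), eo_effect, rep_effect, design, rng
            )
            c.sample_id = row.sample_id
            c.replicate_id = rep
            traces.append(c)
            manifest_rows.append(
                {
                    "sample_id": row.sample_id,
                    "replicate_id": rep,
                    "class_label": int(row.class_label),
                }
            )
    return traces, pd.DataFrame(manifest_rows)


def simulate_log_heights(
    specs: list[PeakSpec], design: StudyDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the post-detection feature matrix directly.

    Draws the same statistical model as :func:`simulate_study` — class
    trajectory + per-oil + per-replicate log effects — plus a small per-peak
    measurement jitter, but skips chromatogram rendering and peak picking.
    Used for classifier calibration studies where the chromatographic layer
    is not under test.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    samples = _sample_table(design)
    cls_heights = np.stack(
        [adjusted_class_log_heights(s, design.separability) for s in specs]
    )  # (P, 4)
    rows, manifest_rows = [], []
    for _, row in samples.iterrows():
        eo_effect = rng.normal(0.0, design.eo_log_sd)
        base = cls_heights[:, int(row.class_label) - 1]
        for rep in range(1, design.replicates_per_sample + 1):
            rep_effect = rng.normal(0.0, design.replicate_log_sd)
            jitter = rng.normal(0.0, design.measurement_log_sd, size=len(specs))
            rows.append(base + eo_effect + rep_effect + jitter)
            manifest_rows.append(
                {
                    "sample_id": row.sample_id,
                    "replicate_id": rep,
                    "class_label": int(row.class_label),
                }
            )
    columns = [f"peak_{s.peak_id:02d}" for s in specs]
    return (
        pd.DataFrame(np.asarray(rows), columns=columns),
        pd.DataFrame(manifest_rows),
    )


def write_study(
    traces: list[Chromatogram], manifest: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write one tabular text file per trace plus a ``manifest.csv``.

    Returns the manifest path; the manifest gains a ``path`` column with
    file names relative to ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for c in traces:
        name = f"{c.sample_id}_r{c.replicate_id}.tsv"
        write_trace(c, outdir / name)
        paths.append(name)
    manifest["path"] = paths
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_study(manifest_path: str | Path) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Read a study written by :func:`write_study`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    traces = []
    for _, row in manifest.iterrows():
        traces.append(
            read_trace(
                manifest_path.parent / row["path"],
                sample_id=row["sample_id"],
                replicate_id=int(row["replicate_id"]),
                class_label=int(row["class_label"]),
            )
        )
    return traces, manifest.drop(columns=["path"])
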