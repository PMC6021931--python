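"""Chromatogram container and plain-text trace IO.

A chromatogram is a single (retention time, intensity) trace with sample
metadata and a processing-stage tag.  Traces move through the pipeline in a
fixed order: ``raw`` -> ``logged`` -> ``baseline_corrected``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("raw", "logged", "baseline_corrected")


@dataclass
class Chromatogram:
    """One (RT, intensity) trace plus sample metadata.

    Parameters
    ----------
    rt : ndarray
        Retention times in minutes, strictly increasing.
    intensity : ndarray
        Intensities in arbitrary units, same length as ``rt``.
    sample_id : str
        Essential-oil sample identifier (shared across replicates).
    replicate_id : int
        Replicate number within the sample (1-based).
    class_label : int or None
        Ripening-stage class in 1..4, or None when unknown.
    stage_tag : str
        One of ``raw``, ``logged``, ``baseline_corrected``.
    """

    rt: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: int = 0
    class_label: int | None = None
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays")
        if len(self.rt) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.rt)} retention times vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("retention times must be strictly increasing")
        if self.stage_tag not in STAGES:
            raise ValueError(f"unknown stage_tag {self.stage_tag!r}")

    def __len__(self) -> int:
        return len(self.rt)

    def with_intensity(self, intensity: np.ndarray, stage_tag: str) -> "Chromatogram":
        """Copy of this trace with new intensities and stage tag."""
        c = replace(self, intensity=np.asarray(intensity, dtype=float))
        c.stage_tag = stage_tag
        return c


def write_trace(c: Chromatogram, path: str | Path) -> None:
    """Write a trace as a two-column tab-separated text file."""
    df = pd.DataFrame({"rt_min": c.rt, "intensity": c.intensity})
    df.to_csv(path, sep="\t", index=False)


def read_trace(
    path: str | Path,
    sample_id: str = "",
    replicate_id: int = 0,
    class_label: int | None = None,
) -> Chromatogram:
    """Read a two-column ``rt_min``/``intensity`` text trace."""
    df = pd.read_csv(path, sep="\t")
    missing = {"rt_min", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return Chromatogram(
        rt=df["rt_min"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        sample_id=sample_id,
        replicate_id=replicate_id,
        class_label=class_label,
    )


def read_mzml_tic(path: str | Path, **meta) -> Chromatogram:
    """Extract the total ion chromatogram from an mzML file.

    Sums the intensity array of every MS1 spectrum; retention times are
    converted to minutes.  Requires :mod:`pyteomics`.
    """
    from pyteomics import mzml  # optional dependency, imported lazily

    rts: list[float] = []
    tic: list[float] = []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            scan = spec["scanList"]["scan"][0]
            t = scan["scan start time"]
            # pyteomics returns a unitfloat; mzML times may be s or min
            unit = getattr(t, "unit_info", "minute")
            t_min = float(t) / 60.0 if unit in ("second", "s") else float(t)
            rts.append(t_min)
            tic.append(float(np.sum(spec["intensity array"])))
    order = np.argsort(rts)
    return Chromatogram(np.asarray(rts)[order], np.asarray(tic)[order], **meta)
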