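"""End-to-end pipeline: simulate -> preprocess -> detect -> train -> select -> permtest.

A single :class:`PipelineConfig` (YAML round-trippable, unknown keys
rejected) drives every stage; `run_pipeline` executes them in order, writes
all intermediate artifacts plus a machine-readable report, and is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import peaks as peaks_mod
from . import preprocess as pre_mod
from . import selection as sel_mod
from . import significance as sig_mod
from . import synthetic as syn_mod
from .modeling import MLPConfig, default_search_space, select_architecture
from .peaks import FeatureMatrix

log = logging.getLogger("chromclass")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class SimulateConfig:
    class_sizes: tuple[int, ...] = (11, 27, 36, 27)
    replicates_per_sample: int = 3
    noise_sd: float = 2.0
    baseline_amplitude: float = 30.0
    replicate_log_sd: float = 0.05
    eo_log_sd: float = 0.15
    measurement_log_sd: float = 0.02
    separability: float = 1.0
    write_traces: bool = False


@dataclass
class PreprocessConfig:
    lam: float = 1e6
    p: float = 0.001
    k: float | None = None  # None = 1% of signal range per trace
    offset: float = 1.0
    quiet_fraction: float = 0.2


@dataclass
class DetectConfig:
    rt_tol: float = 0.1
    presence_threshold: float = 1.0


@dataclass
class ModelingConfig:
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    n_partitions: int = 50
    search_widths: tuple[int, ...] = (2, 4, 8, 13, 16)
    search_depths: tuple[int, ...] = (1, 2)
    max_epochs: int = 300
    patience: int = 30


@dataclass
class SelectionConfig:
    grid_steps: int = 50
    n_partitions: int = 20


@dataclass
class SignificanceConfig:
    n_permutations: int = 200
    n_partitions_null: int = 20
    n_partitions_observed: int = 50


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None  # read an existing study instead of simulating
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)

    _SECTIONS = {
        "simulate": SimulateConfig,
        "preprocess": PreprocessConfig,
        "detect": DetectConfig,
        "modeling": ModelingConfig,
        "selection": SelectionConfig,
        "significance": SignificanceConfig,
    }

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        for key in ("seed", "input_dir"):
            if key in data:
                kwargs[key] = data.pop(key)
        for name, section_cls in cls._SECTIONS.items():
            section = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in config section {name!r}"
                )
            tupled = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            kwargs[name] = section_cls(**tupled)
        if data:
            raise ValueError(f"unknown top-level config key(s) {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def pca_overview(X: np.ndarray | pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (not scaled) PCA of the feature matrix.

    Returns a table of per-component variance fractions (non-increasing,
    summing to 1) and the score coordinates of the first three components.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    pca = PCA()
    scores = pca.fit_transform(Xa)
    frac = pca.explained_variance_ratio_
    table = pd.DataFrame(
        {
            "component": np.arange(1, len(frac) + 1),
            "variance_fraction": frac,
            "cumulative_fraction": np.cumsum(frac),
        }
    )
    return table, scores[:, : min(3, scores.shape[1])]


def _design_from_config(cfg: SimulateConfig, seed: int) -> syn_mod.StudyDesign:
    return syn_mod.StudyDesign(
        class_sizes=tuple(cfg.class_sizes),
        replicates_per_sample=cfg.replicates_per_sample,
        noise_sd=cfg.noise_sd,
        baseline_amplitude=cfg.baseline_amplitude,
        replicate_log_sd=cfg.replicate_log_sd,
        eo_log_sd=cfg.eo_log_sd,
        measurement_log_sd=cfg.measurement_log_sd,
        separability=cfg.separability,
        seed=seed,
    )


def extract_features(
    traces, manifest, pre_cfg: PreprocessConfig, det_cfg: DetectConfig
) -> FeatureMatrix:
    """Preprocess, detect, match and assemble features for a list of traces."""
    params = pre_mod.PsalsaParams(lam=pre_cfg.lam, p=pre_cfg.p, k=pre_cfg.k)
    detections, thresholds = [], []
    for c in traces:
        corrected, stats = pre_mod.preprocess_chromatogram(
            c, params, offset=pre_cfg.offset, quiet_fraction=pre_cfg.quiet_fraction
        )
        detections.append(peaks_mod.detect_peaks(corrected, stats))
        thresholds.append(stats.threshold)
    registry = peaks_mod.match_peaks(
        detections, rt_tol=det_cfg.rt_tol, presence_threshold=det_cfg.presence_threshold
    )
    if len(registry) == 0:
        raise PipelineError("detect", "no peaks passed the presence threshold")
    return peaks_mod.build_feature_matrix(detections, thresholds, manifest, registry)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write artifacts plus ``report.json``.

    Stage order: simulate (or load) -> preprocess + feature extraction ->
    PCA overview -> architecture selection -> sensitivity analysis ->
    sequential feature selection -> final assessment on the selected subset
    -> permutation test.  Returns the report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"seed": config.seed}
    artifacts: list[Path] = []

    # --- stage: input -----------------------------------------------------
    stage = "simulate"
    try:
        if config.input_dir is not None:
            stage = "load"
            manifest_path = Path(config.input_dir) / "manifest.csv"
            if not manifest_path.exists():
                raise FileNotFoundError(f"no manifest at {manifest_path}")
            traces, manifest = syn_mod.read_study(manifest_path)
        else:
            specs = syn_mod.default_peak_specs()
            design = _design_from_config(config.simulate, config.seed)
            traces, manifest = syn_mod.simulate_study(specs, design)
            if config.simulate.write_traces:
                syn_mod.write_study(traces, manifest, outdir / "traces")
        log.info("%s: %d traces, %d oils", stage, len(traces), manifest["sample_id"].nunique())
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # --- stage: features --------------------------------------------------
    try:
        stage = "features"
        fm = extract_features(traces, manifest, config.preprocess, config.detect)
        fm.to_csv(outdir / "features.csv")
        fm.registry.table.to_csv(outdir / "registry.csv", index=False)
        artifacts += [outdir / "features.csv", outdir / "registry.csv"]
        report["n_traces"] = int(len(fm.values))
        report["n_peaks"] = int(len(fm.registry))
        log.info("features: %d x %d", *fm.values.shape)

        stage = "pca"
        pca_table, _ = pca_overview(fm.values)
        pca_table.to_csv(outdir / "pca.csv", index=False)
        artifacts.append(outdir / "pca.csv")
        report["pca_first3_variance"] = float(
            pca_table["cumulative_fraction"].iloc[min(2, len(pca_table) - 1)]
        )

        stage = "architecture"
        space = default_search_space(
            widths=tuple(config.modeling.search_widths),
            depths=tuple(config.modeling.search_depths),
        )
        base = MLPConfig(
            n_inputs=fm.values.shape[1],
            max_epochs=config.modeling.max_epochs,
            patience=config.modeling.patience,
            seed=int(rng.integers(2**31)),
        )
        winner, cv_full = select_architecture(
            fm.values,
            fm.meta,
            search_space=space,
            n_partitions=config.modeling.n_partitions,
            rng=rng,
            fractions=tuple(config.modeling.fractions),
            base_config=base,
        )
        cv_full.search_scores.to_csv(outdir / "architecture_search.csv", index=False)
        artifacts.append(outdir / "architecture_search.csv")
        report["architecture"] = cv_full.summary()
        log.info("winner architecture %s", report["architecture"]["architecture"])

        stage = "sensitivity"
        sens = sel_mod.average_sensitivity(
            cv_full, fm.values, grid_steps=config.selection.grid_steps
        )
        ranks = sel_mod.rank_inputs(sens)
        ranks.to_frame().to_csv(outdir / "rankings.csv")
        artifacts.append(outdir / "rankings.csv")

        stage = "selection"
        trace = sel_mod.sequential_rank_addition(ranks)
        trace = sel_mod.evaluate_trace(
            trace,
            fm.values,
            fm.meta,
            winner,
            n_partitions=config.selection.n_partitions,
            rng=rng,
            fractions=tuple(config.modeling.fractions),
        )
        trace.to_frame().to_csv(outdir / "selection_trace.csv", index=False)
        artifacts.append(outdir / "selection_trace.csv")
        best = trace.best_step
        best_res = trace.step_results[trace.best_step_index]
        report["selection"] = {
            "n_steps": len(trace.steps),
            "best_step": trace.best_step_index + 1,
            "selected_peaks": [int(p) for p in best.cumulative],
            "n_selected": best.count,
            "external_ccr_mean": float(best_res.external_ccr.mean()),
            "external_ccr_sd": float(best_res.external_ccr.std(ddof=1))
            if len(best_res.external_ccr) > 1
            else 0.0,
            "confusion_percent": np.round(best_res.confusion_percent, 2).tolist(),
        }

        stage = "permtest"
        cols = [c for c in fm.values.columns if int(c.split("_")[-1]) in best.cumulative]
        perm = sig_mod.permutation_test(
            fm.values[cols],
            fm.meta,
            dataclasses.replace(winner, n_inputs=len(cols)),
            n_permutations=config.significance.n_permutations,
            rng=rng,
            n_partitions_observed=config.significance.n_partitions_observed,
            n_partitions_null=config.significance.n_partitions_null,
            fractions=tuple(config.modeling.fractions),
        )
        pd.DataFrame(
            {
                "kind": ["observed"] * len(perm.observed_ccrs)
                + ["null"] * len(perm.null_ccrs),
                "ccr": np.concatenate([perm.observed_ccrs, perm.null_ccrs]),
            }
        ).to_csv(outdir / "permutation_ccrs.csv", index=False)
        artifacts.append(outdir / "permutation_ccrs.csv")
        report["significance"] = perm.summary()
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    def _jsonable(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonable))
    artifacts.append(report_path)
    hashes = {p.name: _sha256(p) for p in artifacts}
    (outdir / "artifact_hashes.json").write_text(
        json.dumps(hashes, indent=2, sort_keys=True)
    )
    return report


def format_report(report: dict) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["chromclass pipeline report", "=" * 27]
    lines.append(f"seed: {report.get('seed')}")
    lines.append(
        f"features: {report.get('n_traces')} traces x {report.get('n_peaks')} peaks"
    )
    if "pca_first3_variance" in report:
        lines.append(
            f"PCA: first 3 components carry {100 * report['pca_first3_variance']:.1f}% of variance"
        )
    if "architecture" in report:
        a = report["architecture"]
        lines.append(
            f"architecture {a['architecture']} ({a['hidden_activation']}): "
            f"external CCR {100 * a['external_ccr_mean']:.1f} "
            f"± {100 * a['external_ccr_sd']:.1f}% over {a['n_partitions']} partitions"
        )
    if "selection" in report:
        s = report["selection"]
        lines.append(
            f"selection: step {s['best_step']}/{s['n_steps']} with {s['n_selected']} peaks "
            f"-> external CCR {100 * s['external_ccr_mean']:.1f} ± {100 * s['external_ccr_sd']:.1f}%"
        )
        lines.append(f"selected peaks: {s['selected_peaks']}")
    if "significance" in report:
        g = report["significance"]
        lines.append(
            f"permutation test: observed mean CCR {100 * g['observed_ccr_mean']:.1f}% vs "
            f"null {100 * g['null_ccr_mean']:.1f}% "
            f"(U = {g['U']:.1f}, p = {g['p_value']:.3g}, "
            f"empirical p = {g['p_empirical']:.3g}, {g['n_permutations']} permutations)"
        )
    return "\n".join(lines) + "\n"
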