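"""End-to-end orchestration: simulate -> preprocess -> CRQA -> surrogates -> models.

A :class:`PipelineConfig` bundles every tunable with defaults equal to
the analysis constants (10 Hz, 60-120 s calibration window, 5% target
RR, +-50 lags, 10 phase-randomized surrogates).  :func:`run_pipeline`
executes the stages against a directory tree and writes a manifest;
:func:`analyze_study` is the in-memory path used by simulations and
tests.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .core import AccelTrace
from .design import DropoutSpec, StudyDesign
from .gca import fit_baseline_contrast_models, fit_full_model, fit_posthoc_models
from .preprocess import inclusion_filter, preprocess_conversation
from .recurrence import run_crqa
from .simulate import SimulatedStudy, simulate_study
from .surrogates import build_baseline_drps

__all__ = ["PipelineConfig", "run_pipeline", "analyze_study", "simulate_to_dir"]

DRP_COLUMNS = ["dyad", "conversation", "conv_type", "task", "source", "surrogate_id", "lag", "rr"]


@dataclass
class PipelineConfig:
    seed: int = 0
    in_dir: Optional[str] = None
    out_dir: str = "results"
    n_dyads: int = 21
    n_noise: int = 9
    duration_s: float = 480.0
    sample_rate_hz: float = 250.0
    hazard_per_s: float = 6.4e-4
    target_hz: float = 10.0
    calibration_window: Tuple[float, float] = (60.0, 120.0)
    target_rr: float = 0.05
    max_lag: int = 50
    surrogate_method: str = "phase_randomization"
    n_surrogates: int = 10
    standardized: bool = True
    posthoc: bool = True
    baseline_contrast: bool = True
    random_slopes: str = "backward"
    simulate: bool = True

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Flat key=value config file; unknown keys rejected."""
        kv: Dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: Dict[str, str]) -> "PipelineConfig":
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in kv.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if key == "calibration_window":
                parts = [float(v) for v in str(val).replace(",", " ").split()]
                setattr(cfg, key, (parts[0], parts[1]))
            elif isinstance(current, bool):
                setattr(cfg, key, str(val).lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(val))
            elif isinstance(current, float):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["calibration_window"] = list(self.calibration_window)
        return d


def simulate_to_dir(config: PipelineConfig, out_dir: Path) -> pd.DataFrame:
    """Simulate a study and write raw CSVs plus the metadata table."""
    design = StudyDesign(
        n_dyads=config.n_dyads, n_noise=min(config.n_noise, config.n_dyads),
        conversation_duration_s=config.duration_s,
        sample_rate_hz=config.sample_rate_hz, seed=config.seed,
    )
    study = simulate_study(design, dropout=DropoutSpec(hazard_per_s=config.hazard_per_s))
    raw = out_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    rows = []
    for dyad in study.dyads:
        for conv in dyad.conversations:
            fa = raw / f"{dyad.dyad_id}-conv{conv.number}-a.csv"
            fb = raw / f"{dyad.dyad_id}-conv{conv.number}-b.csv"
            dio.write_movement_csv(conv.trace_a, fa)
            dio.write_movement_csv(conv.trace_b, fb)
            rows.append(
                {
                    "dyad": dyad.dyad_id, "conversation": conv.number,
                    "conv_type": conv.conv_type, "conv_order": conv.number,
                    "task": dyad.task, "file_a": fa.name, "file_b": fb.name,
                }
            )
    meta = pd.DataFrame(rows)
    dio.write_metadata_csv(meta, out_dir / "metadata.csv")
    return meta


def analyze_study(
    study: SimulatedStudy,
    target_rr: float = 0.05,
    max_lag: int = 50,
    n_surrogates: int = 10,
    surrogate_method: str = "phase_randomization",
    surrogate_seed: int = 0,
    calibration_window: Tuple[float, float] = (60.0, 120.0),
    target_hz: float = 10.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """In-memory preprocessing + CRQA + surrogate baseline for a study.

    Returns ``(drps, params, cutoffs)``: the long-format DRP table (real
    and surrogate rows), the per-conversation embedding parameters, and
    the cutoff report.
    """
    drp_rows: List[pd.DataFrame] = []
    surrogate_inputs = []
    param_rows = []
    cutoff_rows = []
    for dyad in study.included_dyads:
        for conv in dyad.conversations:
            sa, sb, cut = preprocess_conversation(
                conv.trace_a, conv.trace_b, target_hz=target_hz,
                window=calibration_window,
            )
            res = run_crqa(sa, sb, target_rr=target_rr, max_lag=max_lag)
            drp_rows.append(
                pd.DataFrame(
                    {
                        "dyad": dyad.dyad_id, "conversation": conv.number,
                        "conv_type": conv.conv_type, "task": dyad.task,
                        "source": "real", "surrogate_id": 0,
                        "lag": res.lags, "rr": res.drp,
                    }
                )
            )
            param_rows.append(
                {
                    "dyad": dyad.dyad_id, "conversation": conv.number,
                    "delay": res.params.delay, "dimension": res.params.dimension,
                    "radius": res.params.radius,
                }
            )
            cutoff_rows.append(
                {
                    "dyad": dyad.dyad_id, "conversation": conv.number,
                    "cutoff_a": cut.jounce_a, "cutoff_b": cut.jounce_b,
                    "cutoff_dyad": cut.dyad,
                }
            )
            surrogate_inputs.append(
                {
                    "dyad": dyad.dyad_id, "conversation": conv.number,
                    "conv_type": conv.conv_type, "task": dyad.task,
                    "series_a": sa, "series_b": sb, "params": res.params,
                }
            )
    if n_surrogates > 0 and surrogate_inputs:
        sur = build_baseline_drps(
            surrogate_inputs, method=surrogate_method, n_surrogates=n_surrogates,
            rng=np.random.default_rng(np.random.SeedSequence(surrogate_seed)),
            max_lag=max_lag,
        )
        drp_rows.append(sur)
    drps = pd.concat(drp_rows, ignore_index=True) if drp_rows else pd.DataFrame(columns=DRP_COLUMNS)
    return drps, pd.DataFrame(param_rows), pd.DataFrame(cutoff_rows)


def _stage(name: str, unit: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed"
                    + (f" for {unit}" if unit else "")
                    + f": {exc}"
                ) from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline against a directory tree.

    With ``config.simulate`` the raw data are generated first; otherwise
    ``config.in_dir`` must hold a ``metadata.csv`` and raw traces.
    Deterministic given ``config.seed``; a manifest records versions,
    the resolved config and per-stage row counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "counts": {},
    }

    if config.simulate:
        with _stage("simulate"):
            meta = simulate_to_dir(config, out)
            in_dir = out
    else:
        if config.in_dir is None or not Path(config.in_dir).exists():
            raise FileNotFoundError(f"input directory {config.in_dir!r} does not exist")
        in_dir = Path(config.in_dir)
        meta = dio.read_metadata_csv(in_dir / "metadata.csv")
    manifest["counts"]["conversations"] = int(len(meta))

    # inclusion rule on raw durations
    with _stage("preprocess"):
        traces: Dict[Tuple[str, int], Tuple[AccelTrace, AccelTrace]] = {}
        dur_rows = []
        for rec in meta.itertuples():
            ta = dio.read_movement_csv(Path(in_dir) / "raw" / rec.file_a)
            tb = dio.read_movement_csv(Path(in_dir) / "raw" / rec.file_b)
            traces[(rec.dyad, rec.conversation)] = (ta, tb)
            dur_rows += [
                {"dyad": rec.dyad, "duration_s": ta.duration_s},
                {"dyad": rec.dyad, "duration_s": tb.duration_s},
            ]
        included = inclusion_filter(pd.DataFrame(dur_rows))
        proc_dir = out / "processed"
        proc_dir.mkdir(exist_ok=True)
        processed = {}
        cutoff_rows = []
        for rec in meta.itertuples():
            if rec.dyad not in included:
                continue
            ta, tb = traces[(rec.dyad, rec.conversation)]
            sa, sb, cut = preprocess_conversation(
                ta, tb, target_hz=config.target_hz, window=config.calibration_window
            )
            processed[(rec.dyad, rec.conversation)] = (sa, sb, rec)
            dio.write_series_csv(sa, proc_dir / f"{rec.dyad}-conv{rec.conversation}-a.csv")
            dio.write_series_csv(sb, proc_dir / f"{rec.dyad}-conv{rec.conversation}-b.csv")
            cutoff_rows.append(
                {
                    "dyad": rec.dyad, "conversation": rec.conversation,
                    "cutoff_a": cut.jounce_a, "cutoff_b": cut.jounce_b,
                    "cutoff_dyad": cut.dyad,
                }
            )
        pd.DataFrame(cutoff_rows).to_csv(out / "cutoffs.csv", index=False)
    manifest["counts"]["included_dyads"] = len(included)

    with _stage("crqa"):
        drp_rows, param_rows, surrogate_inputs = [], [], []
        for (dyad, convnum), (sa, sb, rec) in sorted(processed.items()):
            res = run_crqa(sa, sb, target_rr=config.target_rr, max_lag=config.max_lag)
            drp_rows.append(
                pd.DataFrame(
                    {
                        "dyad": dyad, "conversation": convnum,
                        "conv_type": rec.conv_type, "task": rec.task,
                        "source": "real", "surrogate_id": 0,
                        "lag": res.lags, "rr": res.drp,
                    }
                )
            )
            param_rows.append(
                {
                    "dyad": dyad, "conversation": convnum,
                    "delay": res.params.delay, "dimension": res.params.dimension,
                    "radius": res.params.radius,
                }
            )
            surrogate_inputs.append(
                {
                    "dyad": dyad, "conversation": convnum,
                    "conv_type": rec.conv_type, "task": rec.task,
                    "series_a": sa, "series_b": sb, "params": res.params,
                }
            )
        drps = pd.concat(drp_rows, ignore_index=True)
        pd.DataFrame(param_rows).to_csv(out / "crqa_params.csv", index=False, float_format="%.8f")
    manifest["counts"]["real_drp_rows"] = int(len(drps))

    with _stage("surrogate"):
        sur = build_baseline_drps(
            surrogate_inputs, method=config.surrogate_method,
            n_surrogates=config.n_surrogates,
            rng=np.random.default_rng(np.random.SeedSequence(config.seed + 1)),
            max_lag=config.max_lag,
        )
        all_drps = pd.concat([drps, sur], ignore_index=True)
        all_drps.to_csv(out / "drps.csv", index=False, float_format="%.8f")
    manifest["counts"]["surrogate_drp_rows"] = int(len(sur))

    with _stage("model"):
        coefs = []
        full = fit_full_model(
            drps, standardized=config.standardized, random_slopes=config.random_slopes
        )
        coefs.append(full.coef_frame("full"))
        (out / "random_slope_attempts.json").write_text(json.dumps(full.attempt_log, indent=1))
        if config.posthoc:
            for name, res in fit_posthoc_models(
                drps, standardized=config.standardized, random_slopes=config.random_slopes
            ).items():
                coefs.append(res.coef_frame(f"posthoc-{name}"))
        if config.baseline_contrast and config.n_surrogates > 0:
            for name, res in fit_baseline_contrast_models(
                all_drps, standardized=config.standardized,
                random_slopes=config.random_slopes, posthoc=config.posthoc,
            ).items():
                coefs.append(res.coef_frame(f"contrast-{name}"))
        pd.concat(coefs, ignore_index=True).to_csv(out / "coefficients.csv", index=False)
    manifest["counts"]["models"] = len(coefs)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _versions() -> Dict[str, str]:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "dyadsync": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }
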