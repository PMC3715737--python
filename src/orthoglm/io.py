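"""File I/O and pipeline orchestration.

Formats: BIDS-style ``events.tsv`` (tab-separated; columns ``onset``,
``duration``, ``trial_type`` and optional ``modulation``), plain TSV
series files (a ``time`` column plus one column per region), NIfTI-1
volumes for the voxelwise path, and JSON/TSV comparison reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .compare import DEFAULT_TIE_TOLERANCE, APPROACHES, ComparisonReport, run_report
from .design import (
    EventSpec,
    Regressor,
    build_regressor,
    center_modulations,
    zscore,
)
from .errors import SchemaError
from .learning import rw_trace
from .simulate import reference_dataset, tile_volume

__all__ = [
    "RunConfig",
    "read_events",
    "write_events",
    "read_series",
    "write_series",
    "run_compare",
    "run_voxelwise",
    "run_simulate",
]

log = logging.getLogger("orthoglm")

_REQUIRED_EVENT_COLUMNS = ("onset", "duration", "trial_type")


def read_events(
    path: str | Path, trial_types: Sequence[str] | None = None
) -> dict[str, EventSpec]:
    """Read a BIDS-style events.tsv into one EventSpec per trial type.

    Rows are sorted by onset within each trial type; a missing
    ``modulation`` column defaults to 1 for every event.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no events (at least one trial is required)")
    for col in ("onset", "duration", "modulation"):
        if col not in df.columns:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise ValueError(
                f"{path}: non-numeric {col} value {df[col][bad.idxmax()]!r} "
                f"at line {row}"
            )
        df[col] = numeric
    if "modulation" not in df.columns:
        df["modulation"] = 1.0
    df["modulation"] = df["modulation"].fillna(1.0)

    wanted = trial_types if trial_types is not None else df["trial_type"].unique()
    out: dict[str, EventSpec] = {}
    for tt in wanted:
        sub = df[df["trial_type"] == tt].sort_values("onset")
        if len(sub) == 0:
            raise ValueError(f"{path}: no events of trial_type {tt!r}")
        out[str(tt)] = EventSpec(
            onsets=sub["onset"].to_numpy(),
            durations=sub["duration"].to_numpy(),
            modulations=sub["modulation"].to_numpy(),
            label=str(tt),
        )
    return out


def write_events(events: Mapping[str, EventSpec] | EventSpec, path: str | Path) -> None:
    """Write EventSpec(s) as a BIDS-style events.tsv (sorted by onset)."""
    if isinstance(events, EventSpec):
        events = {events.label: events}
    rows = []
    for spec in events.values():
        for onset, duration, modulation in zip(
            spec.onsets, spec.durations, spec.modulations
        ):
            rows.append(
                {
                    "onset": onset,
                    "duration": duration,
                    "trial_type": spec.label,
                    "modulation": modulation,
                }
            )
    df = pd.DataFrame(rows).sort_values(["onset", "trial_type"])
    df.to_csv(path, sep="\t", index=False)


def read_series(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Read a TSV series file; returns (time, {name: series}, dt)."""
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise SchemaError(f"{path}: series file needs a 'time' column")
    if len(df) < 2:
        raise ValueError(f"{path}: a series needs at least two samples")
    t = df["time"].to_numpy(dtype=float)
    steps = np.diff(t)
    if np.ptp(steps) > 1e-6:
        raise ValueError(f"{path}: sampling interval is not fixed")
    series = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"
    }
    if not series:
        raise SchemaError(f"{path}: no data columns besides 'time'")
    return t, series, float(steps[0])


def write_series(
    time: np.ndarray, series: Mapping[str, np.ndarray], path: str | Path
) -> None:
    df = pd.DataFrame({"time": time, **{k: v for k, v in series.items()}})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which events drive it and how.

    ``source`` is ``"modulation"`` (use the modulation column as the
    per-event amplitude) or ``"rw"`` (treat the modulation column as the
    reward sequence and use Rescorla-Wagner prediction errors as
    amplitudes, with learning rate ``alpha`` and initial value ``v0``).
    """

    name: str
    trial_type: str
    source: str = "modulation"
    alpha: float = 0.5
    v0: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in ("modulation", "rw"):
            raise ValueError(f"unknown model source {self.source!r}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a comparison run (exactly two candidate models)."""

    events: str
    model_a: ModelSpec
    model_b: ModelSpec
    series: str | None = None
    volume: str | None = None
    mask: str | None = None
    dt: float | None = None
    total_duration: float | None = None
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE
    use_abs: bool = False
    seed: int = 0
    hrf_internal_dt: float = 0.1

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RunConfig":
        models = cfg.get("models")
        if not isinstance(models, Mapping) or set(models) != {"A", "B"}:
            raise SchemaError("config must define models A and B")

        def model(key: str) -> ModelSpec:
            m = dict(models[key])
            return ModelSpec(
                name=str(m.get("name", key)),
                trial_type=str(m["trial_type"]),
                source=str(m.get("source", "modulation")),
                alpha=float(m.get("alpha", 0.5)),
                v0=float(m.get("v0", 0.0)),
            )

        a, b = model("A"), model("B")
        if (a.trial_type, a.source, a.alpha, a.v0) == (
            b.trial_type,
            b.source,
            b.alpha,
            b.v0,
        ):
            raise SchemaError(
                "models A and B are identical; the comparison is degenerate"
            )
        return cls(
            events=str(cfg["events"]),
            model_a=a,
            model_b=b,
            series=cfg.get("series"),
            volume=cfg.get("volume"),
            mask=cfg.get("mask"),
            dt=None if cfg.get("dt") is None else float(cfg["dt"]),
            total_duration=(
                None
                if cfg.get("total_duration") is None
                else float(cfg["total_duration"])
            ),
            tie_tolerance=float(cfg.get("tie_tolerance", DEFAULT_TIE_TOLERANCE)),
            use_abs=bool(cfg.get("use_abs", False)),
            seed=int(cfg.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise SchemaError(f"{path}: config must be a mapping")
        base = Path(path).parent
        cfg = dict(cfg)
        for key in ("events", "series", "volume", "mask"):
            if cfg.get(key):
                cfg[key] = str((base / cfg[key]).resolve())
        return cls.from_dict(cfg)


def _model_regressor(
    model: ModelSpec,
    events: Mapping[str, EventSpec],
    total_duration: float,
    dt: float,
) -> Regressor:
    if model.trial_type not in events:
        raise SchemaError(
            f"trial_type {model.trial_type!r} not present in events file "
            f"(has {sorted(events)})"
        )
    spec = events[model.trial_type]
    if model.source == "rw":
        trace = rw_trace(list(spec.modulations), model.alpha, model.v0)
        spec = EventSpec(
            spec.onsets, spec.durations, trace.deltas, label=model.name
        )
    else:
        spec = EventSpec(
            spec.onsets, spec.durations, spec.modulations, label=model.name
        )
    return zscore(build_regressor(center_modulations(spec), total_duration, dt))


def build_model_regressors(
    config: RunConfig, total_duration: float, dt: float
) -> tuple[Regressor, Regressor]:
    """Build and z-score both candidate regressors from the events file."""
    events = read_events(config.events)
    reg_a = _model_regressor(config.model_a, events, total_duration, dt)
    reg_b = _model_regressor(config.model_b, events, total_duration, dt)
    return reg_a, reg_b


# ---------------------------------------------------------------------------
# report writers


def reports_to_json(reports: Sequence[ComparisonReport], meta: Mapping) -> str:
    payload = {
        "meta": dict(meta),
        "regions": [rep.to_dict() for rep in reports],
    }
    return json.dumps(payload, sort_keys=True, indent=2) + "\n"


def reports_to_tsv(reports: Sequence[ComparisonReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for res in rep.results:
            rows.append(
                {
                    "region": rep.region,
                    "approach": res.approach,
                    "statistic_A": res.statistic_A,
                    "statistic_B": res.statistic_B,
                    "margin": res.margin,
                    "winner": res.winner_name,
                    "r": rep.r,
                    "n": rep.n,
                    "k": rep.k,
                }
            )
    return pd.DataFrame(rows)


def _cleanup(paths: Sequence[Path]) -> None:
    for p in paths:
        try:
            Path(p).unlink(missing_ok=True)
        except OSError:  # pragma: no cover
            pass


# ---------------------------------------------------------------------------
# runners


def run_compare(
    config: RunConfig, out_dir: str | Path
) -> list[ComparisonReport]:
    """Run the three-way comparison for every series column; write reports.

    Writes ``report.json`` (sorted keys) and ``report.tsv`` (one row per
    region x approach) into ``out_dir``. On error, partially written
    outputs are removed.
    """
    if config.series is None:
        raise SchemaError("run_compare needs a 'series' path in the config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        t, series, dt_obs = read_series(config.series)
        dt = config.dt if config.dt is not None else dt_obs
        total = (
            config.total_duration
            if config.total_duration is not None
            else len(t) * dt
        )
        reg_a, reg_b = build_model_regressors(config, total, dt)
        n = next(iter(series.values())).size
        if reg_a.n_samples != n:
            raise ValueError(
                f"regressors have {reg_a.n_samples} samples but series "
                f"has {n}; check dt/total_duration"
            )
        reports = [
            run_report(
                y,
                reg_a,
                reg_b,
                tie_tolerance=config.tie_tolerance,
                region=name,
                use_abs=config.use_abs,
            )
            for name, y in series.items()
        ]
        meta = {
            "model_A": config.model_a.name,
            "model_B": config.model_b.name,
            "tie_tolerance": config.tie_tolerance,
            "dt": dt,
            "n": n,
            "seed": config.seed,
        }
        json_path = out / "report.json"
        written.append(json_path)
        json_path.write_text(reports_to_json(reports, meta))
        tsv_path = out / "report.tsv"
        written.append(tsv_path)
        reports_to_tsv(reports).to_csv(tsv_path, sep="\t", index=False)
        for rep in reports:
            log.info(
                "region %s: r=%.3f n=%d k=%d agreement=%s",
                rep.region,
                rep.r,
                rep.n,
                rep.k,
                rep.agreement,
            )
        return reports
    except Exception:
        _cleanup(written)
        raise


WINNER_CODES = {"tie": 0, "A": 1, "B": 2}


def run_voxelwise(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Per-voxel three-way comparison over a masked 4-D volume.

    For each approach writes an integer winner map (0 tie, 1 model A,
    2 model B) and a real margin map as NIfTI-1 files. Returns the mapping
    from output name to path.
    """
    if config.volume is None or config.mask is None:
        raise SchemaError("run_voxelwise needs 'volume' and 'mask' paths")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = nib.load(config.volume)
    mask_img = nib.load(config.mask)
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if data.ndim != 4:
        raise ValueError("volume must be 4-D")
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid "
            f"{data.shape[:3]}"
        )
    n_t = data.shape[3]
    dt = config.dt if config.dt is not None else 1.0
    total = (
        config.total_duration if config.total_duration is not None else n_t * dt
    )
    reg_a, reg_b = build_model_regressors(config, total, dt)

    winner = {a: np.zeros(mask.shape, dtype=np.int16) for a in APPROACHES}
    margin = {a: np.zeros(mask.shape, dtype=np.float32) for a in APPROACHES}
    voxels = np.argwhere(mask)
    if voxels.size == 0:
        log.warning("mask selects no voxels; writing empty maps")
    for idx in voxels:
        rep = run_report(
            data[tuple(idx)],
            reg_a,
            reg_b,
            tie_tolerance=config.tie_tolerance,
            region="voxel",
            use_abs=config.use_abs,
        )
        for res in rep.results:
            winner[res.approach][tuple(idx)] = WINNER_CODES[res.winner]
            margin[res.approach][tuple(idx)] = res.margin

    paths: dict[str, Path] = {}
    for approach in APPROACHES:
        for kind, arr in (("winner", winner[approach]), ("margin", margin[approach])):
            name = f"{kind}_{approach}.nii.gz"
            p = out / name
            nib.save(nib.Nifti1Image(arr, img.affine), p)
            paths[name] = p
    return paths


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    noise_sd: float = 0.2,
    write_nifti: bool = False,
) -> dict[str, Path]:
    """Generate the two-region reference dataset and write it to disk.

    Writes ``events.tsv`` (single trial_type ``reward`` whose modulation
    column is the reward sequence), ``series.tsv``, a ready-to-run
    ``config.yaml`` for the compare command, and ``provenance.json``.
    With ``write_nifti``, also writes a tiled 4-D volume and mask.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = reference_dataset(seed=seed, noise_sd=noise_sd)
    paths: dict[str, Path] = {}

    ro = ds.events["RO"]
    reward_events = EventSpec(
        ro.onsets, ro.durations, ro.modulations, label="reward"
    )
    paths["events"] = out / "events.tsv"
    write_events(reward_events, paths["events"])
    paths["series"] = out / "series.tsv"
    write_series(ds.time, ds.series, paths["series"])

    cfg = {
        "events": "events.tsv",
        "series": "series.tsv",
        "dt": ds.dt,
        "total_duration": ds.total_duration,
        "seed": int(seed),
        "models": {
            "A": {"name": "RO", "trial_type": "reward", "source": "modulation"},
            "B": {
                "name": "RPE",
                "trial_type": "reward",
                "source": "rw",
                "alpha": ds.provenance["alpha"],
                "v0": 0.0,
            },
        },
    }
    paths["config"] = out / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(
        json.dumps(ds.provenance, sort_keys=True, indent=2) + "\n"
    )

    if write_nifti:
        data, mask, _truth = tile_volume(seed=seed, noise_sd=noise_sd)
        affine = np.eye(4)
        paths["volume"] = out / "volume.nii.gz"
        nib.save(nib.Nifti1Image(data, affine), paths["volume"])
        paths["mask"] = out / "mask.nii.gz"
        nib.save(nib.Nifti1Image(mask, affine), paths["mask"])
    return paths
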