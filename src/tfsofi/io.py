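"""File formats and run configuration.

Movies are multi-page grayscale TIFFs (16-bit unsigned counts for camera
frames, 32-bit float for cumulant images, page order = time order) with a
JSON metadata sidecar next to each file.  Z-scan series are one TIFF per
defocus plus an ``index.csv`` (columns ``z_um``, ``filename``).  Run
configurations are YAML with explicit units in key names; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .blinking import BlinkKinetics
from .optics import OpticalConfig, Psf3D, TFSectioningModel
from .simulate import (
    AcquisitionPlan,
    CameraModel,
    EmitterSet,
    Excitation,
    FrameStack,
    ZScanSeries,
    flat_layer_sample,
    uniform_volume_sample,
)

__all__ = [
    "read_stack",
    "write_stack",
    "write_image",
    "read_image",
    "write_zscan",
    "read_zscan",
    "AnalysisOptions",
    "RunConfig",
    "load_run_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar.

    Frames that are non-negative integers within 16 bits are stored as
    uint16; anything else as float32.
    """
    path = Path(path)
    frames = np.asarray(stack.frames)
    integral = np.all(frames >= 0) and np.all(frames == np.rint(frames)) and frames.max(initial=0) < 2**16
    data = frames.astype(np.uint16 if integral else np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "exposure_ms": stack.exposure_ms,
        "n_frames": stack.n_frames,
        **_jsonable(stack.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF movie written by :func:`write_stack`.

    The JSON sidecar is optional; without it pixel size and exposure fall
    back to NaN so the caller must supply them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # malformed file
        raise ValueError(f"could not read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"stack {path} has inconsistent page shapes or dimensionality {frames.shape}"
        )
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return FrameStack(
        frames=frames,
        pixel_size_nm=float(meta.get("pixel_size_nm", float("nan"))),
        exposure_ms=float(meta.get("exposure_ms", float("nan"))),
        metadata={k: v for k, v in meta.items() if k not in ("pixel_size_nm", "exposure_ms", "n_frames")},
    )


def write_image(image: np.ndarray, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a single 2D image as 32-bit float TIFF (cumulant images can be
    negative) with an optional JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack")
    if metadata is not None:
        _sidecar(path).write_text(json.dumps(_jsonable(metadata), indent=2))
    return path


def read_image(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"expected a single-page 2D image in {path}, got shape {arr.shape}")
    return arr


def write_zscan(series: ZScanSeries, out_dir: str | Path, prefix: str = "z") -> Path:
    """Write one TIFF per defocus plus an index CSV (z_um, filename)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (z, stack) in enumerate(series):
        name = f"{prefix}{i:03d}.tif"
        write_stack(stack, out_dir / name)
        rows.append({"z_um": z, "filename": name})
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_zscan(index_path: str | Path) -> ZScanSeries:
    """Read a z-scan series back from its index CSV."""
    index_path = Path(index_path)
    if index_path.is_dir():
        index_path = index_path / "index.csv"
    table = pd.read_csv(index_path)
    for col in ("z_um", "filename"):
        if col not in table.columns:
            raise ValueError(f"z-scan index {index_path} lacks required column '{col}'")
    entries = [
        (float(row.z_um), read_stack(index_path.parent / str(row.filename)))
        for row in table.itertuples()
    ]
    return ZScanSeries(entries)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class AnalysisOptions:
    order: int = 2
    lag: int = 0
    n_regions: int = 8
    fit_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("analysis order must be 2 or 3")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.fit_model not in ("gaussian", "eq1"):
            raise ValueError("fit_model must be 'gaussian' or 'eq1'")


_SAMPLE_KEYS = {
    "flat_layer": {"kind", "n_emitters", "field_um", "z_layer_um", "brightness"},
    "uniform_volume": {"kind", "n_emitters", "field_um", "z_extent_um", "brightness"},
    "emitters": {"kind", "x_um", "y_um", "z_um", "brightness"},
}


@dataclass
class RunConfig:
    """Fully resolved configuration of a simulation + analysis run."""

    psf: Psf3D
    excitation: Excitation
    sample_spec: dict
    kinetics: BlinkKinetics
    camera: CameraModel
    plan: AcquisitionPlan
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    optics: OpticalConfig | None = None
    seed: int = 0

    def build_sample(self) -> EmitterSet:
        """Instantiate the emitter set, deterministically from the run seed."""
        spec = dict(self.sample_spec)
        kind = spec.pop("kind")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(1_000_003,)))
        if kind == "flat_layer":
            return flat_layer_sample(rng=rng, **spec)
        if kind == "uniform_volume":
            return uniform_volume_sample(rng=rng, **spec)
        if kind == "emitters":
            return EmitterSet(**spec)
        raise ValueError(f"unknown sample kind '{kind}'")

    def echo(self) -> dict:
        """Complete resolved configuration as a JSON-serialisable mapping."""
        return _jsonable(
            {
                "seed": self.seed,
                "psf": dataclasses.asdict(self.psf),
                "excitation": {
                    "mode": self.excitation.mode,
                    "model": dataclasses.asdict(self.excitation.model)
                    if self.excitation.model
                    else None,
                },
                "sample": self.sample_spec,
                "kinetics": dataclasses.asdict(self.kinetics),
                "camera": dataclasses.asdict(self.camera),
                "plan": dataclasses.asdict(self.plan),
                "analysis": dataclasses.asdict(self.analysis),
                "optics": dataclasses.asdict(self.optics) if self.optics else None,
            }
        )


def _build(cls, mapping: dict, section: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"config section '{section}' must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    return cls(**mapping)


def load_run_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere are errors.  ``seed_override`` (e.g. from the
    command line) replaces the configured seed; the plan inherits the run
    seed unless it sets its own.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping at top level")
    known = {"seed", "optics", "psf", "sectioning", "excitation", "sample",
             "kinetics", "camera", "plan", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    seed = int(raw.get("seed", 0)) if seed_override is None else int(seed_override)

    psf_raw = raw.get("psf")
    if psf_raw is None:
        raise ValueError("config requires a 'psf' section (lateral_fwhm_nm, axial_fwhm_nm)")
    psf = _build(Psf3D, psf_raw, "psf")

    sectioning = None
    if raw.get("sectioning") is not None:
        sectioning = _build(TFSectioningModel, raw["sectioning"], "sectioning")

    exc_raw = dict(raw.get("excitation") or {"mode": "widefield"})
    unknown = set(exc_raw) - {"mode"}
    if unknown:
        raise ValueError(f"unknown keys in config section 'excitation': {sorted(unknown)}")
    excitation = Excitation(mode=exc_raw.get("mode", "widefield"), model=sectioning)

    sample = raw.get("sample")
    if not isinstance(sample, dict) or "kind" not in sample:
        raise ValueError("config requires a 'sample' section with a 'kind'")
    kind = sample["kind"]
    if kind not in _SAMPLE_KEYS:
        raise ValueError(f"unknown sample kind '{kind}'")
    unknown = set(sample) - _SAMPLE_KEYS[kind]
    if unknown:
        raise ValueError(f"unknown keys in config section 'sample' ({kind}): {sorted(unknown)}")

    plan_raw = dict(raw.get("plan") or {})
    zspec = plan_raw.get("z_positions_um")
    if isinstance(zspec, dict):
        unknown = set(zspec) - {"start", "stop", "step"}
        if unknown:
            raise ValueError(f"unknown keys in plan.z_positions_um: {sorted(unknown)}")
        start, stop, step = float(zspec["start"]), float(zspec["stop"]), float(zspec["step"])
        n = int(round((stop - start) / step)) + 1
        plan_raw["z_positions_um"] = tuple(start + step * np.arange(n))
    elif zspec is not None:
        plan_raw["z_positions_um"] = tuple(float(v) for v in zspec)
    if "frame_shape" in plan_raw:
        plan_raw["frame_shape"] = tuple(plan_raw["frame_shape"])
    plan_raw.setdefault("seed", seed)
    plan = _build(AcquisitionPlan, plan_raw, "plan")

    optics = _build(OpticalConfig, raw["optics"], "optics") if raw.get("optics") else None

    return RunConfig(
        psf=psf,
        excitation=excitation,
        sample_spec=sample,
        kinetics=_build(BlinkKinetics, raw.get("kinetics"), "kinetics"),
        camera=_build(CameraModel, raw.get("camera"), "camera"),
        plan=plan,
        analysis=_build(AnalysisOptions, raw.get("analysis"), "analysis"),
        optics=optics,
        seed=seed,
    )


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialisation."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
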