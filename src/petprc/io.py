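"""Volume and sinogram I/O, frame schedules, and experiment orchestration.

Volumes travel as NIfTI (via nibabel, voxel size and origin in the
affine) or as raw float32 arrays with a YAML sidecar carrying shape,
voxel size, origin and kind.  Sinograms are raw float32 plus a sidecar
with the geometry and subset partition.  Experiments are described by a
YAML config and always write a manifest sufficient to re-run them
bitwise.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .grid import VoxelGrid
from .kernels import rb82_water_params
from .metrics import nema_report
from .phantoms import gen_cardiac, gen_nema_nu4, gen_rat_thorax
from .projection import (
    ProjectionData,
    ProjectionGeometry,
    attenuation_factors,
    make_subsets,
    simulate_acquisition,
)
from .recon import ReconConfig, osem, segment_density


# ---------------------------------------------------------------------------
# Frame schedules
# ---------------------------------------------------------------------------


@dataclass
class FrameSchedule:
    """Dynamic framing: (count, duration s) groups plus a discard interval."""

    frames: list[tuple[int, float]]
    discard_s: float = 0.0

    def __post_init__(self) -> None:
        for count, dur in self.frames:
            if count < 1:
                raise ValueError(f"frame count must be >= 1, got {count}")
            if dur <= 0:
                raise ValueError(f"frame duration must be positive, got {dur}")

    @property
    def n_frames(self) -> int:
        return sum(c for c, _ in self.frames)

    @property
    def total_duration(self) -> float:
        return float(sum(c * d for c, d in self.frames))

    def boundaries(self) -> np.ndarray:
        """Frame edges in seconds, starting after the discard interval."""
        durs = [d for c, d in self.frames for _ in range(c)]
        return self.discard_s + np.concatenate([[0.0], np.cumsum(durs)])


_FRAME_RE = re.compile(r"^\s*(\d+)\s*x\s*(\d+(?:\.\d+)?)\s*$")


def parse_frame_schedule(text: str, discard_s: float = 0.0) -> FrameSchedule:
    """Parse an ``NxS(,NxS)*`` schedule string, e.g. ``"1x6,6x2,1x452"``."""
    frames = []
    pos = 0
    for part in text.split(","):
        m = _FRAME_RE.match(part)
        if not m:
            raise ValueError(f"malformed frame token {part!r} at position {pos}")
        count, dur = int(m.group(1)), float(m.group(2))
        if count < 1 or dur <= 0:
            raise ValueError(f"invalid frame token {part!r} at position {pos}")
        frames.append((count, dur))
        pos += len(part) + 1
    return FrameSchedule(frames, discard_s)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def write_volume(vol: VoxelGrid, path) -> None:
    """Write NIfTI (.nii/.nii.gz) or raw float32 + YAML sidecar."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        affine = np.diag(list(vol.voxel_size) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
        nib.save(img, str(path))
        return
    if path.suffix == ".raw":
        np.asarray(vol.values, dtype=np.float32).tofile(path)
        sidecar = {
            "shape": list(vol.shape),
            "voxel_size_mm": list(vol.voxel_size),
            "origin_mm": list(vol.origin),
            "kind": vol.kind,
            "dtype": "float32",
        }
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh)
        return
    raise ValueError(f"unsupported volume format {path.suffix!r}")


def read_volume(path) -> VoxelGrid:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        affine = img.affine
        vs = tuple(float(affine[i, i]) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return VoxelGrid(np.asarray(img.dataobj, dtype=np.float32), vs, origin, "value")
    if path.suffix == ".raw":
        with open(path.with_suffix(".yaml")) as fh:
            sc = yaml.safe_load(fh)
        shape = tuple(sc["shape"])
        data = np.fromfile(path, dtype=np.float32)
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"raw file holds {data.size} values but sidecar shape {shape} "
                f"needs {int(np.prod(shape))}"
            )
        return VoxelGrid(
            data.reshape(shape),
            tuple(sc["voxel_size_mm"]),
            tuple(sc["origin_mm"]),
            sc.get("kind", "value"),
        )
    raise ValueError(f"unsupported volume format {path.suffix!r}")


def write_sinogram(proj: ProjectionData, path) -> None:
    path = Path(path)
    np.asarray(proj.values, dtype=np.float32).tofile(path)
    geom = proj.geometry
    sidecar = {
        "angles_rad": [float(a) for a in geom.angles],
        "n_radial": geom.n_radial,
        "radial_spacing_mm": geom.radial_spacing,
        "image_shape": list(geom.image_shape),
        "voxel_size_mm": geom.voxel_size,
        "subsets": [[int(i) for i in s] for s in proj.subsets],
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_sinogram(path) -> ProjectionData:
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        sc = yaml.safe_load(fh)
    geom = ProjectionGeometry(
        np.asarray(sc["angles_rad"]),
        sc["n_radial"],
        sc["radial_spacing_mm"],
        tuple(sc["image_shape"]),
        sc["voxel_size_mm"],
    )
    data = np.fromfile(path, dtype=np.float32)
    if data.size != int(np.prod(geom.sino_shape)):
        raise ValueError("raw sinogram size does not match sidecar geometry")
    subsets = [np.asarray(s) for s in sc["subsets"]]
    return ProjectionData(data.reshape(geom.sino_shape).astype(float), geom, subsets)


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Full phantom -> simulate -> reconstruct -> report pipeline settings."""

    phantom: str = "nema"  # nema | cardiac | rat
    voxel_size: float = 0.5
    shape: tuple[int, int, int] | None = None
    n_angles: int = 96
    total_counts: float = 1e6
    seed: int | None = None
    prc_truth_mode: str = "variant"
    detector_fwhm_mm: float = 1.6
    recon: ReconConfig = field(default_factory=ReconConfig)
    mc_decays: int = 200_000
    out_dir: str = "petprc-run"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        recon = ReconConfig(**raw.pop("recon", {}))
        if "shape" in raw and raw["shape"] is not None:
            raw["shape"] = tuple(raw["shape"])
        return cls(recon=recon, **raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "recon"}
        d["shape"] = list(self.shape) if self.shape else None
        d["recon"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.recon.__dict__.items()
        }
        return d


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Re-running with an identical config reproduces every stochastic
    output bitwise (one seed threads through simulation).
    """
    if config.seed is None:
        raise ValueError("config must carry a seed for the stochastic stages")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "phantom"
    try:
        if config.phantom == "nema":
            activity, density, rois = gen_nema_nu4(config.voxel_size, config.shape)
        elif config.phantom == "cardiac":
            activity, density, _ = gen_cardiac(config.voxel_size, config.shape)
            rois = None
        elif config.phantom == "rat":
            activity, density = gen_rat_thorax(config.voxel_size, shape=config.shape)
            rois = None
        else:
            raise ValueError(f"unknown phantom {config.phantom!r}")
        write_volume(activity, out / "activity.nii.gz")
        write_volume(density, out / "density.nii.gz")

        stage = "simulate"
        params = rb82_water_params(config.mc_decays)
        geom = ProjectionGeometry.for_grid(activity, config.n_angles)
        proj = simulate_acquisition(
            activity,
            density,
            params,
            config.prc_truth_mode,
            geom,
            config.total_counts,
            config.seed,
            detector_fwhm_mm=config.detector_fwhm_mm,
            n_subsets=config.recon.subsets,
        )
        write_sinogram(proj, out / "sinogram.raw")

        stage = "reconstruct"
        seg = segment_density(density, config.recon.td_levels)
        att = attenuation_factors(density, geom)
        result = osem(
            proj,
            geom,
            config.recon,
            seg=seg,
            params=params,
            density=density,
            attenuation=att,
            snapshot_iters=[config.recon.iterations],
        )
        write_volume(result.final, out / "recon.nii.gz")

        stage = "metrics"
        report = None
        if rois is not None:
            rep = nema_report(result.final, rois, config.recon.iterations)
            lines = ["iteration,metric,value,sd"]
            lines.append(f"{rep.iteration},pct_sd,{rep.pct_sd:.6g},")
            lines.append(f"{rep.iteration},sor_air,{rep.sor_air:.6g},{rep.sor_air_sd:.6g}")
            lines.append(f"{rep.iteration},sor_water,{rep.sor_water:.6g},{rep.sor_water_sd:.6g}")
            for d in sorted(rep.rc):
                lines.append(f"{rep.iteration},rc_{d}mm,{rep.rc[d]:.6g},{rep.rc_sd[d]:.6g}")
            (out / "nema_report.csv").write_text("\n".join(lines) + "\n")
            report = rep
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "petprc_version": __version__,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return {"manifest": manifest, "report": report, "out_dir": str(out)}
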