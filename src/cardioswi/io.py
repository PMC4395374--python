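"""File formats, run configuration and the end-to-end pipeline.

Interchange conventions: complex echo series travel either in the phantom's
self-describing ``.npz`` container (k-space with embedded echo-time table
and spec snapshot) or as paired real/imaginary NIfTI volumes with a JSON
echo-time sidecar.  All real-valued image products are written as float32
NIfTI with echoes (or averages) along the third axis; ROI sets as an
integer-label NIfTI plus a JSON name-to-label map.  Every pipeline run
writes a provenance record (config hash, seed, package version) next to its
outputs and is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

import cardioswi
from cardioswi.echo_combine import te_average_sweep
from cardioswi.mapping import segment_t2star
from cardioswi.metrics import sweep_report
from cardioswi.phantom import KSpaceSeries, PhantomSpec, TissueParams, phantom_rois, simulate_kspace
from cardioswi.recon import EchoSeries, HpfFilterSpec, hpf_phase, reconstruct, sos_magnitude
from cardioswi.rois import RoiSet
from cardioswi.swi import swi_series

logger = logging.getLogger("cardioswi")

__all__ = [
    "RunConfig",
    "load_config",
    "phantom_spec_from_dict",
    "save_kspace",
    "load_kspace",
    "write_complex_series",
    "read_complex_series",
    "write_stack",
    "read_stack",
    "write_rois",
    "read_rois",
    "run_pipeline",
]


# ---------------------------------------------------------------- containers

def _affine(pixel_size: float = 1.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_size
    return aff


def save_kspace(path: str | Path, k: KSpaceSeries, spec: PhantomSpec | None = None) -> Path:
    """Write k-space to a self-describing .npz (data, echo table, spec snapshot)."""
    path = Path(path)
    extras = {}
    if spec is not None:
        extras["spec_json"] = json.dumps(_spec_to_dict(spec))
    np.savez(path, data=k.data, echo_times=k.echo_times, coil_ids=np.array(k.coil_ids), **extras)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_kspace(path: str | Path) -> KSpaceSeries:
    with np.load(path, allow_pickle=False) as z:
        if "echo_times" not in z:
            raise ValueError(f"{path}: container has no echo-time table")
        return KSpaceSeries(data=z["data"], echo_times=z["echo_times"], coil_ids=list(z["coil_ids"]))


def write_complex_series(out_dir: str | Path, es: EchoSeries, pixel_size: float = 1.0) -> Path:
    """Paired real/imag NIfTI (echo, coil collapsed on 4th axis) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # axes (row, col, echo, coil) on disk: NIfTI convention puts space first
    arr = np.moveaxis(es.data, (0, 1), (2, 3))
    aff = _affine(pixel_size)
    nib.save(nib.Nifti1Image(arr.real.astype(np.float32), aff), out_dir / "real.nii")
    nib.save(nib.Nifti1Image(arr.imag.astype(np.float32), aff), out_dir / "imag.nii")
    (out_dir / "echoes.json").write_text(json.dumps({"echo_times_ms": es.echo_times.tolist()}))
    return out_dir


def read_complex_series(path: str | Path) -> EchoSeries:
    """Read an EchoSeries from a .npz k-space container or a NIfTI pair directory.

    K-space containers are reconstructed to image space on load.  Echo times
    are validated and, if stored unsorted, sorted ascending with the data
    reordered to match (logged at INFO).
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        return reconstruct(load_kspace(path))
    if not (path / "echoes.json").exists():
        raise ValueError(f"{path}: missing echoes.json sidecar with the echo-time table")
    sidecar = json.loads((path / "echoes.json").read_text())
    echo_times = np.asarray(sidecar["echo_times_ms"], dtype=float)
    real = np.asarray(nib.load(path / "real.nii").dataobj)
    imag = np.asarray(nib.load(path / "imag.nii").dataobj)
    if real.shape != imag.shape:
        raise ValueError(f"real/imag volume shapes differ: {real.shape} vs {imag.shape}")
    data = np.moveaxis(real + 1j * imag, (2, 3), (0, 1))
    if data.shape[0] != len(echo_times):
        raise ValueError(
            f"sidecar lists {len(echo_times)} echoes but volume holds {data.shape[0]}"
        )
    if np.any(np.diff(echo_times) < 0):
        order = np.argsort(echo_times, kind="stable")
        logger.info("echo table stored unsorted; reordering echoes ascending")
        echo_times, data = echo_times[order], data[order]
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: complex series contains NaN/Inf")
    return EchoSeries(data=data, echo_times=echo_times)


def write_stack(path: str | Path, stack: np.ndarray, pixel_size: float = 1.0,
                description: str = "") -> Path:
    """Real-valued (echo, row, col) stack as float32 NIfTI, echoes on axis 3."""
    path = Path(path)
    arr = np.moveaxis(np.asarray(stack, dtype=np.float32), 0, 2)
    img = nib.Nifti1Image(arr, _affine(pixel_size))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, path)
    return path


def read_stack(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(path).dataobj, dtype=float)
    return np.moveaxis(arr, 2, 0) if arr.ndim == 3 else arr


def write_rois(out_dir: str | Path, rois: RoiSet, pixel_size: float = 1.0) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels, name_map = rois.to_labels(order=rois.names())
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(pixel_size)), out_dir / "rois.nii")
    (out_dir / "rois.json").write_text(json.dumps(name_map))
    return out_dir


def read_rois(path: str | Path) -> RoiSet:
    path = Path(path)
    labels = np.asarray(nib.load(path / "rois.nii").dataobj)
    name_map = json.loads((path / "rois.json").read_text())
    return RoiSet.from_labels(labels, name_map)


# ------------------------------------------------------------- configuration

def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["echo_times"] = spec.echo_times.tolist()
    return d


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    """Build a PhantomSpec from a config mapping; unknown keys are rejected."""
    d = dict(d)
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
    if "tissues" in d:
        d["tissues"] = {name: TissueParams(**params) for name, params in d["tissues"].items()}
    for key in ("grid_shape", "lv_center", "lesion_center"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomSpec(**d)


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Either ``phantom`` (simulate) or ``input_path`` (existing k-space
    container) must be given.
    """

    phantom: PhantomSpec | None = None
    input_path: str | None = None
    hpf_n_points: int = 64
    n_multiplies: tuple[int, ...] = (3, 6)
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if self.phantom is None and self.input_path is None:
            raise ValueError("config must provide either 'phantom' or 'input_path'")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input path does not exist: {self.input_path}")
        if self.extra:
            raise ValueError(f"unknown config keys: {sorted(self.extra)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"phantom", "input_path", "hpf_n_points", "n_multiplies", "seed", "log_level"}
    extra = {k: v for k, v in raw.items() if k not in known}
    cfg = RunConfig(
        phantom=phantom_spec_from_dict(raw["phantom"]) if "phantom" in raw else None,
        input_path=raw.get("input_path"),
        hpf_n_points=int(raw.get("hpf_n_points", 64)),
        n_multiplies=tuple(raw.get("n_multiplies", (3, 6))),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        extra=extra,
    )
    cfg.validate()
    return cfg


# ------------------------------------------------------------------ pipeline

def _config_digest(cfg: RunConfig) -> str:
    payload = {
        "phantom": _spec_to_dict(cfg.phantom) if cfg.phantom else None,
        "input_path": cfg.input_path,
        "hpf_n_points": cfg.hpf_n_points,
        "n_multiplies": list(cfg.n_multiplies),
        "seed": cfg.seed,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Simulate (optional) -> reconstruct -> HPF phase -> SWI -> sweep -> T2*/metrics.

    Writes magnitude/phase/SWI stacks, the contrast/SDNR sweep table, the
    per-sector T2* table, ROI labels and a provenance record into
    ``out_dir``.  Deterministic given the config and seed.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    if cfg.phantom is not None:
        spec = cfg.phantom.with_(seed=cfg.seed)
        logger.info("simulating phantom k-space (grid %s, %d coils)", spec.grid_shape, spec.n_coils)
        k = simulate_kspace(spec)
        save_kspace(out_dir / "kspace.npz", k, spec=spec)
        rois = phantom_rois(spec)
        pixel_size = spec.pixel_size
    else:
        k = load_kspace(cfg.input_path)
        rois = None
        pixel_size = 1.0

    logger.info("reconstructing %d echoes x %d coils", k.n_echoes, k.n_coils)
    es = reconstruct(k)
    fspec = HpfFilterSpec(n_points=cfg.hpf_n_points)
    mag = sos_magnitude(es)
    phase, valid = hpf_phase(es, fspec)
    write_stack(out_dir / "magnitude.nii", mag, pixel_size, "SOS magnitude")
    write_stack(out_dir / "hpf_phase.nii", phase, pixel_size, f"HPF phase N={cfg.hpf_n_points}")

    swi_stacks = {}
    for n in cfg.n_multiplies:
        label = f"swi{n}"
        swi_stacks[label] = swi_series(mag, phase, n_multiplies=n, valid=valid)
        write_stack(out_dir / f"{label}.nii", swi_stacks[label], pixel_size, f"SWI n_multiplies={n}")
        for avg in te_average_sweep(swi_stacks[label], es.echo_times, source_kind=label):
            write_stack(out_dir / f"{label}_nte{avg.n_te:02d}.nii", avg.data[None],
                        pixel_size, f"{label} TE-averaged nTE={avg.n_te}")

    if rois is not None:
        write_rois(out_dir, rois, pixel_size)
        logger.info("computing contrast/SDNR sweep and sector T2*")
        report = sweep_report(mag, swi_stacks, rois, echo_times=es.echo_times, valid=valid)
        report.to_csv(out_dir / "sweep_metrics.csv", index=False)
        from cardioswi.mapping import aha_sectors  # local import avoids cycle at module load

        sectors = aha_sectors(rois["lv_myocardium"], rv_insertion_angle=np.pi / 3, level="mid")
        segment_t2star(mag, es.echo_times, sectors).to_csv(out_dir / "t2star_sectors.csv", index=False)

    provenance = {
        "package": "cardioswi",
        "version": cardioswi.__version__,
        "config_digest": _config_digest(cfg),
        "seed": cfg.seed,
        "n_echoes": int(k.n_echoes),
        "n_coils": int(k.n_coils),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out_dir
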