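"""Configuration and artifact persistence.

Run configuration lives in a YAML/JSON mapping with SI units in field names;
array containers are HDF5 with embedded metadata (config hash, seed); spectra
and waveforms export to plain two-column / per-ring CSV text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .acoustic import AcousticMedium, PressureRecordSet, SensorGeometry
from .comb import CombSpec
from .interrogation import NoiseSpec, PAWaveformSet, Spectrogram
from .reconstruct import ImageGrid
from .ring_array import RingArraySpec, RingResonance

__all__ = [
    "load_config",
    "config_hash",
    "array_from_config",
    "array_to_config",
    "comb_from_config",
    "medium_from_config",
    "geometry_from_config",
    "noise_from_config",
    "save_records",
    "load_records",
    "save_waveforms_csv",
    "load_waveforms_csv",
    "save_spectrum_txt",
    "save_image",
    "load_image",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, embedded in every artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(cfg: dict, key: str, context: str):
    if key not in cfg:
        raise KeyError(f"missing config field {context}.{key}")
    return cfg[key]


def array_from_config(cfg: dict) -> RingArraySpec:
    """Build a ring array from config: either an explicit per-ring list or an
    assign-resonances style block (n_rings/spacing_hz/band_hz)."""
    from .ring_array import assign_resonances

    if "rings" in cfg:
        rings = [
            RingResonance(
                center_offset_hz=float(_require(r, "center_offset_hz", f"rings[{i}]")),
                q_factor=float(r.get("q_factor", 6e5)),
                dip_depth=float(r.get("dip_depth", 0.9)),
                sensitivity_hz_per_pa=float(r.get("sensitivity_hz_per_pa", 1e5)),
                label=int(r.get("label", i + 1)),
            )
            for i, r in enumerate(cfg["rings"])
        ]
        return RingArraySpec(
            rings=rings,
            optical_carrier_hz=float(cfg.get("optical_carrier_hz", RingArraySpec.optical_carrier_hz)),
            spacing_hz=float(cfg.get("spacing_hz", 1.66e9)),
        )
    band = cfg.get("band_hz", (-20e9, 20e9))
    return assign_resonances(
        int(_require(cfg, "n_rings", "array")),
        float(cfg.get("spacing_hz", 1.66e9)),
        (float(band[0]), float(band[1])),
        q_factor=float(cfg.get("q_factor", 6e5)),
        dip_depth=float(cfg.get("dip_depth", 0.9)),
        sensitivity_hz_per_pa=float(cfg.get("sensitivity_hz_per_pa", 1e5)),
    )


def array_to_config(array: RingArraySpec) -> dict:
    return {
        "optical_carrier_hz": array.optical_carrier_hz,
        "spacing_hz": array.spacing_hz,
        "rings": [
            {
                "center_offset_hz": r.center_offset_hz,
                "q_factor": r.q_factor,
                "dip_depth": r.dip_depth,
                "sensitivity_hz_per_pa": r.sensitivity_hz_per_pa,
                "label": r.label,
            }
            for r in array.rings
        ],
    }


def comb_from_config(cfg: dict) -> CombSpec:
    return CombSpec(
        n_subcarriers=int(cfg.get("n_subcarriers", 1536)),
        dac_rate_hz=float(cfg.get("dac_rate_hz", 60e9)),
        bandwidth_hz=float(cfg.get("bandwidth_hz", 40e9)),
        phase_schedule=cfg.get("phase_schedule", "random"),
        phase_seed=int(cfg.get("phase_seed", 20230605)),
        carrier_suppressed=bool(cfg.get("carrier_suppressed", True)),
    )


def medium_from_config(cfg: dict) -> AcousticMedium:
    return AcousticMedium(
        sound_speed_m_per_s=float(cfg.get("sound_speed_m_per_s", 1500.0)),
        attenuation_db_per_cm_mhz=float(cfg.get("attenuation_db_per_cm_mhz", 0.0)),
        attenuation_exponent=float(cfg.get("attenuation_exponent", 1.0)),
    )


def geometry_from_config(cfg: dict) -> SensorGeometry:
    from .acoustic import linear_array_geometry

    mode = cfg.get("mode", "static")
    kwargs = {}
    if mode == "rotational":
        if "rotation_angles_deg" in cfg:
            kwargs["rotation_angles_deg"] = np.asarray(cfg["rotation_angles_deg"], float)
        else:
            step = float(cfg.get("rotation_step_deg", 1.0))
            kwargs["rotation_angles_deg"] = np.arange(0.0, 360.0, step)
    elif mode == "linear_scan":
        if "scan_offsets_m" in cfg:
            kwargs["scan_offsets_m"] = np.asarray(cfg["scan_offsets_m"], float)
        else:
            half = float(cfg.get("scan_range_m", 8e-3))
            step = float(cfg.get("scan_step_m", 20e-6))
            kwargs["scan_offsets_m"] = np.arange(-half, half + step / 2, step)
    return linear_array_geometry(
        n_sensors=int(cfg.get("n_sensors", 15)),
        pitch_m=float(cfg.get("pitch_m", 400e-6)),
        standoff_m=float(cfg.get("standoff_m", 5e-3)),
        mode=mode,
        **kwargs,
    )


def noise_from_config(cfg: dict, seed: int | None = None) -> NoiseSpec:
    from .interrogation import DEFAULT_RECEIVER_NOISE_DENSITY

    return NoiseSpec(
        receiver_noise_density=float(
            cfg.get("receiver_noise_density", DEFAULT_RECEIVER_NOISE_DENSITY)
        ),
        seed=int(cfg.get("seed", seed if seed is not None else 0)),
        nep_target_pa_per_sqrt_hz=cfg.get("nep_target_pa_per_sqrt_hz"),
    )


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------


def _write_provenance(group, metadata: dict | None) -> None:
    for k, v in (metadata or {}).items():
        try:
            group.attrs[k] = v
        except TypeError:
            group.attrs[k] = json.dumps(v, default=str)


def save_records(path: str | Path, records: PressureRecordSet, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times_s", data=records.times_s)
        f.create_dataset("pressures_pa", data=records.pressures_pa)
        g = f.create_group("geometry")
        g.create_dataset("positions_m", data=records.geometry.positions_m)
        g.attrs["mode"] = records.geometry.mode
        g.attrs["normal"] = records.geometry.normal
        g.attrs["rotation_center_m"] = records.geometry.rotation_center_m
        if records.geometry.rotation_angles_deg is not None:
            g.create_dataset("rotation_angles_deg", data=records.geometry.rotation_angles_deg)
        if records.geometry.scan_offsets_m is not None:
            g.create_dataset("scan_offsets_m", data=records.geometry.scan_offsets_m)
        m = f.create_group("medium")
        m.attrs["sound_speed_m_per_s"] = records.medium.sound_speed_m_per_s
        m.attrs["attenuation_db_per_cm_mhz"] = records.medium.attenuation_db_per_cm_mhz
        m.attrs["attenuation_exponent"] = records.medium.attenuation_exponent
        _write_provenance(f, {**records.metadata, **(metadata or {})})


def load_records(path: str | Path) -> PressureRecordSet:
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        geometry = SensorGeometry(
            positions_m=g["positions_m"][()],
            mode=g.attrs["mode"],
            rotation_angles_deg=g["rotation_angles_deg"][()] if "rotation_angles_deg" in g else None,
            scan_offsets_m=g["scan_offsets_m"][()] if "scan_offsets_m" in g else None,
            normal=tuple(g.attrs["normal"]),
            rotation_center_m=tuple(g.attrs["rotation_center_m"]),
        )
        m = f["medium"]
        medium = AcousticMedium(
            sound_speed_m_per_s=float(m.attrs["sound_speed_m_per_s"]),
            attenuation_db_per_cm_mhz=float(m.attrs["attenuation_db_per_cm_mhz"]),
            attenuation_exponent=float(m.attrs["attenuation_exponent"]),
        )
        return PressureRecordSet(
            times_s=f["times_s"][()],
            pressures_pa=f["pressures_pa"][()],
            geometry=geometry,
            medium=medium,
            metadata=dict(f.attrs),
        )


def save_spectrogram(path: str | Path, sg: Spectrogram, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("freq_offsets_hz", data=sg.freq_offsets_hz)
        f.create_dataset("times_s", data=sg.times_s)
        f.create_dataset("transmission", data=sg.transmission)
        _write_provenance(f, metadata)


def load_spectrogram(path: str | Path) -> Spectrogram:
    with h5py.File(path, "r") as f:
        return Spectrogram(
            freq_offsets_hz=f["freq_offsets_hz"][()],
            times_s=f["times_s"][()],
            transmission=f["transmission"][()],
        )


# ---------------------------------------------------------------------------
# Text exports
# ---------------------------------------------------------------------------


def save_spectrum_txt(path: str | Path, freq_hz: np.ndarray, values: np.ndarray) -> None:
    """Two-column text export (frequency Hz, value)."""
    np.savetxt(path, np.column_stack([freq_hz, values]), header="freq_hz value")


def save_waveforms_csv(path: str | Path, waves: PAWaveformSet) -> None:
    """Per-ring pressure waveforms: time column plus one column per ring."""
    cols = [waves.times_s] + [waves.pressures_pa[:, i] for i in range(waves.pressures_pa.shape[1])]
    header = "time_s," + ",".join(f"ring_{lab}_pa" for lab in waves.ring_labels)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")


def load_waveforms_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Returns (times_s, pressures (n_samples, n_rings), ring labels)."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    labels = [int(h.split("_")[1]) for h in header[1:]]
    return data[:, 0], data[:, 1:], labels


def save_image(path: str | Path, image: ImageGrid, metadata: dict | None = None) -> None:
    """Write an image grid: .tiff (32-bit float raster) or .h5 (full metadata)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.values.astype(np.float32))
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=image.values)
        f.attrs["origin_m"] = image.origin_m
        f.attrs["pixel_size_m"] = image.pixel_size_m
        _write_provenance(f, {**image.metadata, **(metadata or {})})


def load_image(path: str | Path) -> ImageGrid:
    with h5py.File(path, "r") as f:
        vals = f["values"][()]
        return ImageGrid(
            origin_m=tuple(f.attrs["origin_m"]),
            pixel_size_m=float(f.attrs["pixel_size_m"]),
            shape=vals.shape,
            values=vals,
            metadata={
                k: v for k, v in f.attrs.items() if k not in ("origin_m", "pixel_size_m")
            },
        )
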