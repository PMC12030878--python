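"""HDF5 dataset archive for simulated samples.

One group per sample holds the retina field, the normalized input/reference
spectra with their mask and scaling records, the reference contrast map and
contour, the phantom labels of the observation slice, and the split tag.
Geometry attributes live at the root.  Writing disables HDF5 timestamps so
that identical content yields identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np

from .geometry import CameraGeometry
from .phantoms import PhantomConfig
from .scaling import NormalizedPair, ScaleRecord

_CONFIG_FIELDS = (
    "fat_id",
    "gland_id",
    "tumor_case",
    "mirror",
    "rotation",
    "n_rotations",
    "jitter_seed",
    "family",
)


@dataclass
class Sample:
    """One simulated database entry."""

    config: PhantomConfig
    field: np.ndarray
    pair: NormalizedPair
    contrast: np.ndarray
    contour: np.ndarray
    labels_slice: np.ndarray
    split: str = ""
    snr_db: Optional[float] = None


def _write_record(grp, name: str, rec: ScaleRecord) -> None:
    grp.attrs[f"{name}_re_min"] = rec.re_min
    grp.attrs[f"{name}_re_max"] = rec.re_max
    grp.attrs[f"{name}_im_min"] = rec.im_min
    grp.attrs[f"{name}_im_max"] = rec.im_max
    grp.attrs[f"{name}_spectral_max"] = (
        rec.spectral_max if rec.spectral_max is not None else np.nan
    )


def _read_record(grp, name: str) -> ScaleRecord:
    smax = float(grp.attrs[f"{name}_spectral_max"])
    return ScaleRecord(
        float(grp.attrs[f"{name}_re_min"]),
        float(grp.attrs[f"{name}_re_max"]),
        float(grp.attrs[f"{name}_im_min"]),
        float(grp.attrs[f"{name}_im_max"]),
        None if np.isnan(smax) else smax,
    )


def save_dataset(
    path, samples: Sequence[Sample], geometry: CameraGeometry | None = None
) -> None:
    geometry = geometry or CameraGeometry()
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["frequency"] = geometry.frequency
        f.attrs["eps_water"] = geometry.eps_water
        f.attrs["sigma_water"] = geometry.sigma_water
        f.attrs["distance"] = geometry.distance
        f.attrs["n_retina"] = geometry.n_retina
        for i, s in enumerate(samples):
            grp = f.create_group(f"samples/{i:05d}", track_order=True)
            for name, arr in (
                ("field", s.field),
                ("j_norm", s.pair.j_norm),
                ("c_norm", s.pair.c_norm),
                ("mask", s.pair.mask),
                ("contrast", s.contrast),
                ("contour", s.contour),
                ("labels_slice", s.labels_slice),
            ):
                grp.create_dataset(name, data=arr, track_times=False)
            for fname in _CONFIG_FIELDS:
                grp.attrs[fname] = getattr(s.config, fname)
            grp.attrs["split"] = s.split
            grp.attrs["snr_db"] = np.nan if s.snr_db is None else s.snr_db
            _write_record(grp, "j_scale", s.pair.j_scale)
            _write_record(grp, "c_scale", s.pair.c_scale)


def load_dataset(path):
    """Read samples and geometry back; bit-faithful round trip."""
    samples: List[Sample] = []
    with h5py.File(path, "r") as f:
        geometry = CameraGeometry(
            frequency=float(f.attrs["frequency"]),
            eps_water=float(f.attrs["eps_water"]),
            sigma_water=float(f.attrs["sigma_water"]),
            n_retina=int(f.attrs["n_retina"]),
            distance=float(f.attrs["distance"]),
        )
        for key in sorted(f["samples"]):
            grp = f["samples"][key]
            kwargs = {name: grp.attrs[name] for name in _CONFIG_FIELDS}
            kwargs["fat_id"] = int(kwargs["fat_id"])
            kwargs["gland_id"] = int(kwargs["gland_id"])
            kwargs["tumor_case"] = int(kwargs["tumor_case"])
            kwargs["mirror"] = bool(kwargs["mirror"])
            kwargs["rotation"] = int(kwargs["rotation"])
            kwargs["n_rotations"] = int(kwargs["n_rotations"])
            kwargs["jitter_seed"] = int(kwargs["jitter_seed"])
            kwargs["family"] = str(kwargs["family"])
            config = PhantomConfig(**kwargs)
            pair = NormalizedPair(
                j_norm=grp["j_norm"][()],
                c_norm=grp["c_norm"][()],
                mask=grp["mask"][()].astype(bool),
                j_scale=_read_record(grp, "j_scale"),
                c_scale=_read_record(grp, "c_scale"),
                contour=grp["contour"][()].astype(bool),
            )
            snr = float(grp.attrs["snr_db"])
            samples.append(
                Sample(
                    config=config,
                    field=grp["field"][()],
                    pair=pair,
                    contrast=grp["contrast"][()],
                    contour=grp["contour"][()].astype(bool),
                    labels_slice=grp["labels_slice"][()],
                    split=str(grp.attrs["split"]),
                    snr_db=None if np.isnan(snr) else snr,
                )
            )
    return samples, geometry
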