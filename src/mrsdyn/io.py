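"""Cohort HDF5 layout and CSV result tables.

Cohort files hold one group per subject with paired real/imaginary arrays
(n_transients x n_points), a condition-label array, and root attributes with
the acquisition parameters.  Tissue fractions are stored as subject
attributes; for synthetic cohorts a structured-text sidecar
(``<path>.truth.json``) carries the generating ground truth and the realised
latent series so recovery tests can compare against them.

All CSV tables are written with a ``# columns:`` header comment declaring
the schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import AcquisitionProfile, Cohort, GroundTruth

__all__ = ["write_cohort", "read_cohort", "write_csv", "truth_sidecar_path"]

_FORMAT_VERSION = 1


def truth_sidecar_path(path) -> Path:
    return Path(str(path) + ".truth.json")


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to HDF5 (plus a ground-truth sidecar if synthetic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prof = cohort.profile
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["profile_name"] = prof.name
        f.attrs["n_transients"] = prof.n_transients
        f.attrs["tr_s"] = prof.tr_s
        f.attrs["n_points"] = prof.n_points
        f.attrs["sweep_hz"] = prof.sweep_hz
        f.attrs["larmor_mhz"] = prof.larmor_mhz
        f.attrs["residual_water"] = bool(prof.residual_water)
        cond = np.where(cohort.is_on, b"ON", b"OFF")
        subjects = f.create_group("subjects")
        tf = cohort.tissue_fractions
        for s, sid in enumerate(cohort.subject_ids):
            g = subjects.create_group(str(sid))
            g.create_dataset("real", data=cohort.spectra[s].real)
            g.create_dataset("imag", data=cohort.spectra[s].imag)
            g.create_dataset("condition", data=cond)
            for col in ("gm", "wm", "csf"):
                g.attrs[col] = float(tf[col].iloc[s])

    if cohort.truth is not None:
        sidecar = {
            "ground_truth": cohort.truth.to_dict(),
            "tissue_fractions": {
                str(sid): [float(tf[c].iloc[s]) for c in ("gm", "wm", "csf")]
                for s, sid in enumerate(cohort.subject_ids)
            },
        }
        if cohort.latents is not None:
            sidecar["latents"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else
                    {m: a.tolist() for m, a in v.items()} if isinstance(v, dict) else v)
                for k, v in cohort.latents.items()
            }
        truth_sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _require(obj, key, path, kind):
    if key not in obj:
        raise ValueError(f"{path}: missing {kind} {key!r}")
    return obj[key]


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        attrs = f.attrs
        for key in ("profile_name", "n_transients", "tr_s", "n_points",
                    "sweep_hz", "larmor_mhz"):
            _require(attrs, key, path, "attribute")
        profile = AcquisitionProfile(
            name=str(attrs["profile_name"]),
            n_transients=int(attrs["n_transients"]),
            tr_s=float(attrs["tr_s"]),
            n_points=int(attrs["n_points"]),
            sweep_hz=float(attrs["sweep_hz"]),
            larmor_mhz=float(attrs["larmor_mhz"]),
            residual_water=bool(attrs.get("residual_water", False)),
        )
        subjects = _require(f, "subjects", path, "group")
        ids = sorted(subjects.keys())
        if not ids:
            raise ValueError(f"{path}: no subjects")
        spectra = None
        is_on = None
        tissue = []
        for s, sid in enumerate(ids):
            g = subjects[sid]
            re = _require(g, "real", f"{path}:{sid}", "dataset")[()]
            im = _require(g, "imag", f"{path}:{sid}", "dataset")[()]
            cond = _require(g, "condition", f"{path}:{sid}", "dataset")[()]
            if spectra is None:
                spectra = np.empty(
                    (len(ids),) + re.shape,
                    dtype=np.complex64 if re.dtype == np.float32 else np.complex128,
                )
                is_on = np.array([c == b"ON" for c in cond])
            spectra[s] = re + 1j * im
            for col in ("gm", "wm", "csf"):
                _require(g.attrs, col, f"{path}:{sid}", "attribute")
            tissue.append([g.attrs["gm"], g.attrs["wm"], g.attrs["csf"]])

    truth = None
    latents = None
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        truth = GroundTruth.from_dict(data["ground_truth"])
        lat = data.get("latents")
        if lat is not None:
            latents = {
                k: (np.asarray(v) if isinstance(v, list) else
                    {m: np.asarray(a) for m, a in v.items()} if isinstance(v, dict)
                    else v)
                for k, v in lat.items()
            }

    return Cohort(
        profile=profile,
        spectra=spectra,
        is_on=is_on,
        subject_ids=ids,
        tissue_fractions=pd.DataFrame(tissue, columns=["gm", "wm", "csf"]),
        truth=truth,
        latents=latents,
    )


def write_csv(df: pd.DataFrame, path, description: str = "") -> Path:
    """Write a result table with a schema header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if description:
            fh.write(f"# {description}\n")
        fh.write(f"# columns: {', '.join(df.columns)}\n")
        df.to_csv(fh, index=False)
    return path
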