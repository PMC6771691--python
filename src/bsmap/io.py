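"""NIfTI + sidecar-JSON dataset I/O and YAML configuration handling.

Dataset layout (one directory):

* ``mag_plus.nii.gz`` / ``phase_plus.nii.gz`` — 4D volumes, echoes along
  the 4th axis, for the positive-offset acquisition; ``*_minus`` for the
  negative one.  Phase stored as float32 rad wrapped to (−π, π];
  integer phase input is converted using NIfTI scl slope/intercept.
* ``meta.json`` — sidecar with ``EchoTimeMs`` (list), ``OffsetSignHz``
  (list of two signed offsets), ``NPrePulseEchoes``.

Affines pass through unchanged; no resampling is performed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .glm import wrap_phase

__all__ = [
    "write_dataset",
    "read_echo_stacks",
    "write_map",
    "load_config",
    "validate_keys",
]


class InputError(ValueError):
    """Invalid or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration; message names the offending field."""


def validate_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return cfg


def write_dataset(
    out_dir: str | Path,
    phases: np.ndarray,
    magnitudes: np.ndarray,
    te_list,
    f_off_hz: float,
    n_pre: int = 2,
    affine: np.ndarray | None = None,
    truth: dict | None = None,
) -> Path:
    """Write a dual-offset multi-echo dataset (and optional truth maps)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phases = np.asarray(phases, dtype=np.float32)
    magnitudes = np.asarray(magnitudes, dtype=np.float32)
    if phases.shape != magnitudes.shape or phases.shape[0] != 2:
        raise InputError("expected (2, n_echo, *vol) phase/magnitude stacks")
    affine = np.eye(4) if affine is None else affine
    for i, tag in enumerate(("plus", "minus")):
        # echoes to the 4th axis
        ph = np.moveaxis(phases[i], 0, -1)
        mg = np.moveaxis(magnitudes[i], 0, -1)
        nib.save(nib.Nifti1Image(ph, affine), out / f"phase_{tag}.nii.gz")
        nib.save(nib.Nifti1Image(mg, affine), out / f"mag_{tag}.nii.gz")
    meta = {
        "EchoTimeMs": [1e3 * float(t) for t in te_list],
        "OffsetSignHz": [abs(float(f_off_hz)), -abs(float(f_off_hz))],
        "NPrePulseEchoes": int(n_pre),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth:
        tdir = out / "truth"
        tdir.mkdir(exist_ok=True)
        for name, vol in truth.items():
            arr = np.asarray(vol, dtype=np.float32)
            if arr.ndim >= 2:
                nib.save(nib.Nifti1Image(arr, affine), tdir / f"{name}.nii.gz")
    return out


def _load4d(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))  # applies scl slope/inter
    if data.ndim == 3:
        data = data[..., None]
    return data, img.affine


def read_echo_stacks(data_dir: str | Path) -> dict:
    """Read a dataset directory; validate geometry and metadata.

    Returns ``phases``/``magnitudes`` of shape ``(2, n_echo, *vol)`` with
    phase wrapped to (−π, π], plus ``te_list`` (s), ``n_pre``,
    ``offset_signs`` and the affine.
    """
    d = Path(data_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise InputError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("EchoTimeMs", "OffsetSignHz", "NPrePulseEchoes"):
        if key not in meta:
            raise InputError(f"sidecar missing required key {key}")
    te = np.asarray(meta["EchoTimeMs"], dtype=float) * 1e-3
    if te.size < 2 or np.any(np.diff(te) <= 0):
        raise InputError("EchoTimeMs must be a strictly increasing list")
    offs = meta["OffsetSignHz"]
    if len(offs) != 2 or not (offs[0] > 0 > offs[1]):
        raise InputError("OffsetSignHz must list a positive then a negative offset")

    vols, affines = {}, {}
    for tag in ("plus", "minus"):
        for kind in ("phase", "mag"):
            p = d / f"{kind}_{tag}.nii.gz"
            if not p.exists():
                p = d / f"{kind}_{tag}.nii"
            if not p.exists():
                raise InputError(f"missing volume {kind}_{tag}.nii(.gz) in {d}")
            vols[(kind, tag)], affines[(kind, tag)] = _load4d(p)

    shapes = {v.shape for v in vols.values()}
    if len(shapes) != 1:
        raise InputError(f"volume shape mismatch across stacks: {sorted(shapes)}")
    ref_aff = affines[("mag", "plus")]
    for k, a in affines.items():
        if not np.allclose(a, ref_aff, atol=1e-4):
            raise InputError(f"affine mismatch in {k[0]}_{k[1]}")
    n_echo = next(iter(shapes))[-1]
    if n_echo != te.size:
        raise InputError(
            f"echo count mismatch: {n_echo} volumes vs {te.size} echo times"
        )

    def stack(kind):
        return np.stack(
            [np.moveaxis(vols[(kind, t)], -1, 0) for t in ("plus", "minus")]
        )

    phases = wrap_phase(stack("phase"))
    mags = stack("mag")
    if np.any(mags < 0):
        raise InputError("negative magnitudes in input")
    return {
        "phases": phases,
        "magnitudes": mags,
        "te_list": te,
        "n_pre": int(meta["NPrePulseEchoes"]),
        "offset_signs": (1, -1),
        "affine": ref_aff,
    }


def write_map(path: str | Path, vol: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
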