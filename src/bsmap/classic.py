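"""Classic subtraction B1+ estimation and map comparison.

The classic method reads the phase of the first echo after the
off-resonance pulse (the third echo here) in the two opposite-offset
acquisitions, halves their difference to get the Bloch-Siegert phase,
and inverts the quadratic phase law for B1+.  Any phase component common
to both offsets cancels in the subtraction; any component that *differs*
between them (the interleave pseudo-steady-state, motion, drift) biases
the estimate — which is precisely what the GLM method is designed to
absorb.
"""

from __future__ import annotations

import numpy as np

from .glm import wrap_phase
from .pulse import BSPulse, BSSPhaseConstant, bss_phase_constant

__all__ = ["estimate_b1_classic", "compare_maps"]


def estimate_b1_classic(
    phase3_plus: np.ndarray,
    phase3_minus: np.ndarray,
    pulse: BSPulse | BSSPhaseConstant,
    mask: np.ndarray | None = None,
    magnitudes: np.ndarray | None = None,
    nominal_b1p: float | None = None,
) -> dict[str, np.ndarray]:
    """B1+ map from the wrapped post-pulse phase pair.

    ``phi_diff = wrap(phase3_plus − phase3_minus)``; Φ_BSS = phi_diff/2
    must land in [0, π): voxels with negative halved phase (offset labels
    swapped, or noise around zero) are masked, and a ``wrap_flag`` marks
    voxels suspiciously close to the wrap boundary.
    """
    phase3_plus = np.asarray(phase3_plus, dtype=float)
    phase3_minus = np.asarray(phase3_minus, dtype=float)
    if phase3_plus.shape != phase3_minus.shape:
        raise ValueError("plus/minus phase volumes must share a shape")
    const = pulse if isinstance(pulse, BSSPhaseConstant) else bss_phase_constant(
        pulse.with_offset_sign(1)
    )
    if mask is None:
        if magnitudes is not None:
            mag = np.asarray(magnitudes, dtype=float)
            mask = mag > 0.05 * np.percentile(mag, 99)
        else:
            mask = np.ones(phase3_plus.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    phi_diff = wrap_phase(phase3_plus - phase3_minus)
    phi_bss = phi_diff / 2.0
    wrap_flag = np.abs(phi_diff) > 0.95 * np.pi
    valid = mask & (phi_bss >= 0)
    k = const.k_bss
    with np.errstate(invalid="ignore"):
        b1p = np.where(valid, np.sqrt(np.clip(phi_bss, 0, None) / k), np.nan)
    out = {
        "b1p_uT": b1p,
        "phi_diff": phi_diff,
        "wrap_flag": wrap_flag,
        "valid": valid,
        "mask": mask,
    }
    if nominal_b1p is None and isinstance(pulse, BSPulse):
        from .pulse import resolved_peak_b1

        nominal_b1p = resolved_peak_b1(pulse)
    if nominal_b1p:
        out["b1_efficiency"] = b1p / nominal_b1p
    return out


def compare_maps(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray | None = None,
    reference: str = "b",
    n_bins: int = 64,
) -> dict:
    """Voxel-wise percent difference between two maps, plus summaries.

    ``reference`` names the denominator side (``"a"`` or ``"b"``); the
    difference is ``100·(a − b)/reference``.  Returns the percent
    difference volume, mean/SD/median/IQR within the mask, and histogram
    (counts, bin edges).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    if mask is None:
        mask = np.isfinite(a) & np.isfinite(b)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(a) & np.isfinite(b)
    if not mask.any():
        raise ValueError("empty mask: no voxels to compare")
    ref = a if reference == "a" else b
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(mask, 100.0 * (a - b) / ref, np.nan)
    vals = pct[mask]
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    counts, edges = np.histogram(vals, bins=n_bins)
    return {
        "percent_diff": pct,
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "median": float(q50),
        "iqr": float(q75 - q25),
        "n": int(vals.size),
        "hist_counts": counts,
        "hist_edges": edges,
    }
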