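"""Multi-echo GLM estimation of the Bloch-Siegert phase and B1+ map.

The dual-offset multi-echo acquisition yields 16 phase images (8 echoes
× 2 off-resonance signs).  Their phase is modeled voxel-wise as a linear
combination of six sources:

``x_bss``
    0 before the off-resonance pulse, ±1 after it (sign of the pulse
    offset) — its coefficient is the Bloch-Siegert phase Φ_BSS.
``x_b0``
    the echo times — coefficient is the local off-resonance 2π·Δf (rad/s).
``x_odd_even``
    +1 / −1 for odd / even echoes (readout-polarity eddy currents).
``x_offset_plus`` / ``x_offset_minus``
    per-offset intercepts; letting the two interleaves carry different
    initial phase is what removes the interleave bias.
``x_same_sign``
    0 before / 1 after the pulse for both offsets (crusher eddy currents
    and the offset-sign-independent part of the pulse phase).

Coefficients are estimated by magnitude-weighted least squares,
β̂ = (XᵀWX)⁻¹XᵀWY, and Φ_BSS = β̂_bss is converted to B1+ through the
pulse's phase constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pulse import BSPulse, BSSPhaseConstant, b1p_from_phase, bss_phase_constant

__all__ = [
    "COLUMN_NAMES",
    "DesignMatrix",
    "FitResult",
    "build_design_matrix",
    "temporal_unwrap",
    "wls_fit",
    "estimate_b1_glm",
    "estimate_b1_from_echoes",
    "wrap_phase",
]

COLUMN_NAMES = (
    "bss",
    "b0",
    "odd_even",
    "offset_plus",
    "offset_minus",
    "same_sign",
)


class IdentifiabilityError(ValueError):
    pass


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


@dataclass(frozen=True)
class DesignMatrix:
    X: np.ndarray                  # (n_rows, 6)
    te_list: np.ndarray            # (n_echo,) seconds
    offset_signs: tuple[int, int]
    n_pre: int

    @property
    def n_echo(self) -> int:
        return self.te_list.size


@dataclass
class FitResult:
    beta: np.ndarray          # (..., 6)
    residual_rms: np.ndarray  # (...,)
    valid: np.ndarray         # (...,) bool
    b1p: np.ndarray | None = None

    def coeff(self, name: str) -> np.ndarray:
        return self.beta[..., COLUMN_NAMES.index(name)]


def build_design_matrix(
    te_list, n_pre: int = 2, offset_signs: tuple[int, int] = (1, -1)
) -> DesignMatrix:
    """Stack the six phase regressors over ``2 × n_echo`` rows.

    Row order: echoes 1..n of the first offset, then 1..n of the second.
    """
    te = np.asarray(te_list, dtype=float)
    n = te.size
    if n_pre < 1:
        raise IdentifiabilityError("need at least one echo before the BS pulse")
    if 2 * n < 6 or n <= n_pre:
        raise IdentifiabilityError("too few echoes for a rank-6 model")
    post = (np.arange(n) >= n_pre).astype(float)
    odd_even = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)  # echo 1 is odd
    blocks = []
    for i, s in enumerate(offset_signs):
        x = np.zeros((n, 6))
        x[:, 0] = s * post
        x[:, 1] = te
        x[:, 2] = odd_even
        x[:, 3] = 1.0 if s > 0 else 0.0
        x[:, 4] = 0.0 if s > 0 else 1.0
        x[:, 5] = post
        blocks.append(x)
    X = np.vstack(blocks)
    if np.linalg.matrix_rank(X) < 6:
        # identify collinear columns by testing each against the rest
        bad = []
        for j in range(6):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(COLUMN_NAMES[j])
        raise IdentifiabilityError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    return DesignMatrix(X=X, te_list=te, offset_signs=tuple(offset_signs), n_pre=n_pre)


def temporal_unwrap(phases: np.ndarray, magnitudes: np.ndarray | None = None) -> np.ndarray:
    """Unwrap phase across echoes via spatially unwrapped echo differences.

    ``phases`` has shape ``(n_offsets, n_echo, *spatial)`` with values in
    (−π, π].  For each offset, the wrapped difference between successive
    echoes is spatially unwrapped and the differences are cumulatively
    added to the first echo's phase, so inter-echo steps larger than π
    are recovered as long as the difference maps are spatially smooth.
    Inputs with no spatial extent (single voxel) fall back to per-voxel
    temporal unwrapping (wrapped differences summed directly).

    Each spatially unwrapped difference map carries an arbitrary global
    2π multiple (the unwrapper's free reference); it is re-anchored so
    that the majority of voxels keep their principal-value step, i.e.
    assuming most true inter-echo steps lie in (−π, π].
    """
    from skimage.restoration import unwrap_phase as _spatial_unwrap

    phases = np.asarray(phases, dtype=float)
    n_off, n_echo = phases.shape[:2]
    spatial = phases.shape[2:]
    out = np.empty_like(phases)
    single_voxel = int(np.prod(spatial)) <= 1
    for i in range(n_off):
        out[i, 0] = phases[i, 0]
        for k in range(1, n_echo):
            d = wrap_phase(phases[i, k] - phases[i, k - 1])
            if not single_voxel:
                squeezed = np.squeeze(d)
                if squeezed.ndim >= 1 and squeezed.size > 1:
                    wrapped = d
                    d = np.asarray(_spatial_unwrap(squeezed)).reshape(d.shape)
                    # re-anchor the global 2*pi reference (majority principal)
                    turns = np.round(np.median(wrapped - d) / (2 * np.pi))
                    d = d + 2 * np.pi * turns
            out[i, k] = out[i, k - 1] + d
    return out


def wls_fit(Y: np.ndarray, design: DesignMatrix, w: np.ndarray) -> FitResult:
    """Weighted least squares, batched over leading voxel dimensions.

    ``Y`` and ``w`` have shape ``(..., n_rows)``; weights must be ≥ 0 and
    rows with zero weight are retained with no influence.  Voxels whose
    weighted normal matrix is (numerically) singular are flagged invalid.
    """
    X = design.X
    Y = np.asarray(Y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    w = np.broadcast_to(w, Y.shape)
    A = np.einsum("...e,ei,ej->...ij", w, X, X)
    b = np.einsum("...e,ei,...e->...i", w, X, Y)
    eye = np.eye(6)
    sv = np.linalg.svd(A, compute_uv=False)
    valid = sv[..., -1] > 1e-10 * np.maximum(sv[..., 0], 1e-300)
    A_safe = np.where(valid[..., None, None], A, eye)
    beta = np.linalg.solve(A_safe, b[..., None])[..., 0]
    beta = np.where(valid[..., None], beta, np.nan)
    resid = Y - np.einsum("ei,...i->...e", X, beta)
    wsum = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(np.einsum("...e,...e->...", w, resid**2) / wsum)
    return FitResult(beta=beta, residual_rms=rms, valid=valid)


def _default_mask(mag_echo1: np.ndarray) -> np.ndarray:
    return mag_echo1 > 0.05 * np.percentile(mag_echo1, 99)


def estimate_b1_glm(
    phases: np.ndarray,
    magnitudes: np.ndarray,
    te_list,
    pulse: BSPulse | BSSPhaseConstant,
    mask: np.ndarray | None = None,
    weights: str = "mag",
    offset_signs: tuple[int, int] = (1, -1),
    n_pre: int = 2,
    unwrap: bool = True,
    nominal_b1p: float | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise GLM B1+ mapping pipeline: unwrap → WLS → B1+.

    Parameters
    ----------
    phases, magnitudes:
        Arrays of shape ``(2, n_echo, *spatial)``; phases in rad wrapped
        to (−π, π].
    te_list:
        Echo times in seconds.
    pulse:
        The off-resonance pulse (or its precomputed phase constant); the
        constant of the *positive*-offset pulse converts Φ_BSS to µT.
    weights:
        ``"mag"`` (echo magnitude, the default), ``"mag2"`` (squared,
        the variance-optimal choice for complex Gaussian noise) or
        ``"uniform"``.

    Returns a dict of maps: ``b1p_uT``, six ``beta_*`` coefficient maps,
    ``residual_rms``, ``valid`` and ``mask`` (and ``b1_efficiency`` if a
    nominal B1+ is given or derivable from the pulse).
    """
    phases = np.asarray(phases, dtype=float)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if phases.shape != magnitudes.shape:
        raise ValueError("phase and magnitude stacks must share a shape")
    if phases.shape[0] != 2:
        raise ValueError("expected exactly two offset stacks")
    te = np.asarray(te_list, dtype=float)
    if phases.shape[1] != te.size:
        raise ValueError("echo count does not match TE list")

    const = pulse if isinstance(pulse, BSSPhaseConstant) else bss_phase_constant(
        pulse.with_offset_sign(1)
    )
    design = build_design_matrix(te, n_pre=n_pre, offset_signs=offset_signs)
    spatial = phases.shape[2:]
    if mask is None:
        mask = _default_mask(magnitudes[0, 0])
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), spatial)

    unwrapped = temporal_unwrap(phases) if unwrap else phases
    # rows: echoes of offset 0 then offset 1, trailing spatial dims -> (..., 16)
    Y = np.moveaxis(unwrapped.reshape((2 * te.size,) + spatial), 0, -1)
    mags = np.moveaxis(magnitudes.reshape((2 * te.size,) + spatial), 0, -1)
    if weights == "mag":
        w = mags
    elif weights == "mag2":
        w = mags**2
    elif weights == "uniform":
        w = np.ones_like(mags)
    else:
        raise ValueError(f"unknown weighting {weights!r}")

    fit = wls_fit(Y, design, w)
    phi_bss = fit.coeff("bss")
    phi_bss = np.where(mask & fit.valid, phi_bss, np.nan)
    b1p = b1p_from_phase(np.where(np.isnan(phi_bss), -1.0, phi_bss), const)
    fit.b1p = b1p

    out: dict[str, np.ndarray] = {"b1p_uT": b1p}
    for j, name in enumerate(COLUMN_NAMES):
        out[f"beta_{name}"] = fit.beta[..., j]
    out["residual_rms"] = fit.residual_rms
    out["valid"] = fit.valid & mask & (fit.coeff("bss") >= 0)
    out["mask"] = np.array(mask)
    if nominal_b1p is None and isinstance(pulse, BSPulse):
        try:
            from .pulse import resolved_peak_b1

            nominal_b1p = resolved_peak_b1(pulse)
        except Exception:
            nominal_b1p = None
    if nominal_b1p:
        out["b1_efficiency"] = b1p / nominal_b1p
    return out


def estimate_b1_from_echoes(
    s_plus: np.ndarray,
    s_minus: np.ndarray,
    te_list: np.ndarray,
    const: BSSPhaseConstant,
    n_pre: int = 2,
    weights: str = "mag",
) -> float:
    """GLM B1+ from a single voxel's complex ± echo vectors.

    Convenience path used on simulated steady-state echoes; phases are
    temporally unwrapped per voxel.
    """
    phases = np.stack([np.angle(s_plus), np.angle(s_minus)])[:, :, None]
    mags = np.stack([np.abs(s_plus), np.abs(s_minus)])[:, :, None]
    maps = estimate_b1_glm(
        phases,
        mags,
        te_list,
        const,
        mask=np.array([True]),
        weights=weights,
        n_pre=n_pre,
    )
    return float(maps["b1p_uT"][0])
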