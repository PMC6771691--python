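"""Off-resonance (Bloch-Siegert) pulse models.

An off-resonance RF pulse of peak amplitude ``B1p`` (µT) and normalized
envelope :math:`B_1^{norm}(t)` imparts, to first order in
:math:`\\gamma B_1/\\omega_{off}`, a phase on transverse magnetization

.. math::

    \\Phi_{BSS} = B_{1p}^2 \\int_0^T
        \\frac{(\\gamma B_1^{norm}(t))^2}{2\\,\\omega_{off}}\\,dt ,

with :math:`\\omega_{off}` the pulse off-resonance in rad/s.  The integral
factor (``k_bss``, rad/µT²) depends only on the envelope shape, its
duration, and the offset; inverting it maps a measured BSS phase back to
peak transmit amplitude, :math:`B_{1p} = \\sqrt{\\Phi_{BSS}/k_{bss}}`.

The module also provides the envelope-area constant ``k_flip`` used to
calibrate the peak amplitude from the pulse's on-resonance-equivalent flip
angle, and a brute-force off-resonant rotation simulator that serves as
the reference for the quality of the first-order phase formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GAMMA_UT",
    "BSPulse",
    "BSSPhaseConstant",
    "envelope",
    "bss_phase_constant",
    "calibrate_peak_b1",
    "resolved_peak_b1",
    "bss_phase",
    "b1p_from_phase",
    "simulate_bss_phase_full",
    "simulate_flip_full",
]

#: Gyromagnetic ratio of the proton, rad s^-1 µT^-1 (2π · 42.576 MHz/T).
GAMMA_UT = 267.522

_TWO_PI = 2.0 * np.pi


class PulseConfigError(ValueError):
    """Invalid pulse configuration."""


@dataclass(frozen=True)
class BSPulse:
    """A shaped off-resonance pulse.

    Parameters
    ----------
    shape:
        ``"fermi"`` or ``"rect"``.
    duration:
        Pulse duration T in seconds.
    f_off:
        Off-resonance frequency in Hz; the sign carries the ± interleave
        label.
    flip_angle:
        On-resonance-equivalent flip angle in degrees, used to calibrate
        the peak amplitude when ``peak_b1`` is not given.
    peak_b1:
        Peak amplitude in µT.  ``None`` means "calibrate from flip_angle".
    fermi_t0, fermi_a:
        Fermi half-width and transition-width parameters in seconds.
        Defaults: ``0.75 * duration / 2`` and ``duration / 30`` — these
        proportions put the 260° / 2 ms calibration at ≈11.3 µT, i.e.
        γB1/ω_off ≈ 0.24 at a 2 kHz offset.
    n_samples:
        Number of samples of the discretized envelope.
    """

    shape: str = "fermi"
    duration: float = 2.0e-3
    f_off: float = 2000.0
    flip_angle: float = 260.0
    peak_b1: float | None = None
    fermi_t0: float | None = None
    fermi_a: float | None = None
    n_samples: int = 500

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise PulseConfigError("pulse duration must be positive")
        if self.n_samples < 2:
            raise PulseConfigError("n_samples must be at least 2")
        if self.shape not in ("fermi", "rect"):
            raise PulseConfigError(f"unknown pulse shape {self.shape!r}")

    def with_offset_sign(self, sign: int) -> "BSPulse":
        """Return a copy whose off-resonance carries the given sign."""
        return replace(self, f_off=sign * abs(self.f_off))


@dataclass(frozen=True)
class BSSPhaseConstant:
    """Envelope integrals of a pulse.

    Attributes
    ----------
    k_bss:
        rad/µT²; BSS phase per squared peak amplitude (signed with f_off).
    k_flip:
        rad/µT; flip angle per peak amplitude (offset independent).
    k_b0:
        rad/µT² per rad/s of local off-resonance; the first-order
        B0-dependent term of the BSS phase.  It is even in the pulse
        offset, so it cancels exactly in the ± difference.
    """

    k_bss: float
    k_flip: float
    k_b0: float


def envelope(pulse: BSPulse) -> tuple[np.ndarray, np.ndarray]:
    """Sampled normalized amplitude of the pulse.

    Returns ``(t, env)`` with ``t`` uniform on [0, T] and ``env`` in
    [0, 1] with max exactly 1, symmetric about T/2.
    """
    t = np.linspace(0.0, pulse.duration, pulse.n_samples)
    if pulse.shape == "rect":
        return t, np.ones_like(t)
    t0 = pulse.fermi_t0 if pulse.fermi_t0 is not None else 0.75 * pulse.duration / 2
    a = pulse.fermi_a if pulse.fermi_a is not None else pulse.duration / 30
    env = 1.0 / (1.0 + np.exp((np.abs(t - pulse.duration / 2) - t0) / a))
    env = env / env.max()
    return t, env


def bss_phase_constant(pulse: BSPulse) -> BSSPhaseConstant:
    """Envelope integrals by trapezoid quadrature of the sampled shape."""
    if pulse.f_off == 0:
        raise ZeroDivisionError(
            "BS pulse off-resonance frequency is 0 Hz: the Bloch-Siegert "
            "phase constant diverges; set a nonzero f_off"
        )
    t, env = envelope(pulse)
    w_off = _TWO_PI * pulse.f_off  # rad/s, signed
    sq = np.trapezoid((GAMMA_UT * env) ** 2, t)
    k_bss = sq / (2.0 * w_off)
    k_flip = np.trapezoid(GAMMA_UT * env, t)
    k_b0 = sq / (2.0 * w_off**2)
    return BSSPhaseConstant(k_bss=float(k_bss), k_flip=float(k_flip), k_b0=float(k_b0))


def calibrate_peak_b1(pulse: BSPulse) -> float:
    """Peak amplitude (µT) such that the envelope area gives ``flip_angle``."""
    if pulse.flip_angle <= 0:
        raise PulseConfigError("flip_angle must be positive to calibrate peak B1")
    # k_flip is offset independent; compute it directly so f_off=0 is allowed here.
    t, env = envelope(pulse)
    k_flip = float(np.trapezoid(GAMMA_UT * env, t))
    return np.deg2rad(pulse.flip_angle) / k_flip


def resolved_peak_b1(pulse: BSPulse) -> float:
    """Peak amplitude in µT: explicit value if set, else flip-angle calibrated."""
    if pulse.peak_b1 is not None:
        return float(pulse.peak_b1)
    return calibrate_peak_b1(pulse)


def bss_phase(pulse: BSPulse, b1p: float | None = None, df_b0: float = 0.0) -> float:
    """First-order BSS phase (rad) of the pulse at peak amplitude ``b1p``.

    ``df_b0`` (Hz) adds the sign-independent first-order local-field term.
    """
    const = bss_phase_constant(pulse)
    if b1p is None:
        b1p = resolved_peak_b1(pulse)
    return const.k_bss * b1p**2 - const.k_b0 * b1p**2 * (_TWO_PI * df_b0)


def b1p_from_phase(phi_bss: float | np.ndarray, const: BSSPhaseConstant) -> float | np.ndarray:
    """Invert the quadratic phase law: ``B1p = sqrt(phi / k_bss)``.

    Raises on negative scalar input (signals an unwrapping or sign
    convention failure upstream); array input propagates NaN for negative
    voxels so callers can mask them.
    """
    k = const.k_bss
    if k <= 0:
        raise ValueError("k_bss must be positive (use the +offset pulse constant)")
    phi = np.asarray(phi_bss, dtype=float)
    if phi.ndim == 0:
        if phi < 0:
            raise ValueError(
                f"negative BSS phase {float(phi):.4g} rad cannot be inverted; "
                "check offset labels / unwrapping"
            )
        return float(np.sqrt(phi / k))
    out = np.full(phi.shape, np.nan)
    ok = phi >= 0
    out[ok] = np.sqrt(phi[ok] / k)
    return out


def _rotate(M: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Right-handed Rodrigues rotation of a 3-vector."""
    n = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return M * c + np.cross(n, M) * s + n * np.dot(n, M) * (1.0 - c)


def simulate_bss_phase_full(
    pulse: BSPulse, b1p: float | None = None, n_steps: int = 20000
) -> float:
    """BSS phase from full off-resonant rotation of the magnetization.

    Integrates the Bloch precession (no relaxation) in the frame rotating
    with the pulse, where the effective field is
    ``(γ B1(t), 0, ω_off)`` rad/s, starting from transverse magnetization.
    The accrued transverse phase minus the plain ``ω_off · T`` precession
    is the Bloch-Siegert phase, free of the first-order approximation.
    Serves as the independent reference for :func:`bss_phase`.
    """
    if pulse.f_off == 0:
        raise ZeroDivisionError("f_off must be nonzero")
    if b1p is None:
        b1p = resolved_peak_b1(pulse)
    # envelope resampled at the integration resolution
    fine = replace(pulse, n_samples=n_steps + 1)
    t, env = envelope(fine)
    dt = t[1] - t[0]
    w1 = GAMMA_UT * b1p * env  # rad/s
    w_off = _TWO_PI * pulse.f_off
    M = np.array([1.0, 0.0, 0.0])
    phase = 0.0
    prev = 0.0
    for k in range(n_steps):
        # midpoint amplitude over the step
        w1k = 0.5 * (w1[k] + w1[k + 1])
        axis = np.array([w1k, 0.0, w_off])
        ang = np.linalg.norm(axis) * dt
        M = _rotate(M, axis, ang)
        cur = np.arctan2(M[1], M[0])
        d = cur - prev
        phase += np.arctan2(np.sin(d), np.cos(d))  # wrap step to (-pi, pi]
        prev = cur
    return phase - w_off * pulse.duration


def simulate_flip_full(pulse: BSPulse, b1p: float, n_steps: int = 20000) -> float:
    """On-resonance flip angle (rad) by stepwise rotation about x.

    Brute-force check of the ``k_flip`` calibration integral.
    """
    fine = replace(pulse, n_samples=n_steps + 1)
    t, env = envelope(fine)
    dt = t[1] - t[0]
    w1 = GAMMA_UT * b1p * env
    M = np.array([0.0, 0.0, 1.0])
    total = 0.0
    prev = 0.0
    for k in range(n_steps):
        w1k = 0.5 * (w1[k] + w1[k + 1])
        M = _rotate(M, np.array([1.0, 0.0, 0.0]), w1k * dt)
        cur = np.arctan2(M[1], M[2])  # polar angle in the y-z rotation plane
        d = cur - prev
        total += np.arctan2(np.sin(d), np.cos(d))
        prev = cur
    return float(abs(total))
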