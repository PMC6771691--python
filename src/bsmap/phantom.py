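"""Digital phantom generator for the dual-offset multi-echo acquisition.

Two generators:

* :func:`generate_ideal` composes per-voxel phase exactly from the GLM
  forward model (BSS phase from the B1+ field, B0 ramp over TE, odd/even
  eddy-current phase, per-offset initial phases, a common post-pulse
  term) with mono-exponential magnitude decay and optional complex
  Gaussian noise — model-matched data, exact in the noiseless limit.
* :func:`generate_biased` runs the interleaved Bloch simulation per
  tissue class so the *genuine* interleave pseudo-steady-state — the
  bias mechanism — is embedded in the image data rather than injected
  by hand.

Spatial patterns are smooth low-order polynomials so that spatial
unwrapping of inter-echo phase differences is well-posed by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import SequenceParams, TissueParams, run_sequence, steady_state_pair
from .glm import wrap_phase
from .pulse import BSPulse, bss_phase_constant, resolved_peak_b1

__all__ = ["TissueClass", "PhantomSpec", "generate_ideal", "generate_biased"]


@dataclass(frozen=True)
class TissueClass:
    name: str
    t1: float
    t2: float
    m0: float = 1.0


#: Default compartments spanning the relaxation extremes of interest:
#: agar-gel QA phantom, white-matter-like, and long-T1/T2 fluid-like.
DEFAULT_TISSUES = (
    TissueClass("gel", 0.55, 0.07),
    TissueClass("wm", 1.00, 0.07, 0.9),
    TissueClass("fluid", 1.35, 0.10, 1.1),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the digital phantom.

    The B1+ efficiency field is a quadratic bowl spanning
    ``efficiency_range`` of the nominal peak amplitude; the B0 field is
    a smooth ramp+bowl within ``±df_b0_amp`` Hz.  Tissue classes are
    laid out as bands along the last axis.
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    efficiency_range: tuple[float, float] = (0.7, 1.3)
    df_b0_amp: float = 100.0  # Hz
    odd_even_phase: float = 0.05  # rad
    offset_plus_phase: float = 0.30  # rad
    offset_minus_phase: float = 0.10  # rad
    same_sign_phase: float = 0.20  # rad
    noise_sigma: float = 0.0  # complex-Gaussian SD relative to M0 = 1
    seed: int = 0
    tissues: tuple[TissueClass, ...] = DEFAULT_TISSUES
    uniform_fields_per_class: bool = False

    def grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in self.shape]
        return np.meshgrid(*axes, indexing="ij")

    def b1_efficiency(self) -> np.ndarray:
        x, y, z = self.grids()
        lo, hi = self.efficiency_range
        bowl = 1.0 - (x**2 + y**2 + 0.5 * z**2) / 2.5
        bowl = (bowl - bowl.min()) / (bowl.max() - bowl.min() + 1e-30)
        eff = lo + (hi - lo) * bowl
        if self.uniform_fields_per_class:
            lab = self.labels()
            for c in np.unique(lab):
                eff[lab == c] = eff[lab == c].mean()
        return eff

    def df_b0(self) -> np.ndarray:
        x, y, z = self.grids()
        f = 0.6 * x + 0.3 * y**2 - 0.4 * z
        f = f / (np.abs(f).max() + 1e-30) * self.df_b0_amp
        if self.uniform_fields_per_class:
            lab = self.labels()
            for c in np.unique(lab):
                f[lab == c] = f[lab == c].mean()
        return f

    def labels(self) -> np.ndarray:
        lab = np.zeros(self.shape, dtype=int)
        nz = self.shape[-1]
        n_cls = len(self.tissues)
        for i in range(n_cls):
            lab[..., (nz * i) // n_cls : (nz * (i + 1)) // n_cls] = i
        return lab

    def tissue_maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lab = self.labels()
        t1 = np.choose(lab, [c.t1 for c in self.tissues])
        t2 = np.choose(lab, [c.t2 for c in self.tissues])
        m0 = np.choose(lab, [c.m0 for c in self.tissues])
        return t1, t2, m0


def _add_noise(
    mags: np.ndarray, phases: np.ndarray, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Add complex Gaussian noise, return (magnitude, wrapped phase)."""
    z = mags * np.exp(1j * phases)
    z = z + sigma * (rng.standard_normal(z.shape) + 1j * rng.standard_normal(z.shape))
    return np.abs(z), wrap_phase(np.angle(z))


def generate_ideal(
    spec: PhantomSpec,
    te_list=None,
    pulse: BSPulse | None = None,
    n_pre: int = 2,
) -> dict:
    """Model-matched dual-offset stacks plus ground-truth maps.

    Returns a dict with ``phases``/``magnitudes`` of shape
    ``(2, n_echo, *spec.shape)`` (offset order +, −), the TE list, and a
    ``truth`` sub-dict (B1+ µT, efficiency, ΔB0 Hz, Φ_BSS rad, the
    nuisance phase constants and tissue maps).  Bit-reproducible for a
    given seed.
    """
    pulse = pulse if pulse is not None else BSPulse()
    if te_list is None:
        te_list = SequenceParams().te_list
    te = np.asarray(te_list, dtype=float)
    const = bss_phase_constant(pulse.with_offset_sign(1))
    nominal = resolved_peak_b1(pulse)

    eff = spec.b1_efficiency()
    b1p = nominal * eff
    phi_bss = const.k_bss * b1p**2
    df = spec.df_b0()
    t1m, t2m, m0m = spec.tissue_maps()

    n_echo = te.size
    post = (np.arange(n_echo) >= n_pre).astype(float)
    oe = np.where(np.arange(n_echo) % 2 == 0, 1.0, -1.0)
    shape = spec.shape

    phases = np.empty((2, n_echo) + shape)
    mags = np.empty_like(phases)
    for i, (sign, off_phase) in enumerate(
        [(1, spec.offset_plus_phase), (-1, spec.offset_minus_phase)]
    ):
        for k in range(n_echo):
            phases[i, k] = (
                off_phase
                + 2 * np.pi * df * te[k]
                + spec.odd_even_phase * oe[k]
                + post[k] * (spec.same_sign_phase + sign * phi_bss)
            )
            mags[i, k] = m0m * np.exp(-te[k] / t2m)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        mags, phases = _add_noise(mags, phases, spec.noise_sigma, rng)
    else:
        phases = wrap_phase(phases)

    return {
        "phases": phases,
        "magnitudes": mags,
        "te_list": te,
        "n_pre": n_pre,
        "offset_signs": (1, -1),
        "pulse": pulse,
        "truth": {
            "b1p_uT": b1p,
            "b1_efficiency": eff,
            "df_b0_hz": df,
            "phi_bss": phi_bss,
            "t1": t1m,
            "t2": t2m,
            "m0": m0m,
            "odd_even_phase": spec.odd_even_phase,
            "offset_plus_phase": spec.offset_plus_phase,
            "offset_minus_phase": spec.offset_minus_phase,
            "same_sign_phase": spec.same_sign_phase,
        },
    }


def generate_biased(
    spec: PhantomSpec,
    seq: SequenceParams | None = None,
    n_iso: int = 128,
    n_avg: int = 100,
    quantize: int = 3,
) -> dict:
    """Dual-offset stacks carrying the genuine interleave bias.

    Each voxel's complex ± echoes are the pseudo-steady-state means of
    the interleaved Bloch simulation run at the voxel's tissue class,
    B1+ and ΔB0.  Simulations are cached on (T1, T2, B1p, ΔB0) rounded
    to ``quantize`` decimals, so phantoms with piecewise-constant fields
    cost one run per distinct combination.  Returns the same layout as
    :func:`generate_ideal`, plus the per-class pre-pulse ± phase
    difference under ``truth["pre_pulse_diff"]``.
    """
    seq = seq if seq is not None else SequenceParams()
    pulse = seq.pulse
    const = bss_phase_constant(pulse.with_offset_sign(1))
    nominal = resolved_peak_b1(pulse)

    eff = spec.b1_efficiency()
    b1p = nominal * eff
    df = spec.df_b0()
    t1m, t2m, m0m = spec.tissue_maps()
    te = np.asarray(seq.te_list, dtype=float)
    n_echo = te.size
    shape = spec.shape

    keys = np.stack(
        [np.round(t1m, quantize), np.round(t2m, quantize),
         np.round(b1p, quantize), np.round(df, quantize), np.round(m0m, quantize)],
        axis=-1,
    ).reshape(-1, 5)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)

    s_plus = np.empty((uniq.shape[0], n_echo), dtype=complex)
    s_minus = np.empty_like(s_plus)
    pre_diff = np.empty(uniq.shape[0])
    for j, (t1, t2, b1, dfb, m0) in enumerate(uniq):
        tissue = TissueParams(t1=float(t1), t2=float(t2), m0=float(m0), df_b0=float(dfb))
        seq_j = replace(seq, pulse=replace(pulse, peak_b1=float(b1)))
        tl = run_sequence(seq_j, tissue, n_iso=n_iso)
        sp, sm = steady_state_pair(tl, n_avg)
        s_plus[j], s_minus[j] = sp, sm
        pre_diff[j] = float(np.angle(sp[0] * np.conj(sm[0])))

    sp_map = s_plus[inv].reshape(shape + (n_echo,))
    sm_map = s_minus[inv].reshape(shape + (n_echo,))
    stacks = np.stack([np.moveaxis(sp_map, -1, 0), np.moveaxis(sm_map, -1, 0)])

    mags = np.abs(stacks)
    phases = np.angle(stacks)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        mags, phases = _add_noise(mags, phases, spec.noise_sigma, rng)
    else:
        phases = wrap_phase(phases)

    return {
        "phases": phases,
        "magnitudes": mags,
        "te_list": te,
        "n_pre": seq.n_pre,
        "offset_signs": (1, -1),
        "pulse": pulse,
        "truth": {
            "b1p_uT": b1p,
            "b1_efficiency": eff,
            "df_b0_hz": df,
            "t1": t1m,
            "t2": t2m,
            "m0": m0m,
            "pre_pulse_diff": pre_diff[inv].reshape(shape),
        },
    }
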