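"""Dynamic scale-invariant cue stimulus.

The patch cue is carried by the spatial-mean color of a dynamic texture.  The
texture's Fourier coefficients follow independent AR(1) dynamics under a 1/f
amplitude envelope ``S_A(u, v) = (u^2 + v^2)^(-1/2)`` (zero at DC), so single
frames are scale invariant and observers see the same statistics at every
viewing distance.  The cue variable ``X(t) in [0, 1]`` is mapped affinely to a
phase angle ``theta`` and injected into the DC coefficient as ``kappa *
exp(i*theta)`` before the inverse FFT; per-pixel phases are then rendered to
RGB through a perceptually uniform (CIE Luv) lookup table.  The concentration
``kappa`` sets how strongly the mean color dominates the texture and thereby
operationalizes cue reliability.

``decode_phase`` inverts the construction (circular mean of pixel phases) and
is used to measure the effective reliability of rendered frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PhaseEncoding",
    "SpectrumField",
    "Frame",
    "make_amplitude_spectrum",
    "make_decay",
    "init_spectrum",
    "step_spectrum",
    "phase_from_cue",
    "render_frame",
    "make_color_lut",
    "phase_to_color",
    "decode_phase",
    "spectral_slope",
]

# Default phase range: traverses blue -> red along the Luv hue circle.
THETA_MIN_DEFAULT = -2.0 * np.pi / 3.0
THETA_MAX_DEFAULT = 2.0 * np.pi / 3.0


@dataclass(frozen=True)
class PhaseEncoding:
    """Affine map from cue value X in [0, 1] to phase, plus concentration.

    ``kappa`` >= 0 scales the cue term injected at DC: 0 hides the cue in the
    texture entirely; large values pin every pixel's phase near ``theta``.
    """

    kappa: float
    theta_min: float = THETA_MIN_DEFAULT
    theta_max: float = THETA_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


def make_amplitude_spectrum(n: int) -> np.ndarray:
    """1/f spatial amplitude envelope ``S_A`` on an ``n x n`` DFT grid.

    Frequencies are integer DFT coordinates with DC at index (0, 0);
    ``S_A = (u^2 + v^2)^(-1/2)`` and ``S_A(0, 0) = 0``.
    """
    if n < 8 or n % 2:
        raise ValueError(f"grid size must be even and >= 8, got {n}")
    freq = np.fft.fftfreq(n, d=1.0 / n)  # integer frequencies
    u, v = np.meshgrid(freq, freq, indexing="ij")
    r2 = u**2 + v**2
    with np.errstate(divide="ignore"):
        sa = np.where(r2 > 0, r2**-0.5, 0.0)
    return sa


def make_decay(n: int, alpha: float = 0.1, inverse: bool = False) -> np.ndarray:
    """Per-frequency AR(1) persistence ``omega``.

    ``omega = exp(-alpha * S_A)`` by default, which makes low spatial
    frequencies (large ``S_A``) the fastest to decorrelate.  ``inverse=True``
    selects ``exp(-alpha / S_A)`` instead, reversing that direction; both are
    kept because the intended direction is a genuine modeling choice.
    """
    sa = make_amplitude_spectrum(n)
    if inverse:
        with np.errstate(divide="ignore"):
            omega = np.exp(-alpha / np.where(sa > 0, sa, np.inf))
    else:
        omega = np.exp(-alpha * sa)
    return omega


def _conjugate_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    return (-idx[:, None]) % n, (-idx[None, :]) % n


def _master_mask(n: int) -> np.ndarray:
    """One chosen representative per conjugate frequency pair."""
    flat = np.arange(n * n).reshape(n, n)
    ci, cj = _conjugate_index(n)
    partner = flat[ci, cj]
    return flat <= partner


@dataclass
class SpectrumField:
    """AR(1) state of the texture's Fourier coefficients.

    Coefficients on a master half-plane evolve as ``S_f <- omega * S_f +
    sqrt(1 - omega^2) * S_B`` with innovation ``S_B = (R1 + i R2) * S_A``
    (standard-normal R1, R2); the conjugate half is mirrored each step so the
    inverse FFT is real.  Self-conjugate frequencies receive real innovations.
    Each coefficient's real part is then an exact AR(1) process with
    stationary variance ``S_A^2`` and lag-k autocorrelation ``omega^k``.
    """

    n: int
    alpha: float = 0.1
    inverse_decay: bool = False
    amplitude: np.ndarray = field(init=False)
    omega: np.ndarray = field(init=False)
    coeffs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.amplitude = make_amplitude_spectrum(self.n)
        self.omega = make_decay(self.n, self.alpha, self.inverse_decay)
        self.coeffs = np.zeros((self.n, self.n), dtype=complex)


def _innovation(f: SpectrumField, rng: np.random.Generator) -> np.ndarray:
    n = f.n
    r1 = rng.standard_normal((n, n))
    r2 = rng.standard_normal((n, n))
    sb = (r1 + 1j * r2) * f.amplitude
    ci, cj = _conjugate_index(n)
    selfconj = (ci == np.arange(n)[:, None]) & (cj == np.arange(n)[None, :])
    sb[selfconj] = (r1 * f.amplitude)[selfconj]  # must stay real
    return sb


def _symmetrize(coeffs: np.ndarray) -> np.ndarray:
    n = coeffs.shape[0]
    ci, cj = _conjugate_index(n)
    master = _master_mask(n)
    out = np.where(master, coeffs, np.conj(coeffs[ci, cj]))
    return out


def init_spectrum(
    n: int,
    rng: np.random.Generator,
    alpha: float = 0.1,
    inverse_decay: bool = False,
) -> SpectrumField:
    """Fresh field with the t=0 state drawn as a pure innovation.

    A pure innovation already has the stationary variance ``S_A^2``, so no
    burn-in is needed.
    """
    f = SpectrumField(n, alpha, inverse_decay)
    f.coeffs = _symmetrize(_innovation(f, rng))
    return f


def step_spectrum(f: SpectrumField, rng: np.random.Generator) -> SpectrumField:
    """Advance the coefficient field one frame (in place; also returned)."""
    sb = _innovation(f, rng)
    if sb.shape != f.coeffs.shape:
        raise ValueError("innovation/coefficient grid shape mismatch")
    updated = f.omega * f.coeffs + np.sqrt(1.0 - f.omega**2) * sb
    f.coeffs = _symmetrize(updated)
    return f


def phase_from_cue(x: float, enc: PhaseEncoding) -> float:
    """Map cue value ``X in [0, 1]`` to phase ``theta_min + (theta_max - theta_min) X``."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"cue value must lie in [0, 1], got {x}")
    return enc.theta_min + (enc.theta_max - enc.theta_min) * x


@dataclass
class Frame:
    """One rendered stimulus frame."""

    complex_field: np.ndarray
    phase: np.ndarray
    color: np.ndarray | None = None  # uint8 RGB when a LUT was supplied


def render_frame(
    f: SpectrumField,
    enc: PhaseEncoding,
    theta: float,
    lut: np.ndarray | None = None,
) -> Frame:
    """Inverse-transform the texture spectrum with the cue injected at DC.

    ``C = IFFT[S_f + kappa * exp(i*theta) * delta_DC]``: the cue term shifts
    the spatial mean of the complex field, so the mean color encodes theta
    while the 1/f texture masks it in proportion to 1/kappa.
    """
    spectrum = f.coeffs.copy()
    spectrum[0, 0] += enc.kappa * np.exp(1j * theta)
    c = np.fft.ifft2(spectrum)
    phase = np.angle(c)
    color = phase_to_color(phase, lut) if lut is not None else None
    return Frame(c, phase, color)


def make_color_lut(
    n_bins: int = 256, lightness: float = 70.0, chroma: float = 60.0
) -> np.ndarray:
    """Perceptually uniform phase->RGB lookup table.

    ``n_bins`` equally spaced half-open phase bins over [-pi, pi); each bin's
    hue sits at the bin's low edge on the CIE Luv hue circle at fixed
    lightness and chroma.  Returns a ``(n_bins, 3)`` uint8 array.
    """
    from skimage.color import luv2rgb

    if n_bins < 1:
        raise ValueError("LUT needs at least one bin")
    hue = -np.pi + 2.0 * np.pi * np.arange(n_bins) / n_bins
    luv = np.stack(
        [
            np.full(n_bins, lightness),
            chroma * np.cos(hue),
            chroma * np.sin(hue),
        ],
        axis=-1,
    )
    rgb = luv2rgb(luv[None, :, :])[0]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def phase_to_color(phase: np.ndarray, lut: np.ndarray) -> np.ndarray:
    """Map phases to RGB through the LUT; periodic in 2*pi, half-open bins."""
    if lut is None or len(lut) == 0:
        raise ValueError("empty color lookup table")
    n_bins = len(lut)
    wrapped = np.mod(np.asarray(phase) + np.pi, 2.0 * np.pi)  # [0, 2pi)
    idx = np.floor(wrapped / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    return lut[idx]


def decode_phase(frame: Frame) -> tuple[float, float]:
    """Circular mean of per-pixel phases and mean resultant length.

    The decoded angle estimates theta; the resultant length R in [0, 1]
    measures how coherent the frame's phases are (effective reliability).
    """
    c = frame.complex_field
    if not np.any(c):
        raise ValueError("all-zero field has undefined phase")
    z = np.exp(1j * frame.phase).mean()
    return float(np.angle(z)), float(np.abs(z))


def spectral_slope(frames: list[np.ndarray] | np.ndarray) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Input is one or more real-valued spatial frames (e.g. ``frame.complex_
    field.real`` of texture-only renders).  A slope near -1 confirms the 1/f
    construction; white noise gives a slope near 0.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[-1]
    amp = np.mean([np.abs(np.fft.fft2(fr)) for fr in frames], axis=0)
    freq = np.fft.fftfreq(n, d=1.0 / n)
    u, v = np.meshgrid(freq, freq, indexing="ij")
    radius = np.sqrt(u**2 + v**2)
    # integer-radius annuli, excluding DC and the corners beyond Nyquist
    edges = np.arange(1, n // 2 + 1)
    which = np.digitize(radius.ravel(), edges)
    r_mean, a_mean = [], []
    for b in range(1, len(edges)):
        sel = which == b
        if sel.any():
            r_mean.append(radius.ravel()[sel].mean())
            a_mean.append(amp.ravel()[sel].mean())
    if len(r_mean) < 3:
        raise ValueError("need at least 3 radial bins to fit a slope")
    fit = stats.linregress(np.log(r_mean), np.log(a_mean))
    return float(fit.slope)
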