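"""Synthetic ultrasound RF frames from a warped scatterer phantom.

A convolutional point-spread-function model: point scatterers with random
amplitudes are binned (bilinearly, preserving sub-sample delays) onto the
(sample, line) grid at their round-trip delay 2z/c and lateral line position,
then convolved with a separable PSF — a Gaussian-modulated sinusoid axially
and a Gaussian apodization laterally.  This keeps the speckle statistics,
delays and deformation sensitivity that displacement tracking needs, at a
tiny fraction of the cost of a full spatial-impulse-response simulation.

Scatterers inside the tumor are given zero amplitude, so the tumor appears
hypoechoic (dark) in B-mode.

Frames are expressed in the probe coordinate system: the tissue surface in
contact with the probe is treated as fixed, and deeper structures appear to
move toward the probe under compression.  ``to_probe_frame`` converts a
laboratory-frame displacement field accordingly before scatterers are warped.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy.signal import fftconvolve, hilbert

from .phantom_forward import DisplacementField, PhantomGeometry

__all__ = [
    "ProbeConfig",
    "ScattererSet",
    "RFFrame",
    "SPEED_OF_SOUND_M_S",
    "seed_scatterers",
    "to_probe_frame",
    "displace_scatterers",
    "synthesize_rf",
    "envelope",
    "bmode",
    "save_frame",
    "load_frame",
]

#: Standard soft-tissue speed of sound.
SPEED_OF_SOUND_M_S = 1540.0


@dataclass(frozen=True)
class ProbeConfig:
    """Linear-array probe and imaged-region parameters.

    Defaults mirror a 3.5 MHz linear array sampled at 100 MHz with 512 scan
    lines spaced 0.08 mm, focused at 70 mm, imaging the 50 mm depth window
    that encircles the tumor.
    """

    center_frequency_hz: float = 3.5e6
    sampling_frequency_hz: float = 100e6
    n_lines: int = 512
    lateral_spacing_mm: float = 0.08
    pitch_mm: float = 0.44
    kerf_mm: float = 0.05
    element_height_mm: float = 5.0
    focus_depth_mm: float = 70.0
    fractional_bandwidth: float = 0.6
    axial_window_mm: tuple[float, float] = (45.0, 95.0)
    lateral_center_mm: float = 30.0
    lateral_sigma_mm: float = 0.4

    def __post_init__(self) -> None:
        if self.sampling_frequency_hz <= 2.0 * self.center_frequency_hz:
            raise ValueError("sampling frequency must exceed twice the center frequency")
        if self.n_lines < 2 or self.lateral_spacing_mm <= 0.0:
            raise ValueError("need at least two lines with positive spacing")

    @property
    def n_samples(self) -> int:
        z0, z1 = self.axial_window_mm
        return int(np.ceil((z1 - z0) * 1e-3 * 2.0 / SPEED_OF_SOUND_M_S
                           * self.sampling_frequency_hz))

    @property
    def line_positions_mm(self) -> np.ndarray:
        offs = (np.arange(self.n_lines) - 0.5 * (self.n_lines - 1))
        return self.lateral_center_mm + offs * self.lateral_spacing_mm

    @property
    def mm_per_sample(self) -> float:
        """Depth increment per RF sample (one-way), mm."""
        return SPEED_OF_SOUND_M_S / (2.0 * self.sampling_frequency_hz) * 1e3


@dataclass
class ScattererSet:
    """Point scatterers: positions (n, 2) as (axial, lateral) mm; amplitudes (n,)."""

    positions_mm: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if len(self.amplitudes) != len(self.positions_mm):
            raise ValueError("positions and amplitudes must be congruent")


@dataclass
class RFFrame:
    """One RF frame: ``samples`` is (n_lines, n_samples), plus acquisition metadata."""

    samples: np.ndarray
    fs_hz: float
    line_spacing_mm: float
    depth_origin_mm: float
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_lines, n_samples) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")


def seed_scatterers(
    geometry: PhantomGeometry,
    density_per_mm2: float = 10.0,
    seed: int = 0,
    axial_window_mm: tuple[float, float] = (45.0, 95.0),
) -> ScattererSet:
    """Uniform random scatterers over the imaged region, zero inside the tumor.

    Amplitudes are standard normal; scatterers whose position falls inside
    the tumor get amplitude exactly zero, making the tumor anechoic.
    Deterministic per seed.
    """
    if density_per_mm2 <= 0.0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    z0, z1 = axial_window_mm
    area = (z1 - z0) * geometry.lateral_mm
    n = int(round(density_per_mm2 * area))
    z = rng.uniform(z0, z1, n)
    y = rng.uniform(0.0, geometry.lateral_mm, n)
    amp = rng.standard_normal(n)
    tz1, tz2 = geometry.tumor_axial_mm
    ty1, ty2 = geometry.tumor_lateral_bounds()
    inside = (z >= tz1) & (z <= tz2) & (y >= ty1) & (y <= ty2)
    amp[inside] = 0.0
    return ScattererSet(np.column_stack([z, y]), amp)


def to_probe_frame(field: DisplacementField) -> DisplacementField:
    """Re-express a displacement field relative to the probe.

    The probe rides on the tissue surface, so in frame coordinates the
    contact surface is fixed: the axial displacement of the shallowest grid
    row is subtracted column-wise.
    """
    return DisplacementField(
        grid_axial_mm=field.grid_axial_mm,
        grid_lateral_mm=field.grid_lateral_mm,
        ux_mm=field.ux_mm - field.ux_mm[0:1, :],
        uy_mm=field.uy_mm,
        time_s=field.time_s,
        role=field.role,
    )


def displace_scatterers(sset: ScattererSet, field: DisplacementField) -> ScattererSet:
    """Warp scatterer positions by the bilinearly interpolated displacement."""
    try:
        ux = field.interpolator("ux")(sset.positions_mm)
        uy = field.interpolator("uy")(sset.positions_mm)
    except ValueError as err:
        raise ValueError(f"scatterer outside displacement-field support: {err}") from err
    moved = sset.positions_mm + np.column_stack([ux, uy])
    return ScattererSet(moved, sset.amplitudes.copy())


def _axial_pulse(probe: ProbeConfig) -> np.ndarray:
    """Gaussian-enveloped sinusoid at the center frequency, unit peak."""
    fc, fs = probe.center_frequency_hz, probe.sampling_frequency_hz
    sigma_f = probe.fractional_bandwidth * fc / 2.3548
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.cos(2.0 * np.pi * fc * t) * np.exp(-0.5 * (t / sigma_t) ** 2)


def synthesize_rf(sset: ScattererSet, probe: ProbeConfig, time_s: float = 0.0) -> RFFrame:
    """Synthesize one RF frame from a scatterer set.

    Each scatterer contributes, on the lines within its Gaussian lateral
    acceptance, a pulse at its round-trip delay 2z/c, weighted by its
    amplitude.  Deterministic given the set and the probe.
    """
    if len(sset.amplitudes) == 0:
        raise ValueError("scatterer set is empty")
    z0, _ = probe.axial_window_mm
    n_s, n_l = probe.n_samples, probe.n_lines

    # fractional (sample, line) coordinates
    s_f = (sset.positions_mm[:, 0] - z0) / probe.mm_per_sample
    l_f = (sset.positions_mm[:, 1] - probe.line_positions_mm[0]) / probe.lateral_spacing_mm

    keep = (s_f > -1) & (s_f < n_s) & (l_f > -1) & (l_f < n_l)
    s_f, l_f, amp = s_f[keep], l_f[keep], sset.amplitudes[keep]

    refl = np.zeros((n_s, n_l))
    s0 = np.floor(s_f).astype(int)
    l0 = np.floor(l_f).astype(int)
    ws, wl = s_f - s0, l_f - l0
    for ds, w_s in ((0, 1.0 - ws), (1, ws)):
        for dl, w_l in ((0, 1.0 - wl), (1, wl)):
            si, li = s0 + ds, l0 + dl
            ok = (si >= 0) & (si < n_s) & (li >= 0) & (li < n_l)
            np.add.at(refl, (si[ok], li[ok]), amp[ok] * w_s[ok] * w_l[ok])

    pulse = _axial_pulse(probe)
    sig_l = probe.lateral_sigma_mm / probe.lateral_spacing_mm
    half_l = int(np.ceil(3.0 * sig_l))
    lat = np.exp(-0.5 * (np.arange(-half_l, half_l + 1) / sig_l) ** 2)
    rf = fftconvolve(refl, np.outer(pulse, lat), mode="same")
    return RFFrame(
        samples=rf.T,
        fs_hz=probe.sampling_frequency_hz,
        line_spacing_mm=probe.lateral_spacing_mm,
        depth_origin_mm=z0,
        time_s=time_s,
    )


def envelope(frame: RFFrame) -> np.ndarray:
    """Linear echo envelope (analytic-signal magnitude), (n_lines, n_samples)."""
    return np.abs(hilbert(frame.samples, axis=1))


def bmode(frame: RFFrame, dynamic_range_db: float = 50.0) -> np.ndarray:
    """Log-compressed envelope image in [0, 1] (n_lines, n_samples).

    Envelope by analytic-signal magnitude along each line, normalized to its
    maximum and log-compressed over the given dynamic range.  An all-zero
    frame maps to an all-zero image.
    """
    if dynamic_range_db <= 0.0:
        raise ValueError("dynamic range must be positive")
    env = np.abs(hilbert(frame.samples, axis=1))
    peak = env.max()
    if peak == 0.0:
        return np.zeros_like(env)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    return np.clip(1.0 + db / dynamic_range_db, 0.0, 1.0)


def save_frame(path, frame: RFFrame) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=frame.samples)
        f.attrs["fs_hz"] = frame.fs_hz
        f.attrs["line_spacing_mm"] = frame.line_spacing_mm
        f.attrs["depth_origin_mm"] = frame.depth_origin_mm
        f.attrs["time_s"] = frame.time_s


def load_frame(path) -> RFFrame:
    with h5py.File(path, "r") as f:
        return RFFrame(
            samples=f["rf"][:],
            fs_hz=float(f.attrs["fs_hz"]),
            line_spacing_mm=float(f.attrs["line_spacing_mm"]),
            depth_origin_mm=float(f.attrs["depth_origin_mm"]),
            time_s=float(f.attrs["time_s"]),
        )
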