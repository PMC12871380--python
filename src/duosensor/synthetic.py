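"""Ground-truth synthetic data for every analysis stage.

Emulates the statistical structure the pipeline assumes:

* dual-sensor movies in which stimulus-evoked release is confined to
  spatial hotspots, seen simultaneously through a saturating
  high-affinity sensor (active everywhere dopamine diffuses) and a
  non-saturating low-affinity sensor (active only at release sites);
* calcium traces with slow spontaneous wave transients temporally coupled
  to smaller transients in a near-infrared channel;
* z-stacks whose per-slice intensity follows a unimodal axial profile of
  known FWHM.

Concentration units are normalized so that the evoked peak concentration
at a release site is 1.  The two sensors transduce concentration through
a Hill curve, ΔF/F = dff_max · cⁿ/(Kdⁿ + cⁿ), followed by convolution
with a mono-exponential reporter-decay kernel.  The default dissociation
constants (0.01 for the high-affinity sensor, 10 for the low-affinity
sensor) place the sensors on the saturated and linear regions of the
dose–response curve respectively; they are implementer-chosen working
values, not measured constants.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import Movie, Trace, ZStack

__all__ = [
    "SensorModel",
    "SyntheticScene",
    "high_affinity_sensor",
    "low_affinity_sensor",
    "default_scene",
    "concentration_timecourse",
    "sensor_response",
    "render_dual_movie",
    "quinpirole_variant",
    "make_wave_traces",
    "make_z_stack",
    "nominal_grid_snr",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.3548 σ


@dataclass
class SensorModel:
    """Hill-equation fluorescent sensor with mono-exponential reporter decay.

    ``kd`` is in the scene's normalized concentration units (site peak = 1);
    ``dff_max`` is the saturating fractional response; ``tau_off_s`` the
    reporter decay time constant (0 disables the temporal kernel).
    """

    kd: float
    dff_max: float
    hill_n: float = 1.0
    tau_off_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.kd > 0 and self.hill_n > 0 and self.dff_max > 0):
            raise ValueError("kd, hill_n and dff_max must be > 0")
        if self.tau_off_s < 0:
            raise ValueError("tau_off_s must be >= 0")

    def hill(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        cn = np.power(c, self.hill_n, where=c > 0, out=np.zeros_like(c))
        return self.dff_max * cn / (self.kd ** self.hill_n + cn)


def high_affinity_sensor() -> SensorModel:
    """Saturating genetically-encoded-style sensor (visible channel)."""
    return SensorModel(kd=0.01, dff_max=0.9, tau_off_s=0.3)


def low_affinity_sensor() -> SensorModel:
    """Non-saturating nanosensor-style sensor (near-infrared channel)."""
    return SensorModel(kd=10.0, dff_max=0.15, tau_off_s=1.0)


@dataclass
class SyntheticScene:
    """Ground-truth description of a dual-sensor hotspot movie.

    ``site_map`` maps release-site grid squares (row, col) to amplitude
    scales (peak concentration at that site).  The isotropic Gaussian
    "spillover" field (width ``spill_sigma_px``) carries low
    concentrations to every pixel; it is normalized so its spatial peak
    equals ``spill_gain`` site-peak units — large enough to drive the
    high-affinity sensor everywhere, far below the low-affinity sensor's
    noise floor.  ``bleach`` is an optional multiplicative
    double-exponential decay ``(b1, tau1_s, b2, tau2_s)`` applied to the
    rendered fluorescence.
    """

    shape: tuple[int, int] = (152, 152)
    frame_rate_hz: float = 1.47
    n_frames: int = 135
    grid_px: int = 8
    site_map: dict[tuple[int, int], float] = field(default_factory=dict)
    stim_frames: tuple[int, ...] = (20, 60, 100)
    release_tau_rise_s: float = 0.3
    release_tau_decay_s: float = 2.0
    baseline_f: float = 100.0
    noise_sd: float = 0.3
    spill_sigma_px: float = 30.0
    spill_gain: float = 0.002
    bleach: tuple[float, float, float, float] | None = None
    pixel_size_um: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        n_rows = self.shape[0] // self.grid_px
        n_cols = self.shape[1] // self.grid_px
        for (r, c), amp in self.site_map.items():
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise ValueError(f"site {(r, c)} outside the {n_rows}x{n_cols} grid")
            if amp <= 0:
                raise ValueError("site amplitudes must be > 0")
        for s in self.stim_frames:
            if not (0 <= s < self.n_frames):
                raise ValueError(f"stimulus frame {s} outside the movie")


def default_scene(n_sites: int = 100, seed: int = 0, **overrides) -> SyntheticScene:
    """A standard hotspot scene: random release sites of unit amplitude."""
    scene = SyntheticScene(seed=seed, **overrides)
    n_rows = scene.shape[0] // scene.grid_px
    n_cols = scene.shape[1] // scene.grid_px
    if n_sites > n_rows * n_cols:
        raise ValueError("more sites than grid squares")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_rows * n_cols, size=n_sites, replace=False)
    scene.site_map = {(int(i // n_cols), int(i % n_cols)): 1.0 for i in idx}
    return scene


def _unit_transient(t_s: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Release transient (1−e^(−t/τr))·e^(−t/τd), normalized to unit peak; 0 for t<0."""
    t_s = np.asarray(t_s, dtype=float)
    out = np.zeros_like(t_s)
    pos = t_s >= 0
    if tau_rise_s <= 0:
        out[pos] = np.exp(-t_s[pos] / tau_decay_s)
        return out
    t_peak = tau_rise_s * np.log1p(tau_decay_s / tau_rise_s)
    peak = (1 - np.exp(-t_peak / tau_rise_s)) * np.exp(-t_peak / tau_decay_s)
    out[pos] = (1 - np.exp(-t_s[pos] / tau_rise_s)) * np.exp(-t_s[pos] / tau_decay_s) / peak
    return out


def _stim_timecourse(scene: SyntheticScene) -> np.ndarray:
    """Unit-amplitude concentration time course summed over all stimuli."""
    t = np.arange(scene.n_frames) / scene.frame_rate_hz
    g = np.zeros(scene.n_frames)
    for s in scene.stim_frames:
        g += _unit_transient(t - s / scene.frame_rate_hz,
                             scene.release_tau_rise_s, scene.release_tau_decay_s)
    return g


def concentration_timecourse(scene: SyntheticScene, site: tuple[int, int]) -> np.ndarray:
    """Per-frame concentration at one release site (before spillover)."""
    if site not in scene.site_map:
        raise KeyError(f"{site} is not a release site of this scene")
    return scene.site_map[site] * _stim_timecourse(scene)


def _reporter_kernel(tau_off_s: float, frame_rate_hz: float) -> np.ndarray | None:
    if tau_off_s <= 0:
        return None
    dt = 1.0 / frame_rate_hz
    n = max(2, int(np.ceil(5 * tau_off_s / dt)))
    k = np.exp(-np.arange(n) * dt / tau_off_s)
    return k / k.sum()


def sensor_response(c: np.ndarray, model: SensorModel,
                    frame_rate_hz: float = 1.47) -> np.ndarray:
    """Transduce a concentration time series into ΔF/F.

    Hill saturation first, then causal convolution with the normalized
    reporter-decay kernel (unit DC gain, so ΔF/F stays in [0, dff_max]).
    Works on 1-D series or movies with time on axis 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    dff = model.hill(c)
    kernel = _reporter_kernel(model.tau_off_s, frame_rate_hz)
    if kernel is not None:
        dff = _causal_filter(dff, kernel)
    return dff


def _causal_filter(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal FIR filtering along axis 0: y[i] = Σⱼ k[j]·x[i−j]."""
    from scipy.signal import lfilter
    return lfilter(kernel, [1.0], x, axis=0)


def render_dual_movie(scene: SyntheticScene, high: SensorModel | None = None,
                      low: SensorModel | None = None
                      ) -> tuple[Movie, Movie, dict]:
    """Render the visible (high-affinity) and nIR (low-affinity) movies.

    The per-pixel concentration field is the site transients plus an
    isotropically blurred spillover field, so every pixel sees a low
    concentration.  Each channel applies its sensor's Hill transduction
    and reporter kernel, scales onto the baseline fluorescence, applies
    the optional bleach decay, and adds Gaussian noise.

    Returns (high-affinity Movie, low-affinity Movie, ground truth), the
    ground truth holding the site set, per-pixel peak concentration, and
    the scene parameters.
    """
    high = high if high is not None else high_affinity_sensor()
    low = low if low is not None else low_affinity_sensor()

    amp_map = np.zeros(scene.shape)
    g = scene.grid_px
    for (r, c), amp in scene.site_map.items():
        amp_map[r * g:(r + 1) * g, c * g:(c + 1) * g] = amp
    spill = ndimage.gaussian_filter(amp_map, scene.spill_sigma_px)
    if spill.max() > 0:
        spill = scene.spill_gain * spill / spill.max()
    conc_map = amp_map + spill

    timecourse = _stim_timecourse(scene)
    conc = conc_map[None, :, :] * timecourse[:, None, None]

    t = np.arange(scene.n_frames) / scene.frame_rate_hz
    bleach = np.ones(scene.n_frames)
    if scene.bleach is not None:
        b1, tau1, b2, tau2 = scene.bleach
        bleach = 1.0 + b1 * np.exp(-t / tau1) + b2 * np.exp(-t / tau2)

    rng = np.random.default_rng(scene.seed)
    movies = []
    for model, label in ((high, "visible"), (low, "nir")):
        dff = model.hill(conc)
        kernel = _reporter_kernel(model.tau_off_s, scene.frame_rate_hz)
        if kernel is not None:
            dff = _causal_filter(dff, kernel)
        f = scene.baseline_f * (1.0 + dff) * bleach[:, None, None]
        if scene.noise_sd > 0:
            f = f + rng.normal(0.0, scene.noise_sd, size=f.shape)
        np.clip(f, 0.0, None, out=f)
        movies.append(Movie(f.astype(np.float32), scene.frame_rate_hz,
                            scene.pixel_size_um, channel_label=label))

    truth = {
        "sites": set(scene.site_map),
        "site_amplitudes": dict(scene.site_map),
        "peak_concentration": conc_map * timecourse.max(),
        "stim_frames": tuple(scene.stim_frames),
        "grid_px": scene.grid_px,
    }
    return movies[0], movies[1], truth


def quinpirole_variant(scene: SyntheticScene, survive_fraction: float,
                       amp_scale: float, seed: int) -> SyntheticScene:
    """Scene after a release-suppressing perturbation (D2-agonist-like).

    A seeded random ``survive_fraction`` of sites is retained and the
    surviving amplitudes are scaled by ``amp_scale``.
    """
    if not (0 <= survive_fraction <= 1 and 0 <= amp_scale <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    sites = sorted(scene.site_map)
    n_keep = int(round(survive_fraction * len(sites)))
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(sites), size=n_keep, replace=False) if sites else []
    new_map = {sites[i]: scene.site_map[sites[i]] * amp_scale for i in sorted(keep_idx)}
    return replace(scene, site_map=new_map, seed=seed)


def nominal_grid_snr(scene: SyntheticScene, model: SensorModel) -> float:
    """Per-grid-square SNR: peak site ΔF/F over per-square ΔF/F noise SD.

    The peak accounts for discrete frame sampling and the reporter
    kernel; the noise SD for spatial averaging over grid_px² pixels.
    """
    if scene.noise_sd == 0:
        return np.inf
    amp = max(scene.site_map.values()) if scene.site_map else 1.0
    single = replace(scene, stim_frames=(scene.stim_frames[0],))
    dff = model.hill(amp * _stim_timecourse(single))
    kernel = _reporter_kernel(model.tau_off_s, scene.frame_rate_hz)
    if kernel is not None:
        dff = _causal_filter(dff, kernel)
    noise_dff_sd = scene.noise_sd / (scene.baseline_f * scene.grid_px)
    return float(dff.max() / noise_dff_sd)


def make_wave_traces(n_waves: int, amplitudes: float | list[float], coupling_scale: float,
                     lag_s: float, noise_sd: float, duration_s: float, fps: float,
                     seed: int, wave_sigma_s: float = 2.0, nir_tau_rise_s: float = 2.0,
                     nir_tau_decay_s: float = 6.0,
                     margin_s: float = 35.0, min_sep_s: float = 10.0,
                     initial_decay: tuple[float, float, float, float] | None = None,
                     ) -> tuple[Trace, Trace, np.ndarray]:
    """Coupled calcium / near-infrared trace pair with known wave times.

    The calcium trace is a sum of Gaussian wave templates plus noise.
    The nIR trace carries a causal release transient per wave — unit-peak
    (1−e^(−t/τr))·e^(−t/τd), starting ``lag_s`` after the wave peak,
    scaled by ``coupling_scale`` — so it is lagged and broadened relative
    to the wave and is zero before the trigger, as a release signal
    evoked by the wave should be.  Independent noise is added to both
    channels, plus an optional initial double-exponential decay
    ``(a1, τ1, a2, τ2)`` on the nIR channel for detrending tests.  Wave
    centers are evenly spaced inside ``margin_s`` edge margins with small
    seeded jitter.

    Returns (cal trace, nir trace, true event frame indices).
    """
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_waves,)).copy()
    if n_waves > 1:
        spacing = (duration_s - 2 * margin_s) / (n_waves - 1)
        if spacing < min_sep_s:
            raise ValueError("infeasible schedule: waves closer than the minimum separation")
        centers = margin_s + spacing * np.arange(n_waves)
    else:
        if duration_s < 2 * margin_s:
            raise ValueError("infeasible schedule: trace shorter than twice the margin")
        centers = np.array([duration_s / 2.0])
    rng = np.random.default_rng(seed)
    jitter_room = max(0.0, ((duration_s - 2 * margin_s) / max(1, n_waves - 1) - min_sep_s) / 2
                      if n_waves > 1 else 1.0)
    centers = centers + rng.uniform(-1, 1, size=n_waves) * min(1.0, jitter_room)
    centers = np.round(centers * fps) / fps   # frame-aligned so event frames are exact

    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    cal = np.zeros(n)
    nir = np.zeros(n)
    for a, c in zip(amps, centers):
        cal += a * np.exp(-((t - c) ** 2) / (2 * wave_sigma_s ** 2))
        nir += coupling_scale * a * _unit_transient(t - c - lag_s,
                                                    nir_tau_rise_s, nir_tau_decay_s)
    if initial_decay is not None:
        a1, tau1, a2, tau2 = initial_decay
        nir += a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    if noise_sd > 0:
        cal = cal + rng.normal(0, noise_sd, n)
        nir = nir + rng.normal(0, noise_sd, n)
    event_frames = np.round(centers * fps).astype(int)
    return (Trace(cal, fps, kind="dff"), Trace(nir, fps, kind="dff"), event_frames)


def make_z_stack(fwhm_um: float, z_step_um: float, n_slices: int,
                 profile_shape: str = "gaussian", noise_sd: float = 0.0, seed: int = 0,
                 shape: tuple[int, int] = (32, 32), peak_intensity: float = 100.0,
                 ) -> tuple[ZStack, float]:
    """Z-stack of a uniform thin film with a known axial profile.

    Per-slice mean intensity follows a Gaussian or Lorentzian of the
    requested FWHM, centered in the stack; per-pixel Gaussian noise is
    added.  Returns the stack and the true FWHM.
    """
    if n_slices * z_step_um <= 2 * fwhm_um:
        raise ValueError("stack range must exceed twice the FWHM")
    z = np.arange(n_slices) * z_step_um
    z0 = z[-1] / 2.0
    if profile_shape == "gaussian":
        sigma = fwhm_um / GAUSSIAN_FWHM_FACTOR
        profile = np.exp(-((z - z0) ** 2) / (2 * sigma ** 2))
    elif profile_shape == "lorentzian":
        hwhm = fwhm_um / 2.0
        profile = 1.0 / (1.0 + ((z - z0) / hwhm) ** 2)
    else:
        raise ValueError(f"unknown profile shape {profile_shape!r}")
    data = peak_intensity * profile[:, None, None] * np.ones((n_slices,) + shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0, noise_sd, size=data.shape)
    return ZStack(data.astype(np.float32), z_step_um), float(fwhm_um)
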