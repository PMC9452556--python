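"""Synthetic calcium traces and registered slice-image scenes.

Every downstream stage of the pipeline is testable against planted ground
truth: the trace generator plants Poisson event times with a step change
in rate at the stimulation onset, and the scene generator plants smooth
"innervation" and "activation" intensity fields inside an elliptical
nucleus together with spatially heterogeneous autofluorescence.

The trace model is

    F(t) = baseline + bleach_slope * t - sum_k A * g(t - t_k) + noise,
    g(u) = (1 - exp(-u/tau_rise)) * exp(-u/tau_decay) / g_max   for u >= 0,

i.e. a *negative-going* indicator: each transient is a transient decrease
of green fluorescence with a finite rise (the indicator tracks the
underlying Ca2+ excursion, which builds over seconds) and exponential
recovery; the kernel is normalised so the planted peak depth is exactly
``A``.  Transient onsets t_k follow an inhomogeneous Poisson process whose
rate steps from ``basal_event_rate`` to ``stim_event_rate`` at
``stim_onset_s``.  Ground truth records both the onsets and the planted
peak times t_k + tau_rise*log(1 + tau_decay/tau_rise) — the latter are
what an event detector is expected to localise.

Successive transients in one ROI cannot start within a transient's width
of each other (they would be one fluorescence excursion, not two), so the
event process is a renewal process with a dead time
(``min_interevent_s``) followed by an exponential wait.  Each rate epoch
is simulated in renewal equilibrium, which makes the expected event count
in a window exactly rate x duration despite the dead time.

Scene images are generated at source resolution (default 10 µm/px) so the
grid-partition stage has real work to do; planted regions are reported at
grid resolution using the same >= 50% coverage rule the partition applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import RoiTrace, SliceRecording

__all__ = [
    "TraceSimConfig",
    "BlobSpec",
    "GaussianFieldSpec",
    "NucleusSpec",
    "SceneSimConfig",
    "GroundTruth",
    "Scene",
    "simulate_trace",
    "simulate_slice_recording",
    "simulate_scene_pair",
]


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration field '{name}': {msg}")


@dataclass(frozen=True)
class TraceSimConfig:
    """Study-design defaults: 3 min basal + 3 min stimulated recording at
    1 Hz, 50 ROIs per subregion, basal rate 0.5 events/min stepping to
    1.25 events/min at onset (rate ratio 2.5).

    Transient duration and event rates are chosen so frames inside
    transients stay below ~20% of each baseline segment — the operating
    regime the 80th-percentile baseline assumes — and the noise level is
    the one implied by the 0.004 event-threshold clamp (silent-trace
    thresholds fall at or below the clamp).
    """

    duration_s: float = 360.0
    frame_rate_hz: float = 1.0
    baseline_level: float = 100.0
    bleach_slope: float = -0.02
    basal_event_rate: float = 0.5   # events/min
    stim_event_rate: float = 1.25   # events/min
    stim_onset_s: float = 180.0
    transient_amplitude: float = 0.15  # fraction of baseline, applied as a DECREASE
    transient_rise_s: float = 1.5
    transient_decay_s: float = 4.0
    min_interevent_s: float = 8.0
    noise_sd: float = 0.002         # fraction of baseline
    n_rois_per_subregion: int = 50
    seed: int = 0

    def validate(self) -> None:
        _check(self.duration_s > 0, "duration_s", "must be > 0")
        _check(self.frame_rate_hz > 0, "frame_rate_hz", "must be > 0")
        _check(self.baseline_level > 0, "baseline_level", "must be > 0")
        _check(self.bleach_slope <= 0, "bleach_slope", "must be <= 0 (bleaching)")
        _check(self.basal_event_rate >= 0, "basal_event_rate", "must be >= 0")
        _check(self.stim_event_rate >= 0, "stim_event_rate", "must be >= 0")
        _check(0 <= self.stim_onset_s <= self.duration_s, "stim_onset_s", "must lie in the recording")
        _check(0 < self.transient_amplitude < 1, "transient_amplitude", "must be in (0, 1)")
        _check(self.transient_rise_s > 0, "transient_rise_s", "must be > 0")
        _check(self.transient_decay_s > 0, "transient_decay_s", "must be > 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.n_rois_per_subregion >= 1, "n_rois_per_subregion", "must be >= 1")
        _check(self.min_interevent_s >= 0, "min_interevent_s", "must be >= 0")
        for name, rate in [
            ("basal_event_rate", self.basal_event_rate),
            ("stim_event_rate", self.stim_event_rate),
        ]:
            _check(
                rate / 60.0 * self.min_interevent_s < 1.0,
                name,
                "rate too high for the configured minimum inter-event interval",
            )

    @property
    def peak_lag_s(self) -> float:
        """Time from transient onset to the planted kernel maximum."""
        return self.transient_rise_s * np.log(
            1.0 + self.transient_decay_s / self.transient_rise_s
        )


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated trace, recording or scene."""

    event_times: dict[str, np.ndarray] = field(default_factory=dict)
    event_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    true_rate_ratio: float | None = None
    planted_active_region: np.ndarray | None = None       # grid-resolution binary
    planted_afferent_region: np.ndarray | None = None     # grid-resolution binary


def _equilibrium_renewal_times(
    rate_per_s: float, dead_s: float, t0: float, t1: float, rng: np.random.Generator
) -> list[float]:
    """Arrival times in [t0, t1) of an equilibrium renewal process.

    Intervals are ``dead_s`` plus an Exp(mu) wait with mu chosen so the
    mean interval is 1/rate; the first arrival is drawn from the
    equilibrium forward-recurrence distribution, so E[count] is exactly
    rate * (t1 - t0).  With dead_s = 0 this is a plain Poisson process.
    """
    if rate_per_s <= 0 or t1 <= t0:
        return []
    mean = 1.0 / rate_per_s
    exp_mean = mean - dead_s  # > 0 enforced by config validation
    times = []
    # forward recurrence: uniform over the dead time w.p. dead/mean,
    # else dead + Exp (memorylessness of the exponential part)
    if rng.uniform() < dead_s / mean:
        t = t0 + rng.uniform(0.0, dead_s)
    else:
        t = t0 + dead_s + rng.exponential(exp_mean)
    while t < t1:
        times.append(t)
        t += dead_s + rng.exponential(exp_mean)
    return times


def _event_times(cfg: TraceSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Transient onset times with a step rate change at the stimulation onset."""
    times: list[float] = []
    for t0, t1, rate_per_min in [
        (0.0, cfg.stim_onset_s, cfg.basal_event_rate),
        (cfg.stim_onset_s, cfg.duration_s, cfg.stim_event_rate),
    ]:
        times += _equilibrium_renewal_times(
            rate_per_min / 60.0, cfg.min_interevent_s, t0, t1, rng
        )
    return np.asarray(times)


def simulate_trace(
    config: TraceSimConfig, roi_index: int, subregion: str = "core"
) -> tuple[RoiTrace, GroundTruth]:
    """Simulate one ROI trace; deterministic given (seed, roi_index)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, roi_index]))
    n = int(round(config.duration_s * config.frame_rate_hz))
    t = np.arange(n) / config.frame_rate_hz
    trace = config.baseline_level + config.bleach_slope * t
    onsets = _event_times(config, rng)
    amp = config.transient_amplitude * config.baseline_level
    tau_r, tau_d = config.transient_rise_s, config.transient_decay_s
    lag = config.peak_lag_s
    g_max = (1.0 - np.exp(-lag / tau_r)) * np.exp(-lag / tau_d)
    for tk in onsets:
        u = t[t >= tk] - tk
        trace[t >= tk] -= amp * (1.0 - np.exp(-u / tau_r)) * np.exp(-u / tau_d) / g_max
    if config.noise_sd > 0:
        trace = trace + rng.normal(
            0.0, config.noise_sd * config.baseline_level, size=n
        )
    roi = RoiTrace(
        roi_id=f"roi{roi_index:04d}",
        subregion=subregion,
        values=trace,
        frame_rate_hz=config.frame_rate_hz,
        stim_onset_s=config.stim_onset_s,
    )
    gt = GroundTruth(
        event_times={roi.roi_id: onsets + lag},
        event_onsets={roi.roi_id: onsets},
        true_rate_ratio=(
            config.stim_event_rate / config.basal_event_rate
            if config.basal_event_rate > 0
            else None
        ),
    )
    return roi, gt


def simulate_slice_recording(
    config: TraceSimConfig, slice_id: str = "slice0", subregions: Sequence[str] = ("core", "shell")
) -> tuple[SliceRecording, GroundTruth]:
    """Simulate one slice: ``n_rois_per_subregion`` traces per subregion."""
    config.validate()
    traces: list[RoiTrace] = []
    gt = GroundTruth(
        true_rate_ratio=(
            config.stim_event_rate / config.basal_event_rate
            if config.basal_event_rate > 0
            else None
        )
    )
    idx = 0
    for sub in subregions:
        for _ in range(config.n_rois_per_subregion):
            roi, roi_gt = simulate_trace(config, idx, subregion=sub)
            old_id = roi.roi_id
            roi = replace_roi_id(roi, f"{slice_id}_{old_id}")
            traces.append(roi)
            gt.event_times[roi.roi_id] = roi_gt.event_times[old_id]
            gt.event_onsets[roi.roi_id] = roi_gt.event_onsets[old_id]
            idx += 1
    rec = SliceRecording(slice_id=slice_id, traces=traces, stim_onset_s=config.stim_onset_s)
    return rec, gt


def replace_roi_id(roi: RoiTrace, new_id: str) -> RoiTrace:
    return RoiTrace(
        roi_id=new_id,
        subregion=roi.subregion,
        values=roi.values,
        frame_rate_hz=roi.frame_rate_hz,
        stim_onset_s=roi.stim_onset_s,
    )


# ---------------------------------------------------------------------------
# Scenes


@dataclass(frozen=True)
class BlobSpec:
    """A circular intensity blob with a logistic (sharp) edge.

    field(d) = amplitude / (1 + exp((d - radius_px) / edge_width_px)),
    truncated to exactly zero beyond radius + 10 edge widths so regions far
    from the blob carry no planted signal at all.

    The planted binary region is d <= radius_px (the half-maximum contour).
    """

    center_rc: tuple[float, float]
    radius_px: float
    amplitude: float
    edge_width_px: float = 2.0

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d = np.hypot(rr - self.center_rc[0], cc - self.center_rc[1])
        field = self.amplitude / (1.0 + np.exp((d - self.radius_px) / self.edge_width_px))
        return np.where(d <= self.radius_px + 10.0 * self.edge_width_px, field, 0.0)

    def region(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d = np.hypot(rr - self.center_rc[0], cc - self.center_rc[1])
        return d <= self.radius_px


@dataclass(frozen=True)
class GaussianFieldSpec:
    """A smooth broad Gaussian intensity field: base + amp * exp(-d^2/2s^2)."""

    center_rc: tuple[float, float]
    sigma_px: float
    amplitude: float
    base: float = 0.0

    def render(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d2 = (rr - self.center_rc[0]) ** 2 + (cc - self.center_rc[1]) ** 2
        return self.base + self.amplitude * np.exp(-d2 / (2.0 * self.sigma_px**2))


@dataclass(frozen=True)
class NucleusSpec:
    """Elliptical nucleus with a concentric elliptical core; shell = rest."""

    center_rc: tuple[float, float]
    semi_axes_px: tuple[float, float]
    core_scale: float = 0.55

    def masks(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        a, b = self.semi_axes_px
        u = ((rr - self.center_rc[0]) / a) ** 2 + ((cc - self.center_rc[1]) / b) ** 2
        nucleus = u <= 1.0
        core = u <= self.core_scale**2
        shell = nucleus & ~core
        return nucleus, core, shell


def _default_afferent(shape_px: tuple[int, int]) -> tuple[BlobSpec, ...]:
    # innervation territories in both subregions (denser in the core)
    return (
        BlobSpec(center_rc=(shape_px[0] * 0.50, shape_px[1] * 0.52), radius_px=60.0, amplitude=6.0),
        BlobSpec(center_rc=(shape_px[0] * 0.53, shape_px[1] * 0.82), radius_px=38.0, amplitude=6.0),
    )


def _default_activation_basal(shape_px: tuple[int, int]) -> tuple[GaussianFieldSpec | BlobSpec, ...]:
    return (GaussianFieldSpec(center_rc=(shape_px[0] * 0.53, shape_px[1] * 0.55), sigma_px=75.0, amplitude=2.0),)


def _default_activation_stim(shape_px: tuple[int, int]) -> tuple[GaussianFieldSpec | BlobSpec, ...]:
    # stimulated activation: one territory per subregion, overlapping the
    # afferent fields, on top of the basal photoconversion gradient
    return (
        GaussianFieldSpec(center_rc=(shape_px[0] * 0.53, shape_px[1] * 0.55), sigma_px=75.0, amplitude=2.0),
        BlobSpec(center_rc=(shape_px[0] * 0.50, shape_px[1] * 0.55), radius_px=50.0, amplitude=5.0),
        # amplitude compensates the weaker basal gradient under the shell
        # territory so both plateaus sit at a comparable activation level
        BlobSpec(center_rc=(shape_px[0] * 0.55, shape_px[1] * 0.80), radius_px=34.0, amplitude=6.2),
    )


@dataclass(frozen=True)
class SceneSimConfig:
    """A registered basal/stimulated slice-image pair plus no-virus controls.

    Geometry is parametric (ellipse nucleus, concentric core), not an
    anatomical atlas; basal and stimulated members are registered to the
    same masks by construction.  Defaults give a 60x80 grid of 50 µm cells
    rendered at 10 µm source pixels.
    """

    grid_shape: tuple[int, int] = (60, 80)
    grid_um: float = 50.0
    source_um_per_px: float = 10.0
    nucleus_spec: NucleusSpec | None = None
    afferent_field_spec: tuple[BlobSpec, ...] | None = None
    activation_basal_spec: tuple[GaussianFieldSpec | BlobSpec, ...] | None = None
    activation_stim_spec: tuple[GaussianFieldSpec | BlobSpec, ...] | None = None
    autofluorescence_spec: GaussianFieldSpec | None = None
    background_level: float = 5.0
    noise_sd: float = 0.5
    n_control_images: int = 9
    background_roi_grid: tuple[int, int, int, int] = (0, 6, 0, 6)  # r0, r1, c0, c1
    seed: int = 0

    @property
    def source_shape(self) -> tuple[int, int]:
        f = self.px_per_grid
        return (self.grid_shape[0] * f, self.grid_shape[1] * f)

    @property
    def px_per_grid(self) -> int:
        f = self.grid_um / self.source_um_per_px
        if abs(f - round(f)) > 1e-9 or f < 1:
            raise ValueError("grid_um must be an integer multiple of source_um_per_px")
        return int(round(f))

    def validate(self) -> None:
        _check(self.grid_shape[0] > 0 and self.grid_shape[1] > 0, "grid_shape", "must be positive")
        _check(self.background_level >= 0, "background_level", "must be >= 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.n_control_images >= 1, "n_control_images", "must be >= 1")

    def resolved(self) -> "SceneSimConfig":
        """Fill in geometry defaults that depend on the image shape."""
        shape = self.source_shape
        nucleus = self.nucleus_spec or NucleusSpec(
            center_rc=(shape[0] * 0.53, shape[1] * 0.55),
            semi_axes_px=(shape[0] * 0.40, shape[1] * 0.38),
        )
        return replace(
            self,
            nucleus_spec=nucleus,
            afferent_field_spec=self.afferent_field_spec
            if self.afferent_field_spec is not None
            else _default_afferent(shape),
            activation_basal_spec=self.activation_basal_spec
            if self.activation_basal_spec is not None
            else _default_activation_basal(shape),
            activation_stim_spec=self.activation_stim_spec
            if self.activation_stim_spec is not None
            else _default_activation_stim(shape),
            autofluorescence_spec=self.autofluorescence_spec
            or GaussianFieldSpec(
                center_rc=(shape[0] * 0.4, shape[1] * 0.6),
                sigma_px=shape[1] * 0.5,
                amplitude=3.0,
                base=2.0,
            ),
        )


@dataclass
class Scene:
    """Source-resolution images and masks for one basal/stim slice pair."""

    basal: np.ndarray
    stim: np.ndarray
    afferent: np.ndarray
    controls: list[np.ndarray]
    nucleus_mask: np.ndarray
    core_mask: np.ndarray
    shell_mask: np.ndarray
    source_um_per_px: float
    grid_um: float
    background_roi_grid: tuple[int, int, int, int]


def _coarsen_region(region_px: np.ndarray, factor: int) -> np.ndarray:
    """Grid cell is planted iff >= 50% of its source pixels are planted."""
    r, c = region_px.shape
    blocks = region_px[: r - r % factor, : c - c % factor].reshape(
        r // factor, factor, c // factor, factor
    )
    return blocks.mean(axis=(1, 3)) >= 0.5


def _render_fields(specs: Sequence[BlobSpec | GaussianFieldSpec], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    for s in specs:
        out += s.render(shape)
    return out


def simulate_scene_pair(config: SceneSimConfig) -> tuple[Scene, GroundTruth]:
    """Render a registered basal/stim image pair, controls, and ground truth.

    stim = autofluorescence + background + stim activation field + noise;
    basal analogously with the basal field; controls carry autofluorescence
    + background + noise only (no virus).  The afferent reporter channel is
    rendered once (innervation does not change between conditions).
    """
    config.validate()
    cfg = config.resolved()
    shape = cfg.source_shape
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    nucleus, core, shell = cfg.nucleus_spec.masks(shape)
    if not nucleus.any():
        raise ValueError("nucleus mask spec produced an empty nucleus")
    auto = cfg.autofluorescence_spec.render(shape)
    base = auto + cfg.background_level

    def noisy(img: np.ndarray) -> np.ndarray:
        if cfg.noise_sd == 0:
            return img.copy()
        return img + rng.normal(0.0, cfg.noise_sd, size=shape)

    afferent_field = _render_fields(cfg.afferent_field_spec, shape)
    basal_field = _render_fields(cfg.activation_basal_spec, shape)
    stim_field = _render_fields(cfg.activation_stim_spec, shape)
    # expression is confined to the nucleus: fields are zero outside it
    afferent_img = noisy(base + np.where(nucleus, afferent_field, 0.0))
    basal_img = noisy(base + np.where(nucleus, basal_field, 0.0))
    stim_img = noisy(base + np.where(nucleus, stim_field, 0.0))
    controls = [noisy(base) for _ in range(cfg.n_control_images)]

    factor = cfg.px_per_grid
    planted_active = np.zeros(cfg.grid_shape, dtype=bool)
    for s in cfg.activation_stim_spec:
        if isinstance(s, BlobSpec):
            planted_active |= _coarsen_region(s.region(shape) & nucleus, factor)
    planted_afferent = np.zeros(cfg.grid_shape, dtype=bool)
    for s in cfg.afferent_field_spec:
        if isinstance(s, BlobSpec):
            planted_afferent |= _coarsen_region(s.region(shape) & nucleus, factor)

    scene = Scene(
        basal=basal_img,
        stim=stim_img,
        afferent=afferent_img,
        controls=controls,
        nucleus_mask=nucleus,
        core_mask=core,
        shell_mask=shell,
        source_um_per_px=cfg.source_um_per_px,
        grid_um=cfg.grid_um,
        background_roi_grid=cfg.background_roi_grid,
    )
    gt = GroundTruth(
        planted_active_region=planted_active,
        planted_afferent_region=planted_afferent,
    )
    return scene, gt
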