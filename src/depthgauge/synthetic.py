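"""Seeded generators for every input the pipeline consumes.

Real inputs to the analysis stages — the EM-reconstructed connectivity
matrix, GCaMP movies, larval swimming videos, and opsin absorbance
spectra — are emulated here with ground truth exposed, so each analysis
stage can be tested end to end.  The connectome fixture reproduces the
circuit topology of the larval head (four cPRCs feeding RGW/NOS
interneurons and flask-shaped sensory-neurosecretory cells, the
rhabdomeric eye circuit with its interneuron layers, and the three
forward bridge sites between them).  The behavior generator implements
an antagonistic two-drive model (broad-band phototaxis up, UV-violet
avoidance down after a ~60 s latency) calibrated so the two drives cancel
at a configurable UV fraction of a 380/480 nm mixture.

Every generator takes an explicit seed; the same seed gives bit-identical
output.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .calcium import FluorescenceMovie
from .connectome import CellTable, CiliaryBranchSet
from .behavior import Trajectory
from .stimulus import AbsorbanceSpectrum, StimulusSchedule

__all__ = [
    "ConnectomeFixtureSpec",
    "BehaviorModelParams",
    "PlantedCell",
    "MovieModelParams",
    "make_reference_connectome",
    "make_branch_set",
    "simulate_movie",
    "default_cell_layout",
    "simulate_trajectories",
    "expected_drift",
    "render_video",
    "simulate_spectrum",
    "raised_cosine",
]

import pandas as pd

# ---------------------------------------------------------------------------
# Connectome fixture

#: Cell classes whose counts are anatomically fixed in the larval head.
_FIXED_COUNTS = {"cPRC": 4, "IN_RGW": 4, "IN_preMN": 6, "MS": 2, "Ser_h1": 2}


@dataclass(frozen=True)
class ConnectomeFixtureSpec:
    """Per-class cell counts and per-edge-class synapse-count ranges.

    Counts for cPRC, IN_RGW, IN_preMN, MS and Ser_h1 are anatomically
    fixed; the remaining classes are configurable.  ``deterministic`` pins
    every synapse count to its range midpoint for exact tests.
    """

    counts: dict = field(
        default_factory=lambda: {
            "cPRC": 4,
            "IN_RGW": 4,
            "IN_NOS": 4,
            "SN_flask": 4,
            "IN_sn": 2,
            "IN_preMN": 6,
            "MS": 2,
            "vMN": 2,
            "IN_pro": 2,
            "rPRC_adult_eye": 4,
            "rPRC_eyespot": 2,
            "Ser_h1": 2,
            "MC": 1,
            "ciliary_band": 2,
        }
    )
    synapse_range: tuple[int, int] = (2, 8)
    deterministic: bool = False

    def __post_init__(self) -> None:
        for cls_name, n in _FIXED_COUNTS.items():
            if self.counts.get(cls_name) != n:
                raise ValueError(f"count for {cls_name} is fixed at {n}")
        for cls_name in ("SN_flask",):
            if self.counts.get(cls_name, 0) < 4:
                raise ValueError("SN_flask count must be >= 4")
        for cls_name in ("IN_sn", "vMN", "IN_pro", "rPRC_eyespot", "ciliary_band"):
            if self.counts.get(cls_name, 0) < 2:
                raise ValueError(f"{cls_name} count must be >= 2")


#: Directed edge classes realized by the fixture (presynaptic class ->
#: postsynaptic classes).  SN_flask cells have no postsynaptic partners;
#: no rPRC-circuit class projects into the cPRC circuit.
_EDGE_CLASSES: tuple[tuple[str, str], ...] = (
    ("cPRC", "IN_RGW"),
    ("cPRC", "IN_NOS"),
    ("cPRC", "SN_flask"),
    ("IN_RGW", "IN_sn"),
    ("IN_RGW", "IN_preMN"),
    ("IN_RGW", "MS"),
    ("IN_RGW", "Ser_h1"),
    ("IN_preMN", "vMN"),
    ("MS", "vMN"),
    ("MS", "IN_pro"),
    ("rPRC_adult_eye", "IN_pro"),
    ("IN_pro", "IN_sn"),
    ("IN_sn", "vMN"),
    ("rPRC_eyespot", "ciliary_band"),
    ("rPRC_eyespot", "vMN"),
    ("Ser_h1", "MC"),
)


def make_reference_connectome(
    spec: ConnectomeFixtureSpec | None = None, seed: int = 0
) -> tuple[CellTable, pd.DataFrame]:
    """Build the reference connectome fixture.

    Every edge class in the head-circuit topology is realized all-to-all
    between its member cells, with synapse counts drawn uniformly from the
    spec's range (or pinned to the midpoint in deterministic mode).
    By construction the only forward bridges from the cPRC circuit into
    the rPRC circuit are the direct IN_RGW->IN_sn synapses and the
    two-hop paths through the IN_preMN and MS cells, and no cell of the
    rPRC circuit is presynaptic to the cPRC circuit.
    """
    if spec is None:
        spec = ConnectomeFixtureSpec()
    rng = np.random.default_rng(seed)
    records = []
    by_class: dict[str, list[str]] = {}
    for cls_name in spec.counts:
        side_cycle = ("left", "right")
        ids = []
        for i in range(spec.counts[cls_name]):
            cid = f"{cls_name}_{i + 1}"
            side = "median" if cls_name in {"MS", "MC"} else side_cycle[i % 2]
            records.append((cid, f"{cls_name} #{i + 1}", cls_name, side))
            ids.append(cid)
        by_class[cls_name] = ids
    cells = CellTable.from_records(records)

    ids = cells.cell_ids
    matrix = pd.DataFrame(0, index=ids, columns=ids, dtype=np.int64)
    lo, hi = spec.synapse_range
    mid = (lo + hi) // 2
    for pre_cls, post_cls in _EDGE_CLASSES:
        for pre in by_class[pre_cls]:
            for post in by_class[post_cls]:
                count = mid if spec.deterministic else int(rng.integers(lo, hi + 1))
                matrix.loc[pre, post] = count
    return cells, matrix


def make_branch_set(
    n_branches: int = 50,
    diameter_mean_nm: float = 130.0,
    diameter_sd_nm: float = 19.0,
    total_length_um: float = 677.0,
    seed: int = 0,
) -> CiliaryBranchSet:
    """Random ciliary branch set with lengths summing exactly to a target.

    Branch lengths are a Dirichlet split of the total; diameters are
    normal, truncated positive by resampling.  Defaults match the measured
    branch statistics of one cPRC (130 +/- 19 nm diameter, 677 um total
    length).
    """
    if n_branches < 1 or total_length_um <= 0:
        raise ValueError("need a positive branch count and total length")
    rng = np.random.default_rng(seed)
    lengths = rng.dirichlet(np.full(n_branches, 5.0)) * total_length_um
    diameters = rng.normal(diameter_mean_nm, diameter_sd_nm, n_branches)
    while np.any(diameters <= 0):
        bad = diameters <= 0
        diameters[bad] = rng.normal(diameter_mean_nm, diameter_sd_nm, bad.sum())
    return CiliaryBranchSet(diameters, lengths, basal_body_counts=None)


# ---------------------------------------------------------------------------
# Fluorescence movies


@dataclass(frozen=True)
class PlantedCell:
    """Ground truth for one synthetic cell body in the movie."""

    label: str
    cell_class: str  # cPRC | IN_RGW | SN_early | SN_late
    row: float
    col: float
    radius_px: float = 3.0


@dataclass(frozen=True)
class MovieModelParams:
    """Parameters of the synthetic GCaMP movie.

    cPRC pixels have an elevated resting baseline (the high dark-state
    calcium of these cells makes them identifiable without stimulation);
    ``knockout`` lowers it and flattens the cPRC kernels, emulating the
    c-opsin1 loss-of-function phenotype.  ``stim_gain`` is a multiplicative
    whole-frame gain applied during stimulation epochs (stimulation-laser
    bleed-through); ``noise_scale`` scales photon (shot-like) noise with
    sd = noise_scale * sqrt(intensity).
    """

    frame_shape: tuple[int, int] = (254, 254)
    frame_interval_s: float = 0.8
    cells: tuple[PlantedCell, ...] = ()
    background: float = 50.0
    baseline: float = 150.0
    cprc_baseline: float = 400.0
    noise_scale: float = 1.0
    stim_gain: float = 1.05
    knockout: bool = False


def default_cell_layout(frame_shape: tuple[int, int] = (254, 254)) -> tuple[PlantedCell, ...]:
    """Plant 4 cPRCs, 4 RGW interneurons, 2 early and 2 late sensory neurons
    on a regular grid well inside the frame."""
    h, w = frame_shape
    classes = ["cPRC"] * 4 + ["IN_RGW"] * 4 + ["SN_early"] * 2 + ["SN_late"] * 2
    cells = []
    n_cols = 4
    for i, cls_name in enumerate(classes):
        r = h * (0.25 + 0.25 * (i // n_cols))
        c = w * (0.2 + 0.2 * (i % n_cols))
        cells.append(PlantedCell(f"{cls_name}_{i}", cls_name, r, c, radius_px=max(2.0, h / 24)))
    return tuple(cells)


def _kernel_biphasic(t: np.ndarray, offset_rel: float) -> np.ndarray:
    dip = -0.35 * (t / 6.0) * np.exp(1.0 - t / 6.0)
    rise = 1.5 * 0.5 * (1.0 + np.tanh((t - 30.0) / 8.0))
    return np.where(t >= 0, dip + rise, 0.0)


def _kernel_sustained_dip(t: np.ndarray, offset_rel: float) -> np.ndarray:
    env = np.clip(t / 6.0, 0.0, 1.0)
    decay = np.where(t > offset_rel, np.exp(-(t - offset_rel) / 15.0), 1.0)
    return np.where(t >= 0, -0.35 * env * decay, 0.0)


def _kernel_onset(t: np.ndarray, offset_rel: float) -> np.ndarray:
    return np.where(t >= 0, 0.9 / (1.0 + np.exp(-(t - 3.0) / 1.5)) * np.exp(-t / 90.0), 0.0)


def _kernel_delayed(t: np.ndarray, offset_rel: float) -> np.ndarray:
    return np.where(t >= 0, 0.9 * 0.5 * (1.0 + np.tanh((t - 30.0) / 8.0)), 0.0)


def _kernel_none(t: np.ndarray, offset_rel: float) -> np.ndarray:
    return np.zeros_like(t)


#: Wavelength-conditional response kernels per cell class (dF/F scale).
_CLASS_KERNELS = {
    "cPRC": {405.0: _kernel_biphasic, 488.0: _kernel_sustained_dip},
    "IN_RGW": {405.0: _kernel_biphasic, 488.0: _kernel_none},
    "SN_early": {405.0: _kernel_onset, 488.0: _kernel_none},
    "SN_late": {405.0: _kernel_delayed, 488.0: _kernel_delayed},
}
#: Blue-response amplitude scaling (SN_late responds to blue, but weakly).
_BLUE_SCALE = {"SN_late": 0.3}

#: Joint cell type recovered by the classifier for each planted class.
GROUND_TRUTH_TYPES = {
    "cPRC": "cPRC_like",
    "IN_RGW": "RGW_follower",
    "SN_early": "SN_early",
    "SN_late": "SN_late",
}


def simulate_movie(
    params: MovieModelParams,
    stimulus: tuple[int, int, float],
    n_frames: int,
    seed: int = 0,
) -> tuple[FluorescenceMovie, tuple[PlantedCell, ...]]:
    """Render a synthetic GCaMP movie for one stimulation program.

    ``stimulus`` is (onset_frame, offset_frame, wavelength_nm).  Each
    planted cell is a Gaussian blob whose intensity follows its class- and
    wavelength-specific dF/F kernel on top of its resting baseline; the
    whole frame is scaled by ``stim_gain`` during the stimulation epoch
    and shot-like Gaussian noise is added.  Returns the movie plus the
    planted ground truth.
    """
    onset, offset, wavelength = stimulus
    if not 0 <= onset < offset <= n_frames:
        raise ValueError("stimulus epoch outside the movie")
    h, w = params.frame_shape
    for cell in params.cells:
        if not (0 <= cell.row < h and 0 <= cell.col < w):
            raise ValueError(f"cell {cell.label} out of frame bounds")
    rng = np.random.default_rng(seed)
    t_frames = np.arange(n_frames, dtype=float)
    t_rel = (t_frames - onset) * params.frame_interval_s
    offset_rel = (offset - onset) * params.frame_interval_s

    clean = np.full((n_frames, h, w), params.background, dtype=float)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for cell in params.cells:
        if cell.cell_class == "cPRC":
            base = params.baseline if params.knockout else params.cprc_baseline
            kernel_fn = _kernel_none if params.knockout else _CLASS_KERNELS["cPRC"][wavelength]
        else:
            base = params.baseline
            kernel_fn = _CLASS_KERNELS[cell.cell_class][wavelength]
        dff = kernel_fn(t_rel, offset_rel)
        if wavelength == 488.0:
            dff = dff * _BLUE_SCALE.get(cell.cell_class, 1.0)
        blob = np.exp(
            -((rr - cell.row) ** 2 + (cc - cell.col) ** 2) / (2.0 * (cell.radius_px / 1.5) ** 2)
        )
        clean += base * (1.0 + dff)[:, None, None] * blob[None, :, :]

    gain = np.where((t_frames >= onset) & (t_frames < offset), params.stim_gain, 1.0)
    clean *= gain[:, None, None]
    if params.noise_scale > 0:
        clean = clean + rng.normal(0.0, params.noise_scale * np.sqrt(clean))
    movie = FluorescenceMovie(
        np.clip(clean, 0.0, None),
        params.frame_interval_s,
        ((onset, offset, wavelength),),
    )
    return movie, params.cells


# ---------------------------------------------------------------------------
# Behavior


def raised_cosine(wavelength_nm, center_nm: float, half_width_nm: float):
    """Raised-cosine sensitivity bump: 1 at the center, 0 beyond +/- half width."""
    wl = np.asarray(wavelength_nm, dtype=float)
    x = (wl - center_nm) / half_width_nm
    out = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class BehaviorModelParams:
    """Two-drive model of larval vertical swimming.

    Upward drift is phototaxis_speed * S_pt(lambda); downward drift is
    avoidance_speed * S_uv(lambda), switched on ``avoidance_latency_s``
    after stimulus onset (the behavioral latency of the UV response,
    about one minute).  Sensitivity curves are raised-cosine bumps: the
    phototaxis curve is broad (UV through green), the avoidance curve is
    c-opsin1-like, peaked in the UV-violet.  These are behavioral
    stand-ins, not opsin absorbance spectra; their half-widths were chosen
    so downward responses span ~340-400 nm, upward ~440-600 nm and
    ~420 nm is close to neutral.

    ``avoidance_speed=None`` calibrates it from the zero-net-drift
    condition at ``balance_fraction`` under the 380/480 nm mixture:
    v_uv * f* * S_uv(380) = v_pt * (f* * S_pt(380) + (1 - f*) * S_pt(480)).
    The knockout flag zeroes the avoidance drive.
    """

    phototaxis_center_nm: float = 490.0
    phototaxis_half_width_nm: float = 130.0
    avoidance_center_nm: float = 380.0
    avoidance_half_width_nm: float = 62.0
    phototaxis_speed_mm_s: float = 0.3
    avoidance_speed_mm_s: float | None = None
    avoidance_latency_s: float = 60.0
    latency_ramp_s: float = 0.0  # 0 = hard switch; >0 = linear ramp width
    noise_mm_sqrt_s: float = 0.15
    balance_fraction: float = 0.40
    knockout: bool = False
    arena_height_mm: float = 160.0
    arena_width_mm: float = 31.0

    def phototaxis_sensitivity(self, wavelength_nm):
        return raised_cosine(wavelength_nm, self.phototaxis_center_nm, self.phototaxis_half_width_nm)

    def avoidance_sensitivity(self, wavelength_nm):
        return raised_cosine(wavelength_nm, self.avoidance_center_nm, self.avoidance_half_width_nm)

    def calibrated_avoidance_speed(
        self, uv_wavelength_nm: float = 380.0, fill_wavelength_nm: float = 480.0
    ) -> float:
        """Avoidance speed solving zero net drift at the balance fraction."""
        if self.avoidance_speed_mm_s is not None:
            return self.avoidance_speed_mm_s
        f = self.balance_fraction
        up = self.phototaxis_speed_mm_s * (
            f * self.phototaxis_sensitivity(uv_wavelength_nm)
            + (1.0 - f) * self.phototaxis_sensitivity(fill_wavelength_nm)
        )
        down_per_speed = f * self.avoidance_sensitivity(uv_wavelength_nm)
        if down_per_speed <= 0:
            raise ValueError("avoidance sensitivity vanishes at the UV wavelength")
        return up / down_per_speed


def _schedule_fractions(stimulus) -> dict[float, float]:
    if isinstance(stimulus, StimulusSchedule):
        return stimulus.wavelength_fractions()
    return {float(stimulus): 1.0}


def expected_drift(
    params: BehaviorModelParams, stimulus, t_s: float | np.ndarray
) -> float | np.ndarray:
    """Closed-form expected vertical drift (mm/s, positive upward) at time t.

    ``stimulus`` is a wavelength in nm or a duty-cycle
    :class:`~depthgauge.stimulus.StimulusSchedule`; its per-wavelength
    time fractions weight the two sensitivity curves.  Boundary reflection
    is ignored.
    """
    fractions = _schedule_fractions(stimulus)
    s_pt = sum(f * params.phototaxis_sensitivity(wl) for wl, f in fractions.items())
    s_uv = sum(f * params.avoidance_sensitivity(wl) for wl, f in fractions.items())
    t = np.asarray(t_s, dtype=float)
    if params.knockout:
        gate = np.zeros_like(t)
    elif params.latency_ramp_s > 0:
        gate = np.clip((t - params.avoidance_latency_s) / params.latency_ramp_s, 0.0, 1.0)
    else:
        gate = (t > params.avoidance_latency_s).astype(float)
    v_uv = 0.0 if params.knockout else params.calibrated_avoidance_speed()
    drift = params.phototaxis_speed_mm_s * s_pt - v_uv * s_uv * gate
    return float(drift) if np.isscalar(t_s) else drift


def simulate_trajectories(
    params: BehaviorModelParams,
    stimulus,
    n_larvae: int,
    duration_s: float = 240.0,
    dt_s: float = 1.0,
    seed: int = 0,
    z0_range_mm: tuple[float, float] = (40.0, 120.0),
) -> list[Trajectory]:
    """Simulate larval trajectories under a stimulus program.

    Vertical motion is the deterministic two-drive drift plus Gaussian
    diffusion, with reflecting boundaries at the bottom (0) and the water
    surface (arena height).  Horizontal motion is a reflected random walk
    across the column width.  ``stimulus`` is a wavelength (nm) or a
    :class:`~depthgauge.stimulus.StimulusSchedule`; stimulus onset is at
    t = 0.
    """
    if n_larvae < 1:
        raise ValueError("need at least one larva")
    if dt_s <= 0 or duration_s <= 0:
        raise ValueError("duration and time step must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    n_steps = t.size - 1
    drift = expected_drift(params, stimulus, t[:-1]) * dt_s
    sigma = params.noise_mm_sqrt_s * math.sqrt(dt_s)

    z0 = rng.uniform(*z0_range_mm, size=n_larvae)
    steps = drift[None, :] + rng.normal(0.0, sigma, size=(n_larvae, n_steps))
    z = np.concatenate([z0[:, None], z0[:, None] + np.cumsum(steps, axis=1)], axis=1)
    z = _reflect(z, params.arena_height_mm)

    x0 = rng.uniform(0.0, params.arena_width_mm, size=n_larvae)
    x_steps = rng.normal(0.0, sigma, size=(n_larvae, n_steps))
    x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(x_steps, axis=1)], axis=1)
    x = _reflect(x, params.arena_width_mm)

    return [
        Trajectory(f"larva_{i:04d}", t, x[i], z[i], params.arena_height_mm)
        for i in range(n_larvae)
    ]


def _reflect(values: np.ndarray, upper: float) -> np.ndarray:
    """Fold positions back into [0, upper] (reflecting boundaries)."""
    folded = np.mod(values, 2.0 * upper)
    return np.where(folded > upper, 2.0 * upper - folded, folded)


def render_video(
    trajs: Sequence[Trajectory],
    frame_shape: tuple[int, int],
    px_per_mm: float,
    particle_radius_px: float = 2.0,
    frame_interval_s: float = 1.0,
    amplitude: float = 150.0,
    background: float = 10.0,
    noise_scale: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render trajectories as a video of Gaussian-blob particles.

    Positions are sampled at frame times by linear interpolation; z maps
    to rows measured down from the bottom row (row = n_rows - 1 -
    z * px_per_mm).  Particles drifting off-frame are clipped to the
    border.  Returns (stack, truth) where truth[frame, larva] holds the
    rendered (row, col) positions.
    """
    if px_per_mm <= 0:
        raise ValueError("calibration px_per_mm must be positive")
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    t_end = min(tr.t_s[-1] for tr in trajs) if trajs else 0.0
    times = np.arange(0.0, t_end + frame_interval_s / 2.0, frame_interval_s)
    stack = np.full((times.size, h, w), background, dtype=float)
    truth = np.zeros((times.size, len(trajs), 2), dtype=float)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    for j, tr in enumerate(trajs):
        z = np.interp(times, tr.t_s, tr.z_mm)
        x = np.interp(times, tr.t_s, tr.x_mm)
        rows = np.clip(h - 1 - z * px_per_mm, 0, h - 1)
        cols = np.clip(x * px_per_mm, 0, w - 1)
        truth[:, j, 0] = rows
        truth[:, j, 1] = cols
        for fi in range(times.size):
            stack[fi] += amplitude * np.exp(
                -((rr - rows[fi]) ** 2 + (cc - cols[fi]) ** 2)
                / (2.0 * particle_radius_px**2)
            )
    if noise_scale > 0:
        stack += rng.normal(0.0, noise_scale, size=stack.shape)
    return np.clip(stack, 0.0, None), truth


# ---------------------------------------------------------------------------
# Spectra


def simulate_spectrum(
    lambda_max_nm: float = 384.0,
    half_width_nm: float = 50.0,
    noise_scale: float = 0.005,
    seed: int = 0,
    grid_nm: np.ndarray | None = None,
) -> tuple[AbsorbanceSpectrum, AbsorbanceSpectrum]:
    """Synthetic dark/bleached absorbance-spectrum pair.

    The dark pigment is a log-normal-in-wavelength template peaked at
    ``lambda_max_nm`` (a documented stand-in, not a claim about opsin
    photochemistry).  Bleaching depletes the dark peak and forms a
    blue-shifted photoproduct, so both the dark spectrum and the
    dark-light difference spectrum peak at ``lambda_max_nm``.
    """
    if grid_nm is None:
        grid_nm = np.arange(300.0, 501.0, 1.0)
    grid_nm = np.asarray(grid_nm, dtype=float)
    if not grid_nm[0] <= lambda_max_nm <= grid_nm[-1]:
        raise ValueError("lambda-max must lie within the wavelength grid")
    rng = np.random.default_rng(seed)
    s = half_width_nm / (2.355 * lambda_max_nm)  # FWHM -> log-sigma
    dark_clean = np.exp(-0.5 * (np.log(grid_nm / lambda_max_nm) / s) ** 2)
    product = 0.45 * np.exp(-0.5 * ((grid_nm - (lambda_max_nm - 84.0)) / 30.0) ** 2)
    bleached_clean = 0.2 * dark_clean + product
    dark = dark_clean + rng.normal(0.0, noise_scale, grid_nm.size)
    bleached = bleached_clean + rng.normal(0.0, noise_scale, grid_nm.size)
    return AbsorbanceSpectrum(grid_nm, dark), AbsorbanceSpectrum(grid_nm, bleached)
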