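"""Larval vertical-swimming behavior analysis.

Larvae in a vertical water column swim up (phototaxis, mediated by the
pigmented rhabdomeric eyes) or down (UV avoidance, mediated by the ciliary
photoreceptors).  This module tracks larvae in video frames, computes
30-s-binned and windowed vertical displacement, builds per-wavelength
action spectra, estimates the UV fraction at which the two antagonistic
drives cancel (the balance point of the ratio-chromatic depth gauge), and
runs multiplicity-corrected group comparisons.

Sign convention: z increases upward in mm.  Video row coordinates increase
downward, so rows are negated at calibration time when converting pixels
to column coordinates.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage import measure

__all__ = [
    "Trajectory",
    "DisplacementStat",
    "DisplacementSeries",
    "ActionSpectrum",
    "RatioResponse",
    "NoSignChangeError",
    "ANALYSIS_WINDOWS",
    "track_particles",
    "bin_displacement",
    "net_displacement",
    "action_spectrum",
    "balance_point",
    "holm_sidak_reject",
    "sidak_bonferroni_reject",
    "compare_groups",
    "trajectories_to_frame",
    "trajectories_from_frame",
]

#: Named analysis windows (seconds relative to stimulus onset).
#: "column" covers 1.5-3.5 min after onset (vertical-column action spectra);
#: "action" is the last 2 min of a 3.5-min stimulus; "cuvette" the last
#: 45 s of a 60-s stimulus; "bins" marks 30-s binning from onset.
ANALYSIS_WINDOWS: dict[str, tuple[float, float]] = {
    "column": (90.0, 210.0),
    "action": (90.0, 210.0),
    "cuvette": (15.0, 60.0),
}


@dataclass(frozen=True)
class Trajectory:
    """One larva's time-stamped positions in the vertical arena (mm)."""

    larva_id: str
    t_s: np.ndarray
    x_mm: np.ndarray
    z_mm: np.ndarray
    arena_height_mm: float = 160.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_mm, dtype=float)
        z = np.asarray(self.z_mm, dtype=float)
        for name, arr in (("t_s", t), ("x_mm", x), ("z_mm", z)):
            object.__setattr__(self, name, arr)
        if not (t.shape == x.shape == z.shape) or t.ndim != 1:
            raise ValueError("t, x, z must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if z.size and (z.min() < -1e-9 or z.max() > self.arena_height_mm + 1e-9):
            raise ValueError("z outside [0, arena height]")

    def covers(self, t0: float, t1: float) -> bool:
        return self.t_s.size > 0 and self.t_s[0] <= t0 and self.t_s[-1] >= t1

    def z_at(self, t: float) -> float:
        return float(np.interp(t, self.t_s, self.z_mm))


def trajectories_to_frame(trajs: Iterable[Trajectory]) -> pd.DataFrame:
    """Long-format table (larva_id, t_s, x_mm, z_mm)."""
    parts = [
        pd.DataFrame(
            {"larva_id": tr.larva_id, "t_s": tr.t_s, "x_mm": tr.x_mm, "z_mm": tr.z_mm}
        )
        for tr in trajs
    ]
    if not parts:
        return pd.DataFrame(columns=["larva_id", "t_s", "x_mm", "z_mm"])
    return pd.concat(parts, ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame, arena_height_mm: float = 160.0) -> list[Trajectory]:
    return [
        Trajectory(str(lid), g["t_s"].to_numpy(), g["x_mm"].to_numpy(),
                   g["z_mm"].to_numpy(), arena_height_mm)
        for lid, g in df.groupby("larva_id", sort=True)
    ]


def track_particles(
    frames: np.ndarray,
    intensity_threshold: float,
    max_link_distance_px: float,
    min_track_length: int = 3,
    *,
    px_per_mm: float,
    frame_interval_s: float = 1.0,
    arena_height_mm: float | None = None,
) -> list[Trajectory]:
    """Detect and link bright particles into trajectories.

    Detections are centroids of connected components above
    ``intensity_threshold``.  Frame-to-frame linking is greedy nearest
    neighbor within ``max_link_distance_px`` (closest pairs first, ties to
    the lowest track id); unmatched detections start new tracks.  Tracks
    shorter than ``min_track_length`` frames are dropped.  Calibration
    (``px_per_mm``) is required; z is measured upward from the bottom frame
    row.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (frame, row, column) stack")
    if px_per_mm <= 0:
        raise ValueError("calibration px_per_mm must be positive")
    n_rows = frames.shape[1]
    if arena_height_mm is None:
        arena_height_mm = (n_rows - 1) / px_per_mm

    # active tracks: list of dict(frames, rows, cols, last)
    tracks: list[dict] = []
    active: list[int] = []
    for fi, frame in enumerate(frames):
        labels = measure.label(frame > intensity_threshold)
        dets = np.array(
            [p.centroid for p in measure.regionprops(labels)], dtype=float
        ).reshape(-1, 2)
        used_det: set[int] = set()
        matched_tracks: set[int] = set()
        if dets.size and active:
            last = np.array([tracks[ti]["pos"] for ti in active])
            dist = np.linalg.norm(last[:, None, :] - dets[None, :, :], axis=2)
            pairs = sorted(
                (dist[a, d], active[a], d)
                for a in range(len(active))
                for d in range(len(dets))
                if dist[a, d] <= max_link_distance_px
            )
            for _dist, ti, d in pairs:
                if ti in matched_tracks or d in used_det:
                    continue
                tr = tracks[ti]
                tr["frames"].append(fi)
                tr["rows"].append(dets[d, 0])
                tr["cols"].append(dets[d, 1])
                tr["pos"] = dets[d]
                matched_tracks.add(ti)
                used_det.add(d)
        for d in range(len(dets)):
            if d not in used_det:
                tracks.append(
                    {"frames": [fi], "rows": [dets[d, 0]], "cols": [dets[d, 1]], "pos": dets[d]}
                )
        active = [ti for ti, tr in enumerate(tracks) if tr["frames"][-1] == fi]

    out: list[Trajectory] = []
    for i, tr in enumerate(tracks):
        if len(tr["frames"]) < min_track_length:
            continue
        t = np.asarray(tr["frames"], dtype=float) * frame_interval_s
        rows = np.asarray(tr["rows"])
        cols = np.asarray(tr["cols"])
        z = np.clip((n_rows - 1 - rows) / px_per_mm, 0.0, arena_height_mm)
        out.append(Trajectory(f"track_{i:04d}", t, cols / px_per_mm, z, arena_height_mm))
    return out


@dataclass(frozen=True)
class DisplacementStat:
    """Mean vertical displacement over a window, with dispersion."""

    mean_mm: float
    sem_mm: float
    n: int
    per_larva_mm: np.ndarray


@dataclass(frozen=True)
class DisplacementSeries:
    """Binned vertical displacement: contiguous half-open bins [t, t+w)."""

    bin_edges_s: np.ndarray
    mean_mm: np.ndarray
    sem_mm: np.ndarray
    n: np.ndarray

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def net_displacement(trajs: Sequence[Trajectory], window: tuple[float, float]) -> DisplacementStat:
    """Mean over larvae of z(window end) - z(window start), positive upward.

    Only larvae whose tracks cover the whole window contribute.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    deltas = np.array([tr.z_at(t1) - tr.z_at(t0) for tr in trajs if tr.covers(t0, t1)])
    if deltas.size == 0:
        raise ValueError("no trajectory covers the analysis window")
    sem = float(deltas.std(ddof=1) / np.sqrt(deltas.size)) if deltas.size > 1 else 0.0
    return DisplacementStat(float(deltas.mean()), sem, int(deltas.size), deltas)


def bin_displacement(
    trajs: Sequence[Trajectory],
    bin_width_s: float = 30.0,
    t_start_s: float = 0.0,
    t_end_s: float | None = None,
) -> DisplacementSeries:
    """Per-bin mean vertical displacement across larvae (mm per bin).

    Larvae present for the whole bin only; larvae entering or leaving the
    field mid-bin are excluded from that bin.  Per-bin displacements
    telescope: their sum equals the window net displacement for larvae
    present throughout.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    if not trajs:
        raise ValueError("no trajectories given")
    if t_end_s is None:
        t_end_s = max(tr.t_s[-1] for tr in trajs)
    edges = np.arange(t_start_s, t_end_s + 1e-9, bin_width_s)
    if edges.size < 2:
        raise ValueError("window shorter than one bin")
    means, sems, ns = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        deltas = np.array([tr.z_at(hi) - tr.z_at(lo) for tr in trajs if tr.covers(lo, hi)])
        ns.append(deltas.size)
        means.append(deltas.mean() if deltas.size else np.nan)
        sems.append(
            deltas.std(ddof=1) / np.sqrt(deltas.size) if deltas.size > 1 else 0.0
        )
    return DisplacementSeries(edges, np.asarray(means), np.asarray(sems), np.asarray(ns))


@dataclass(frozen=True)
class ActionSpectrum:
    """Net vertical displacement per stimulus wavelength in a fixed window."""

    wavelengths_nm: np.ndarray
    displacement_mm: np.ndarray
    sem_mm: np.ndarray
    n: np.ndarray
    window_s: tuple[float, float]


def action_spectrum(
    trials: Mapping[float, Sequence[Trajectory]],
    window: tuple[float, float] = ANALYSIS_WINDOWS["column"],
) -> ActionSpectrum:
    """Net displacement per wavelength (downward avoidance is negative).

    Assumes the per-wavelength stimuli were delivered at equal photon
    irradiance, as in the monochromator assays.
    """
    if not trials:
        raise ValueError("empty trial set")
    wavelengths = np.array(sorted(trials), dtype=float)
    stats = [net_displacement(trials[wl], window) for wl in wavelengths]
    return ActionSpectrum(
        wavelengths,
        np.array([s.mean_mm for s in stats]),
        np.array([s.sem_mm for s in stats]),
        np.array([s.n for s in stats]),
        tuple(window),
    )


class NoSignChangeError(ValueError):
    """The ratio-response never crosses zero (e.g. the UV/red control)."""


@dataclass(frozen=True)
class RatioResponse:
    """Net displacement as a function of the UV fraction of a mixture."""

    uv_fractions: np.ndarray
    displacement_mm: np.ndarray
    sem_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.uv_fractions, dtype=float)
        d = np.asarray(self.displacement_mm, dtype=float)
        object.__setattr__(self, "uv_fractions", f)
        object.__setattr__(self, "displacement_mm", d)
        if f.shape != d.shape or f.ndim != 1:
            raise ValueError("fractions and displacements must match")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("UV fractions must lie in [0, 1]")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("UV fractions must be strictly increasing")


def balance_point(response: RatioResponse) -> float:
    """UV fraction at which net vertical displacement crosses zero.

    Linear interpolation between the two grid fractions bracketing the
    upward-to-downward (positive-to-negative) sign change; with multiple
    crossings, the one descending from the largest positive response is
    used.  Raises :class:`NoSignChangeError` when the response never
    changes sign (as for UV/red mixtures, which never drive upward
    swimming).
    """
    f, d = response.uv_fractions, response.displacement_mm
    exact = np.nonzero(d == 0)[0]
    crossings = [i for i in range(f.size - 1) if d[i] > 0 and d[i + 1] < 0]
    if not crossings:
        if exact.size:
            return float(f[exact[0]])
        raise NoSignChangeError("net displacement does not change sign across the UV-fraction grid")
    i = max(crossings, key=lambda j: d[j])
    return float(f[i] + d[i] * (f[i + 1] - f[i]) / (d[i] - d[i + 1]))


def holm_sidak_reject(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down rejection decisions for a p-value vector.

    Sort p ascending; stage i (1-based) uses alpha_i = 1 - (1-alpha)^(1/(m-i+1));
    rejection stops at the first p exceeding its stage threshold.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        stage_alpha = 1.0 - (1.0 - alpha) ** (1.0 / (m - rank))
        if p[idx] <= stage_alpha:
            reject[idx] = True
        else:
            break
    return reject


def sidak_bonferroni_reject(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Single-step Sidak correction: reject p <= 1 - (1-alpha)^(1/m)."""
    p = np.asarray(p, dtype=float)
    return p <= 1.0 - (1.0 - alpha) ** (1.0 / p.size)


def compare_groups(
    groups_a: Sequence[np.ndarray] | np.ndarray,
    groups_b: Sequence[np.ndarray] | np.ndarray,
    correction: str = "holm_sidak",
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Welch two-sample t-tests with family-wise multiplicity correction.

    ``groups_a`` and ``groups_b`` are matched sequences of samples, one
    pair per comparison (a single pair of 1-D arrays is also accepted).
    ``correction`` is ``holm_sidak`` (step-down) or ``sidak_bonferroni``
    (single step).  Zero-variance identical pairs are flagged as
    degenerate (p set to 1, never rejected).  Returns a table with t, p,
    rejection decisions and flags.
    """
    if isinstance(groups_a, np.ndarray) and np.asarray(groups_a).ndim == 1:
        groups_a, groups_b = [groups_a], [groups_b]
    groups_a = [np.asarray(g, dtype=float) for g in groups_a]
    groups_b = [np.asarray(g, dtype=float) for g in groups_b]
    if len(groups_a) != len(groups_b):
        raise ValueError("mismatched number of comparisons")
    if any(g.size < 2 for g in groups_a + groups_b):
        raise ValueError("each group needs at least 2 observations")
    if correction not in {"holm_sidak", "sidak_bonferroni"}:
        raise ValueError(f"unknown correction {correction!r}")

    t_stats, p_values, degenerate = [], [], []
    for a, b in zip(groups_a, groups_b):
        degen = a.std() == 0 and b.std() == 0
        if degen:
            t_val, p_val = 0.0, 1.0
        else:
            t_val, p_val = sstats.ttest_ind(a, b, equal_var=False)
        t_stats.append(float(t_val))
        p_values.append(float(p_val))
        degenerate.append(degen)
    p_arr = np.asarray(p_values)
    if correction == "holm_sidak":
        reject = holm_sidak_reject(p_arr, alpha)
    else:
        reject = sidak_bonferroni_reject(p_arr, alpha)
    reject = reject & ~np.asarray(degenerate)
    return pd.DataFrame(
        {
            "comparison": labels if labels is not None else list(range(len(groups_a))),
            "t": t_stats,
            "p": p_values,
            "reject": reject,
            "degenerate": degenerate,
        }
    )
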