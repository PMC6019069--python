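"""GCaMP calcium-imaging analysis: dF/F0 traces, correlation maps, response typing.

The ciliary photoreceptors (cPRCs) of the larva respond biphasically to
violet (405 nm) light — a transient calcium dip (hyperpolarization proxy)
followed by a strong rise (depolarization proxy) — but show a sustained dip
only under blue (488 nm) light of equal photon flux.  Downstream neurons
(IN_RGW interneurons, early- and late-responding sensory neurons) show
wavelength-specific response types.  This module extracts ROI traces,
normalizes them as dF/F0 (fixed pre-stimulus window or time-dependent
reference-region baseline), builds pixelwise Pearson correlation maps
against a seed trace, and classifies responses.

Conventions: pixel coordinates are 0-based (row, column); frame times are
frame_index * frame_interval with t = 0 at the first frame.  Movies are
assumed motion-registered.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceMovie",
    "RegionOfInterest",
    "Trace",
    "ResponseFeatures",
    "CellClassification",
    "extract_trace",
    "compute_dff",
    "correlation_map",
    "render_correlation_map",
    "detect_response",
    "classify_cells",
]


@dataclass(frozen=True)
class FluorescenceMovie:
    """Intensity stack indexed (frame, row, column) with stimulus annotations.

    ``stimuli`` is a list of (onset_frame, offset_frame, wavelength_nm)
    tuples; the default frame interval of 0.8 s corresponds to 1.25
    frames/s.
    """

    data: np.ndarray
    frame_interval_s: float = 0.8
    stimuli: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("movie must be a (frame, row, column) stack")
        if self.frame_interval_s <= 0:
            raise ValueError("frame interval must be positive")
        for onset, offset, _wl in self.stimuli:
            if not 0 <= onset < offset <= data.shape[0]:
                raise ValueError(f"stimulus ({onset}, {offset}) outside movie")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class RegionOfInterest:
    """A set of 0-based (row, column) pixels."""

    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=int)
        cols = np.asarray(self.cols, dtype=int)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)
        if rows.size == 0 or rows.shape != cols.shape:
            raise ValueError("ROI must be non-empty with matching row/col arrays")

    @classmethod
    def from_disk(cls, center: tuple[float, float], radius: float,
                  frame_shape: tuple[int, int]) -> "RegionOfInterest":
        """Circular ROI of given pixel radius clipped to the frame."""
        r0, c0 = center
        rr, cc = np.mgrid[0:frame_shape[0], 0:frame_shape[1]]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        return cls(*np.nonzero(mask))

    @classmethod
    def from_rect(cls, row_slice: slice, col_slice: slice,
                  frame_shape: tuple[int, int]) -> "RegionOfInterest":
        rr, cc = np.mgrid[row_slice, col_slice]
        mask = np.zeros(frame_shape, dtype=bool)
        mask[rr, cc] = True
        return cls(*np.nonzero(mask))


@dataclass(frozen=True)
class Trace:
    """A labeled dF/F0 (or raw) time series."""

    time_s: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be equal-length 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")


def extract_trace(movie: FluorescenceMovie, roi: RegionOfInterest) -> np.ndarray:
    """Per-frame arithmetic mean of the ROI pixels (raw intensity series)."""
    if roi.rows.max() >= movie.frame_shape[0] or roi.cols.max() >= movie.frame_shape[1]:
        raise ValueError("ROI extends outside the frame")
    if roi.rows.min() < 0 or roi.cols.min() < 0:
        raise ValueError("ROI coordinates must be nonnegative")
    return movie.data[:, roi.rows, roi.cols].mean(axis=1)


def compute_dff(
    raw: np.ndarray,
    baseline: tuple[int, int] | np.ndarray,
    frame_interval_s: float = 0.8,
    pre_window: tuple[int, int] | None = None,
    label: str = "",
) -> Trace:
    """Normalize a raw intensity series to dF/F0.

    Two baseline modes:

    * fixed window — ``baseline`` is a (start_frame, end_frame) half-open
      window; F0 is the mean of the pre-stimulus window and
      dF/F0 = (F - F0) / F0.
    * time-dependent — ``baseline`` is an intensity series from a reference
      region with no calcium activity; dF/F0(t) = (F(t) - F0(t)) / F0(t).
      This cancels per-frame multiplicative artefacts (stimulation-laser
      bleed-through, detector gain) exactly.  If ``pre_window`` is also
      given, the normalized ratio is additionally re-referenced to its
      pre-stimulus mean so the trace starts at 0.
    """
    raw = np.asarray(raw, dtype=float)
    t = np.arange(raw.size) * frame_interval_s
    if isinstance(baseline, tuple) and len(baseline) == 2 and np.isscalar(baseline[0]):
        start, end = baseline
        f0 = float(raw[start:end].mean())
        if f0 <= 0:
            raise ValueError("baseline must be strictly positive")
        return Trace(t, (raw - f0) / f0, label)
    f0t = np.asarray(baseline, dtype=float)
    if f0t.shape != raw.shape:
        raise ValueError("reference baseline series must match trace length")
    if np.any(f0t <= 0):
        raise ValueError("baseline must be strictly positive")
    ratio = raw / f0t
    if pre_window is not None:
        start, end = pre_window
        r0 = float(ratio[start:end].mean())
        if r0 <= 0:
            raise ValueError("pre-stimulus ratio baseline must be positive")
        return Trace(t, (ratio - r0) / r0, label)
    return Trace(t, ratio - 1.0, label)


def correlation_map(movie: FluorescenceMovie, seed: Trace | np.ndarray) -> np.ndarray:
    """Pearson correlation of a seed trace with every pixel's time series.

    Pixels with zero variance (or a zero-variance seed) map to 0 so the
    result renders cleanly on a symmetric [-1, 1] scale.
    """
    seed_values = seed.values if isinstance(seed, Trace) else np.asarray(seed, dtype=float)
    if seed_values.size != movie.n_frames:
        raise ValueError("seed length must equal the movie frame count")
    x = seed_values - seed_values.mean()
    sx = np.sqrt((x**2).sum())
    pixels = movie.data.reshape(movie.n_frames, -1)
    y = pixels - pixels.mean(axis=0)
    sy = np.sqrt((y**2).sum(axis=0))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, x @ y / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    return r.reshape(movie.frame_shape)


def render_correlation_map(corr: np.ndarray, path) -> None:
    """Write a correlation map as a two-color diverging heat map on [-1, 1]."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(corr, cmap="bwr", vmin=-1.0, vmax=1.0, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


@dataclass(frozen=True)
class ResponseFeatures:
    """Features of one stimulus response.

    ``response_class`` is one of ``biphasic_cPRC``, ``hyperpolarizing_only``,
    ``onset_depolarizing``, ``delayed_depolarizing`` or ``none``.
    """

    response_class: str
    dip_present: bool
    dip_time_s: float | None = None
    depol_onset_time_s: float | None = None
    depol_amplitude: float | None = None

    def __post_init__(self) -> None:
        if (
            self.dip_time_s is not None
            and self.depol_onset_time_s is not None
            and self.depol_onset_time_s < self.dip_time_s
        ):
            raise ValueError("depolarization onset cannot precede the dip")


def _first_sustained(mask: np.ndarray, min_run: int) -> int | None:
    """Index of the first run of at least ``min_run`` consecutive True values."""
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def detect_response(
    trace: Trace,
    onset_s: float,
    offset_s: float,
    dip_threshold: float | None = None,
    depol_threshold: float | None = None,
    onset_window_s: float = 10.0,
    min_run: int = 3,
    threshold_floor: float = 0.05,
) -> ResponseFeatures:
    """Classify a dF/F0 trace into a stimulus-response type.

    A dip is the first sustained (>= ``min_run`` frames) excursion below
    -dip_threshold after stimulus onset; a depolarization is the first
    sustained excursion above +depol_threshold after the dip (or after
    onset when there is no dip).  Depolarization after stimulus offset
    still counts — the delayed rise outlives the stimulus.  Thresholds
    default to 3x the pre-stimulus standard deviation, floored at
    ``threshold_floor`` dF/F0 so noise-free traces remain classifiable.

    Decision table: dip then rise -> ``biphasic_cPRC``; dip without rise ->
    ``hyperpolarizing_only``; rise within ``onset_window_s`` of onset, no
    dip -> ``onset_depolarizing``; later rise, no dip ->
    ``delayed_depolarizing``; otherwise ``none``.
    """
    t, v = trace.time_s, trace.values
    if not (t[0] <= onset_s < offset_s <= t[-1] + 1e-9):
        raise ValueError("stimulus window must lie within the trace")
    pre = v[t < onset_s]
    sigma = float(pre.std()) if pre.size else 0.0
    if dip_threshold is None:
        dip_threshold = max(3.0 * sigma, threshold_floor)
    if depol_threshold is None:
        depol_threshold = max(3.0 * sigma, threshold_floor)
    if dip_threshold <= 0 or depol_threshold <= 0:
        raise ValueError("thresholds must be positive")

    post = t >= onset_s
    idx_post = np.nonzero(post)[0]
    dip_start = _first_sustained(v[idx_post] < -dip_threshold, min_run)
    dip_idx = idx_post[dip_start] if dip_start is not None else None

    if dip_idx is not None:
        below = v < -dip_threshold
        i = dip_idx
        while i < v.size and below[i]:
            i += 1
        search_from = i  # rise is looked for after the dip has ended
        dip_seg = slice(dip_idx, i)
        dip_time = float(t[dip_idx + int(np.argmin(v[dip_seg]))])
    else:
        search_from = idx_post[0]
        dip_time = None

    rise_rel = _first_sustained(v[search_from:] > depol_threshold, min_run)
    if rise_rel is not None:
        rise_idx = search_from + rise_rel
        rise_time = float(t[rise_idx])
        amplitude = float(v[rise_idx:].max())
    else:
        rise_time = None
        amplitude = None

    if dip_idx is not None and rise_time is not None:
        cls = "biphasic_cPRC"
    elif dip_idx is not None:
        cls = "hyperpolarizing_only"
    elif rise_time is not None:
        cls = (
            "onset_depolarizing"
            if rise_time - onset_s <= onset_window_s
            else "delayed_depolarizing"
        )
    else:
        cls = "none"
    return ResponseFeatures(cls, dip_idx is not None, dip_time, rise_time, amplitude)


@dataclass(frozen=True)
class CellClassification:
    """Joint cell type from violet and blue responses."""

    cell_type: str
    per_wavelength: Mapping[float, ResponseFeatures] = field(default_factory=dict)


def classify_cells(
    traces: Mapping[str, Mapping[float, Trace]],
    stimuli: Mapping[float, tuple[float, float]],
    violet_nm: float = 405.0,
    blue_nm: float = 488.0,
    weak_ratio: float = 0.5,
    **detect_kwargs,
) -> dict[str, CellClassification]:
    """Assign a joint cell type from responses to violet and blue programs.

    ``traces`` maps cell label -> wavelength -> dF/F0 trace; ``stimuli``
    maps wavelength -> (onset_s, offset_s).  Joint types:

    * ``cPRC_like`` — biphasic at violet, hyperpolarizing-only at blue;
    * ``RGW_follower`` — follows the cPRC biphasic pattern at violet, no
      blue response;
    * ``SN_early`` — onset depolarization at violet only;
    * ``SN_late`` — delayed depolarization at violet; blue response absent
      or weak (amplitude < ``weak_ratio`` of the violet amplitude);
    * ``none`` otherwise.
    """
    for wl in (violet_nm, blue_nm):
        if wl not in stimuli:
            raise ValueError(f"missing stimulus window for {wl} nm")
    out: dict[str, CellClassification] = {}
    for cell, per_wl in traces.items():
        if violet_nm not in per_wl or blue_nm not in per_wl:
            raise ValueError(f"cell {cell!r} lacks a {violet_nm} or {blue_nm} nm trace")
        feats = {
            wl: detect_response(per_wl[wl], *stimuli[wl], **detect_kwargs)
            for wl in (violet_nm, blue_nm)
        }
        fv, fb = feats[violet_nm], feats[blue_nm]
        if fv.response_class == "biphasic_cPRC" and fb.response_class == "hyperpolarizing_only":
            cell_type = "cPRC_like"
        elif fv.response_class == "biphasic_cPRC" and fb.response_class == "none":
            cell_type = "RGW_follower"
        elif fv.response_class == "onset_depolarizing" and fb.response_class == "none":
            cell_type = "SN_early"
        elif fv.response_class == "delayed_depolarizing" and _blue_weak_or_absent(
            fv, fb, weak_ratio
        ):
            cell_type = "SN_late"
        else:
            cell_type = "none"
        out[cell] = CellClassification(cell_type, feats)
    return out


def _blue_weak_or_absent(fv: ResponseFeatures, fb: ResponseFeatures, weak_ratio: float) -> bool:
    if fb.response_class == "none":
        return True
    if fb.depol_amplitude is None or fv.depol_amplitude in (None, 0):
        return False
    return fb.depol_amplitude / fv.depol_amplitude < weak_ratio
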