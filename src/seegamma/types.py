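"""Shared data containers and constants for the sEEG gamma-power pipeline.

All times are in milliseconds and are anchored to the onset of the static
frame (t = 0) unless stated otherwise.  A *lead* is a single recording
contact; analyses operate on binned gamma-band (50-150 Hz) power expressed
in z units relative to the 1-s pre-stimulus baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

# --- study design constants -------------------------------------------------

#: the five possible static-frame durations (ms)
STATIC_DURATIONS_MS: tuple[int, ...] = (275, 450, 575, 725, 875)
#: duration of the full-length video clip (ms)
LONG_VIDEO_MS: int = 1166
#: baseline epoch (BEp) relative to static onset
BASELINE_WINDOW_MS: tuple[float, float] = (-1000.0, 0.0)
#: static epoch (SEp): 200-ms window starting 75 ms after static onset
STATIC_EPOCH_WINDOW_MS: tuple[float, float] = (75.0, 275.0)
#: analysed frequency band (Hz)
GAMMA_BAND_HZ: tuple[float, float] = (50.0, 150.0)
#: binary stimulus factors (2**6 = 64 distinct videos)
STIMULUS_FACTORS: tuple[str, ...] = (
    "actor", "action", "hand_shape", "hand_position", "size", "inversion",
)
#: surface nodes assigned to every lead
NODES_PER_LEAD: int = 7
#: geodesic-disk radius (mm) and logistic node-weight parameters
DISK_RADIUS_MM: float = 10.0
WEIGHT_STEEPNESS_PER_MM: float = 2.0
WEIGHT_MIDPOINT_MM: float = 7.5

TASKS: tuple[str, str] = ("action", "actor")
LEAD_CLASSES: tuple[str, ...] = ("doubly", "static", "task", "none")


# --- trial and behavioral records -------------------------------------------

@dataclass
class TrialRecord:
    """One trial of the 2 (task) x 2 (length) design.

    ``rt`` is measured from static-frame onset (see docs/methods.md for the
    anchor convention); ``factors`` holds the six binary stimulus factors.
    """

    trial_id: int
    subject: str
    task: str                      # "action" | "actor"
    length: str                    # "long" | "short"
    block: int
    static_duration: int           # one of STATIC_DURATIONS_MS
    video_duration: float          # 1166 for long; truncation point for short
    truncation_offset: float | None = None   # ms, short trials only
    factors: dict[str, bool] = field(default_factory=dict)
    rt: float | None = None        # ms from static onset
    correct: bool | None = None
    ied_flag: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.static_duration not in STATIC_DURATIONS_MS:
            raise ValueError(
                f"static_duration must be one of {STATIC_DURATIONS_MS}"
            )

    @property
    def static_end_ms(self) -> float:
        return float(self.static_duration)


def trials_to_frame(trials: Iterable[TrialRecord]):
    """Flatten trial records into a pandas DataFrame (one row per trial)."""
    import pandas as pd

    rows = []
    for t in trials:
        row = {
            "trial_id": t.trial_id, "subject": t.subject, "task": t.task,
            "length": t.length, "block": t.block,
            "static_duration": t.static_duration,
            "video_duration": t.video_duration,
            "truncation_offset": t.truncation_offset,
            "rt": t.rt, "correct": t.correct, "ied_flag": t.ied_flag,
        }
        for k in STIMULUS_FACTORS:
            row[f"factor_{k}"] = t.factors.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


# --- voltage and power time courses ------------------------------------------

@dataclass
class VoltageEpoch:
    """Raw multichannel-free voltage snippet for one channel and trial.

    ``samples`` are microvolts at ``sfreq`` Hz; ``t0_offset_ms`` gives the
    time of the first sample relative to static onset.
    """

    samples: np.ndarray
    sfreq: float = 1000.0
    channel: str = ""
    trial_id: int | None = None
    t0_offset_ms: float = -1000.0


@dataclass
class RawPowerCourse:
    """Binned, not-yet-normalized band power for one channel and trial."""

    values: np.ndarray
    bin_ms: float
    t0_offset_ms: float
    channel: str = ""
    trial_id: int | None = None
    boundary_mask: np.ndarray | None = None   # bins inside wavelet edge support

    @property
    def bin_centers_ms(self) -> np.ndarray:
        n = len(self.values)
        return self.t0_offset_ms + (np.arange(n) + 0.5) * self.bin_ms


@dataclass
class GammaTimeCourse:
    """Binned z-scored gamma power for one lead (one trial or an average)."""

    values: np.ndarray
    bin_ms: float
    t0_offset_ms: float
    lead_id: str = ""
    trial_id: int | str | None = None   # int, or "average"
    n_trials_averaged: int = 1
    flags: dict = field(default_factory=dict)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        n = len(self.values)
        return self.t0_offset_ms + (np.arange(n) + 0.5) * self.bin_ms

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        c = self.bin_centers_ms
        return (c >= window[0]) & (c < window[1])

    def window_mean(self, window: tuple[float, float]) -> float:
        m = self.window_mask(window)
        if not m.any():
            raise ValueError(f"no bins inside window {window}")
        return float(self.values[m].mean())


@dataclass
class LeadTimeCourses:
    """Per-trial binned z-scored traces for one lead (trials x bins)."""

    values: np.ndarray               # shape (n_trials, n_bins)
    bin_ms: float
    t0_offset_ms: float
    lead_id: str
    trial_ids: np.ndarray            # shape (n_trials,)
    flags: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)   # generator ground truth

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def bin_centers_ms(self) -> np.ndarray:
        n = self.values.shape[1]
        return self.t0_offset_ms + (np.arange(n) + 0.5) * self.bin_ms

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        c = self.bin_centers_ms
        return (c >= window[0]) & (c < window[1])

    def trial_index(self, trial_id: int) -> int:
        idx = np.flatnonzero(self.trial_ids == trial_id)
        if len(idx) == 0:
            raise KeyError(f"trial {trial_id} not in lead {self.lead_id}")
        return int(idx[0])

    def get_trial(self, trial_id: int) -> GammaTimeCourse:
        i = self.trial_index(trial_id)
        return GammaTimeCourse(
            values=self.values[i], bin_ms=self.bin_ms,
            t0_offset_ms=self.t0_offset_ms, lead_id=self.lead_id,
            trial_id=int(trial_id),
        )

    def average(self, trial_ids: Sequence[int] | None = None) -> GammaTimeCourse:
        if trial_ids is None:
            sub = self.values
            n = self.n_trials
        else:
            rows = [self.trial_index(t) for t in trial_ids]
            sub = self.values[rows]
            n = len(rows)
        if n == 0:
            raise ValueError("cannot average over zero trials")
        return GammaTimeCourse(
            values=sub.mean(axis=0), bin_ms=self.bin_ms,
            t0_offset_ms=self.t0_offset_ms, lead_id=self.lead_id,
            trial_id="average", n_trials_averaged=n,
        )


# --- leads, mesh, maps --------------------------------------------------------

@dataclass
class LeadRecord:
    """A recording lead: identity, anatomy and mesh assignment."""

    lead_id: str
    subject: str = ""
    hemisphere: str = "right"       # "left" | "right"
    region: str = "other"           # ATL-L, ATL-R, FG, OTC, OFC, other
    node_ids: np.ndarray | None = None   # exactly NODES_PER_LEAD mesh nodes
    true_class: str | None = None   # generator ground truth, if synthetic
    flags: dict = field(default_factory=dict)


@dataclass
class ToyMesh:
    """Triangulated surface patch: node coordinates (mm) and triangles."""

    nodes: np.ndarray      # (n_nodes, 3)
    triangles: np.ndarray  # (n_tris, 3) int
    node_region: np.ndarray | None = None   # per-node region label (object)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) int array."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)


@dataclass
class DiskWeights:
    """Geodesic disk around one node with logistic distance weights."""

    origin: int
    members: dict[int, float]       # node -> weight in (0, 1]
    radius_mm: float = DISK_RADIUS_MM


@dataclass
class SurfaceMap:
    """Per-node map (sampling density or relative responsiveness) + mask."""

    values: np.ndarray
    kind: str                       # "density" | "relative_responsiveness"
    mask: np.ndarray                # True where the node is masked OUT


# --- analysis results ---------------------------------------------------------

@dataclass
class SpecificityIndices:
    """Task (R_pa) and static (R_sv) specificity, R = (A1-A2)/(A1+A2)."""

    r_pa: float
    r_sv: float
    clamped_pa: bool = False
    clamped_sv: bool = False
    undefined_pa: bool = False
    undefined_sv: bool = False


@dataclass
class LeadClassification:
    """Responsiveness screen + Tukey-rule specificity class for one lead."""

    lead_id: str
    overall_responsive: bool
    p_task: float
    p_interaction: float
    lead_class: str = "none"        # doubly | static | task | none
    r_pa: float = float("nan")
    r_sv: float = float("nan")
    clamped_pa: bool = False
    clamped_sv: bool = False
    flags: dict = field(default_factory=dict)


@dataclass
class ResponseTiming:
    """Threshold-crossing onset latency and duration for one lead."""

    latency_ms: float
    duration_ms: float
    threshold_level: float
    valid: bool
    censored: bool = False
    per_static_duration: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


@dataclass
class SubjectTimingSummary:
    """Per-subject regional mean latency paired with mean reaction time."""

    subject: str
    region: str
    mean_latency_ms: float
    mean_rt_ms: float
    n_leads: int


@dataclass
class LeadRTCorrelation:
    """Trial-wise correlation between adjusted-window gamma power and RT."""

    lead_id: str
    hemisphere: str
    r: float
    p: float
    n_trials: int
    window_ms: tuple[float, float]
    flags: dict = field(default_factory=dict)


__all__ = [n for n in dir() if not n.startswith("_")]
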