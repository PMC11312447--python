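"""Event-related averaging with trial filtering and cluster-bootstrap
standard errors."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .physio import FeatureSeries


@dataclass
class EventTable:
    onsets_s: np.ndarray
    trial_type: np.ndarray | None = None
    response: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if np.any(np.diff(self.onsets_s) < 0):
            raise ValueError("onsets must be sorted ascending")
        if self.trial_type is None:
            self.trial_type = np.array(["event"] * self.onsets_s.size)
        else:
            self.trial_type = np.asarray(self.trial_type)
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=bool)

    def __len__(self) -> int:
        return self.onsets_s.size


@dataclass
class EventAverage:
    time_s: np.ndarray
    mean: np.ndarray
    se: np.ndarray | None = None
    n_trials: int = 0
    n_subjects: int = 0
    subject_means: np.ndarray | None = None  # subjects x time


def filter_trials(events: EventTable, min_gap_s: float = 30.0,
                  require_response: bool = False) -> EventTable:
    """Drop trials closer than ``min_gap_s`` to an adjacent trial (both
    members of a close pair are removed) and, optionally, non-responses."""
    onsets = events.onsets_s
    n = onsets.size
    keep = np.ones(n, dtype=bool)
    if n > 1:
        gaps = np.diff(onsets)
        close = gaps < min_gap_s
        keep[:-1] &= ~close
        keep[1:] &= ~close
    if require_response:
        if events.response is None:
            raise ValueError("require_response set but no response column")
        keep &= events.response
    return EventTable(
        onsets_s=onsets[keep],
        trial_type=events.trial_type[keep],
        response=None if events.response is None else events.response[keep],
        subject_id=events.subject_id,
    )


def _extract_trials(series: FeatureSeries, onsets_s: np.ndarray,
                    grid_s: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-trial segments interpolated to the peri-event grid."""
    v = series.values
    t = np.arange(v.size) * series.tr_s
    run_end = t[-1]
    segs, dropped = [], 0
    for onset in onsets_s:
        if onset + grid_s[-1] > run_end or onset < t[0]:
            dropped += 1
            continue
        segs.append(np.interp(onset + grid_s, t, v))
    return (np.array(segs) if segs else np.empty((0, grid_s.size))), dropped


def event_average(per_subject: list, window_s: float = 29.0,
                  zscore: bool = True) -> EventAverage:
    """Group event-related average from onset out to ``window_s``.

    ``per_subject`` is a list of ``(FeatureSeries, EventTable)`` pairs.
    Each run is z-scored (unless disabled), trial segments are linearly
    interpolated to a peri-event grid with step equal to the repetition
    time, averaged over trials within subject and then across subjects.
    Trials whose window exceeds the run end are dropped with a warning.
    """
    if not per_subject:
        raise ValueError("no subjects supplied")
    tr = per_subject[0][0].tr_s
    grid = np.arange(0.0, window_s + 1e-9, tr)
    subject_means, n_trials, n_dropped = [], 0, 0
    for series, events in per_subject:
        v = series.values
        if zscore:
            sd = v.std()
            v = (v - v.mean()) / (sd if sd > 0 else 1.0)
            series = FeatureSeries(values=v, tr_s=series.tr_s,
                                   name=series.name, units="z")
        segs, dropped = _extract_trials(series, events.onsets_s, grid)
        n_dropped += dropped
        if segs.shape[0] == 0:
            continue
        n_trials += segs.shape[0]
        subject_means.append(segs.mean(axis=0))
    if n_dropped:
        warnings.warn(f"{n_dropped} trial(s) dropped: window exceeds run end",
                      stacklevel=2)
    if not subject_means:
        raise ValueError("no usable trials")
    subject_means = np.array(subject_means)
    mean = subject_means.mean(axis=0)
    se = None
    if subject_means.shape[0] >= 2:
        se = cluster_bootstrap_se(subject_means)
    return EventAverage(time_s=grid, mean=mean, se=se, n_trials=n_trials,
                        n_subjects=subject_means.shape[0],
                        subject_means=subject_means)


def cluster_bootstrap_se(subject_means: np.ndarray, n_boot: int = 500,
                         seed: int = 0) -> np.ndarray:
    """SE of the group mean by resampling subjects with replacement."""
    subject_means = np.atleast_2d(np.asarray(subject_means, dtype=float))
    n_sub = subject_means.shape[0]
    if n_sub < 2:
        raise ValueError("cluster bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    reps = subject_means[idx].mean(axis=1)  # n_boot x time
    return reps.std(axis=0)


def eeg_event_power(per_subject_trials: list, time_s: np.ndarray,
                    baseline_s=(-1.0, 0.0), window_s: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Baseline log-ratio (dB) event-related time-frequency average.

    ``per_subject_trials`` is a list over subjects of arrays shaped
    trials x time x frequency on the common peri-event ``time_s`` grid
    (which must include the 1 s pre-onset baseline). Per subject: average
    power across trials, then 10*log10(P(t,f) / mean_baseline P(f));
    subjects are then averaged. Returns ``(db_map, out_time_s)`` with the
    map cropped to onset..window_s.
    """
    time_s = np.asarray(time_s, dtype=float)
    base = (time_s >= baseline_s[0]) & (time_s < baseline_s[1])  # up to onset
    if time_s[0] > baseline_s[0] or not base.any():
        raise ValueError("peri-event grid lacks the pre-onset baseline span")
    keep = (time_s >= 0) & (time_s <= window_s)
    maps = []
    for trials in per_subject_trials:
        trials = np.asarray(trials, dtype=float)
        p = trials.mean(axis=0)  # time x freq
        p_base = p[base].mean(axis=0, keepdims=True)
        db = 10.0 * np.log10(p / p_base)
        maps.append(db[keep])
    return np.mean(maps, axis=0), time_s[keep]
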