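"""Fibre-photometry preprocessing and peri-event analysis.

The recording protocol: GCaMP6s fluorescence on a 470 nm channel and a
calcium-independent 415 nm control channel, both at 40 samples/s, with a
2-minute intruder-free baseline before the behavioural trial. Processing:

1. subtract the control channel from the signal channel (cancels
   autofluorescence, bleaching and motion);
2. dF/F against F0 = mean of the corrected trace over the FINAL minute of
   the baseline window;
3. z-score the dF/F trace (by default over the whole session).

Peri-event analysis aligns the processed trace to behaviour-bout onsets and
distinguishes, on attack days, bouts of social investigation that precede
an attack from bouts that occur in isolation, and attacks with versus
without a prior investigation bout — the bout taxonomy behind the
appetitive-to-consummatory transition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

INVESTIGATION = "investigation"
ATTACK = "attack"

CLASS_INV_PRECEDING = "investigation_preceding_attack"
CLASS_INV_ISOLATED = "investigation_isolated"
CLASS_ATTACK_WITH_INV = "attack_with_prior_investigation"
CLASS_ATTACK_WITHOUT_INV = "attack_without_prior_investigation"


@dataclass
class PhotometrySession:
    """One two-channel recording with its behaviour annotations."""

    time_s: np.ndarray
    signal: np.ndarray
    control: np.ndarray
    rate_hz: float
    baseline_window_s: tuple[float, float]
    events: pd.DataFrame  # columns: label, start_s, stop_s

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.signal) != n or len(self.control) != n:
            raise ValueError("signal, control and time_s must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if n > 1:
            dt = np.diff(self.time_s)
            if dt.min() <= 0:
                raise ValueError("time_s must be strictly increasing")
            if abs(dt.mean() * self.rate_hz - 1.0) > 0.01:
                raise ValueError("rate_hz inconsistent with time_s spacing")
        b0, b1 = self.baseline_window_s
        if b1 <= b0:
            raise ValueError("empty baseline window")
        starts = self.events["start_s"] if len(self.events) else pd.Series(dtype=float)
        if len(starts) and starts.min() < b1:
            raise ValueError("baseline window must precede the first event")

    def to_files(self, trace_path, events_path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "signal": self.signal, "control": self.control}
        ).to_csv(trace_path, sep="\t", index=False, float_format="%.10g")
        self.events.to_csv(events_path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_files(
        cls, trace_path, events_path, rate_hz: float, baseline_window_s: tuple[float, float]
    ) -> "PhotometrySession":
        trace = pd.read_csv(trace_path, sep="\t")
        events = pd.read_csv(events_path, sep="\t")
        return cls(
            time_s=trace["time_s"].to_numpy(),
            signal=trace["signal"].to_numpy(),
            control=trace["control"].to_numpy(),
            rate_hz=rate_hz,
            baseline_window_s=baseline_window_s,
            events=events,
        )


def preprocess(
    session: PhotometrySession,
    zscore_scope: str = "session",
    control_fit: str = "subtract",
) -> np.ndarray:
    """z-scored dF/F trace for one session.

    ``control_fit='subtract'`` applies the raw channel difference;
    ``'regression'`` instead subtracts the least-squares projection of the
    control onto the signal (a common variant, off by default).
    ``zscore_scope`` is ``'session'`` (default) or ``'baseline'``.
    """
    b0, b1 = session.baseline_window_s
    if b1 - b0 < 60.0:
        raise ValueError("need at least 60 s of baseline for F0")
    if control_fit == "subtract":
        corrected = session.signal - session.control
    elif control_fit == "regression":
        slope, intercept, *_ = stats.linregress(session.control, session.signal)
        corrected = session.signal - (slope * session.control + intercept)
    else:
        raise ValueError(f"unknown control_fit {control_fit!r}")

    f0_mask = (session.time_s >= b1 - 60.0) & (session.time_s < b1)
    f0 = corrected[f0_mask].mean()
    if f0 <= 0:
        raise ValueError("baseline F0 <= 0; dF/F undefined")
    dff = (corrected - f0) / f0

    if zscore_scope == "session":
        ref = dff
    elif zscore_scope == "baseline":
        ref = dff[(session.time_s >= b0) & (session.time_s < b1)]
    else:
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
    sd = ref.std()
    if sd == 0:
        raise ValueError("zero-variance dF/F; z-score undefined")
    return (dff - ref.mean()) / sd


def classify_bouts(events: pd.DataFrame, gap_s: float = 2.0) -> tuple[pd.DataFrame, str]:
    """Label bouts by their relation to attacks.

    An investigation bout is ``investigation_preceding_attack`` when an
    attack starts within ``gap_s`` seconds after the bout ends, otherwise
    ``investigation_isolated``. An attack is
    ``attack_with_prior_investigation`` when an investigation bout ends
    within ``gap_s`` seconds before (or at) its start. Bouts with other
    labels keep their label as their class. Returns the annotated table and
    the session-level label (``attack_day`` / ``no_attack_day``).
    """
    if gap_s < 0:
        raise ValueError("gap_s must be non-negative")
    ev = events.sort_values("start_s", kind="stable").reset_index(drop=True)
    if (ev["stop_s"] < ev["start_s"]).any():
        raise ValueError("bout stop before start")
    for label, grp in ev.groupby("label"):
        g = grp.sort_values("start_s")
        if (g["start_s"].to_numpy()[1:] < g["stop_s"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping {label!r} bouts")

    attack_starts = ev.loc[ev["label"] == ATTACK, "start_s"].to_numpy()
    inv_stops = ev.loc[ev["label"] == INVESTIGATION, "stop_s"].to_numpy()

    classes: list[str] = []
    for _, row in ev.iterrows():
        if row["label"] == INVESTIGATION:
            dt = attack_starts - row["stop_s"]
            hit = np.any((dt >= 0) & (dt <= gap_s))
            classes.append(CLASS_INV_PRECEDING if hit else CLASS_INV_ISOLATED)
        elif row["label"] == ATTACK:
            dt = row["start_s"] - inv_stops
            hit = np.any((dt >= 0) & (dt <= gap_s))
            classes.append(CLASS_ATTACK_WITH_INV if hit else CLASS_ATTACK_WITHOUT_INV)
        else:
            classes.append(str(row["label"]))
    ev = ev.assign(bout_class=classes)
    session_label = "attack_day" if len(attack_starts) else "no_attack_day"
    return ev, session_label


@dataclass
class PeriEventSet:
    """Trials x timepoints matrix of z-scored dF/F aligned to bout onsets."""

    matrix: np.ndarray
    window_s: tuple[float, float]
    event_class: str
    alignment: int  # onset index within each row
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]


def peri_event(
    trace: np.ndarray,
    rate_hz: float,
    labelled_events: pd.DataFrame,
    window_s: tuple[float, float] = (4.0, 4.0),
) -> dict[str, PeriEventSet]:
    """Extract per-class peri-event matrices aligned to bout starts.

    Trials whose window falls outside the recording are excluded and
    counted in ``n_excluded``; a class with no usable trial yields an empty
    set rather than an error.
    """
    pre_s, post_s = window_s
    pre_n = int(round(pre_s * rate_hz))
    post_n = int(round(post_s * rate_hz))
    if pre_n + post_n < 1:
        raise ValueError("window too short for sampling rate")
    out: dict[str, PeriEventSet] = {}
    for cls, grp in labelled_events.groupby("bout_class", sort=True):
        rows, excluded = [], 0
        for start in grp["start_s"]:
            i = int(round(start * rate_hz))
            if i - pre_n < 0 or i + post_n > len(trace):
                excluded += 1
                continue
            rows.append(trace[i - pre_n : i + post_n])
        matrix = np.vstack(rows) if rows else np.empty((0, pre_n + post_n))
        out[str(cls)] = PeriEventSet(matrix, window_s, str(cls), pre_n, excluded)
    return out


@dataclass
class PrePostSummary:
    """Per-class before/after quantification of peri-event activity."""

    event_class: str
    pre_means: np.ndarray
    post_means: np.ndarray
    mean_difference: float
    p_paired: float | None  # Wilcoxon signed-rank; None for <2 trials

    @property
    def differences(self) -> np.ndarray:
        return self.post_means - self.pre_means


def pre_post_stats(
    perisets: dict[str, PeriEventSet]
) -> tuple[dict[str, PrePostSummary], pd.DataFrame]:
    """Per-trial pre/post means, paired tests per class, and pairwise
    between-class comparison of post-minus-pre differences (rank-sum)."""
    summaries: dict[str, PrePostSummary] = {}
    for cls, ps in perisets.items():
        if ps.n_trials == 0:
            continue
        pre = ps.matrix[:, : ps.alignment].mean(axis=1)
        post = ps.matrix[:, ps.alignment :].mean(axis=1)
        diff = post - pre
        if ps.n_trials >= 2 and np.any(diff != 0):
            p = float(stats.wilcoxon(pre, post).pvalue)
        elif ps.n_trials >= 2:
            p = 1.0
        else:
            p = None  # single trial: descriptive only
        summaries[cls] = PrePostSummary(cls, pre, post, float(diff.mean()), p)

    rows = []
    names = sorted(summaries)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            da, db = summaries[a].differences, summaries[b].differences
            if len(da) >= 2 and len(db) >= 2:
                p = float(stats.mannwhitneyu(da, db, alternative="two-sided").pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "mean_diff_a": float(da.mean()),
                    "mean_diff_b": float(db.mean()),
                    "p_between": p,
                }
            )
    between = pd.DataFrame(rows, columns=["class_a", "class_b", "mean_diff_a", "mean_diff_b", "p_between"])
    return summaries, between
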