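"""Event-history data model and CSV I/O for alternating-sojourn trials.

A trial is stored as two tables: one row per subject (covariates, nominal
study length, dropout outcome) and one row per sojourn (an uninterrupted
interval spent in the asymptomatic state 1 or the symptomatic state 2).
Within a subject the states strictly alternate starting from state 1, and at
most the final sojourn is right-censored at the end of follow-up.

Follow-up for a subject ends at ``min(study_length, dropout_time)``; a
subject counts as a dropout only when the exit precedes the nominal study end
by more than the dropout window (default 30 days) — late exits inside the
window are administratively complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .families import COVARIATE_FIELDS, SubjectCovariates

__all__ = [
    "SojournRecord",
    "TrialDataset",
    "read_trial",
    "write_trial",
    "episodes_to_sojourns",
    "DEFAULT_DROPOUT_WINDOW",
    "MIN_EVENT_DURATION",
]

DEFAULT_DROPOUT_WINDOW = 30.0
#: completed sojourns shorter than half a day are rejected: log h diverges as
#: t -> 0 for shape > 1 families and same-day onset/resolution is not
#: resolvable at daily granularity
MIN_EVENT_DURATION = 0.5

SOJOURN_COLUMNS = ["subject_id", "episode", "state", "duration", "event"]
SUBJECT_COLUMNS = list(COVARIATE_FIELDS) + ["study_length", "dropout_time", "dropout_flag"]


@dataclass(frozen=True)
class SojournRecord:
    """One observed interval in a state.

    ``event`` is True when the transition to the other state was observed,
    False when the sojourn was still open at the end of follow-up
    (right-censored).
    """

    subject_id: str
    episode_index: int
    state: int
    duration: float
    event: bool

    def __post_init__(self):
        if self.state not in (1, 2):
            raise ValueError(f"state must be 1 or 2, got {self.state}")
        if self.episode_index < 1:
            raise ValueError("episode_index starts at 1")
        if self.duration <= 0:
            raise ValueError(
                f"duration must be > 0 (subject {self.subject_id}, "
                f"episode {self.episode_index})"
            )
        if self.event and self.duration < MIN_EVENT_DURATION:
            raise ValueError(
                f"completed sojourn shorter than {MIN_EVENT_DURATION} days "
                f"(subject {self.subject_id}, episode {self.episode_index})"
            )


@dataclass
class TrialDataset:
    """Subjects plus their alternating sojourn histories.

    ``subjects``: DataFrame indexed by subject_id with the covariate columns,
    ``study_length``, ``dropout_time`` (NaN when follow-up ran to the nominal
    end) and ``dropout_flag``. ``sojourns``: DataFrame with columns
    subject_id, episode, state, duration, event.
    """

    subjects: pd.DataFrame
    sojourns: pd.DataFrame
    dropout_window: float = DEFAULT_DROPOUT_WINDOW

    def __post_init__(self):
        self.subjects = self.subjects.copy()
        self.sojourns = self.sojourns[SOJOURN_COLUMNS].copy()
        self.sojourns["subject_id"] = self.sojourns["subject_id"].astype(str)
        self.subjects.index = self.subjects.index.astype(str)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        missing = set(self.sojourns["subject_id"]) - set(self.subjects.index)
        if missing:
            raise ValueError(f"sojourns reference unknown subjects: {sorted(missing)[:5]}")
        for col in SUBJECT_COLUMNS:
            if col not in self.subjects.columns:
                raise ValueError(f"subjects table missing column {col!r}")
        if (self.subjects["study_length"] <= 0).any():
            raise ValueError("study_length must be > 0 for every subject")
        for sid, grp in self.sojourns.groupby("subject_id", sort=False):
            grp = grp.sort_values("episode")
            episodes = grp["episode"].to_numpy()
            if not np.array_equal(episodes, np.arange(1, len(grp) + 1)):
                raise ValueError(f"subject {sid}: episode indices not 1..n")
            states = grp["state"].to_numpy()
            if states[0] != 1:
                raise ValueError(f"subject {sid}: history must start in state 1")
            if np.any(states[1:] == states[:-1]):
                raise ValueError(f"subject {sid}: states must strictly alternate")
            ev = grp["event"].to_numpy(dtype=bool)
            if np.any(~ev[:-1]):
                raise ValueError(
                    f"subject {sid}: only the final sojourn may be censored"
                )
            dur = grp["duration"].to_numpy(dtype=float)
            if np.any(dur <= 0):
                raise ValueError(f"subject {sid}: non-positive duration")
            if np.any(ev & (dur < MIN_EVENT_DURATION)):
                raise ValueError(
                    f"subject {sid}: completed sojourn shorter than "
                    f"{MIN_EVENT_DURATION} days"
                )
            total = dur.sum()
            if total > self.follow_up_end(sid) + 1e-6:
                raise ValueError(
                    f"subject {sid}: total sojourn time {total:.3f} exceeds "
                    f"follow-up {self.follow_up_end(sid):.3f}"
                )
        # dropout flag must agree with the window rule
        fu = self.follow_up_ends()
        expected = fu < self.subjects["study_length"] - self.dropout_window
        flag = self.subjects["dropout_flag"].astype(bool)
        if not (expected == flag).all():
            bad = self.subjects.index[expected != flag].tolist()
            raise ValueError(f"dropout_flag inconsistent with window rule for {bad[:5]}")

    # -- accessors --------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.index)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def follow_up_end(self, subject_id: str) -> float:
        row = self.subjects.loc[str(subject_id)]
        t = row["dropout_time"]
        return float(row["study_length"] if pd.isna(t) else min(t, row["study_length"]))

    def follow_up_ends(self) -> pd.Series:
        t = self.subjects["dropout_time"]
        return t.fillna(np.inf).clip(upper=self.subjects["study_length"])

    def covariates(self, subject_id: str) -> SubjectCovariates:
        row = self.subjects.loc[str(subject_id)]
        return SubjectCovariates(
            treatment=int(row["treatment"]),
            disease_stage=int(row["disease_stage"]),
            smoke=int(row["smoke"]),
            pack_years=float(row["pack_years"]),
            season=int(row["season"]),
            study_length=float(row["study_length"]),
        )

    def n_exacerbations(self) -> pd.Series:
        """Observed 1->2 transitions (completed state-1 sojourns) per subject."""
        s = self.sojourns
        counts = (
            s[(s["state"] == 1) & s["event"]].groupby("subject_id").size()
        )
        return counts.reindex(self.subjects.index, fill_value=0)

    def state_time(self, state: int) -> pd.Series:
        """Total time spent in ``state`` per subject."""
        s = self.sojourns[self.sojourns["state"] == state]
        tot = s.groupby("subject_id")["duration"].sum()
        return tot.reindex(self.subjects.index, fill_value=0.0)

    def total_person_time(self) -> float:
        return float(self.sojourns["duration"].sum())

    def records(self) -> list[SojournRecord]:
        return [
            SojournRecord(
                subject_id=str(r.subject_id),
                episode_index=int(r.episode),
                state=int(r.state),
                duration=float(r.duration),
                event=bool(r.event),
            )
            for r in self.sojourns.itertuples(index=False)
        ]


def episodes_to_sojourns(
    subject_id: str,
    intervals: list[tuple[float, float]],
    study_length: float,
    follow_up_end: float | None = None,
) -> list[SojournRecord]:
    """Convert exacerbation (onset, resolution) intervals into alternating
    sojourn records.

    The gap before the first onset is a state-1 sojourn; a gap after the last
    resolution is a censored state-1 sojourn; an exacerbation still open at
    the end of follow-up yields a censored state-2 sojourn.
    """
    end = study_length if follow_up_end is None else follow_up_end
    if end <= 0 or end > study_length + 1e-9:
        raise ValueError("follow_up_end must lie in (0, study_length]")
    prev_end = 0.0
    for onset, resolution in intervals:
        if onset < prev_end - 1e-9:
            raise ValueError(f"subject {subject_id}: overlapping or unsorted intervals")
        if resolution < onset:
            raise ValueError(f"subject {subject_id}: resolution precedes onset")
        if resolution > end + 1e-9:
            raise ValueError(f"subject {subject_id}: interval extends past follow-up")
        prev_end = resolution
    records: list[SojournRecord] = []
    t = 0.0
    ep = 1
    for onset, resolution in intervals:
        records.append(SojournRecord(subject_id, ep, 1, onset - t, True))
        ep += 1
        if math.isclose(resolution, end, abs_tol=1e-9):
            records.append(SojournRecord(subject_id, ep, 2, resolution - onset, False))
            return records
        records.append(SojournRecord(subject_id, ep, 2, resolution - onset, True))
        ep += 1
        t = resolution
    records.append(SojournRecord(subject_id, ep, 1, end - t, False))
    return records


def sojourns_from_records(records: list[SojournRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "episode": [r.episode_index for r in records],
            "state": [r.state for r in records],
            "duration": [r.duration for r in records],
            "event": [r.event for r in records],
        }
    )


# -- CSV dialect -----------------------------------------------------------

_CSV_COLUMNS = SOJOURN_COLUMNS[:2] + SOJOURN_COLUMNS[2:] + SUBJECT_COLUMNS
_INTERVAL_COLUMNS = {"subject_id", "onset", "resolution"}


def write_trial(dataset: TrialDataset, path) -> None:
    """Write the long-format CSV (one row per sojourn, covariates repeated)."""
    df = dataset.sojourns.merge(
        dataset.subjects.reset_index(names="subject_id"), on="subject_id", how="left"
    )
    df = df[_CSV_COLUMNS]
    df.to_csv(path, index=False)


def read_trial(
    path,
    dropout_window: float = DEFAULT_DROPOUT_WINDOW,
    study_length: float | None = None,
) -> TrialDataset:
    """Read either accepted CSV layout into a validated :class:`TrialDataset`.

    The primary layout is one row per sojourn with the covariate columns
    repeated. The secondary layout has columns subject_id, onset, resolution
    (plus optional covariate columns and study_length) and is converted via
    :func:`episodes_to_sojourns`; ``study_length`` supplies the follow-up
    length when the file lacks that column.
    """
    df = pd.read_csv(path)
    if _INTERVAL_COLUMNS.issubset(df.columns):
        return _read_intervals(df, dropout_window, study_length)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    subj = (
        df.drop_duplicates("subject_id")
        .set_index("subject_id")[SUBJECT_COLUMNS]
        .copy()
    )
    subj["dropout_flag"] = subj["dropout_flag"].astype(bool)
    sojourns = df[SOJOURN_COLUMNS].copy()
    sojourns["event"] = sojourns["event"].astype(bool)
    try:
        return TrialDataset(subj, sojourns, dropout_window=dropout_window)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def _read_intervals(df: pd.DataFrame, dropout_window: float, study_length) -> TrialDataset:
    if "study_length" not in df.columns:
        if study_length is None:
            raise ValueError(
                "interval layout without a study_length column requires the "
                "study_length argument"
            )
        df = df.assign(study_length=study_length)
    records: list[SojournRecord] = []
    rows = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        sid = str(sid)
        T = float(grp["study_length"].iloc[0])
        ivals = [
            (float(o), float(r))
            for o, r in zip(grp["onset"], grp["resolution"])
            if not (pd.isna(o) or pd.isna(r))
        ]
        ivals.sort()
        records.extend(episodes_to_sojourns(sid, ivals, T))
        row = {c: 0 for c in COVARIATE_FIELDS}
        for c in COVARIATE_FIELDS:
            if c in grp.columns:
                row[c] = grp[c].iloc[0]
        row.update(study_length=T, dropout_time=np.nan, dropout_flag=False)
        rows[sid] = row
    subjects = pd.DataFrame.from_dict(rows, orient="index")
    subjects.index.name = "subject_id"
    return TrialDataset(subjects, sojourns_from_records(records), dropout_window=dropout_window)
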