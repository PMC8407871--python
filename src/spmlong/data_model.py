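"""Panel/event data containers, validation, delimited-text I/O and design matrices.

The package works on long-format panel data: one row per subject-visit with a
continuous outcome measured at continuous times (years since the index visit),
plus a one-row-per-subject event table holding an event/censoring time and one
or two cause-status indicators (e.g. dementia, death).  Missing outcomes are
encoded by *absence*: a visit that never happened simply has no row (or an
empty outcome cell, treated identically), so the missingness indicator is
derivable from the visit pattern against a declared wave schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "SubjectRecord",
    "PanelDataset",
    "ModelSpec",
    "DesignBundle",
    "ConfigurationError",
    "DataError",
    "read_panel",
    "write_panel",
    "build_designs",
    "summarize_cohort",
    "DEFAULT_WAVES",
]

#: Default scheduled assessment waves (years since index visit).
DEFAULT_WAVES = (0.0, 6.0, 15.0, 18.0, 20.0)


class ConfigurationError(ValueError):
    """A column, covariate or option named by the user does not exist / is invalid."""


class DataError(ValueError):
    """The data violate a structural invariant (duplicated visits, event < visit ...)."""


@dataclass(frozen=True)
class EventRecord:
    """Event/censoring time with per-cause status indicators.

    ``status`` has one entry per cause; at most one entry may be 1 (the cause
    observed), all zeros meaning censored at ``time``.
    """

    time: float
    status: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.time < 0:
            raise DataError(f"event time must be >= 0, got {self.time}")
        if any(s not in (0, 1) for s in self.status):
            raise DataError(f"status entries must be 0/1, got {self.status}")
        if sum(self.status) > 1:
            raise DataError("at most one cause may have status 1")

    @property
    def n_causes(self) -> int:
        return len(self.status)


@dataclass(frozen=True)
class SubjectRecord:
    id: str
    x_base: np.ndarray          # baseline covariates, aligned with covariate_names
    times: np.ndarray           # visit times (years), strictly increasing
    y: np.ndarray               # outcomes at the visit times
    event: EventRecord | None = None

    def __post_init__(self):
        object.__setattr__(self, "x_base", np.asarray(self.x_base, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.times.shape != self.y.shape:
            raise DataError(f"subject {self.id}: times and outcomes differ in length")
        if self.times.size and self.times[0] < 0:
            raise DataError(f"subject {self.id}: negative visit time")
        if np.any(np.diff(self.times) <= 0):
            raise DataError(f"subject {self.id}: visit times not strictly increasing")

    @property
    def n_visits(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PanelDataset:
    """Validated cohort: subject-visit outcome rows plus per-subject events."""

    subjects: tuple[SubjectRecord, ...]
    covariate_names: tuple[str, ...]
    outcome_name: str = "y"
    time_name: str = "time"
    allow_empty_subjects: bool = False

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        seen = set()
        for s in self.subjects:
            if s.id in seen:
                raise DataError(f"duplicate subject id {s.id!r}")
            seen.add(s.id)
            if s.x_base.size != len(self.covariate_names):
                raise DataError(
                    f"subject {s.id}: {s.x_base.size} covariates, expected "
                    f"{len(self.covariate_names)}"
                )
            if s.n_visits == 0 and s.event is None and not self.allow_empty_subjects:
                raise DataError(f"subject {s.id} has no visits and no event record")
            if s.event is not None and s.n_visits:
                if s.event.time < s.times[-1] - 1e-12:
                    raise DataError(
                        f"subject {s.id}: event time {s.event.time} earlier than "
                        f"last visit at {s.times[-1]}"
                    )
        causes = {s.event.n_causes for s in self.subjects if s.event is not None}
        if len(causes) > 1:
            raise DataError(f"inconsistent number of causes across subjects: {causes}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_visits for s in self.subjects)

    @property
    def n_causes(self) -> int:
        for s in self.subjects:
            if s.event is not None:
                return s.event.n_causes
        return 0

    def covariate_index(self, name: str) -> int:
        try:
            return self.covariate_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown covariate {name!r}; available: {list(self.covariate_names)}"
            ) from None

    def covariate_matrix(self) -> np.ndarray:
        """(N, n_cov) baseline covariate matrix in subject order."""
        if not self.subjects:
            return np.empty((0, len(self.covariate_names)))
        return np.vstack([s.x_base for s in self.subjects])

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Long panel frame and one-row-per-subject event frame."""
        rows = []
        for s in self.subjects:
            for t, y in zip(s.times, s.y):
                rows.append({"id": s.id, self.time_name: t, self.outcome_name: y,
                             **dict(zip(self.covariate_names, s.x_base))})
        panel_cols = ["id", self.time_name, self.outcome_name, *self.covariate_names]
        panel = pd.DataFrame(rows, columns=panel_cols)

        k = max(self.n_causes, 1)
        erows = []
        for s in self.subjects:
            if s.event is None:
                continue
            row = {"id": s.id, "etime": s.event.time}
            for c in range(k):
                col = "status" if c == 0 else f"status{c + 1}"
                row[col] = s.event.status[c]
            erows.append(row)
        ecols = ["id", "etime"] + ["status" if c == 0 else f"status{c + 1}" for c in range(k)]
        events = pd.DataFrame(erows, columns=ecols)
        return panel, events

    def subset(self, ids: Sequence[str]) -> "PanelDataset":
        want = set(ids)
        return replace(self, subjects=tuple(s for s in self.subjects if s.id in want))


# ----------------------------------------------------------------------------- I/O

def read_panel(panel_path, event_path, *, outcome="y", time="time",
               covariates: Sequence[str] | None = None,
               id_col="id", etime_col="etime",
               status_cols: Sequence[str] = ("status",)) -> PanelDataset:
    """Read a long-format panel CSV plus a per-subject event CSV.

    Rows whose outcome cell is empty are dropped: their absence *is* the
    missingness indicator.  Column names can be remapped via the keyword
    arguments; ``covariates`` defaults to every panel column that is neither
    id, time nor outcome.
    """
    panel = pd.read_csv(panel_path)
    events = pd.read_csv(event_path)

    for col in (id_col, time, outcome):
        if col not in panel.columns:
            raise ConfigurationError(f"panel file missing column {col!r}")
    if covariates is None:
        covariates = [c for c in panel.columns if c not in (id_col, time, outcome)]
    for col in covariates:
        if col not in panel.columns:
            raise ConfigurationError(f"panel file missing covariate column {col!r}")
    for col in (id_col, etime_col, *status_cols):
        if col not in events.columns:
            raise ConfigurationError(f"event file missing column {col!r}")
    if events[id_col].duplicated().any():
        dups = events.loc[events[id_col].duplicated(), id_col].astype(str).tolist()
        raise DataError(f"event file has duplicate subject rows: {dups}")

    panel = panel.dropna(subset=[outcome])
    dup = panel.duplicated(subset=[id_col, time])
    if dup.any():
        bad = panel.loc[dup, id_col].astype(str).unique().tolist()
        raise DataError(f"duplicate (id, time) rows for subjects: {bad}")

    events = events.set_index(events[id_col].astype(str))
    subjects = []
    ids = list(dict.fromkeys(panel[id_col].astype(str)))
    # subjects appearing only in the event table get zero visits
    ids += [i for i in events.index if i not in set(ids)]
    offending = []
    grouped = {str(k): g for k, g in panel.groupby(panel[id_col].astype(str), sort=False)}
    for sid in ids:
        g = grouped.get(sid)
        if g is not None:
            g = g.sort_values(time)
            times = g[time].to_numpy(float)
            yv = g[outcome].to_numpy(float)
            xb = g.iloc[0][list(covariates)].to_numpy(float)
        else:
            times = np.empty(0)
            yv = np.empty(0)
            xb = np.full(len(covariates), np.nan)
        ev = None
        if sid in events.index:
            erow = events.loc[sid]
            ev = EventRecord(float(erow[etime_col]),
                             tuple(int(erow[c]) for c in status_cols))
            if times.size and ev.time < times[-1] - 1e-12:
                offending.append(sid)
        subjects.append(SubjectRecord(sid, xb, times, yv, ev))
    if offending:
        raise DataError(f"event time earlier than a visit for subjects: {offending}")
    return PanelDataset(tuple(subjects), tuple(covariates), outcome_name=outcome,
                        time_name=time, allow_empty_subjects=True)


def write_panel(data: PanelDataset, panel_path, event_path) -> None:
    """Write the dataset as panel + event CSVs; inverse of :func:`read_panel`."""
    panel, events = data.to_frames()
    panel.to_csv(panel_path, index=False)
    events.to_csv(event_path, index=False)


# --------------------------------------------------------------------- model spec

@dataclass(frozen=True)
class ModelSpec:
    """Design description shared by all fitters.

    Longitudinal fixed effects: intercept, time, exposure, exposure x time and
    the adjustors (plus optional adjustor x time interactions).  Random effects
    are a subject intercept or intercept + slope.  The hazard design uses
    baseline (time-fixed) covariates only and may differ from the longitudinal
    set; loading factors attach to every random effect by default.
    """

    exposure: str
    adjustors: tuple[str, ...] = ()
    random_effects: str = "intercept_slope"     # or "intercept"
    hazard_covariates: tuple[str, ...] | None = None   # default: exposure + adjustors
    adjustor_time_interactions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.random_effects not in ("intercept", "intercept_slope"):
            raise ConfigurationError(
                f"random_effects must be 'intercept' or 'intercept_slope', "
                f"got {self.random_effects!r}")
        object.__setattr__(self, "adjustors", tuple(self.adjustors))
        object.__setattr__(self, "adjustor_time_interactions",
                           tuple(self.adjustor_time_interactions))
        if self.hazard_covariates is not None:
            object.__setattr__(self, "hazard_covariates", tuple(self.hazard_covariates))
        extra = set(self.adjustor_time_interactions) - set(self.adjustors)
        if extra:
            raise ConfigurationError(
                f"adjustor x time interactions for non-adjustors: {sorted(extra)}")

    @property
    def n_random(self) -> int:
        return 2 if self.random_effects == "intercept_slope" else 1

    @property
    def fixed_names(self) -> tuple[str, ...]:
        names = ["intercept", "time", self.exposure, f"{self.exposure}:time"]
        names += list(self.adjustors)
        names += [f"{a}:time" for a in self.adjustor_time_interactions]
        return tuple(names)

    def hazard_names(self) -> tuple[str, ...]:
        if self.hazard_covariates is None:
            return (self.exposure, *self.adjustors)
        return self.hazard_covariates


@dataclass
class DesignBundle:
    """Stacked design matrices plus per-subject indexing, consumed by all fitters."""

    spec: ModelSpec
    fixed_names: tuple[str, ...]
    X: np.ndarray               # (n_obs, p) stacked longitudinal fixed-effect rows
    Z: np.ndarray               # (n_obs, q) stacked random-effect rows: (1,) or (1, t)
    y: np.ndarray               # (n_obs,)
    t: np.ndarray               # (n_obs,) visit times
    subject_index: np.ndarray   # (n_obs,) int index into subjects
    n_visits: np.ndarray        # (N,) visits per subject
    X_haz: np.ndarray           # (N, h) baseline hazard covariates
    hazard_names: tuple[str, ...]
    event_time: np.ndarray      # (N,) event/censoring time (nan when absent)
    status: np.ndarray          # (N, K) cause indicators (K >= 1; zeros when absent)
    ids: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def fixed_row(self, x_base: np.ndarray, t: float) -> np.ndarray:
        """One longitudinal fixed-effect design row for a covariate profile at time t."""
        return _fixed_rows(self.spec, x_base[None, :], np.array([t]),
                           self._cov_index)[0]

    _cov_index: dict = None  # set in build_designs


def _fixed_rows(spec: ModelSpec, xb: np.ndarray, t: np.ndarray,
                cov_index: dict[str, int]) -> np.ndarray:
    """Rows (1, t, exposure, exposure*t, adjustors..., adjustor*t...)."""
    expo = xb[:, cov_index[spec.exposure]]
    cols = [np.ones_like(t), t, expo, expo * t]
    for a in spec.adjustors:
        cols.append(xb[:, cov_index[a]])
    for a in spec.adjustor_time_interactions:
        cols.append(xb[:, cov_index[a]] * t)
    return np.column_stack(cols)


def build_designs(data: PanelDataset, spec: ModelSpec) -> DesignBundle:
    """Assemble stacked longitudinal and hazard design matrices.

    Column order is fixed by the spec (not by the data), so parameter indexing
    is identical across datasets sharing a spec.
    """
    for name in (spec.exposure, *spec.adjustors, *spec.hazard_names()):
        data.covariate_index(name)  # raises ConfigurationError if unknown
    cov_index = {c: i for i, c in enumerate(data.covariate_names)}

    N = data.n_subjects
    sub_idx, times, ys = [], [], []
    xb_rows = np.vstack([s.x_base for s in data.subjects]) if N else \
        np.empty((0, len(data.covariate_names)))
    n_visits = np.array([s.n_visits for s in data.subjects], dtype=int)
    for i, s in enumerate(data.subjects):
        sub_idx += [i] * s.n_visits
        times.append(s.times)
        ys.append(s.y)
    sub_idx = np.asarray(sub_idx, dtype=int)
    t = np.concatenate(times) if times else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)

    xb_per_obs = xb_rows[sub_idx] if len(sub_idx) else np.empty((0, xb_rows.shape[1]))
    X = _fixed_rows(spec, xb_per_obs, t, cov_index) if len(t) else \
        np.empty((0, len(spec.fixed_names)))
    if spec.n_random == 2:
        Z = np.column_stack([np.ones_like(t), t]) if len(t) else np.empty((0, 2))
    else:
        Z = np.ones((len(t), 1))

    hnames = spec.hazard_names()
    X_haz = xb_rows[:, [cov_index[h] for h in hnames]] if N else np.empty((0, len(hnames)))

    K = max(data.n_causes, 1)
    etime = np.full(N, np.nan)
    status = np.zeros((N, K), dtype=int)
    for i, s in enumerate(data.subjects):
        if s.event is not None:
            etime[i] = s.event.time
            status[i, : s.event.n_causes] = s.event.status

    bundle = DesignBundle(spec=spec, fixed_names=spec.fixed_names, X=X, Z=Z, y=y, t=t,
                          subject_index=sub_idx, n_visits=n_visits, X_haz=X_haz,
                          hazard_names=hnames, event_time=etime, status=status,
                          ids=tuple(s.id for s in data.subjects))
    bundle._cov_index = cov_index
    return bundle


# ----------------------------------------------------------------------- summaries

def assign_waves(times: np.ndarray, waves: Sequence[float], tol: float = 2.0) -> np.ndarray:
    """Map visit times to the nearest scheduled wave index (-1 when off-schedule)."""
    waves = np.asarray(waves, dtype=float)
    if times.size == 0:
        return np.empty(0, dtype=int)
    d = np.abs(times[:, None] - waves[None, :])
    idx = d.argmin(axis=1)
    idx[d[np.arange(len(times)), idx] > tol] = -1
    return idx


def summarize_cohort(data: PanelDataset, *, waves: Sequence[float] = DEFAULT_WAVES,
                     group: str | None = None) -> dict:
    """Completion/retention bookkeeping against a declared wave schedule.

    A *completer* has a visit matched to every scheduled wave.  Returns counts,
    percentages (0-100), baseline covariate means/SDs, and a per-level breakdown
    when ``group`` names a baseline covariate.
    """
    if group is not None:
        gi = data.covariate_index(group)

    def _one(subjects) -> dict:
        n = len(subjects)
        complete = 0
        for s in subjects:
            w = set(assign_waves(s.times, waves))
            w.discard(-1)
            if len(w) == len(waves):
                complete += 1
        lost = n - complete
        xb = np.vstack([s.x_base for s in subjects]) if n else \
            np.empty((0, len(data.covariate_names)))
        return {
            "n": n,
            "n_completers": complete,
            "n_lost": lost,
            "pct_completers": 100.0 * complete / n if n else float("nan"),
            "pct_lost": 100.0 * lost / n if n else float("nan"),
            "covariate_mean": dict(zip(data.covariate_names, xb.mean(axis=0)))
            if n else {},
            "covariate_sd": dict(zip(data.covariate_names, xb.std(axis=0, ddof=1)))
            if n > 1 else {},
        }

    out = _one(data.subjects)
    if group is not None:
        levels = sorted({float(s.x_base[gi]) for s in data.subjects})
        out["by_group"] = {
            lev: _one([s for s in data.subjects if float(s.x_base[gi]) == lev])
            for lev in levels
        }
        out["group"] = group
    return out
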