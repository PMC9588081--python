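"""Longitudinal coded-record ingestion: binning, transforms, and table I/O.

The raw input is a stream of timestamped events ``(patient_id, feature_id,
date)``.  Events are tallied into consecutive, non-overlapping fixed-width
time bins anchored at each patient's own origin date (typically the first
occurrence of the phenotype's sentinel code).  All downstream modelling
consumes the log1p-transformed counts ``C = log(1 + raw)``; raw counts are
kept only for bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_DAYS = 30


@dataclass
class EventRecord:
    """A single timestamped feature observation."""

    patient_id: str
    feature_id: str
    timestamp: date

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be nonempty")


@dataclass
class FeaturePanel:
    """Binned feature counts for a cohort.

    Attributes
    ----------
    feature_ids : list of str
        Shared feature ordering (length p) for every patient's matrix.
    raw : dict
        patient_id -> (T_i, p) nonnegative integer count matrix.
    C : dict
        patient_id -> (T_i, p) float matrix, elementwise ``log(1 + raw)``.
    H : dict
        patient_id -> nonnegative utilization covariate
        (log of mean monthly encounter count + 1).
    bin_width_days : int
        Width of each time bin in days.
    origin : dict
        patient_id -> date of the start of bin 1 (optional; empty for
        synthetic panels with no calendar anchor).
    """

    feature_ids: list
    raw: dict
    C: dict
    H: dict
    bin_width_days: int = DEFAULT_BIN_WIDTH_DAYS
    origin: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> list:
        return list(self.raw.keys())

    @property
    def p(self) -> int:
        return len(self.feature_ids)

    def T(self, pid) -> int:
        return self.raw[pid].shape[0]

    @property
    def n_patients(self) -> int:
        return len(self.raw)

    def validate(self) -> None:
        for pid, mat in self.raw.items():
            if mat.shape[0] < 1:
                raise ValueError(f"patient {pid!r} has zero bins")
            if mat.shape[1] != self.p:
                raise ValueError(f"patient {pid!r} count matrix has wrong width")
            if (mat < 0).any():
                raise ValueError(f"patient {pid!r} has negative counts")
            if self.H[pid] < 0:
                raise ValueError(f"patient {pid!r} has negative utilization")

    def subset(self, patient_ids) -> "FeaturePanel":
        """Restrict to the given patients (order preserved)."""
        return FeaturePanel(
            feature_ids=self.feature_ids,
            raw={pid: self.raw[pid] for pid in patient_ids},
            C={pid: self.C[pid] for pid in patient_ids},
            H={pid: self.H[pid] for pid in patient_ids},
            bin_width_days=self.bin_width_days,
            origin={pid: self.origin[pid] for pid in patient_ids if pid in self.origin},
        )


@dataclass
class LabelSeries:
    """Per-bin binary phenotype states for (a subset of) patients.

    ``y[pid]`` is a 0/1 vector of length T_i.  The first-event CDF
    F_i(t) = 1 - prod_{k<=t}(1 - y_k) and the all-event counting process
    N_i(t) = sum_{k<=t} y_k (1 - y_{k-1}) (with y_0 = 0) are derived views.
    """

    y: dict

    @property
    def patient_ids(self) -> list:
        return list(self.y.keys())

    def first_event_cdf(self, pid) -> np.ndarray:
        return first_event_cdf(self.y[pid])

    def counting_process(self, pid) -> np.ndarray:
        return counting_process(self.y[pid])

    def validate(self) -> None:
        for pid, yv in self.y.items():
            yv = np.asarray(yv)
            if not np.isin(yv, (0, 1)).all():
                raise ValueError(f"labels for patient {pid!r} are not binary")


def first_event_cdf(y: np.ndarray) -> np.ndarray:
    """Indicator that any event has occurred by each bin."""
    y = np.asarray(y, dtype=float)
    return 1.0 - np.cumprod(1.0 - y)


def counting_process(y: np.ndarray) -> np.ndarray:
    """Cumulative number of 0->1 transitions by each bin (y_0 = 0)."""
    y = np.asarray(y, dtype=int)
    onset = y * (1 - np.concatenate(([0], y[:-1])))
    return np.cumsum(onset)


# ---------------------------------------------------------------------------
# Binning


def bin_events(
    records,
    bin_width_days: int = DEFAULT_BIN_WIDTH_DAYS,
    origin: dict | None = None,
    follow_up_end: dict | None = None,
    encounter_counts: dict | None = None,
) -> FeaturePanel:
    """Tally events into fixed-width, half-open bins per patient.

    Bin t (1-based) covers days ``[origin + (t-1)*w, origin + t*w)``.
    Each patient's origin defaults to their earliest event date; an explicit
    per-patient ``origin`` mapping overrides this (events before the origin
    are dropped).  The panel extends to the bin containing the patient's
    last event, or to ``follow_up_end`` when supplied; intermediate bins
    with no events are zero-filled.

    Parameters
    ----------
    records : iterable of EventRecord
    bin_width_days : int
        Must be positive.
    origin, follow_up_end : dict, optional
        patient_id -> date.
    encounter_counts : dict, optional
        patient_id -> sequence of monthly encounter counts used for the
        utilization covariate; defaults to per-bin total event counts.
    """
    if bin_width_days <= 0:
        raise ValueError("bin_width_days must be positive")
    records = list(records)
    if not records:
        raise ValueError("no event records supplied")

    feature_ids = sorted({r.feature_id for r in records})
    fidx = {f: j for j, f in enumerate(feature_ids)}

    by_patient: dict = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    raw, C, H, origins = {}, {}, {}, {}
    for pid, recs in by_patient.items():
        anchor = origin.get(pid) if origin else None
        if anchor is None:
            anchor = min(r.timestamp for r in recs)
        usable = [r for r in recs if r.timestamp >= anchor]
        if not usable:
            logger.warning("patient %r has no records on/after origin; excluded", pid)
            continue
        bins = [(r.timestamp - anchor).days // bin_width_days for r in usable]
        T = max(bins) + 1
        if follow_up_end and pid in follow_up_end:
            end_bin = (follow_up_end[pid] - anchor).days // bin_width_days + 1
            T = max(T, end_bin)
        mat = np.zeros((T, len(feature_ids)), dtype=np.int64)
        for r, b in zip(usable, bins):
            mat[b, fidx[r.feature_id]] += 1
        raw[pid] = mat
        C[pid] = np.log1p(mat.astype(float))
        origins[pid] = anchor
        if encounter_counts and pid in encounter_counts:
            H[pid] = compute_utilization(encounter_counts[pid])
        else:
            H[pid] = compute_utilization(mat.sum(axis=1))

    if not raw:
        raise ValueError("all patients excluded during binning")
    return FeaturePanel(
        feature_ids=feature_ids,
        raw=raw,
        C=C,
        H=H,
        bin_width_days=bin_width_days,
        origin=origins,
    )


def compute_utilization(monthly_counts) -> float:
    """Utilization covariate H = log(mean monthly encounter count + 1)."""
    counts = np.asarray(monthly_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("at least one month of encounter counts required")
    if (counts < 0).any():
        raise ValueError("encounter counts must be nonnegative")
    return float(np.log1p(counts.mean()))


# ---------------------------------------------------------------------------
# Delimited-table I/O (long format throughout; zero rows omitted)


def write_panel(panel: FeaturePanel, path) -> None:
    rows = []
    for pid in panel.patient_ids:
        mat = panel.raw[pid]
        t_idx, f_idx = np.nonzero(mat)
        for t, j in zip(t_idx, f_idx):
            rows.append((pid, int(t) + 1, panel.feature_ids[j], int(mat[t, j])))
        # preserve T_i for patients whose trailing bins are empty
        rows.append((pid, panel.T(pid), "__T__", 0))
    df = pd.DataFrame(rows, columns=["patient_id", "bin", "feature_id", "count"])
    df.to_csv(path, index=False)


def read_panel(path, feature_ids=None, H: dict | None = None) -> FeaturePanel:
    """Read a long-format panel CSV (``patient_id,bin,feature_id,count``).

    Rows with the sentinel feature ``__T__`` mark each patient's bin count
    and carry no counts.  ``H`` may be supplied externally; otherwise it is
    recomputed from per-bin total event counts.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "feature_id": str})
    markers = df[df["feature_id"] == "__T__"]
    df = df[df["feature_id"] != "__T__"]
    if feature_ids is None:
        feature_ids = sorted(df["feature_id"].unique())
    fidx = {f: j for j, f in enumerate(feature_ids)}
    unknown = set(df["feature_id"]) - set(feature_ids)
    if unknown:
        raise ValueError(f"panel features not in feature list: {sorted(unknown)}")

    T_marked = dict(zip(markers["patient_id"], markers["bin"]))
    raw, C, Hout = {}, {}, {}
    for pid, grp in df.groupby("patient_id", sort=False):
        T = int(max(grp["bin"].max(), T_marked.get(pid, 1)))
        mat = np.zeros((T, len(feature_ids)), dtype=np.int64)
        for b, f, c in zip(grp["bin"], grp["feature_id"], grp["count"]):
            mat[int(b) - 1, fidx[f]] += int(c)
        raw[pid] = mat
        C[pid] = np.log1p(mat.astype(float))
        Hout[pid] = H[pid] if H and pid in H else compute_utilization(mat.sum(axis=1))
    for pid, T in T_marked.items():  # patients with no nonzero counts at all
        if pid not in raw:
            mat = np.zeros((int(T), len(feature_ids)), dtype=np.int64)
            raw[pid] = mat
            C[pid] = np.log1p(mat.astype(float))
            Hout[pid] = H[pid] if H and pid in H else 0.0
    return FeaturePanel(feature_ids=list(feature_ids), raw=raw, C=C, H=Hout)


def write_labels(labels: LabelSeries, path) -> None:
    rows = [
        (pid, t + 1, int(v))
        for pid in labels.patient_ids
        for t, v in enumerate(labels.y[pid])
    ]
    pd.DataFrame(rows, columns=["patient_id", "bin", "y"]).to_csv(path, index=False)


def read_labels(path, known_patients=None) -> LabelSeries:
    df = pd.read_csv(path, dtype={"patient_id": str})
    if known_patients is not None:
        unknown = set(df["patient_id"]) - set(known_patients)
        if unknown:
            raise ValueError(f"labels reference unknown patients: {sorted(unknown)}")
    y = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("bin")
        if not (grp["bin"].to_numpy() == np.arange(1, len(grp) + 1)).all():
            raise ValueError(f"labels for patient {pid!r} have gaps in bin index")
        vals = grp["y"].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"labels for patient {pid!r} are not binary")
        y[pid] = vals.astype(np.int8)
    return LabelSeries(y=y)


def write_embedding_matrix(V: np.ndarray, feature_ids, path) -> None:
    """Write an m x p embedding matrix as one CSV row per feature."""
    df = pd.DataFrame(np.asarray(V).T, index=pd.Index(feature_ids, name="feature_id"))
    df.columns = [f"dim{k + 1}" for k in range(df.shape[1])]
    df.to_csv(path)


def read_embedding_matrix(path, feature_ids) -> np.ndarray:
    """Read an embedding CSV and align columns to ``feature_ids`` by id.

    Returns the m x p matrix with columns in panel feature order; raises if
    any panel feature lacks an embedding row.
    """
    df = pd.read_csv(path, dtype={"feature_id": str}).set_index("feature_id")
    missing = [f for f in feature_ids if f not in df.index]
    if missing:
        raise ValueError(f"features missing from embedding matrix: {missing}")
    return df.loc[list(feature_ids)].to_numpy(dtype=float).T


def write_predictions(predictions, path) -> None:
    """Write per patient-bin posteriors and derived curves.

    ``predictions`` maps patient_id -> dict with keys ``pi`` (marginal
    posteriors), ``F`` (first-event CDF), ``N`` (predicted counting
    process); each a length-T_i vector.
    """
    rows = []
    for pid, d in predictions.items():
        for t in range(len(d["pi"])):
            rows.append((pid, t + 1, d["pi"][t], d["F"][t], d["N"][t]))
    pd.DataFrame(
        rows, columns=["patient_id", "bin", "pi_hat", "F_hat", "N_hat"]
    ).to_csv(path, index=False)


def read_predictions(path) -> dict:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("bin")
        out[pid] = {
            "pi": grp["pi_hat"].to_numpy(),
            "F": grp["F_hat"].to_numpy(),
            "N": grp["N_hat"].to_numpy(),
        }
    return out
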