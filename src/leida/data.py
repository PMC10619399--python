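"""Core containers and cohort I/O.

A *scan* is one resting-state fMRI session reduced to parcellated
region-of-interest (ROI) time courses: a frames x regions matrix sampled
every TR seconds.  A *cohort* is a set of scans organised in a paired
two-session design (baseline / follow_up per subject) with a group label
per subject (recurrent / non_recurrent).

On disk a scan is a tab-separated table whose header row holds the region
labels, and a cohort is a manifest TSV with columns
``subject_id, session, group, tr, path``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SESSIONS = ("baseline", "follow_up")
GROUPS = ("recurrent", "non_recurrent")

MANIFEST_COLUMNS = ["subject_id", "session", "group", "tr", "path"]


@dataclass
class RoiTimeSeries:
    """One scan's ROI signal matrix with its sampling interval and labels.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, n_regions)``; finite, at least 2 frames.
    tr
        Repetition time (sampling interval) in seconds.
    region_labels
        Ordered region names, one per column.
    subject_id, session, group
        Cohort bookkeeping; ``session`` is ``"baseline"`` or ``"follow_up"``.
    """

    data: np.ndarray
    tr: float
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    session: str = "baseline"
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D frames x regions array")
        if self.data.shape[0] < 2:
            raise ValueError("a scan needs at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError(
                f"scan {self.subject_id}/{self.session} contains non-finite values"
            )
        if not self.region_labels:
            self.region_labels = [f"roi{j:03d}" for j in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.region_labels)} region labels for "
                f"{self.data.shape[1]} data columns"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        """Return a copy of this scan carrying new signal values."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))


def scan_key(ts: RoiTimeSeries) -> tuple[str, str]:
    """Stable (subject_id, session) identifier of a scan."""
    return (ts.subject_id, ts.session)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_scan_tsv(ts: RoiTimeSeries, path: str | Path) -> Path:
    """Write one scan as a frames x regions TSV with region-label header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def read_scan_tsv(
    path: str | Path,
    tr: float,
    subject_id: str = "",
    session: str = "baseline",
    group: str | None = None,
) -> RoiTimeSeries:
    """Read a frames x regions TSV (header = region labels) back into a scan."""
    frame = pd.read_csv(path, sep="\t")
    if frame.isna().any().any():
        raise ValueError(f"scan file {path} contains missing values")
    return RoiTimeSeries(
        data=frame.to_numpy(dtype=float),
        tr=tr,
        region_labels=[str(c) for c in frame.columns],
        subject_id=subject_id,
        session=session,
        group=group,
    )


def write_cohort(scans: list[RoiTimeSeries], directory: str | Path) -> Path:
    """Write every scan plus a manifest TSV; return the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in scans:
        fname = f"{ts.subject_id}_{ts.session}.tsv"
        write_scan_tsv(ts, directory / fname)
        rows.append(
            {
                "subject_id": ts.subject_id,
                "session": ts.session,
                "group": ts.group or "",
                "tr": ts.tr,
                "path": fname,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = directory / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[RoiTimeSeries]:
    """Load and validate a paired cohort from a manifest TSV.

    Checks that every referenced scan file exists, that region labels agree
    across scans, and that each subject contributes exactly one baseline and
    one follow_up session; violations raise ``ValueError`` naming the
    offending subject or file.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest is missing columns: {sorted(missing_cols)}")

    scans: list[RoiTimeSeries] = []
    for row in manifest.itertuples(index=False):
        scan_path = Path(row.path)
        if not scan_path.is_absolute():
            scan_path = manifest_path.parent / scan_path
        if not scan_path.exists():
            raise FileNotFoundError(
                f"scan file for subject {row.subject_id} not found: {scan_path}"
            )
        group = str(row.group) if isinstance(row.group, str) and row.group else None
        scans.append(
            read_scan_tsv(
                scan_path,
                tr=float(row.tr),
                subject_id=str(row.subject_id),
                session=str(row.session),
                group=group,
            )
        )

    labels = scans[0].region_labels
    for ts in scans[1:]:
        if ts.region_labels != labels:
            raise ValueError(
                f"region labels of {ts.subject_id}/{ts.session} do not match "
                "the rest of the cohort"
            )

    sessions_by_subject: dict[str, set[str]] = {}
    for ts in scans:
        sessions_by_subject.setdefault(ts.subject_id, set()).add(ts.session)
    for subject, sessions in sorted(sessions_by_subject.items()):
        if sessions != set(SESSIONS):
            raise ValueError(
                f"subject {subject} is unpaired: has sessions {sorted(sessions)}, "
                f"needs {sorted(SESSIONS)}"
            )
    return scans


def split_arms(
    scans: list[RoiTimeSeries],
) -> tuple[list[RoiTimeSeries], list[RoiTimeSeries]]:
    """Partition a cohort into (recurrent, non_recurrent) arms by group label."""
    recurrent = [ts for ts in scans if ts.group == "recurrent"]
    non_recurrent = [ts for ts in scans if ts.group == "non_recurrent"]
    return recurrent, non_recurrent
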