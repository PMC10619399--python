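"""Per-scan PL-state metrics: fractional occupancy, lifetime, decoupling.

Fractional occupancy is the fraction of a scan's frames assigned to a
state; lifetime is the mean duration (in seconds) of consecutive-frame runs
in a state; the decoupling metric is the time-averaged absolute angular
difference between the circular mean phase of a state's positive-sign
community and that of its negative-sign community, in degrees.  Decoupling
is computed over the entire scan, not only the frames where the state is
dominant: it measures how far a functional subsystem de-phases from the
rest of the brain at any moment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _validate_labels(assignments: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(assignments, dtype=int)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("assignments must be a non-empty 1-D label sequence")
    if labels.min() < 1 or labels.max() > k:
        raise ValueError(f"state labels must lie in [1, {k}]")
    return labels


def fractional_occupancy(assignments: np.ndarray, k: int) -> np.ndarray:
    """Proportion of frames spent in each of ``k`` states (sums to 1)."""
    labels = _validate_labels(assignments, k)
    counts = np.bincount(labels - 1, minlength=k)
    return counts / labels.size


def run_lengths(assignments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence -> (state per run, run length).

    Runs truncated by the scan boundary count as complete runs.
    """
    labels = np.asarray(assignments, dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change + 1, labels.size]
    return labels[starts], ends - starts


def lifetime(assignments: np.ndarray, k: int, tr: float) -> np.ndarray:
    """Mean run duration per state in seconds; 0 for states never visited."""
    labels = _validate_labels(assignments, k)
    states, lengths = run_lengths(labels)
    out = np.zeros(k)
    for s in range(1, k + 1):
        mask = states == s
        if mask.any():
            out[s - 1] = lengths[mask].mean() * tr
    return out


def decoupling_metric(theta: np.ndarray, centroid: np.ndarray) -> float:
    """Time-averaged phase shift (degrees) between a centroid's communities.

    At every frame, the circular mean phase (angle of the summed unit
    phasors) is taken across the regions with positive centroid sign and
    across those with negative sign; the absolute wrapped difference of the
    two, averaged over all frames, is returned in [0, 180] degrees.
    Arithmetic means of wrapped angles would be wrong near +/-pi, hence the
    phasor form.
    """
    theta = np.asarray(theta, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if theta.ndim != 2 or theta.shape[1] != centroid.size:
        raise ValueError("theta must be frames x regions matching the centroid")
    positive = centroid > 0
    negative = centroid < 0
    if not positive.any() or not negative.any():
        raise ValueError(
            "decoupling is undefined for a single-sign centroid "
            "(no community/rest split)"
        )
    mean_pos = np.exp(1j * theta[:, positive]).mean(axis=1)
    mean_neg = np.exp(1j * theta[:, negative]).mean(axis=1)
    diff = np.abs(np.angle(mean_pos * np.conj(mean_neg)))
    return float(np.degrees(diff.mean()))


def scan_state_metrics(
    assignments: np.ndarray,
    k: int,
    tr: float,
    theta: np.ndarray | None = None,
    centroids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-state metrics for one scan.

    Decoupling is filled when phases and centroids are supplied; states
    whose centroid has a single sign (typically the global in-phase mode)
    get NaN there, since the community/rest split does not exist.
    """
    occ = fractional_occupancy(assignments, k)
    life = lifetime(assignments, k, tr)
    rows = []
    for s in range(k):
        dec = np.nan
        if theta is not None and centroids is not None:
            centroid = centroids[s]
            if (centroid > 0).any() and (centroid < 0).any():
                dec = decoupling_metric(theta, centroid)
        rows.append(
            {
                "state": s + 1,
                "fractional_occupancy": occ[s],
                "lifetime": life[s],
                "decoupling": dec,
            }
        )
    return pd.DataFrame(rows)


def build_metrics_table(
    pool_index: pd.DataFrame,
    assignments_by_k: dict[int, np.ndarray],
    centroids_by_k: dict[int, np.ndarray],
    phases: dict[tuple[str, str], np.ndarray],
    tr: float,
) -> pd.DataFrame:
    """Per (subject, session, k, state) metrics table for a whole cohort.

    ``pool_index`` is the eigenvector pool's provenance index (columns
    subject_id, session, frame); ``assignments_by_k[k]`` labels the pooled
    rows for partition model k; ``phases`` maps each scan to its frames x
    regions phase matrix (used for decoupling, over all frames).
    """
    records = []
    for k, labels in sorted(assignments_by_k.items()):
        if len(labels) != len(pool_index):
            raise ValueError(f"assignments for k={k} do not match the pool index")
        centroids = centroids_by_k[k]
        for (subject, session), block in pool_index.groupby(
            ["subject_id", "session"], sort=False
        ):
            scan_labels = np.asarray(labels)[block.index.to_numpy()]
            theta = phases.get((subject, session))
            table = scan_state_metrics(scan_labels, k, tr, theta, centroids)
            table.insert(0, "subject_id", subject)
            table.insert(1, "session", session)
            table.insert(2, "k", k)
            records.append(table)
    return pd.concat(records, ignore_index=True)
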