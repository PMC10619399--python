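"""Instantaneous phases, phase-locking matrices and leading eigenvectors.

The analytic signal of each demeaned ROI time course gives an
instantaneous phase theta(t) per region.  At every frame the pairwise
phase-locking matrix is ``PL[n, p] = cos(theta_n - theta_p)`` — 1 for
in-phase pairs, -1 for anti-phase pairs.  Its leading eigenvector V1
summarizes the dominant instantaneous connectivity pattern, reducing the
data from N x N to N x 1 per frame; the sign pattern of V1 splits the
regions into two communities, the positive one marking the phase-shifted
functional subsystem.

A useful identity: since ``cos(a - b) = cos a cos b + sin a sin b``, the PL
matrix is exactly ``c c^T + s s^T`` with ``c = cos(theta)``,
``s = sin(theta)`` — a rank-2 positive semi-definite matrix.  Its leading
eigenvector therefore lives in span{c, s} and is obtained exactly from the
2x2 Gram matrix of (c, s); `eigenvector_series` exploits this, while
`leading_eigenvector` handles arbitrary symmetric matrices through LAPACK.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from scipy import signal as sp_signal

from .data import RoiTimeSeries, scan_key

logger = logging.getLogger(__name__)


@dataclass
class EigenvectorPool:
    """Leading eigenvectors pooled over scans, with provenance.

    ``vectors`` is total_frames x n_regions, one unit-norm row per retained
    frame; ``index`` has columns subject_id, session, frame aligned with the
    rows.
    """

    vectors: np.ndarray
    index: pd.DataFrame

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D")
        if len(self.index) != self.vectors.shape[0]:
            raise ValueError("index rows must match vector rows")
        self.index = self.index.reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]


def instantaneous_phase(ts: RoiTimeSeries) -> np.ndarray:
    """Analytic-signal phase per region per frame, wrapped to (-pi, pi].

    The input should already be demeaned and band-passed; an all-zero
    region column has no defined phase and raises.
    """
    data = ts.data
    if np.all(data == 0, axis=0).any():
        zero = [ts.region_labels[j] for j in np.flatnonzero(np.all(data == 0, axis=0))]
        raise ValueError(f"phase undefined for all-zero region(s): {zero}")
    analytic = sp_signal.hilbert(data, axis=0)
    return np.angle(analytic)


def phase_locking_matrix(theta_row: np.ndarray) -> np.ndarray:
    """Pairwise phase-locking matrix cos(theta_n - theta_p) for one frame."""
    theta_row = np.asarray(theta_row, dtype=float)
    if not np.isfinite(theta_row).all():
        raise ValueError("phases must be finite")
    pl = np.cos(theta_row[:, None] - theta_row[None, :])
    np.fill_diagonal(pl, 1.0)
    return pl


def canonical_sign(v: np.ndarray) -> np.ndarray:
    """Fix the eigenvector sign ambiguity.

    Convention: flip so the majority of elements are negative — the global
    in-phase mode carries negative sign and the positive elements mark the
    phase-shifted community.  On an exact count tie, make the
    largest-magnitude element negative.
    """
    v = np.asarray(v, dtype=float)
    n_neg = int((v < 0).sum())
    n_pos = int((v > 0).sum())
    if n_neg < n_pos:
        return -v
    if n_neg == n_pos and v[int(np.argmax(np.abs(v)))] > 0:
        return -v
    return v


def leading_eigenvector(
    pl: np.ndarray, degenerate_tol: float = 1e-9
) -> np.ndarray:
    """Unit-norm leading eigenvector of a symmetric matrix, canonical sign.

    If the top eigenvalue is degenerate within ``degenerate_tol`` (relative),
    the eigenvector LAPACK returns for the largest eigenvalue is kept (a
    deterministic choice) and the event is logged.
    """
    pl = np.asarray(pl, dtype=float)
    if pl.ndim != 2 or pl.shape[0] != pl.shape[1]:
        raise ValueError("phase-locking matrix must be square")
    if not np.allclose(pl, pl.T, atol=1e-10):
        raise ValueError("phase-locking matrix must be symmetric")
    n = pl.shape[0]
    vals, vecs = sp_linalg.eigh(pl, subset_by_index=[n - 2, n - 1])
    if abs(vals[1] - vals[0]) <= degenerate_tol * max(abs(vals[1]), 1.0):
        logger.info(
            "degenerate top eigenvalue (%.3g ~ %.3g); keeping LAPACK ordering",
            vals[1],
            vals[0],
        )
    v1 = vecs[:, 1]
    v1 = v1 / np.linalg.norm(v1)
    return canonical_sign(v1)


def _rank2_leading_eigenvectors(theta: np.ndarray) -> np.ndarray:
    """Exact per-frame V1 from the rank-2 structure of the PL matrix.

    For each frame the PL matrix is U U^T with U = [cos theta, sin theta]
    (N x 2); the top eigenvector is U w / |U w| where w is the top
    eigenvector of the 2x2 Gram matrix U^T U, computed in closed form.
    """
    c = np.cos(theta)
    s = np.sin(theta)
    a = np.einsum("ij,ij->i", c, c)
    b = np.einsum("ij,ij->i", c, s)
    d = np.einsum("ij,ij->i", s, s)
    half_gap = np.sqrt(((a - d) / 2) ** 2 + b**2)
    lam = (a + d) / 2 + half_gap
    # two algebraically equivalent eigenvector forms; pick the better
    # conditioned one per frame (both degenerate only when the Gram matrix
    # is a multiple of the identity)
    w1 = np.stack([b, lam - a], axis=1)
    w2 = np.stack([lam - d, b], axis=1)
    use_w2 = np.linalg.norm(w2, axis=1) > np.linalg.norm(w1, axis=1)
    w = np.where(use_w2[:, None], w2, w1)
    norms = np.linalg.norm(w, axis=1)
    degenerate = norms < 1e-12 * np.maximum(lam, 1.0)
    if degenerate.any():
        logger.info(
            "degenerate top eigenvalue at %d frame(s); using cos-direction",
            int(degenerate.sum()),
        )
        w[degenerate] = (1.0, 0.0)
    v = w[:, :1] * c + w[:, 1:] * s
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.apply_along_axis(canonical_sign, 1, v)


def eigenvector_series(
    ts: RoiTimeSeries,
    trim_edges: int = 0,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame leading eigenvectors of one preprocessed scan.

    ``trim_edges`` frames are dropped from each end of the eigenvector
    sequence to guard against Hilbert boundary distortion.  The default of
    0 keeps all frames, matching the convention in which a 204-frame scan
    contributes 204 eigenvectors.  Pass a precomputed phase matrix via
    ``theta`` to avoid repeating the Hilbert transform.
    """
    if theta is None:
        theta = instantaneous_phase(ts)
    n_frames = theta.shape[0]
    if trim_edges < 0:
        raise ValueError("trim_edges must be non-negative")
    if n_frames - 2 * trim_edges < 2:
        raise ValueError(
            f"trimming {trim_edges} frames from each end of {n_frames} leaves "
            "fewer than 2 frames"
        )
    vectors = _rank2_leading_eigenvectors(theta)
    if trim_edges:
        vectors = vectors[trim_edges:-trim_edges]
    return vectors


def pool_eigenvectors(
    scans: list[RoiTimeSeries],
    trim_edges: int = 0,
    phases: dict[tuple[str, str], np.ndarray] | None = None,
) -> EigenvectorPool:
    """Concatenate per-frame leading eigenvectors over scans and subjects.

    Rows are ordered by (subject, session, frame) in the order the scans
    are supplied; the pool index records that provenance.  All scans must
    share the same region count.
    """
    if not scans:
        raise ValueError("no scans to pool")
    n_regions = scans[0].n_regions
    blocks = []
    idx_rows = []
    for ts in scans:
        if ts.n_regions != n_regions:
            raise ValueError(
                f"scan {ts.subject_id}/{ts.session} has {ts.n_regions} regions, "
                f"expected {n_regions}"
            )
        theta = phases.get(scan_key(ts)) if phases is not None else None
        vectors = eigenvector_series(ts, trim_edges=trim_edges, theta=theta)
        blocks.append(vectors)
        idx_rows.extend(
            {
                "subject_id": ts.subject_id,
                "session": ts.session,
                "frame": frame + trim_edges,
            }
            for frame in range(vectors.shape[0])
        )
    return EigenvectorPool(
        vectors=np.vstack(blocks), index=pd.DataFrame(idx_rows)
    )
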