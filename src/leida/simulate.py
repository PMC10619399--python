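"""Synthetic paired-cohort generator with a planted phase-locking repertoire.

The generator emulates the statistical objects that the downstream analysis
measures, without modelling voxels or hemodynamics.  A latent discrete-time
Markov chain switches between ``n_states_true`` phase-locking (PL) states.
Every region carries a common band-limited sinusoidal carrier; while state
*s* is active, the regions in that state's *positive community* are phase
advanced by a state-specific offset (> 90 degrees by default, matching the
convention that a PL-state's functional subsystem is the set of regions
shifted by more than 90 degrees from the main phase orientation).  Gaussian
observation noise is added on top.

Between-session effects are planted multiplicatively on the follow-up scans
of the *recurrent* arm only:

* an entry-probability factor on a state raises its fractional occupancy,
* a self-transition factor lengthens its lifetime,
* a phase-offset increment (radians) raises its decoupling.

Ground truth (state sequences, planted communities, realized occupancy and
lifetime) is returned alongside the cohort so that parameter-recovery tests
can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GROUPS, SESSIONS, RoiTimeSeries
from .metrics import fractional_occupancy, lifetime


@dataclass
class EffectSpec:
    """Planted follow-up change for one state (recurrent arm only).

    ``entry_factor`` multiplies the probability of entering the state from
    any other state (an occupancy effect); ``self_transition_factor``
    multiplies the probability of staying in the state (a lifetime effect);
    ``phase_offset_increment`` is added, in radians, to the state's
    community phase offset (a decoupling effect).  Factors must be positive;
    1.0 / 0.0 means "no effect".
    """

    state: int
    entry_factor: float = 1.0
    self_transition_factor: float = 1.0
    phase_offset_increment: float = 0.0

    def __post_init__(self) -> None:
        if self.state < 1:
            raise ValueError("state indices are 1-based")
        if self.entry_factor <= 0 or self.self_transition_factor <= 0:
            raise ValueError("effect factors must be positive")


def default_effects() -> list[EffectSpec]:
    """Default planted effects: one per metric, each on its own state.

    Magnitudes are sized for unambiguous parameter recovery at the design's
    sample size (11 recurrent pairs, 204 frames per scan): doubling a
    state's entry probability moves its stationary occupancy from 1/3 to
    1/2; the self-transition factor lengthens dwell times by roughly a
    factor 2.3; the 0.6 rad offset increment shifts decoupling by about 11
    degrees while keeping every community offset below pi, where the
    wrapped angular difference remains monotone in the offset.
    """
    return [
        EffectSpec(state=1, entry_factor=2.0),
        EffectSpec(state=2, self_transition_factor=1.10),
        EffectSpec(state=3, phase_offset_increment=0.6),
    ]


def null_effects() -> list[EffectSpec]:
    """No planted effects: baseline and follow-up sessions are exchangeable."""
    return []


def default_transition_matrix(n_states: int, p_self: float = 0.85) -> np.ndarray:
    """Uniform-switching baseline chain with self-transition ``p_self``.

    With TR = 2 s and p_self = 0.85 the expected dwell time is
    TR / (1 - p_self) ~ 13 s, in the range reported for fMRI PL-states.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    if n_states == 1:
        return np.ones((1, 1))
    off = (1.0 - p_self) / (n_states - 1)
    mat = np.full((n_states, n_states), off)
    np.fill_diagonal(mat, p_self)
    return mat


def _validate_stochastic(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("transition matrix must be square")
    if (matrix < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    rowsums = matrix.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-12):
        raise ValueError(f"transition-matrix rows must sum to 1, got {rowsums}")
    return matrix


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the emulated design: 80 regions, 204 analyzed frames
    at TR = 2 s, band-limited carriers at 0.04 Hz (mid band of the
    0.01-0.1 Hz filter), 11 recurrent and 17 non-recurrent subjects with
    two sessions each, and three planted PL-states.
    """

    n_regions: int = 80
    n_frames: int = 204
    tr: float = 2.0
    n_states_true: int = 3
    carrier_freq: float = 0.04
    noise_sd: float = 0.5
    transition_matrix_baseline: np.ndarray | None = None
    effects: list[EffectSpec] = field(default_factory=default_effects)
    n_recurrent: int = 11
    n_nonrecurrent: int = 17
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_frames < 2:
            raise ValueError("need at least 2 regions and 2 frames")
        if not (0.01 < self.carrier_freq < 0.1):
            raise ValueError("carrier_freq must lie strictly inside (0.01, 0.1) Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transition_matrix_baseline is None:
            self.transition_matrix_baseline = default_transition_matrix(
                self.n_states_true
            )
        self.transition_matrix_baseline = _validate_stochastic(
            self.transition_matrix_baseline
        )
        if self.transition_matrix_baseline.shape[0] != self.n_states_true:
            raise ValueError("transition matrix size must equal n_states_true")
        for eff in self.effects:
            if eff.state > self.n_states_true:
                raise ValueError(
                    f"effect on state {eff.state} but only "
                    f"{self.n_states_true} states exist"
                )


@dataclass
class PlantedStates:
    """Planted PL-state definitions: +/-1 community signs and phase offsets.

    ``centroids[s]`` is a length-``n_regions`` vector of +1 (regions in
    state *s*'s phase-shifted community) and -1 (the rest); ``offsets[s]``
    is the community phase advance in radians while the state is active.
    """

    centroids: np.ndarray  # (n_states, n_regions), entries +/-1
    offsets: np.ndarray  # (n_states,) radians

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.centroids.ndim != 2:
            raise ValueError("centroids must be (n_states, n_regions)")
        if len(self.offsets) != self.centroids.shape[0]:
            raise ValueError("one phase offset per state required")

    @property
    def n_states(self) -> int:
        return self.centroids.shape[0]


def make_true_states(
    config: SynthConfig, rng: np.random.Generator
) -> PlantedStates:
    """Build the planted repertoire: disjoint communities, offsets > 90 deg.

    Communities are consecutive disjoint blocks of
    ``n_regions // (n_states_true + 1)`` regions, leaving a block of
    never-shifted regions; offsets are pi/2 plus a per-state jitter drawn
    once from U(0.3, 0.8) rad, so every community is shifted by more than
    90 degrees while states remain mutually distinguishable.
    """
    k = config.n_states_true
    block = config.n_regions // (k + 1)
    if block < 1:
        raise ValueError("too many states for the number of regions")
    centroids = -np.ones((k, config.n_regions))
    for s in range(k):
        centroids[s, s * block : (s + 1) * block] = 1.0
    offsets = np.pi / 2 + rng.uniform(0.3, 0.8, size=k)
    return PlantedStates(centroids=centroids, offsets=offsets)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic row-stochastic chain."""
    matrix = _validate_stochastic(transition_matrix)
    vals, vecs = np.linalg.eig(matrix.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_sequence(
    transition_matrix: np.ndarray,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a 1-based latent state sequence from a Markov chain.

    The initial state is drawn from the chain's stationary distribution so
    that scans are statistically homogeneous in time.
    """
    matrix = _validate_stochastic(transition_matrix)
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = matrix.shape[0]
    seq = np.empty(n_frames, dtype=int)
    state = rng.choice(k, p=stationary_distribution(matrix))
    seq[0] = state
    for t in range(1, n_frames):
        state = rng.choice(k, p=matrix[state])
        seq[t] = state
    return seq + 1


def apply_effects(
    transition_matrix: np.ndarray,
    states: PlantedStates,
    effects: list[EffectSpec],
) -> tuple[np.ndarray, PlantedStates]:
    """Return the effect-modified chain and state repertoire.

    Entry factors scale the off-diagonal probabilities *into* the affected
    state; self-transition factors scale the diagonal; each modified row is
    renormalized by rescaling its untouched entries.  Probabilities are
    capped below 1 so the chain stays ergodic.
    """
    matrix = _validate_stochastic(transition_matrix).copy()
    offsets = states.offsets.copy()
    for eff in effects:
        s = eff.state - 1
        if eff.entry_factor != 1.0:
            for r in range(matrix.shape[0]):
                if r == s:
                    continue
                old = matrix[r, s]
                new = min(old * eff.entry_factor, 0.95)
                rest = 1.0 - old
                if rest <= 0:  # degenerate row: everything pointed at s already
                    matrix[r] = (1.0 - new) / (matrix.shape[0] - 1)
                else:
                    matrix[r] *= (1.0 - new) / rest
                matrix[r, s] = new
        if eff.self_transition_factor != 1.0:
            old = matrix[s, s]
            new = min(old * eff.self_transition_factor, 0.99)
            rest = 1.0 - old
            if rest <= 0:
                matrix[s] = (1.0 - new) / (matrix.shape[0] - 1)
            else:
                matrix[s] *= (1.0 - new) / rest
            matrix[s, s] = new
        offsets[s] += eff.phase_offset_increment
    matrix /= matrix.sum(axis=1, keepdims=True)  # kill 1e-16 drift
    return matrix, PlantedStates(centroids=states.centroids, offsets=offsets)


def simulate_scan(
    state_sequence: np.ndarray,
    states: PlantedStates,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    session: str = "baseline",
    group: str | None = None,
) -> RoiTimeSeries:
    """Render one scan from a latent state sequence.

    Every region carries ``cos(2*pi*f*t + phi0)``; while state *s* is
    active the regions in its positive community are advanced by
    ``offsets[s]`` radians.  Gaussian noise with sd ``noise_sd`` is added.
    The random initial carrier phase ``phi0`` is drawn per scan (omitted
    when no generator is supplied, keeping noise-free scans exactly
    reproducible).
    """
    seq = np.asarray(state_sequence, dtype=int)
    if seq.min() < 1 or seq.max() > states.n_states:
        raise ValueError("state sequence indices outside the planted repertoire")
    if states.centroids.shape[1] != config.n_regions:
        raise ValueError("planted centroids do not match n_regions")
    n = len(seq)
    t = np.arange(n) * config.tr
    phi0 = rng.uniform(0.0, 2 * np.pi) if rng is not None else 0.0
    base = 2 * np.pi * config.carrier_freq * t + phi0
    community = states.centroids[seq - 1] > 0  # (n_frames, n_regions)
    theta = base[:, None] + states.offsets[seq - 1][:, None] * community
    signal = np.cos(theta)
    if config.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)
    return RoiTimeSeries(
        data=signal,
        tr=config.tr,
        subject_id=subject_id,
        session=session,
        group=group,
    )


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery against the planted model."""

    states: PlantedStates
    followup_states: PlantedStates  # repertoire of recurrent follow-up scans
    transition_matrix_baseline: np.ndarray
    transition_matrix_followup: np.ndarray
    effects: list[EffectSpec]
    state_sequences: dict[tuple[str, str], np.ndarray]
    realized: pd.DataFrame  # subject_id, session, group, state, occupancy, lifetime

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "centroids": self.states.centroids.tolist(),
            "offsets": self.states.offsets.tolist(),
            "followup_offsets": self.followup_states.offsets.tolist(),
            "transition_matrix_baseline": self.transition_matrix_baseline.tolist(),
            "transition_matrix_followup": self.transition_matrix_followup.tolist(),
            "effects": [vars(e) for e in self.effects],
            "state_sequences": {
                f"{subj}/{sess}": seq.tolist()
                for (subj, sess), seq in self.state_sequences.items()
            },
            "realized": self.realized.to_dict(orient="list"),
        }
        path.write_text(json.dumps(payload))
        return path


def generate_cohort(
    config: SynthConfig,
) -> tuple[list[RoiTimeSeries], pd.DataFrame, SyntheticGroundTruth]:
    """Generate the full paired cohort plus its ground truth.

    Every subject contributes a baseline and a follow_up scan.  Follow-up
    scans of the recurrent arm are drawn from the effect-modified chain and
    offsets; all other scans use the baseline model, so with
    ``null_effects()`` the two sessions are exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    states = make_true_states(config, rng)
    p_base = config.transition_matrix_baseline
    p_follow, states_follow = apply_effects(p_base, states, config.effects)

    subjects = [(f"rec{i + 1:02d}", "recurrent") for i in range(config.n_recurrent)]
    subjects += [
        (f"non{i + 1:02d}", "non_recurrent") for i in range(config.n_nonrecurrent)
    ]

    scans: list[RoiTimeSeries] = []
    sequences: dict[tuple[str, str], np.ndarray] = {}
    realized_rows = []
    for subject_id, group in subjects:
        for session in SESSIONS:
            altered = group == "recurrent" and session == "follow_up"
            matrix = p_follow if altered else p_base
            repertoire = states_follow if altered else states
            seq = sample_state_sequence(matrix, config.n_frames, rng)
            sequences[(subject_id, session)] = seq
            scans.append(
                simulate_scan(
                    seq,
                    repertoire,
                    config,
                    rng,
                    subject_id=subject_id,
                    session=session,
                    group=group,
                )
            )
            occ = fractional_occupancy(seq, config.n_states_true)
            life = lifetime(seq, config.n_states_true, config.tr)
            for s in range(config.n_states_true):
                realized_rows.append(
                    {
                        "subject_id": subject_id,
                        "session": session,
                        "group": group,
                        "state": s + 1,
                        "occupancy": occ[s],
                        "lifetime": life[s],
                    }
                )

    manifest = pd.DataFrame(
        [
            {
                "subject_id": ts.subject_id,
                "session": ts.session,
                "group": ts.group,
                "tr": ts.tr,
                "path": f"{ts.subject_id}_{ts.session}.tsv",
            }
            for ts in scans
        ]
    )
    truth = SyntheticGroundTruth(
        states=states,
        followup_states=states_follow,
        transition_matrix_baseline=p_base,
        transition_matrix_followup=p_follow,
        effects=list(config.effects),
        state_sequences=sequences,
        realized=pd.DataFrame(realized_rows),
    )
    return scans, manifest, truth
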