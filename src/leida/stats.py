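"""Within-subject inference on PL-state metrics.

Baseline vs follow-up differences are tested per (k, state, metric) with a
sign-flip permutation paired t-test: the observed statistic is the ordinary
paired t on the differences, and the null distribution is built by randomly
negating each subject's difference — valid whenever the two sessions are
exchangeable under the null.  p-values are two-sided with add-one
smoothing, so p is never exactly 0.  Benjamini-Hochberg FDR adjustment is
applied within each partition model (per k, per metric), mirroring a sweep
over 19 partition models.  Paired Cohen's d and a
Jeffreys-Zellner-Siow (JZS) Bayes factor quantify effect size and evidence;
the Bayes factor is computed by numerical integration of the noncentral-t
marginal likelihood over a Cauchy prior on the standardized effect, with
one-sided alternatives handled by truncating the prior.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import integrate, stats as sp_stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PRIOR_SCALE = float(1.0 / np.sqrt(2.0))  # conventional "medium" JZS scale
METRICS = ("fractional_occupancy", "lifetime", "decoupling")
DIRECTIONS = ("two_sided", "greater", "less")


def _paired_diffs(baseline: np.ndarray, followup: np.ndarray) -> np.ndarray:
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape or baseline.ndim != 1:
        raise ValueError("baseline and followup must be equal-length 1-D vectors")
    if baseline.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(baseline).all() and np.isfinite(followup).all()):
        raise ValueError("missing or non-finite values in the paired vectors")
    return followup - baseline


def paired_t_statistic(diffs: np.ndarray) -> float:
    """Ordinary paired t: mean(d) / (sd(d)/sqrt(n)), sample sd (n-1)."""
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(diffs.mean() / (sd / np.sqrt(n)))


def paired_permutation_ttest(
    baseline: np.ndarray,
    followup: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Sign-flip permutation paired t-test; returns (t_obs, two-sided p).

    The null is built from ``n_perm`` random independent sign flips of the
    per-pair differences; p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1).
    Zero-variance differences make t undefined: the test warns and returns
    (nan, 1.0).
    """
    diffs = _paired_diffs(baseline, followup)
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    n = diffs.size
    if diffs.std(ddof=1) == 0:
        warnings.warn(
            "zero-variance paired differences: t undefined, p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.nan, 1.0
    t_obs = paired_t_statistic(diffs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    flipped = signs * diffs
    means = flipped.mean(axis=1)
    sds = flipped.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(
            sds > 0, means / (sds / np.sqrt(n)), np.inf * np.sign(means)
        )
    n_extreme = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    p = (1 + n_extreme) / (n_perm + 1)
    return t_obs, float(p)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    if np.any(p_values <= 0) or np.any(p_values > 1) or not np.isfinite(p_values).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


def cohens_d_paired(baseline: np.ndarray, followup: np.ndarray) -> float:
    """Paired Cohen's d: mean(diff) / sd(diff); nan (with warning) if sd = 0."""
    diffs = _paired_diffs(baseline, followup)
    sd = diffs.std(ddof=1)
    if sd == 0:
        warnings.warn(
            "zero-variance paired differences: Cohen's d undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.nan
    return float(diffs.mean() / sd)


def jzs_bayes_factor_from_t(
    t: float,
    n: int,
    direction: str = "two_sided",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """JZS Bayes factor BF10 for a one-sample (paired) t statistic.

    The marginal likelihood under H1 integrates the noncentral-t density of
    the observed t over a Cauchy(0, prior_scale) prior on the standardized
    effect delta (noncentrality delta * sqrt(n)); one-sided alternatives
    truncate the prior to the tested half-line (doubling its density).  H0
    is the central t.  BF01 is simply 1 / BF10.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if n < 2:
        raise ValueError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return sp_stats.nct.pdf(t, df, delta * sqrt_n) * sp_stats.cauchy.pdf(
            delta, scale=prior_scale
        )

    pieces = []
    if direction in ("two_sided", "greater"):
        pieces.append(integrate.quad(integrand, 0, np.inf, limit=200))
    if direction in ("two_sided", "less"):
        pieces.append(integrate.quad(integrand, -np.inf, 0, limit=200))
    numerator = sum(val for val, _ in pieces)
    abserr = sum(err for _, err in pieces)
    if direction != "two_sided":
        numerator *= 2.0  # truncated prior renormalization
        abserr *= 2.0
    if numerator < 0 or abserr > 1e-4 * numerator + 1e-12:
        raise RuntimeError(
            f"JZS integration failed: value={numerator:.3e}, abserr={abserr:.3e}, "
            f"t={t:.4g}, n={n}, direction={direction}"
        )
    denominator = sp_stats.t.pdf(t, df)
    return float(numerator / denominator)


def jzs_bayes_factor_paired(
    baseline: np.ndarray,
    followup: np.ndarray,
    direction: str = "two_sided",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """JZS Bayes factor BF10 for paired data (one-sample test on differences)."""
    diffs = _paired_diffs(baseline, followup)
    t = paired_t_statistic(diffs)
    if not np.isfinite(t):
        warnings.warn(
            "zero-variance paired differences: Bayes factor undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.nan
    return jzs_bayes_factor_from_t(t, diffs.size, direction, prior_scale)


def _pivot_sessions(block: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    wide = block.pivot_table(
        index="subject_id", columns="session", values=value, aggfunc="first"
    )
    for session in ("baseline", "follow_up"):
        if session not in wide.columns or wide[session].isna().any():
            bad = (
                sorted(wide.index[wide[session].isna()])
                if session in wide.columns
                else sorted(wide.index)
            )
            raise ValueError(f"unpaired subjects (missing {session}): {bad}")
    wide = wide.sort_index()
    return wide["baseline"].to_numpy(), wide["follow_up"].to_numpy()


def analyze_cohort(
    metrics: pd.DataFrame,
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    bayes_direction: str = "greater",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    bayes: bool = True,
) -> pd.DataFrame:
    """Full within-subject analysis of a tidy state-metrics table.

    For every (k, state, metric) a sign-flip permutation paired t-test
    (two-sided) compares baseline against follow_up across subjects; BH-FDR
    is applied within each (k, metric) family, i.e. separately per
    partition model; paired Cohen's d and a JZS Bayes factor (one-sided by
    default, testing baseline < follow_up) are attached.  States with an
    undefined metric value (NaN decoupling of single-sign centroids) are
    excluded from that metric's family.  Permutation seeds are derived per
    test from ``seed``, so results are reproducible and independent of
    iteration order.
    """
    required = {"subject_id", "session", "k", "state"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    rows = []
    for metric_idx, metric in enumerate(METRICS):
        if metric not in metrics.columns:
            continue
        for k, k_block in metrics.groupby("k", sort=True):
            for state, block in k_block.groupby("state", sort=True):
                if block[metric].isna().any():
                    continue
                baseline, followup = _pivot_sessions(block, metric)
                test_seed = np.random.SeedSequence(
                    entropy=seed if seed is not None else 0,
                    spawn_key=(int(k), int(state), metric_idx),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    t_obs, p_perm = paired_permutation_ttest(
                        baseline,
                        followup,
                        n_perm=n_perm,
                        seed=np.random.default_rng(test_seed),
                    )
                    d = cohens_d_paired(baseline, followup)
                    bf10 = (
                        jzs_bayes_factor_paired(
                            baseline, followup, bayes_direction, prior_scale
                        )
                        if bayes and np.isfinite(t_obs)
                        else np.nan
                    )
                rows.append(
                    {
                        "k": int(k),
                        "state": int(state),
                        "metric": metric,
                        "label": f"k{int(k)}c{int(state)}",
                        "n_pairs": baseline.size,
                        "df": baseline.size - 1,
                        "t_obs": t_obs,
                        "p_perm": p_perm,
                        "cohens_d": d,
                        "bayes_factor_10": bf10,
                    }
                )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["p_fdr"] = np.nan
    for (_, _), family in result.groupby(["k", "metric"], sort=False):
        result.loc[family.index, "p_fdr"] = bh_fdr(family["p_perm"].to_numpy())
    result["significant"] = result["p_fdr"] < alpha
    order = [
        "k", "state", "metric", "label", "n_pairs", "df",
        "t_obs", "p_perm", "p_fdr", "cohens_d", "bayes_factor_10", "significant",
    ]
    return result[order].sort_values(["metric", "k", "state"]).reset_index(drop=True)


def summarize(stat_table: pd.DataFrame, alpha: float = 0.05) -> str:
    """Human-readable summary: significant states per partition model."""
    lines = []
    if stat_table.empty:
        return "no tests were run\n"
    for metric, block in stat_table.groupby("metric", sort=True):
        sig = block[block["p_fdr"] < alpha]
        lines.append(f"{metric}: {len(sig)} FDR-significant state(s) of {len(block)}")
        for row in sig.itertuples(index=False):
            lines.append(
                f"  {row.label}: t({row.df}) = {row.t_obs:.2f}, "
                f"p-perm = {row.p_perm:.4f}, p-FDR = {row.p_fdr:.4f}, "
                f"d = {row.cohens_d:.2f}, BF10 = {row.bayes_factor_10:.2f}"
            )
    return "\n".join(lines) + "\n"
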