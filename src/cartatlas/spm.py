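"""Nonparametric 1-D statistical parametric mapping (SnPM) for paired designs.

Compares two conditions measured on the same subjects along a 1-D domain
(here: stance percentage). The pointwise statistic is the paired t on
subject-wise differences; family-wise error across the domain is
controlled by the permutation distribution of the maximum |t| under
subject-wise sign flips of the differences. For n <= 12 subjects all 2^n
sign patterns are enumerated (exact, deterministic); larger designs use
seeded Monte-Carlo sampling. Supra-threshold clusters receive p-values
from the permutation distribution of the maximum cluster extent at the
same threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["PairedTrajectories", "SPMResult", "pointwise_paired_t",
           "snpm_paired"]

EXHAUSTIVE_MAX_N = 12
DEFAULT_MC_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class PairedTrajectories:
    cond_a: np.ndarray      # (n_subjects, n_points)
    cond_b: np.ndarray
    stance_pct: np.ndarray  # (n_points,)

    def __post_init__(self):
        a = np.asarray(self.cond_a, dtype=float)
        b = np.asarray(self.cond_b, dtype=float)
        g = np.asarray(self.stance_pct, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != len(g):
            raise ValueError("cond_a/cond_b must be (n_subjects, n_points) "
                             "matching the stance grid")
        if a.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        object.__setattr__(self, "cond_a", a)
        object.__setattr__(self, "cond_b", b)
        object.__setattr__(self, "stance_pct", g)

    @classmethod
    def from_csvs(cls, path_a, path_b):
        import pandas as pd
        a = pd.read_csv(path_a, index_col=0)
        b = pd.read_csv(path_b, index_col=0)
        grid = np.array([float(c) for c in a.columns])
        return cls(a.to_numpy(), b.to_numpy(), grid)


@dataclass(frozen=True)
class SPMResult:
    t_stat: np.ndarray
    threshold: float
    clusters: list          # of dicts: start_pct, end_pct, extent, p
    alpha: float
    n_permutations: int
    exhaustive: bool

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def to_json(self, path):
        payload = {
            "t_stat": self.t_stat.tolist(),
            "threshold": self.threshold,
            "clusters": self.clusters,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def pointwise_paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic at each domain point; sample sd (n-1 denominator).

    Zero-variance points: t = 0 where the mean is also zero, otherwise a
    signed infinity sentinel (a constant nonzero difference is infinitely
    strong evidence under this statistic).
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("diffs must be (n >= 2, T)")
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0.0
    t[zero_sd & (mean == 0.0)] = 0.0
    t[zero_sd & (mean > 0.0)] = np.inf
    t[zero_sd & (mean < 0.0)] = -np.inf
    return t


def _perm_t(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for many sign-flip patterns at once, (n_perm, T)."""
    n, _ = diffs.shape
    ss = (diffs ** 2).sum(axis=0)                     # invariant to flips
    m = signs @ diffs / n                             # (P, T)
    var = np.maximum(ss - n * m ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[np.isnan(t)] = 0.0
    return t


def _clusters_bool(mask: np.ndarray):
    """Maximal contiguous runs of True: list of (start, end) inclusive."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))




def snpm_paired(data: PairedTrajectories, alpha: float = 0.05,
                n_permutations: int = DEFAULT_MC_PERMUTATIONS,
                seed: int = 0) -> SPMResult:
    """Sign-flip permutation SPM on paired trajectories.

    Threshold = (1 - alpha) quantile of the permutation max-|t|
    distribution; clusters are contiguous runs with |t| above it, and
    each cluster's p-value is the max-statistic p of its peak: the
    fraction of permutations whose field-wide max |t| reaches the
    cluster's peak |t| (the identity permutation always counts, so
    p >= 1/n_permutations; with n subjects the minimum achievable p is
    2/2^n because the all-flipped pattern mirrors the observed one).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    diffs = data.cond_b - data.cond_a
    n, T = diffs.shape
    if np.all(diffs == 0.0):
        # identical conditions: zero t field, nothing supra-threshold
        return SPMResult(np.zeros(T), np.inf, [], alpha, 0, True)
    if not np.all(np.isfinite(diffs)):
        raise ValueError("trajectories must be finite")
    per_subject_sd = diffs.std(axis=1)
    if np.all(diffs.std(axis=0) == 0.0) and np.all(per_subject_sd == 0.0):
        raise ValueError("degenerate data: differences have no variance "
                         "under any sign-flip")

    exhaustive = n <= EXHAUSTIVE_MAX_N or n_permutations >= 2 ** n
    if exhaustive:
        P = 2 ** n
        bits = (np.arange(P)[:, None] >> np.arange(n)) & 1
        signs = 1.0 - 2.0 * bits                      # row 0 = identity
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        signs[0] = 1.0                                # include the identity
        P = n_permutations

    t_perm = _perm_t(diffs, signs)
    t_obs = pointwise_paired_t(diffs)
    max_t = np.abs(t_perm).max(axis=1)
    threshold = float(np.quantile(max_t, 1.0 - alpha, method="higher"))

    # the identity permutation (row 0) is the observed statistic computed
    # by the same arithmetic as every other row, so threshold and peak
    # comparisons are exact rather than epsilon-sensitive
    obs_abs = np.abs(t_perm[0])
    obs_mask = obs_abs > threshold
    clusters = []
    runs = _clusters_bool(obs_mask)
    if runs:
        grid = data.stance_pct
        for start, end in runs:
            peak = obs_abs[start:end + 1].max()
            p = float((max_t >= peak).sum() / P)
            clusters.append({"start_pct": float(grid[start]),
                             "end_pct": float(grid[end]),
                             "extent": int(end - start + 1),
                             "peak_t": float(peak), "p": p})
    return SPMResult(t_obs, threshold, clusters, alpha, int(P), exhaustive)
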