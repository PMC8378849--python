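"""Cluster-mass permutation inference on response curves.

Per-lag conventional tests (one-sample t, paired t, or 2x2 repeated-measures
ANOVA) are thresholded at p < 0.05 (two-tailed); maximal runs of adjacent
supra-threshold lags with the same effect sign form clusters whose mass is
the summed test statistic. A permutation null — per-observer sign flips for
one-sample tests, per-observer condition relabelling for paired tests and
ANOVAs — yields the distribution of the most extreme cluster mass per
iteration, from which each observed cluster gets a Monte Carlo p-value.
Clusters with p < 0.01 are considered significant.

The 2x2 ANOVA has one numerator df per effect, so each per-lag F equals the
squared paired t on the corresponding within-observer contrast scores; F
clusters use the p < 0.05 criterion alone (an F carries no sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ClusterResult

DESIGNS = ("one-sample", "paired", "rm-anova-2x2")
ANOVA_EFFECTS = ("stimulus", "task", "interaction")

# contrast weights over conditions ordered
# (stim0/task0, stim0/task1, stim1/task0, stim1/task1)
_CONTRASTS = {
    "stimulus": np.array([1.0, 1.0, -1.0, -1.0]) / 2.0,
    "task": np.array([1.0, -1.0, 1.0, -1.0]) / 2.0,
    "interaction": np.array([1.0, -1.0, -1.0, 1.0]) / 2.0,
}


def _one_sample_t(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t and two-tailed p per lag for observers x lags data; zero-variance
    lags yield NaN (they break clusters)."""
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observers")
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def pointwise_tests(
    curves: np.ndarray, design: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-lag statistic and p maps.

    ``curves`` is (observers, lags) for one-sample, (observers, 2, lags) for
    paired, (observers, 4, lags) for the 2x2 ANOVA with conditions ordered
    (rivalry-ignore, rivalry-report, onscreen-ignore, onscreen-report).
    Returns {effect: (stat, p)}; t effects are signed, F effects not.
    """
    if design == "one-sample":
        return {"mean": _one_sample_t(curves)}
    if design == "paired":
        return {"difference": _one_sample_t(curves[:, 0, :] - curves[:, 1, :])}
    if design == "rm-anova-2x2":
        out = {}
        for effect, w in _CONTRASTS.items():
            scores = np.tensordot(curves, w, axes=([1], [0]))
            t, p = _one_sample_t(scores)
            out[effect] = (t ** 2, p)  # F with (1, n-1) df; same p as |t|
        return out
    raise ValueError(f"unknown design {design!r}")


@dataclass
class Cluster:
    start_idx: int
    end_idx: int  # inclusive
    mass: float
    sign: int


def form_clusters(
    stat: np.ndarray,
    p: np.ndarray,
    alpha_enter: float = 0.05,
    signed: bool = True,
) -> list[Cluster]:
    """Maximal runs of adjacent lags with p < alpha and a common effect sign.

    For unsigned (F) maps only the p criterion applies. NaN p-values (e.g.
    zero-variance lags) break clusters.
    """
    with np.errstate(invalid="ignore"):
        sig = (p < alpha_enter) & ~np.isnan(p)
    if signed:
        key = np.where(sig, np.sign(stat), 0.0)
    else:
        key = sig.astype(float)
    clusters = []
    i = 0
    n = len(stat)
    while i < n:
        if key[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and key[j + 1] == key[i]:
            j += 1
        clusters.append(Cluster(i, j, float(stat[i:j + 1].sum()),
                                int(key[i]) if signed else 0))
        i = j + 1
    return clusters


def _max_mass(clusters: list[Cluster]) -> float:
    return max((abs(c.mass) for c in clusters), default=0.0)


def permutation_null(
    curves: np.ndarray,
    design: str,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha_enter: float = 0.05,
    effects: tuple[str, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Null distribution of the most extreme cluster mass, per effect.

    One-sample: each iteration flips the sign of each observer's whole curve
    independently. Paired / ANOVA: each iteration randomly reassigns each
    observer's data to conditions independently. All effects of an ANOVA are
    recomputed per iteration, keeping a separate max-mass null per effect.
    """
    if n_iter < 100:
        warnings.warn("permutation distribution with fewer than 100 iterations")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_obs = curves.shape[0]
    maps = pointwise_tests(curves, design)
    if effects is None:
        effects = tuple(maps.keys())
    null = {e: np.empty(n_iter) for e in effects}
    signed = design != "rm-anova-2x2"
    for it in range(n_iter):
        if design == "one-sample":
            flips = rng.choice([-1.0, 1.0], size=n_obs)
            perm = curves * flips[:, None]
        else:
            perm = np.empty_like(curves)
            n_cond = curves.shape[1]
            for o in range(n_obs):
                perm[o] = curves[o, rng.permutation(n_cond)]
        pmaps = pointwise_tests(perm, design)
        for e in effects:
            stat, p = pmaps[e]
            null[e][it] = _max_mass(form_clusters(stat, p, alpha_enter, signed))
    return null


def cluster_pvalues(
    clusters: list[Cluster],
    null_masses: np.ndarray,
    lags_s: np.ndarray,
    effect: str = "mean",
) -> list[ClusterResult]:
    """Monte Carlo p per observed cluster.

    p is the proportion of the null distribution strictly more extreme than
    the observed |mass|, with the +1 correction that keeps p in
    [1/(n_iter+1), 1] (an observed mass beyond every null value is stored as
    1/(n_iter+1) rather than the printed 0).
    """
    n = len(null_masses)
    out = []
    for c in clusters:
        k = int(np.sum(null_masses > abs(c.mass)))
        out.append(ClusterResult(
            effect=effect,
            start_s=float(lags_s[c.start_idx]),
            end_s=float(lags_s[c.end_idx]),
            mass=c.mass,
            p=(k + 1) / (n + 1),
            sign=c.sign,
        ))
    return out


def cluster_test(
    curves: np.ndarray,
    lags_s: np.ndarray,
    design: str = "one-sample",
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha_enter: float = 0.05,
) -> dict[str, list[ClusterResult]]:
    """Full cluster-mass permutation test; returns results per effect."""
    maps = pointwise_tests(curves, design)
    null = permutation_null(curves, design, n_iter, seed, alpha_enter)
    signed = design != "rm-anova-2x2"
    out = {}
    for effect, (stat, p) in maps.items():
        obs = form_clusters(stat, p, alpha_enter, signed)
        out[effect] = cluster_pvalues(obs, null[effect], lags_s, effect)
    return out
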