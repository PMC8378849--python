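"""Cluster-mass permutation statistics on the deconvolved response curves.

Reads the per-observer curves written by 04_deconvolve.py and runs:

* one-sample cluster tests per condition on the switch-locked
  rate-of-change curves (which time windows differ from zero);
* the 2x2 stimulus-by-task repeated-measures ANOVA across conditions;
* one-sample tests on the preceding-duration covariate curves (the
  adaptation-like amplitude dependence).

Output: results/stats/clusters.tsv, one row per cluster with its time
window, mass, Monte Carlo p (1000 permutations) and significance at p<0.01.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pupilswitch import cluster
from pupilswitch.pipeline import ANOVA_CONDITION_ORDER

GLM = Path(__file__).resolve().parents[1] / "results" / "glm"
OUT = Path(__file__).resolve().parents[1] / "results" / "stats"
SEED = 99


def read_curves(path: Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    obs_cols = [c for c in df.columns if c.startswith("obs")]
    curves = {}
    for name, grp in df.groupby("regressor", sort=False):
        curves[name] = grp[obs_cols].to_numpy().T  # observers x lags
        lags = grp["lag_s"].to_numpy()
    return lags, curves


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []

    lags, percond = read_curves(GLM / "percond_curves.tsv")
    for cond in ANOVA_CONDITION_ORDER:
        res = cluster.cluster_test(percond[f"switch:{cond}"], lags,
                                   "one-sample", 1000, SEED)["mean"]
        rows += [dict(analysis="switch_rate", effect=cond, start_s=c.start_s,
                      end_s=c.end_s, mass=c.mass, p=c.p, sign=c.sign)
                 for c in res]
    stacked = np.stack([percond[f"switch:{c}"] for c in ANOVA_CONDITION_ORDER],
                       axis=1)
    anova = cluster.cluster_test(stacked, lags, "rm-anova-2x2", 1000, SEED)
    for eff, clusters in anova.items():
        rows += [dict(analysis="switch_rate_anova", effect=eff,
                      start_s=c.start_s, end_s=c.end_s, mass=c.mass, p=c.p,
                      sign=c.sign) for c in clusters]

    lags_c, cov = read_curves(GLM / "covariate_curves.tsv")
    for cond in ANOVA_CONDITION_ORDER:
        res = cluster.cluster_test(cov[f"switch:{cond}:dur_preceding"],
                                   lags_c, "one-sample", 1000, SEED)["mean"]
        rows += [dict(analysis="preceding_duration_covariate", effect=cond,
                      start_s=c.start_s, end_s=c.end_s, mass=c.mass, p=c.p,
                      sign=c.sign) for c in res]

    df = pd.DataFrame(rows)
    df["significant"] = df["p"] < 0.01
    df.to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    sig = df[df.significant]
    print(f"{len(df)} clusters, {len(sig)} significant at p<0.01")
    for _, r in sig.iterrows():
        print(f"  {r.analysis} / {r.effect}: {r.start_s:+.1f} to "
              f"{r.end_s:+.1f} s, sign {r.sign:+d}, p = {r.p:.4f}")


if __name__ == "__main__":
    main()
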