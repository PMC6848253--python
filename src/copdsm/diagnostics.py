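"""Simulation-based model diagnostics: posterior predictive checks, visual
predictive checks with k-means duration binning, and convergence reporting.

For each of ``n_replicates`` replicates a parameter vector is drawn from the
posterior and a full trial with the observed design (same subjects,
covariates and study lengths) is simulated; scalar statistics of the
replicates are compared with the observed data (PPC), and binned duration
counts per state are compared with observed counts (VPC). Replicate ``r``
uses seed ``base_seed + r`` so reports are reproducible draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialDataset
from .inference import PosteriorFit

__all__ = [
    "PPCReport",
    "VPCBinning",
    "VPCReport",
    "ppc",
    "choose_bins",
    "vpc",
    "convergence_report",
    "plot_ppc",
    "plot_vpc",
]


# ---------------------------------------------------------------------------
# replicate simulation
# ---------------------------------------------------------------------------


def simulate_replicates(
    fit: PosteriorFit, dataset: TrialDataset, n_replicates: int, seed: int
) -> list[TrialDataset]:
    """Posterior predictive replicate trials with the observed design."""
    from .simulate import simulate_matched

    n_total = fit.n_total_draws()
    reps = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        i = int(rng.integers(n_total))
        spec_12 = fit.transition_spec("1->2", i)
        spec_21 = fit.transition_spec("2->1", i)
        drop = fit.dropout_spec(i)
        reps.append(simulate_matched(dataset, spec_12, spec_21, drop, rng))
    return reps


def _scalar_stats(ds: TrialDataset) -> dict:
    s = ds.sojourns
    return {
        "total_observations": float(len(s)),
        "observations_state1": float((s["state"] == 1).sum()),
        "observations_state2": float((s["state"] == 2).sum()),
        "total_exacerbations": float(ds.n_exacerbations().sum()),
        "dropout_count": float(ds.subjects["dropout_flag"].sum()),
    }


@dataclass
class PPCStat:
    observed: float
    replicates: np.ndarray
    #: posterior predictive upper-tail probability P(T_rep >= T_obs)
    tail_prob: float


@dataclass
class PPCReport:
    stats: dict
    exacerbation_table: pd.DataFrame
    n_replicates: int

    def tail_probs(self) -> dict:
        return {k: v.tail_prob for k, v in self.stats.items()}


def ppc(
    fit: PosteriorFit, dataset: TrialDataset, n_replicates: int = 100, seed: int = 0
) -> PPCReport:
    """Posterior predictive check on the scalar summary statistics and on
    the per-subject exacerbation-count distribution."""
    reps = simulate_replicates(fit, dataset, n_replicates, seed)
    obs = _scalar_stats(dataset)
    rep_stats = {k: np.array([_scalar_stats(r)[k] for r in reps]) for k in obs}
    stats = {
        k: PPCStat(
            observed=obs[k],
            replicates=rep_stats[k],
            tail_prob=float(np.mean(rep_stats[k] >= obs[k])),
        )
        for k in obs
    }
    obs_counts = dataset.n_exacerbations().to_numpy()
    k_max = int(max(obs_counts.max(initial=0),
                    max(r.n_exacerbations().max() for r in reps)))
    rows = []
    for k in range(k_max + 1):
        rep_k = np.array([(r.n_exacerbations().to_numpy() == k).sum() for r in reps])
        lo, med, hi = np.percentile(rep_k, [2.5, 50, 97.5])
        rows.append(
            {"count": k, "observed": int((obs_counts == k).sum()),
             "lo": lo, "median": med, "hi": hi}
        )
    return PPCReport(stats=stats, exacerbation_table=pd.DataFrame(rows),
                     n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# VPC binning
# ---------------------------------------------------------------------------


@dataclass
class VPCBinning:
    """Duration bins from 1-D k-means: the number of clusters is picked at
    the elbow of the within-cluster sum of squares (largest second
    difference), and bin boundaries are midpoints between adjacent cluster
    centers."""

    k: int
    centers: np.ndarray
    edges: np.ndarray  # interior boundaries, length k-1
    wss: dict
    state: int | None = None

    def assign(self, durations) -> np.ndarray:
        return np.digitize(np.asarray(durations, dtype=float), self.edges)

    def counts(self, durations) -> np.ndarray:
        return np.bincount(self.assign(durations), minlength=self.k)


def _kmeans_wss(x: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, float]:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel()), float(km.inertia_)


def choose_bins(
    durations,
    k_max: int = 8,
    k: int | None = None,
    seed: int = 0,
    state: int | None = None,
) -> VPCBinning:
    """Run 1-D k-means for k = 1..k_max on the observed durations and select
    k automatically by the elbow rule (``k`` overrides the rule)."""
    x = np.asarray(durations, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 durations to bin")
    n_distinct = len(np.unique(x))
    if n_distinct < 2:
        centers, _ = _kmeans_wss(x, 1, seed)
        return VPCBinning(k=1, centers=centers, edges=np.array([]),
                          wss={1: 0.0}, state=state)
    capped = min(k_max, n_distinct)
    wss = {}
    centers_by_k = {}
    for kk in range(1, capped + 1):
        centers_by_k[kk], wss[kk] = _kmeans_wss(x, kk, seed)
    if k is None:
        if capped <= 2:
            k = capped
        else:
            ks = range(2, capped)  # second difference needs k-1 and k+1
            k = max(ks, key=lambda kk: (wss[kk - 1] - 2 * wss[kk] + wss[kk + 1]))
    elif k > capped:
        k = capped
    centers = centers_by_k[k]
    edges = (centers[:-1] + centers[1:]) / 2.0
    return VPCBinning(k=k, centers=centers, edges=edges, wss=wss, state=state)


@dataclass
class VPCReport:
    state_tables: dict  # state -> DataFrame(bin_lo, bin_hi, observed, lo, median, hi)
    exacerbation_table: pd.DataFrame
    n_replicates: int

    def coverage(self, state: int) -> float:
        t = self.state_tables[state]
        return float(((t["observed"] >= t["lo"]) & (t["observed"] <= t["hi"])).mean())


def vpc(
    fit: PosteriorFit,
    dataset: TrialDataset,
    binnings: dict | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    k_max: int = 8,
) -> VPCReport:
    """Visual predictive check: per state, binned counts of completed
    sojourn durations (observed vs the replicates' 95% interval), plus the
    per-subject exacerbation-count check."""
    reps = simulate_replicates(fit, dataset, n_replicates, seed)
    state_tables = {}
    def _done(ds, state):
        s = ds.sojourns
        return s.loc[(s["state"] == state) & s["event"], "duration"].to_numpy()

    for state in (1, 2):
        obs_dur = _done(dataset, state)
        if binnings and state in binnings:
            binning = binnings[state]
        else:
            binning = choose_bins(obs_dur, k_max=k_max, state=state)
        obs_counts = binning.counts(obs_dur)
        rep_counts = np.stack([binning.counts(_done(r, state)) for r in reps])
        lo, med, hi = np.percentile(rep_counts, [2.5, 50, 97.5], axis=0)
        lo_edges = np.concatenate([[0.0], binning.edges])
        hi_edges = np.concatenate([binning.edges, [np.inf]])
        state_tables[state] = pd.DataFrame(
            {"bin_lo": lo_edges, "bin_hi": hi_edges, "observed": obs_counts,
             "lo": lo, "median": med, "hi": hi}
        )
    obs_counts = dataset.n_exacerbations().to_numpy()
    k_top = int(max(obs_counts.max(initial=0),
                    max(r.n_exacerbations().max() for r in reps)))
    rows = []
    for k in range(k_top + 1):
        rep_k = np.array([(r.n_exacerbations().to_numpy() == k).sum() for r in reps])
        lo, med, hi = np.percentile(rep_k, [2.5, 50, 97.5])
        rows.append({"count": k, "observed": int((obs_counts == k).sum()),
                     "lo": lo, "median": med, "hi": hi})
    return VPCReport(state_tables=state_tables,
                     exacerbation_table=pd.DataFrame(rows),
                     n_replicates=n_replicates)


def convergence_report(fit: PosteriorFit) -> pd.DataFrame:
    """Split-Rhat and effective sample size for the top-level parameters."""
    return fit.summary()[["rhat", "ess"]]


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------


def plot_ppc(report: PPCReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.stats)
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3))
    for ax, name in zip(np.atleast_1d(axes), names):
        st = report.stats[name]
        ax.hist(st.replicates, bins=20, color="steelblue", alpha=0.7)
        ax.axvline(st.observed, color="red")
        ax.set_title(f"{name}\np={st.tail_prob:.2f}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(report: VPCReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("state 1 durations", report.state_tables[1]),
              ("state 2 durations", report.state_tables[2]),
              ("exacerbations per subject", report.exacerbation_table)]
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, (title, tab) in zip(axes, panels):
        x = np.arange(len(tab))
        ax.bar(x, tab["observed"], color="grey", alpha=0.7, label="observed")
        yerr = np.vstack([tab["median"] - tab["lo"], tab["hi"] - tab["median"]])
        ax.errorbar(x, tab["median"], yerr=yerr, fmt="o", color="black",
                    capsize=3, label="simulated 95% CI")
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
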