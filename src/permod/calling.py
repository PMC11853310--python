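"""Per-read binarization and per-site m6A calling from modProbs.

A nucleotide of a read is 'modified' when its modification probability is
greater than or equal to the threshold tau (0.5 by default).  A position is
a called site when it has at least ``min_cov`` overlapping reads and at
least ``min_freq`` of them are modified — with the defaults (25 reads, 5%)
a site needs a minimum of 2 modified reads at 25x coverage.

Also provides Youden-index threshold optimization on labeled modProb
streams, stoichiometry recovery on in-silico mixtures, false-positive-rate
evaluation on unmodified controls, and replicate concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PermodError

DEFAULT_TAU = 0.5
DEFAULT_MIN_COV = 25
DEFAULT_MIN_FREQ = 0.05


def binarize(mod_prob, tau: float = DEFAULT_TAU):
    """Modified iff modProb >= tau (closed inequality). Vectorized."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    arr = np.asarray(mod_prob)
    out = arr >= tau
    return out if arr.ndim else bool(out)


def call_sites(calls: pd.DataFrame, tau: float = DEFAULT_TAU,
               min_cov: int = DEFAULT_MIN_COV,
               min_freq: float = DEFAULT_MIN_FREQ) -> pd.DataFrame:
    """Aggregate per-read calls into per-site modification calls.

    Parameters
    ----------
    calls
        Per-read per-base calls with columns ref_id (or chrom), pos,
        strand, mod_prob.  Coverage of a site counts the reads that carry a
        call there (deletions contribute no call and are excluded).

    Returns
    -------
    One row per covered (chrom, pos, strand), ordered by (chrom, pos), with
    coverage, n_modified, frequency, the threshold used and the ``passed``
    flag (coverage >= min_cov and frequency >= min_freq).
    """
    chrom_col = "chrom" if "chrom" in calls.columns else "ref_id"
    df = calls.assign(_mod=binarize(calls["mod_prob"].to_numpy(), tau))
    grouped = (
        df.groupby([chrom_col, "pos", "strand"], sort=False)
        .agg(coverage=("_mod", "size"), n_modified=("_mod", "sum"))
        .reset_index()
        .rename(columns={chrom_col: "chrom"})
    )
    grouped["frequency"] = grouped["n_modified"] / grouped["coverage"]
    grouped["passed"] = (grouped["coverage"] >= min_cov) & (grouped["frequency"] >= min_freq)
    grouped["tau"] = tau
    return grouped.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


@dataclass
class ThresholdScan:
    """Youden-index scan over a threshold grid.

    tau_star maximizes J(tau) = TPR(tau) - FPR(tau); ties resolve to the
    smallest grid point (conservative toward sensitivity).
    """

    grid: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tau_star: float

    @property
    def youden_j(self) -> np.ndarray:
        return self.tpr - self.fpr

    @property
    def j_star(self) -> float:
        return float(np.max(self.youden_j))


def youden_threshold(modified_probs, unmodified_probs,
                     grid=None) -> ThresholdScan:
    """Find the modProb threshold maximizing the Youden index.

    TPR(tau) is the fraction of known-modified bases with modProb >= tau,
    FPR(tau) the same fraction among known-unmodified bases.
    """
    mod = np.asarray(modified_probs, dtype=float)
    unmod = np.asarray(unmodified_probs, dtype=float)
    if mod.size == 0 or unmod.size == 0:
        raise PermodError("both modified and unmodified inputs must be non-empty")
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    grid = np.sort(np.asarray(grid, dtype=float))
    tpr = np.array([(mod >= t).mean() for t in grid])
    fpr = np.array([(unmod >= t).mean() for t in grid])
    j = tpr - fpr
    tau_star = float(grid[int(np.argmax(j))])  # argmax returns first = smallest tau
    return ThresholdScan(grid=grid, tpr=tpr, fpr=fpr, tau_star=tau_star)


def stoichiometry_recovery(mixtures: dict[float, pd.DataFrame],
                           tau_list=(0.5, 0.1, 0.01)) -> pd.DataFrame:
    """Estimate modification frequency of in-silico mixtures per threshold.

    Parameters
    ----------
    mixtures
        target stoichiometry (fraction) -> per-read call table of that
        mixture (e.g. from :func:`permod.synthetic.mix_pools`).
    tau_list
        modProb thresholds at which stoichiometry is estimated.

    Returns
    -------
    One row per (target, tau) with the mean per-site estimated frequency
    and its bias (estimate - target).
    """
    rows = []
    for target, calls in sorted(mixtures.items()):
        for tau in tau_list:
            sites = call_sites(calls, tau=tau, min_cov=1, min_freq=0.0)
            est = float(sites["frequency"].mean())
            rows.append({"target": target, "tau": tau,
                         "estimate": est, "bias": est - target})
    return pd.DataFrame(rows)


@dataclass
class FPRSummary:
    """False-positive-rate summary on a known-unmodified control."""

    n_testable: int
    n_passed: int
    fpr: float
    replicable_fpr: float | None = None


def evaluate_fpr(site_calls, min_cov: int = DEFAULT_MIN_COV) -> FPRSummary:
    """FPR of site calling on an unmodified (IVT-like) control.

    ``site_calls`` is one site-call table or a list of per-replicate
    tables.  FPR = passed sites / testable positions (coverage >= min_cov).
    With replicates, the replicable variant counts positions passing in all
    replicates over positions testable in all replicates.
    """
    reps = site_calls if isinstance(site_calls, (list, tuple)) else [site_calls]
    testable = [r[r["coverage"] >= min_cov] for r in reps]
    if any(len(t) == 0 for t in testable):
        raise PermodError("no testable positions (coverage gate)")
    first = testable[0]
    summary = FPRSummary(
        n_testable=len(first),
        n_passed=int(first["passed"].sum()),
        fpr=float(first["passed"].mean()),
    )
    if len(reps) > 1:
        keys = [set(map(tuple, t[["chrom", "pos", "strand"]].to_numpy())) for t in testable]
        shared = set.intersection(*keys)
        if not shared:
            raise PermodError("no positions testable in all replicates")
        passed = [
            set(map(tuple, t.loc[t["passed"], ["chrom", "pos", "strand"]].to_numpy()))
            for t in testable
        ]
        summary.replicable_fpr = len(set.intersection(*passed) & shared) / len(shared)
    return summary


@dataclass
class ConcordanceResult:
    """Between-replicate agreement of called sites."""

    overlap_pct_rep1: float
    overlap_pct_rep2: float
    spearman_rho: float
    n_shared: int


def replicate_concordance(sites_rep1: pd.DataFrame, sites_rep2: pd.DataFrame,
                          min_cov: int = DEFAULT_MIN_COV) -> ConcordanceResult:
    """Overlap of passed sites and Spearman rho of per-site frequencies.

    Overlap is reported relative to each replicate's passed set; rho is
    computed on sites with coverage >= min_cov in both replicates.
    """
    key = ["chrom", "pos", "strand"]
    p1 = set(map(tuple, sites_rep1.loc[sites_rep1["passed"], key].to_numpy()))
    p2 = set(map(tuple, sites_rep2.loc[sites_rep2["passed"], key].to_numpy()))
    both = len(p1 & p2)
    t1 = sites_rep1[sites_rep1["coverage"] >= min_cov]
    t2 = sites_rep2[sites_rep2["coverage"] >= min_cov]
    merged = t1.merge(t2, on=key, suffixes=("_1", "_2"))
    if merged.empty:
        raise PermodError("no shared testable sites between replicates")
    if merged["frequency_1"].nunique() == 1 and merged["frequency_2"].nunique() == 1:
        rho = 1.0 if merged["frequency_1"].equals(merged["frequency_2"]) else 0.0
    else:
        rho = float(stats.spearmanr(merged["frequency_1"], merged["frequency_2"]).statistic)
    return ConcordanceResult(
        overlap_pct_rep1=100.0 * both / len(p1) if p1 else 0.0,
        overlap_pct_rep2=100.0 * both / len(p2) if p2 else 0.0,
        spearman_rho=rho,
        n_shared=len(merged),
    )
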