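"""Single-molecule analyses on per-read modification calls.

Covers four questions that only per-read (not per-site) data can answer:

* do pairs of modified sites co-occur on the same molecules more often than
  independence predicts (NSD statistic)?
* do modified molecules carry longer polyA tails?
* are modified sites further from exon boundaries than random motif
  positions in the same genes?
* does modification stoichiometry at a shared genomic site differ between
  transcript isoforms?

Co-occurrence of a site pair (A, B) is quantified on the C reads spanning
both sites: with per-site modified fractions fA and fB the expected number
of doubly modified reads under independence is Exp = fA*fB*C, and

    NSD = (Obs - Exp) / sqrt(Exp * (1 - fA*fB))

is the number of binomial standard deviations by which the observed count
deviates.  Pairs are eligible when C >= 200 and Exp >= 2.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .calling import DEFAULT_MIN_COV, DEFAULT_MIN_FREQ, DEFAULT_TAU, binarize, call_sites
from .errors import PermodError
from .feature_io import UNIQUE_ASSIGNMENT_CLASSES, Transcript

#: pair-eligibility gates: reads spanning both sites, and expected
#: co-modified reads under independence
MIN_PAIR_COVERAGE = 200
MIN_EXPECTED = 2.0

DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")  # T stands for U


def nsd_for_pair(obs: float, fa: float, fb: float, coverage: float) -> float:
    """NSD of one site pair from its observed co-modification count.

    Parameters are the observed count of doubly modified reads, the
    per-site modified fractions on the spanning reads, and the number of
    spanning reads.  Positive NSD means more co-modification than the
    independence expectation.
    """
    joint = fa * fb
    if joint >= 1.0:
        raise PermodError("fA*fB = 1: NSD undefined")
    exp = joint * coverage
    if exp <= 0:
        raise PermodError("expected co-modification is zero: NSD undefined")
    return float((obs - exp) / math.sqrt(exp * (1.0 - joint)))


@dataclass
class NSDSummary:
    """Distribution-level summary of per-pair NSD values."""

    n_pairs: int
    nsd: np.ndarray
    distance: np.ndarray
    null_sample: np.ndarray
    mannwhitney_p: float | None
    spearman_rho: float | None
    spearman_p: float | None


def scan_cooccurrence(calls: pd.DataFrame, isoform_assignments: pd.DataFrame,
                      tau: float = DEFAULT_TAU,
                      min_cov: int = DEFAULT_MIN_COV,
                      min_freq: float = DEFAULT_MIN_FREQ,
                      min_pair_coverage: int = MIN_PAIR_COVERAGE,
                      min_expected: float = MIN_EXPECTED,
                      seed: int = 0) -> tuple[pd.DataFrame, NSDSummary]:
    """Enumerate eligible site pairs per transcript and their NSD values.

    Only reads unambiguously assigned to one isoform (classes 'unique',
    'fsm', 'mono_exon_match') enter.  Modified sites are first called per
    transcript (coverage >= min_cov, frequency >= min_freq); then for every
    pair of called sites the spanning-read subset defines C, fA, fB, Obs
    and Exp.  Ineligible pairs are kept in the pair table with a reason
    code but excluded from the NSD summary.

    The summary compares the NSD distribution against a seeded normal null
    of the same size and standard deviation centered at 0 (Mann–Whitney,
    two-sided) and reports Spearman rho of NSD vs. log10 pair distance.
    """
    keep = isoform_assignments[
        isoform_assignments["class"].isin(UNIQUE_ASSIGNMENT_CLASSES)
    ]
    tx_of = dict(zip(keep["read_id"], keep["transcript_id"]))
    df = calls[calls["read_id"].map(tx_of).notna()].copy()
    df["transcript_id"] = df["read_id"].map(tx_of)

    pair_rows = []
    for tid, tgrp in df.groupby("transcript_id", sort=True):
        sites = call_sites(tgrp, tau=tau, min_cov=min_cov, min_freq=min_freq)
        called = sites.loc[sites["passed"], "pos"].to_numpy()
        if len(called) < 2:
            continue
        mod = tgrp.assign(_mod=binarize(tgrp["mod_prob"].to_numpy(), tau))
        by_pos = {p: g.set_index("read_id")["_mod"]
                  for p, g in mod.groupby("pos") if p in called}
        for i in range(len(called)):
            for j in range(i + 1, len(called)):
                pa, pb = int(called[i]), int(called[j])
                a, b = by_pos[pa], by_pos[pb]
                shared = a.index.intersection(b.index)
                c = len(shared)
                if c == 0:
                    continue
                na, nb = int(a[shared].sum()), int(b[shared].sum())
                fa_, fb_ = na / c, nb / c
                obs = int((a[shared] & b[shared]).sum())
                exp = fa_ * fb_ * c
                if c < min_pair_coverage:
                    reason = "low_pair_coverage"
                elif exp < min_expected:
                    reason = "low_expected"
                elif fa_ * fb_ >= 1.0:
                    reason = "saturated"
                else:
                    reason = ""
                pair_rows.append({
                    "transcript_id": tid, "pos_a": pa, "pos_b": pb,
                    "fa": fa_, "fb": fb_, "coverage": c, "obs": obs,
                    "exp": exp, "distance": pb - pa,
                    "nsd": nsd_for_pair(obs, fa_, fb_, c) if reason == "" else np.nan,
                    "excluded": reason,
                })
    pairs = pd.DataFrame(pair_rows, columns=[
        "transcript_id", "pos_a", "pos_b", "fa", "fb", "coverage",
        "obs", "exp", "distance", "nsd", "excluded"])

    eligible = pairs[pairs["excluded"] == ""]
    nsd = eligible["nsd"].to_numpy(dtype=float)
    dist = eligible["distance"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if len(nsd) == 0:
        summary = NSDSummary(0, nsd, dist, np.array([]), None, None, None)
    else:
        null = rng.normal(0.0, np.std(nsd) if len(nsd) > 1 else 1.0, len(nsd))
        null = null - null.mean()  # exactly mean-0 by construction
        mw = stats.mannwhitneyu(nsd, null, alternative="two-sided").pvalue if len(nsd) > 1 else None
        if len(nsd) > 2 and np.ptp(dist) > 0 and np.ptp(nsd) > 0:
            sp = stats.spearmanr(nsd, np.log10(dist))
            rho, sp_p = float(sp.statistic), float(sp.pvalue)
        else:
            rho = sp_p = None
        summary = NSDSummary(len(nsd), nsd, dist, null,
                             float(mw) if mw is not None else None, rho, sp_p)
    return pairs, summary


# ---------------------------------------------------------------------------
# polyA association
# ---------------------------------------------------------------------------

@dataclass
class PolyAComparison:
    """PolyA tail lengths of modified vs. unmodified molecules."""

    n_modified_reads: int
    n_unmodified_reads: int
    median_modified: float
    median_unmodified: float
    mannwhitney_p: float
    scope: str


def polya_compare(calls: pd.DataFrame, polya: pd.DataFrame,
                  tau: float = DEFAULT_TAU,
                  min_cov: int = DEFAULT_MIN_COV,
                  min_freq: float = DEFAULT_MIN_FREQ,
                  min_length: float = 10.0,
                  scope: str = "global",
                  gene_of: pd.DataFrame | None = None) -> PolyAComparison:
    """Compare polyA tail lengths of m6A-containing vs. m6A-free reads.

    A read is m6A-containing iff it has at least one base with
    modProb >= tau at a site passing the site-calling gates.  Reads with
    polyA length below ``min_length`` nt are excluded from both groups.

    scope='global' tests all reads; 'm6A_genes_only' restricts to reads of
    genes that contain at least one called site; 'per_gene_median'
    aggregates each gene to one median per group before testing (both gene
    scopes need a ``gene_of`` frame with read_id, gene_id).
    """
    sites = call_sites(calls, tau=tau, min_cov=min_cov, min_freq=min_freq)
    passed = set(map(tuple, sites.loc[sites["passed"],
                                      ["chrom", "pos", "strand"]].to_numpy()))
    chrom_col = "chrom" if "chrom" in calls.columns else "ref_id"
    at_passed = calls[[
        (c, p, s) in passed
        for c, p, s in zip(calls[chrom_col], calls["pos"], calls["strand"])
    ]]
    mod_reads = set(at_passed.loc[binarize(at_passed["mod_prob"].to_numpy(), tau),
                                  "read_id"])

    tails = polya[polya["polya_length"] >= min_length].copy()
    tails["has_m6a"] = tails["read_id"].isin(mod_reads)
    # restrict to reads actually carrying calls (sequenced in this dataset)
    tails = tails[tails["read_id"].isin(set(calls["read_id"]))]

    if scope in ("m6A_genes_only", "per_gene_median"):
        if gene_of is None:
            raise PermodError(f"scope {scope!r} requires a read->gene table")
        g = dict(zip(gene_of["read_id"], gene_of["gene_id"]))
        tails["gene_id"] = tails["read_id"].map(g)
        tails = tails.dropna(subset=["gene_id"])
        m6a_genes = set(tails.loc[tails["has_m6a"], "gene_id"])
        tails = tails[tails["gene_id"].isin(m6a_genes)]

    grp_mod = tails.loc[tails["has_m6a"], "polya_length"]
    grp_unmod = tails.loc[~tails["has_m6a"], "polya_length"]
    if scope == "per_gene_median":
        grp_mod = tails[tails["has_m6a"]].groupby("gene_id")["polya_length"].median()
        grp_unmod = tails[~tails["has_m6a"]].groupby("gene_id")["polya_length"].median()
    for name, grp in (("m6A-containing", grp_mod), ("unmodified", grp_unmod)):
        if len(grp) == 0:
            raise PermodError(f"group {name!r} is empty")
    return PolyAComparison(
        n_modified_reads=len(grp_mod),
        n_unmodified_reads=len(grp_unmod),
        median_modified=float(grp_mod.median()),
        median_unmodified=float(grp_unmod.median()),
        mannwhitney_p=float(stats.mannwhitneyu(
            grp_mod, grp_unmod, alternative="two-sided").pvalue),
        scope=scope,
    )


# ---------------------------------------------------------------------------
# exon-boundary distance
# ---------------------------------------------------------------------------

def _distance_to_exon_boundary(pos: int, transcript: Transcript) -> int | None:
    """Distance (nt) from a genomic position to its containing exon's
    closest boundary, or None when outside every exon."""
    for start, end in transcript.exons:
        if start <= pos < end:
            return min(pos - start, end - 1 - pos)
    return None


@dataclass
class ExonDistanceResult:
    """Observed vs. random-motif exon-boundary distance distributions."""

    observed: np.ndarray
    control: np.ndarray
    median_observed: float
    median_control: float
    mannwhitney_p: float
    n_excluded_outside_exons: int


def exon_boundary_distance(sites: pd.DataFrame,
                           annotation: dict[str, Transcript],
                           sequences: dict[str, str],
                           seed: int = 0,
                           control_per_site: int = 1) -> ExonDistanceResult:
    """Distance of called sites to exon boundaries vs. random DRACH motifs.

    ``sites`` needs transcript_id and pos (transcript-genomic coordinate);
    ``sequences`` maps transcript_id to its (spliced, 5'->3') sequence used
    for the DRACH scan.  The control samples DRACH-motif positions from the
    same transcripts (count-matched per transcript, without replacement,
    seeded) and runs through the same distance code path.  The motif center
    (the A of DRACH) is position +2 of each match.
    """
    rng = np.random.default_rng(seed)
    observed, excluded = [], 0
    per_tx_counts: dict[str, int] = {}
    for row in sites.itertuples(index=False):
        tx = annotation.get(row.transcript_id)
        if tx is None:
            excluded += 1
            continue
        d = _distance_to_exon_boundary(int(row.pos), tx)
        if d is None:
            excluded += 1
            continue
        observed.append(d)
        per_tx_counts[row.transcript_id] = per_tx_counts.get(row.transcript_id, 0) + 1

    control = []
    exon_offset: dict[str, int] = {}
    for tid, n_sites in sorted(per_tx_counts.items()):
        tx = annotation[tid]
        seq = sequences.get(tid)
        if seq is None:
            continue
        # map spliced-sequence index -> genomic coordinate
        genomic = np.concatenate([np.arange(s, e) for s, e in tx.exons])
        if tx.strand == "-":
            genomic = genomic[::-1]
        motif_idx = np.array([m.start(1) + 2 for m in DRACH_RE.finditer(seq)],
                             dtype=int)
        motif_idx = motif_idx[motif_idx < len(genomic)]
        if len(motif_idx) == 0:
            continue
        n_draw = min(n_sites * control_per_site, len(motif_idx))
        chosen = rng.choice(motif_idx, size=n_draw, replace=False)
        for idx in chosen:
            d = _distance_to_exon_boundary(int(genomic[idx]), tx)
            if d is not None:
                control.append(d)

    obs = np.asarray(observed, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if len(obs) == 0 or len(ctl) == 0:
        raise PermodError("no usable observed or control distances")
    return ExonDistanceResult(
        observed=obs, control=ctl,
        median_observed=float(np.median(obs)),
        median_control=float(np.median(ctl)),
        mannwhitney_p=float(stats.mannwhitneyu(
            obs, ctl, alternative="two-sided").pvalue),
        n_excluded_outside_exons=excluded,
    )


# ---------------------------------------------------------------------------
# isoform-specific stoichiometry
# ---------------------------------------------------------------------------

def isoform_diff(replicates: list[pd.DataFrame], min_cov: int = 40,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Isoform-specific modification stoichiometry at shared genomic sites.

    Each replicate frame has one row per (site_id, isoform_id) with
    coverage and n_modified.  Sites kept only when >= 2 isoforms share them
    and every isoform has coverage >= min_cov in every replicate.  Per
    replicate and site: mean absolute pairwise frequency difference across
    isoforms and a two-proportion z-test on the most divergent isoform
    pair, BH-adjusted across sites.  A site is flagged ``replicated`` when
    it is significant with the same direction (same most-divergent ordered
    pair sign) in all replicates.  The Spearman correlation of per-isoform
    frequencies between the first two replicates is attached as
    ``df.attrs['spearman_between_replicates']``.
    """
    if not replicates:
        raise PermodError("need at least one replicate")
    # harmonize and gate
    gated = []
    for rep in replicates:
        rep = rep.copy()
        rep["frequency"] = rep["n_modified"] / rep["coverage"]
        gated.append(rep)
    keys = [set(map(tuple, r.loc[r["coverage"] >= min_cov,
                                 ["site_id", "isoform_id"]].to_numpy()))
            for r in gated]
    shared = set.intersection(*keys)
    site_iso: dict[str, list[str]] = {}
    for site, iso in shared:
        site_iso.setdefault(site, []).append(iso)
    usable_sites = {s for s, isos in site_iso.items() if len(isos) >= 2}

    rows = []
    for r_i, rep in enumerate(gated):
        rep = rep.set_index(["site_id", "isoform_id"])
        sub_rows = []
        for site in sorted(usable_sites):
            isos = sorted(site_iso[site])
            freqs = {i: rep.loc[(site, i)] for i in isos}
            diffs = []
            best = None
            for a_i in range(len(isos)):
                for b_i in range(a_i + 1, len(isos)):
                    ia, ib = isos[a_i], isos[b_i]
                    d = freqs[ia]["frequency"] - freqs[ib]["frequency"]
                    diffs.append(abs(d))
                    if best is None or abs(d) > abs(best[2]):
                        best = (ia, ib, d)
            ia, ib, d = best
            count = np.array([freqs[ia]["n_modified"], freqs[ib]["n_modified"]])
            nobs = np.array([freqs[ia]["coverage"], freqs[ib]["coverage"]])
            _z, p = proportions_ztest(count, nobs)
            sub_rows.append({
                "site_id": site, "replicate": r_i,
                "n_isoforms": len(isos),
                "mean_abs_diff": float(np.mean(diffs)),
                "top_pair": f"{ia}|{ib}", "top_diff": float(d),
                "pvalue": float(p),
            })
        if sub_rows:
            sub = pd.DataFrame(sub_rows)
            sub["p_adj"] = multipletests(sub["pvalue"], method="fdr_bh")[1]
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["site_id", "replicate", "n_isoforms",
                                     "mean_abs_diff", "top_pair", "top_diff",
                                     "pvalue", "p_adj", "replicated"])
    out = pd.concat(rows, ignore_index=True)

    def _replicated(site_grp: pd.DataFrame) -> bool:
        sig = (site_grp["p_adj"] < alpha).all()
        same_pair = site_grp["top_pair"].nunique() == 1
        same_dir = (np.sign(site_grp["top_diff"]).nunique() == 1)
        return bool(sig and same_pair and same_dir
                    and len(site_grp) == len(replicates))

    flags = out.groupby("site_id").apply(_replicated, include_groups=False)
    out["replicated"] = out["site_id"].map(flags)

    if len(gated) >= 2 and usable_sites:
        a = gated[0].set_index(["site_id", "isoform_id"])["frequency"]
        b = gated[1].set_index(["site_id", "isoform_id"])["frequency"]
        idx = sorted(shared)
        idx = [k for k in idx if k[0] in usable_sites]
        va, vb = a.loc[idx].to_numpy(), b.loc[idx].to_numpy()
        if len(va) > 2 and np.ptp(va) > 0 and np.ptp(vb) > 0:
            out.attrs["spearman_between_replicates"] = float(
                stats.spearmanr(va, vb).statistic)
    return out
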