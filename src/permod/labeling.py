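"""Semi-supervised per-read modification labeling from paired samples.

The engine turns paired (treated vs. control) per-base feature tables into
high-confidence per-read modification labels:

1. features are aggregated per 7-mer across all reference positions whose
   centered 7-mer matches, balancing read counts between the two samples at
   every position;
2. candidate 7-mers are selected by a two-sample Kolmogorov–Smirnov test on
   the most informative features, with Benjamini–Hochberg correction across
   7-mers;
3. for each selected 7-mer, reads are labeled in three stages: a Gradient
   Boosting classifier trained on sample-of-origin labels (control =
   unmodified, treated = modified); low-confidence training reads are
   marked unknown and re-labeled by KNN-kernel label propagation over
   standardized features; a final Gradient Boosting classifier trained on
   the relabeled training half predicts every test read.

The semi-supervision matters because the treated sample is only
substoichiometrically modified: its sample-of-origin label is wrong for the
unmodified fraction of treated reads, and stages 2-3 correct exactly those.

A supervised per-7-mer evaluation for fully modified/unmodified training
pairs (Random Forest, 50:50 split, ROC AUC) is also provided.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.semi_supervised import LabelPropagation
from statsmodels.stats.multitest import multipletests

from .errors import PermodError
from .feature_io import FEATURES_RNA002

DEFAULT_ALPHA = 0.01
DEFAULT_D_MIN = 0.1
DEFAULT_N_MIN = 30
#: stage-1 probability band whose reads are marked 'unknown' before
#: label propagation
DEFAULT_CONF_BAND = (0.3, 0.7)
#: features used when data-driven ranking is infeasible: trace of the
#: reference base and signal intensity
FALLBACK_FEATURES = ("TR", "SI")


def derive_seed(seed: int, kmer: str) -> int:
    """Deterministic per-k-mer seed below 2^31 from a pipeline-level seed."""
    return (seed * 1_000_003 + zlib.crc32(kmer.encode())) % (2**31 - 1)


@dataclass
class KmerAggregate:
    """Balanced control/treated feature matrices of one 7-mer.

    ``data`` carries one row per retained read with its features, sample of
    origin and provenance (ref_id, pos, read_id).  After balancing, control
    and treated counts are equal at every contributing position.
    """

    kmer: str
    data: pd.DataFrame
    n_dropped_positions: int = 0

    @property
    def n_per_sample(self) -> pd.Series:
        return self.data["sample"].value_counts()


def aggregate_by_kmer(records: pd.DataFrame, max_reads_per_position: int = 1000,
                      seed: int = 0) -> dict[str, KmerAggregate]:
    """Aggregate per-base features by centered 7-mer, balancing samples.

    At every reference position each sample is downsampled (seeded, without
    replacement) to ``min(n_control, n_treated, max_reads_per_position)``;
    positions where either sample is absent are dropped and counted.
    """
    samples = set(records["sample"].unique())
    for required in ("control", "treated"):
        if required not in samples:
            raise PermodError(f"missing sample in input: {required!r}")
    aggregates: dict[str, KmerAggregate] = {}
    for kmer, kgrp in records.groupby("kmer", sort=True):
        rng = np.random.default_rng(derive_seed(seed, kmer))
        kept, dropped = [], 0
        for (_ref, _pos), pgrp in kgrp.groupby(["ref_id", "pos"], sort=True):
            counts = pgrp["sample"].value_counts()
            n = min(counts.get("control", 0), counts.get("treated", 0),
                    max_reads_per_position)
            if n < 1:
                dropped += 1
                continue
            for sample in ("control", "treated"):
                sub = pgrp[pgrp["sample"] == sample]
                idx = rng.choice(len(sub), size=n, replace=False)
                kept.append(sub.iloc[np.sort(idx)])
        if kept:
            aggregates[kmer] = KmerAggregate(
                kmer=kmer,
                data=pd.concat(kept, ignore_index=True),
                n_dropped_positions=dropped,
            )
    return aggregates


def _ks_per_feature(agg: KmerAggregate, features) -> dict[str, tuple[float, float]]:
    ctrl = agg.data[agg.data["sample"] == "control"]
    trt = agg.data[agg.data["sample"] == "treated"]
    out = {}
    for feat in features:
        res = stats.ks_2samp(ctrl[feat], trt[feat], method="asymp")
        out[feat] = (float(res.statistic), float(res.pvalue))
    return out


def rank_informative_features(aggregates: dict[str, KmerAggregate],
                              features=tuple(FEATURES_RNA002),
                              n_min: int = DEFAULT_N_MIN) -> list[str]:
    """Order features by mean per-k-mer KS statistic (descending).

    Ties break deterministically by the fixed feature-name order of the
    schema.  Raises if no aggregate reaches ``n_min`` reads per sample.
    """
    usable = [a for a in aggregates.values()
              if a.n_per_sample.min() >= n_min]
    if not usable:
        raise PermodError(f"no aggregate with >= {n_min} reads per sample")
    order = {f: i for i, f in enumerate(features)}
    mean_d = {f: float(np.mean([_ks_per_feature(a, [f])[f][0] for a in usable]))
              for f in features}
    return sorted(features, key=lambda f: (-mean_d[f], order[f]))


def ks_select_kmers(aggregates: dict[str, KmerAggregate],
                    features=None,
                    alpha: float = DEFAULT_ALPHA,
                    d_min: float = DEFAULT_D_MIN,
                    n_min: int = DEFAULT_N_MIN) -> pd.DataFrame:
    """Two-sample KS scan over 7-mers on the most informative features.

    ``features`` defaults to the top-2 of :func:`rank_informative_features`
    (falling back to trace + signal intensity when ranking is infeasible).
    P-values are Benjamini–Hochberg-adjusted across k-mers per feature; a
    7-mer is selected iff any tested feature has adjusted p < alpha and
    KS statistic D >= d_min.  Aggregates below ``n_min`` reads per sample
    are skipped (reason column 'insufficient_reads').
    """
    if features is None:
        try:
            features = rank_informative_features(aggregates, n_min=n_min)[:2]
        except PermodError:
            features = list(FALLBACK_FEATURES)
    rows = []
    for kmer, agg in sorted(aggregates.items()):
        if agg.n_per_sample.min() < n_min:
            for feat in features:
                rows.append({"kmer": kmer, "feature": feat, "D": np.nan,
                             "pvalue": np.nan, "skipped": "insufficient_reads"})
            continue
        for feat, (d, p) in _ks_per_feature(agg, features).items():
            rows.append({"kmer": kmer, "feature": feat, "D": d,
                         "pvalue": p, "skipped": ""})
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(p_adj=[], selected=[])
    result["p_adj"] = np.nan
    for feat in features:
        mask = (result["feature"] == feat) & (result["skipped"] == "")
        if mask.any():
            result.loc[mask, "p_adj"] = multipletests(
                result.loc[mask, "pvalue"], method="fdr_bh")[1]
    result["pass_feature"] = (result["p_adj"] < alpha) & (result["D"] >= d_min)
    selected_kmers = result.groupby("kmer")["pass_feature"].any()
    result["selected"] = result["kmer"].map(selected_kmers)
    min_padj = result.groupby("kmer")["p_adj"].min()
    result["_rank"] = result["kmer"].map(min_padj)
    result = (result.sort_values(["_rank", "kmer", "feature"], kind="mergesort")
              .drop(columns=["_rank", "pass_feature"])
              .reset_index(drop=True))
    return result


@dataclass
class LabelingReport:
    """Diagnostics of one 7-mer's 3-stage labeling run."""

    kmer: str
    n_train: int
    n_test: int
    n_unknown_stage2: int
    propagation_fallback: bool = False
    no_signal: bool = False


def label_kmer_reads(aggregate: KmerAggregate, split: float = 0.5,
                     seed: int = 0, features=tuple(FEATURES_RNA002),
                     conf_band: tuple[float, float] = DEFAULT_CONF_BAND,
                     n_neighbors: int = 10,
                     ) -> tuple[pd.DataFrame, LabelingReport]:
    """Three-stage semi-supervised labeling of one 7-mer's reads.

    Returns one row per read with its partition (train/test), the stage that
    produced its final label, the label itself and a confidence in [0, 1].

    Stage-1 probabilities on the training half are out-of-fold (5-fold CV)
    predictions: resubstitution probabilities of a boosted ensemble are
    driven to 0/1 and would never fall inside the confidence band.  Because
    only the treated sample contains modified reads, the stage-1
    probability of an unmodified read plateaus at s/(1+s) (s = treated
    stoichiometry) rather than 0, so the scores are min-max calibrated
    within the k-mer (2nd/98th percentile) before the band is applied.

    Stage-2 'unknown' marks and propagation happen on the training half
    only; the test half always receives a definite stage-3 label.  When one
    class has essentially no confident seed reads, propagation cannot be
    anchored and the whole k-mer collapses to the seeded class (or to
    'unmodified' when both are missing — no evidence of modification); the
    report flags this fallback.
    """
    rng_seed = derive_seed(seed, aggregate.kmer)
    df = aggregate.data.reset_index(drop=True)
    x = df[list(features)].to_numpy(dtype=float)
    origin = (df["sample"] == "treated").to_numpy().astype(int)  # treated=1

    idx_train, idx_test = train_test_split(
        np.arange(len(df)), train_size=split, random_state=rng_seed,
        stratify=origin)
    lo, hi = conf_band

    # stage 1: supervised on sample-of-origin labels, out-of-fold scores
    gb1 = GradientBoostingClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1,
        random_state=rng_seed)
    p1 = cross_val_predict(gb1, x[idx_train], origin[idx_train],
                           cv=5, method="predict_proba")[:, 1]
    # no detectable control/treated separation means the k-mer carries no
    # evidence of modification: every read is unmodified
    sep_p = stats.mannwhitneyu(p1[origin[idx_train] == 1],
                               p1[origin[idx_train] == 0],
                               alternative="greater").pvalue
    if sep_p >= 0.01:
        n = len(idx_train) + len(idx_test)
        out = pd.DataFrame({
            "read_id": df["read_id"].iloc[np.concatenate([idx_train, idx_test])],
            "ref_id": df["ref_id"].iloc[np.concatenate([idx_train, idx_test])],
            "pos": df["pos"].iloc[np.concatenate([idx_train, idx_test])],
            "kmer": aggregate.kmer,
            "partition": ["train"] * len(idx_train) + ["test"] * len(idx_test),
            "stage": [1] * len(idx_train) + [3] * len(idx_test),
            "label": "unmodified",
            "confidence": 1.0 - float(min(sep_p, 0.5)),
        }).reset_index(drop=True)
        report = LabelingReport(
            kmer=aggregate.kmer, n_train=len(idx_train), n_test=len(idx_test),
            n_unknown_stage2=0, propagation_fallback=False, no_signal=True)
        return out, report
    q_lo, q_hi = np.quantile(p1, [0.02, 0.98])
    if q_hi - q_lo >= 0.2:
        score = np.clip((p1 - q_lo) / (q_hi - q_lo), 0.0, 1.0)
    else:  # near-degenerate score range: calibration would amplify noise
        score = p1

    # stage 2: mark mid-confidence training reads unknown, propagate
    labels = np.where(score >= 0.5, 1, 0)
    unknown = (score > lo) & (score < hi)
    fallback = False
    min_seeds = max(3, int(0.05 * len(idx_train)))
    n_seed_mod = int((labels[~unknown] == 1).sum())
    n_seed_unmod = int((labels[~unknown] == 0).sum())
    if n_seed_mod < min_seeds or n_seed_unmod < min_seeds:
        # propagation has no anchor on one side: collapse to the seeded
        # class, defaulting to 'unmodified' when neither side has evidence
        labels[:] = 1 if (n_seed_mod >= min_seeds) else 0
        unknown[:] = False
        fallback = True
    elif unknown.any():
        scaler = StandardScaler().fit(x[idx_train])
        z = scaler.transform(x[idx_train])
        y_semi = labels.copy()
        y_semi[unknown] = -1
        try:
            lp = LabelPropagation(
                kernel="knn",
                n_neighbors=min(n_neighbors, int((~unknown).sum())),
                max_iter=1000)
            lp.fit(z, y_semi)
            labels[unknown] = lp.transduction_[unknown]
        except Exception:
            unknown[:] = False  # keep stage-1 hard labels
            fallback = True

    # stage 3: final classifier on relabeled training half, predict test half
    gb3 = GradientBoostingClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.1,
        random_state=rng_seed)
    if len(np.unique(labels)) < 2:
        # degenerate training labels: every test read gets the single class
        p_test = np.full(len(idx_test), float(labels[0]))
    else:
        gb3.fit(x[idx_train], labels)
        p_test = gb3.predict_proba(x[idx_test])[:, 1]

    name = {1: "modified", 0: "unmodified"}
    out_rows = []
    stage_train = np.where(unknown & ~fallback, 2, 1)
    for j, i in enumerate(idx_train):
        out_rows.append({
            "read_id": df.at[i, "read_id"], "ref_id": df.at[i, "ref_id"],
            "pos": df.at[i, "pos"], "kmer": aggregate.kmer,
            "partition": "train", "stage": int(stage_train[j]),
            "label": name[int(labels[j])],
            "confidence": float(score[j] if labels[j] == 1 else 1 - score[j]),
        })
    for j, i in enumerate(idx_test):
        pred = int(p_test[j] >= 0.5)
        out_rows.append({
            "read_id": df.at[i, "read_id"], "ref_id": df.at[i, "ref_id"],
            "pos": df.at[i, "pos"], "kmer": aggregate.kmer,
            "partition": "test", "stage": 3,
            "label": name[pred],
            "confidence": float(p_test[j] if pred else 1 - p_test[j]),
        })
    report = LabelingReport(
        kmer=aggregate.kmer, n_train=len(idx_train), n_test=len(idx_test),
        n_unknown_stage2=int(unknown.sum()), propagation_fallback=fallback)
    return pd.DataFrame(out_rows), report


def label_dataset(records: pd.DataFrame, seed: int = 0,
                  max_reads_per_position: int = 1000,
                  alpha: float = DEFAULT_ALPHA, d_min: float = DEFAULT_D_MIN,
                  n_min: int = DEFAULT_N_MIN, split: float = 0.5,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[LabelingReport]]:
    """End-to-end pipeline: aggregate, select 7-mers, label their reads.

    Returns (per-read labels of all selected 7-mers, k-mer KS report,
    per-k-mer labeling reports).
    """
    aggregates = aggregate_by_kmer(records, max_reads_per_position, seed)
    ks_report = ks_select_kmers(aggregates, alpha=alpha, d_min=d_min, n_min=n_min)
    selected = (ks_report.loc[ks_report["selected"] == True, "kmer"].unique()
                if len(ks_report) else [])
    frames, reports = [], []
    for kmer in selected:
        labels, rep = label_kmer_reads(aggregates[kmer], split=split, seed=seed)
        frames.append(labels)
        reports.append(rep)
    labels = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["read_id", "ref_id", "pos", "kmer",
                                         "partition", "stage", "label",
                                         "confidence"]))
    return labels, ks_report, reports


# ---------------------------------------------------------------------------
# supervised per-7-mer AUC (fully modified vs. unmodified training pairs)
# ---------------------------------------------------------------------------

def auc_from_scores(y_true, scores) -> float:
    """ROC AUC of scores against binary labels (probability that a random
    positive outscores a random negative, ties counted half)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))


def _single_central_base(kmer: str, base: str = "A") -> bool:
    """True for 7-mers whose only candidate base is the central one."""
    return kmer[3] == base and kmer.count(base) == 1


def kmer_classifier_auc(records: pd.DataFrame, feature_cols,
                        split: float = 0.5, min_coverage: int = 100,
                        seed: int = 0, central_base: str = "A",
                        ) -> pd.DataFrame:
    """Per-7-mer Random Forest ROC AUC on fully labeled samples.

    ``records`` holds per-base features of a fully modified and a fully
    unmodified sample ('treated'/'control' in the sample column, here used
    as class labels).  Only 7-mers with the candidate base exclusively at
    the center are evaluated; per position, samples are balanced to the
    lower coverage and positions below ``min_coverage`` reads per sample
    are skipped.  Data is split 50:50 and AUC measured on the test half.
    """
    rows = []
    skipped_cov = skipped_kmer = 0
    for kmer, kgrp in records.groupby("kmer", sort=True):
        if not _single_central_base(kmer, central_base):
            skipped_kmer += 1
            continue
        rng = np.random.default_rng(derive_seed(seed, kmer))
        kept = []
        for (_r, _p), pgrp in kgrp.groupby(["ref_id", "pos"], sort=True):
            counts = pgrp["sample"].value_counts()
            n = min(counts.get("control", 0), counts.get("treated", 0))
            if n < min_coverage:
                skipped_cov += 1
                continue
            for sample in ("control", "treated"):
                sub = pgrp[pgrp["sample"] == sample]
                idx = rng.choice(len(sub), size=n, replace=False)
                kept.append(sub.iloc[np.sort(idx)])
        if not kept:
            continue
        data = pd.concat(kept, ignore_index=True)
        x = data[list(feature_cols)].to_numpy(dtype=float)
        y = (data["sample"] == "treated").to_numpy().astype(int)
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), train_size=split,
            random_state=derive_seed(seed, kmer), stratify=y)
        rf = RandomForestClassifier(n_estimators=100,
                                    random_state=derive_seed(seed, kmer))
        rf.fit(x[idx_train], y[idx_train])
        scores = rf.predict_proba(x[idx_test])[:, 1]
        rows.append({"kmer": kmer, "auc": auc_from_scores(y[idx_test], scores),
                     "n_test": len(idx_test)})
    out = pd.DataFrame(rows, columns=["kmer", "auc", "n_test"])
    out.attrs["skipped_low_coverage"] = skipped_cov
    out.attrs["skipped_multi_candidate_kmers"] = skipped_kmer
    return out
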