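"""K-mer aggregation/balancing, KS selection, 3-stage labeling, AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import permod
from permod.errors import PermodError
from permod.labeling import FEATURES_RNA002, KmerAggregate


def _records(kmer="CCTAGCA", pos=10, ref="r", n_control=50, n_treated=50,
             tr_control=0.9, tr_treated=0.9, si_control=80.0, si_treated=80.0,
             seed=0):
    """Feature rows for one position with controllable TR/SI separation."""
    rng = np.random.default_rng(seed)
    frames = []
    for sample, n, tr, si in (("control", n_control, tr_control, si_control),
                              ("treated", n_treated, tr_treated, si_treated)):
        frames.append(pd.DataFrame({
            "read_id": [f"{sample}_{pos}_{i}" for i in range(n)],
            "ref_id": ref, "pos": pos, "strand": "+", "ref_base": "A",
            "kmer": kmer, "sample": sample,
            "SI": rng.normal(si, 2, n), "MP": rng.uniform(0, 0.2, n),
            "DT": rng.lognormal(2, 0.2, n), "DT10": rng.lognormal(2, 0.2, n),
            "TR": np.clip(rng.normal(tr, 0.03, n), 0, 1),
            "TA": 0.1, "TC": 0.1, "TG": 0.1, "TT": 0.1,
        }))
    return pd.concat(frames, ignore_index=True)


class TestAggregation:
    def test_min_then_cap_balancing(self):
        recs = _records(n_control=60, n_treated=100)
        aggs = permod.aggregate_by_kmer(recs, max_reads_per_position=50)
        counts = aggs["CCTAGCA"].n_per_sample
        assert counts["control"] == counts["treated"] == 50

    def test_position_without_control_dropped(self):
        recs = _records(n_control=60, n_treated=60)
        treated_only = _records(pos=99, n_control=0, n_treated=40)
        aggs = permod.aggregate_by_kmer(pd.concat([recs, treated_only]))
        agg = aggs["CCTAGCA"]
        assert agg.n_dropped_positions == 1
        assert set(agg.data["pos"]) == {10}

    def test_positions_sharing_kmer_merge_with_provenance(self):
        recs = pd.concat([_records(pos=10), _records(pos=200, seed=1)])
        aggs = permod.aggregate_by_kmer(recs)
        assert set(aggs["CCTAGCA"].data["pos"]) == {10, 200}

    def test_per_position_balance_invariant(self):
        rng = np.random.default_rng(3)
        recs = pd.concat([
            _records(pos=p, n_control=int(rng.integers(30, 90)),
                     n_treated=int(rng.integers(30, 90)), seed=p)
            for p in (10, 50, 90)
        ])
        aggs = permod.aggregate_by_kmer(recs)
        per_pos = aggs["CCTAGCA"].data.groupby(["pos", "sample"]).size().unstack()
        assert (per_pos["control"] == per_pos["treated"]).all()

    def test_single_sample_input_is_error(self):
        recs = _records(n_control=0)
        recs = recs[recs["sample"] == "treated"]
        with pytest.raises(PermodError, match="control"):
            permod.aggregate_by_kmer(recs)


class TestFeatureRanking:
    def test_effect_only_on_tr_ranks_tr_first(self):
        recs = _records(tr_control=0.9, tr_treated=0.3, n_control=100,
                        n_treated=100)
        aggs = permod.aggregate_by_kmer(recs)
        assert permod.rank_informative_features(aggs)[0] == "TR"

    def test_effect_on_tr_and_si_gives_top2(self):
        recs = _records(tr_control=0.9, tr_treated=0.3, si_control=80,
                        si_treated=95, n_control=100, n_treated=100)
        aggs = permod.aggregate_by_kmer(recs)
        assert set(permod.rank_informative_features(aggs)[:2]) == {"TR", "SI"}

    def test_null_ranking_is_deterministic(self):
        recs = _records(n_control=100, n_treated=100)
        aggs = permod.aggregate_by_kmer(recs)
        assert (permod.rank_informative_features(aggs)
                == permod.rank_informative_features(aggs))


class TestKsSelection:
    def test_identical_samples_not_selected(self):
        base = _records(n_control=40, n_treated=40)
        # same rows in both samples: D = 0 exactly
        ctrl = base[base["sample"] == "control"]
        dup = ctrl.copy()
        dup["sample"] = "treated"
        dup["read_id"] = dup["read_id"] + "_t"
        aggs = permod.aggregate_by_kmer(pd.concat([ctrl, dup]))
        res = permod.ks_select_kmers(aggs, features=["TR", "SI"])
        assert (res["D"] == 0).all()
        assert not res["selected"].any()

    def test_complete_separation_selected(self):
        recs = _records(tr_control=0.95, tr_treated=0.05, n_control=60,
                        n_treated=60)
        aggs = permod.aggregate_by_kmer(recs)
        res = permod.ks_select_kmers(aggs, features=["TR"])
        assert res.loc[0, "D"] == 1.0
        assert res["selected"].all()

    def test_below_nmin_skipped_with_reason(self):
        recs = _records(n_control=10, n_treated=10)
        aggs = permod.aggregate_by_kmer(recs)
        res = permod.ks_select_kmers(aggs, features=["TR"])
        assert (res["skipped"] == "insufficient_reads").all()


class TestLabeling:
    def _run(self, stoichiometry, seed=17, n_reads=300):
        cfg = permod.GeneratorConfig(
            seed=seed, n_reads_per_sample=n_reads, n_affected_kmers=1,
            n_unaffected_kmers=0, stoichiometry=stoichiometry, residual=0.0)
        feats, truth = permod.simulate_feature_dataset(cfg)
        aggs = permod.aggregate_by_kmer(feats, seed=seed)
        agg = next(iter(aggs.values()))
        labels, report = permod.label_kmer_reads(agg, seed=seed)
        merged = labels.merge(truth.read_labels, on=["read_id", "ref_id", "pos"])
        return merged, report

    def test_saturated_recovery(self):
        merged, _ = self._run(1.0)
        test_treated = merged[(merged["partition"] == "test")
                              & (merged["sample"] == "treated")]
        assert (test_treated["label"] == "modified").mean() >= 0.95

    def test_null_aggregate_labels_nothing_modified(self):
        merged, report = self._run(0.0)
        test_treated = merged[(merged["partition"] == "test")
                              & (merged["sample"] == "treated")]
        assert (test_treated["label"] == "modified").mean() <= 0.05

    def test_half_stoichiometry_recovers_read_labels(self):
        merged, _ = self._run(0.5, n_reads=500)
        test = merged[merged["partition"] == "test"]
        acc = ((test["label"] == "modified") == test["modified"]).mean()
        assert acc >= 0.90

    def test_partitions_disjoint_and_test_fully_labeled(self):
        merged, _ = self._run(0.5)
        train = set(merged.loc[merged["partition"] == "train", "read_id"])
        test = set(merged.loc[merged["partition"] == "test", "read_id"])
        assert not train & test
        assert set(merged.loc[merged["partition"] == "test", "label"]) <= {
            "modified", "unmodified"}

    def test_stage1_confident_labels_preserved(self):
        # reads labeled at stage 1 were outside the confidence band, so
        # their reported confidence stays >= the band's upper edge
        merged, report = self._run(0.5)
        if not report.propagation_fallback:
            stage1 = merged[(merged["partition"] == "train")
                            & (merged["stage"] == 1)]
            assert (stage1["confidence"] >= 0.7 - 1e-9).all()

    def test_accuracy_monotone_in_signal_shift(self):
        # dwell/trace effects off: separation driven by the SI shift alone
        accs = []
        for shift in (0.5, 1.0, 2.0, 4.0):
            eff = permod.EffectSpec(
                si_shift_sd=shift, trace_mod=(10.0, 1.5),
                trace_unmod=(10.0, 1.5), mp_mod=(1.0, 15.0),
                mp_unmod=(1.0, 15.0), dwell_factor=1.0)
            cfg = permod.GeneratorConfig(
                seed=23, n_reads_per_sample=400, n_affected_kmers=1,
                n_unaffected_kmers=0, stoichiometry=0.5, residual=0.0,
                effect=eff)
            feats, truth = permod.simulate_feature_dataset(cfg)
            aggs = permod.aggregate_by_kmer(feats, seed=23)
            labels, _ = permod.label_kmer_reads(
                next(iter(aggs.values())), seed=23)
            merged = labels.merge(truth.read_labels,
                                  on=["read_id", "ref_id", "pos"])
            test = merged[merged["partition"] == "test"]
            accs.append(((test["label"] == "modified") == test["modified"]).mean())
        assert all(b >= a for a, b in zip(accs, accs[1:]))


class TestClassifierAuc:
    def _fully_labeled(self, sep, n=120, kmer="CCTAGCC"):
        # 'treated' = fully modified sample, 'control' = fully unmodified
        return _records(kmer=kmer, n_control=n, n_treated=n,
                        tr_control=0.9, tr_treated=0.9 - sep)

    def test_perfect_separation_gives_auc_one(self):
        recs = self._fully_labeled(sep=0.8)
        res = permod.kmer_classifier_auc(recs, FEATURES_RNA002,
                                         min_coverage=100)
        assert res.loc[0, "auc"] == 1.0

    def test_null_auc_near_half(self):
        recs = self._fully_labeled(sep=0.0, n=500)
        res = permod.kmer_classifier_auc(recs, FEATURES_RNA002,
                                         min_coverage=100)
        assert res.loc[0, "auc"] == pytest.approx(0.5, abs=0.05)

    def test_low_coverage_positions_skipped(self):
        recs = self._fully_labeled(sep=0.5, n=50)
        res = permod.kmer_classifier_auc(recs, FEATURES_RNA002,
                                         min_coverage=100)
        assert len(res) == 0
        assert res.attrs["skipped_low_coverage"] == 1

    def test_multi_candidate_kmers_excluded(self):
        recs = self._fully_labeled(sep=0.5, kmer="ACTAGCC")  # two A's
        res = permod.kmer_classifier_auc(recs, FEATURES_RNA002,
                                         min_coverage=100)
        assert len(res) == 0
        assert res.attrs["skipped_multi_candidate_kmers"] == 1

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n1, n0 = rng.integers(5, 60, size=2)
            scores = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)])
            y = np.concatenate([np.ones(n1), np.zeros(n0)])
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            assert abs(permod.auc_from_scores(y, scores) - u / (n1 * n0)) <= 1e-9
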