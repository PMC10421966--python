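"""Metric implementations against brute-force oracles."""

import numpy as np
import pytest

from mhc2tx import (
    AlleleRecord,
    Dataset,
    PeptideRecord,
    per_allele_report,
    pr_curve,
    roc_auc,
    threshold_metrics,
)


def brute_force_auc(scores, labels):
    """Concordant-pair counting with half credit for ties."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_inversion(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        assert roc_auc(scores, [0, 0, 1, 1]) == 1.0
        assert roc_auc(scores, [1, 1, 0, 0]) == 0.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert np.isclose(roc_auc(scores, labels), brute_force_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        base = roc_auc(scores, labels)
        assert np.isclose(roc_auc(np.exp(3 * scores) + 7, labels), base)
        assert np.isclose(roc_auc(np.log(scores + 1e-9), labels), base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestThresholdMetrics:
    def _from_confusion(self, tp, fp, fn, tn, rng):
        scores = np.concatenate([
            rng.uniform(0.5, 1, tp), rng.uniform(0.5, 1, fp),
            rng.uniform(0, 0.49, fn), rng.uniform(0, 0.49, tn),
        ])
        labels = np.concatenate([
            np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)
        ]).astype(int)
        return scores, labels

    def test_chance_level_confusion(self):
        rng = np.random.default_rng(2)
        scores, labels = self._from_confusion(25, 25, 25, 25, rng)
        rep = threshold_metrics(scores, labels)
        assert np.isclose(rep.mcc, 0.0)
        assert np.isclose(rep.f1, 0.5)

    def test_direct_formula_evaluation(self):
        rng = np.random.default_rng(3)
        scores, labels = self._from_confusion(90, 10, 10, 90, rng)
        rep = threshold_metrics(scores, labels)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (90, 10, 10, 90)
        assert np.isclose(rep.mcc, 0.8)
        assert np.isclose(rep.f1, 0.9)
        assert np.isclose(rep.precision, 0.9) and np.isclose(rep.recall, 0.9)

    def test_all_positive_predictions(self):
        labels = np.array([1, 0, 0, 1, 0])
        rep = threshold_metrics(np.full(5, 0.9), labels)
        assert rep.recall == 1.0
        assert np.isclose(rep.precision, labels.mean())  # prevalence
        assert rep.mcc == 0.0 and rep.mcc_degenerate

    def test_random_confusions_match_formulas(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + fn == 0 or fp + tn == 0:
                continue
            scores, labels = self._from_confusion(tp, fp, fn, tn, rng)
            rep = threshold_metrics(scores, labels)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert np.isclose(rep.f1, f1)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom:
                assert np.isclose(rep.mcc, (tp * tn - fp * fn) / np.sqrt(denom))
            else:
                assert rep.mcc == 0.0 and rep.mcc_degenerate


class TestPrCurve:
    def test_perfect_separation_precision_one(self):
        # every achieved recall is attainable at precision 1 (the sweep also
        # visits the trivial all-positive threshold, where precision is the
        # prevalence, so compare the best precision per recall level)
        pts = pr_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        best = {}
        for r, p in pts:
            best[r] = max(best.get(r, 0.0), p)
        assert all(p == 1.0 for r, p in best.items() if r > 0)

    def test_matches_exhaustive_threshold_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        pts = set(pr_curve(scores, labels))
        expected = set()
        for thr in np.unique(scores):
            pred = scores >= thr
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            fn = int(np.sum(~pred & (labels == 1)))
            expected.add((tp / (tp + fn), tp / (tp + fp)))
        assert expected <= pts
        recalls = [r for r, _ in sorted(pts)]
        assert recalls == sorted(recalls)

    def test_precision_at_full_recall_approaches_prevalence(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=5000)
        scores = rng.random(5000)  # uninformative
        pts = pr_curve(scores, labels)
        full_recall_precision = min(p for r, p in pts if r == 1.0)
        assert np.isclose(full_recall_precision, labels.mean(), atol=0.02)


class TestPerAllele:
    PSEUDO = "ACDEFGHIKLMNPQRSTVWY" + "A" * 14

    def _dataset(self):
        alleles = {n: AlleleRecord(n, self.PSEUDO) for n in ("AL0", "AL1", "AL2")}
        rng = np.random.default_rng(6)
        records, scores = [], []
        difficulty = {"AL0": 0.9, "AL1": 0.7, "AL2": 0.55}
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for name, sep in difficulty.items():
            for label in (0, 1):
                for _ in range(30):
                    records.append(
                        PeptideRecord(
                            "".join(rng.choice(aa, size=12)), "EL", float(label),
                            allele_name=name,
                        )
                    )
                    scores.append(rng.random() * (1 - sep) + sep * label)
        return Dataset(records=records, alleles=alleles), np.array(scores)

    def test_strata_match_restricted_recomputation(self):
        dataset, scores = self._dataset()
        reports = per_allele_report(dataset, scores)
        assert set(reports) == {"AL0", "AL1", "AL2"}
        for allele, rep in reports.items():
            sel = [r.allele_name == allele for r in dataset.records]
            labels = np.array([int(r.target) for r in dataset.records])[sel]
            assert np.isclose(rep.auc, brute_force_auc(scores[sel], labels))

    def test_disjoint_two_allele_stratification_identity(self):
        dataset, scores = self._dataset()
        reports = per_allele_report(dataset, scores)
        sel = np.array([r.allele_name == "AL0" for r in dataset.records])
        labels = np.array([int(r.target) for r in dataset.records])[sel]
        solo = threshold_metrics(scores[sel], labels)
        assert reports["AL0"].to_dict() == solo.to_dict()

    def test_single_class_allele_flagged_unevaluable(self):
        alleles = {"AL0": AlleleRecord("AL0", self.PSEUDO)}
        records = [
            PeptideRecord("ACDEFGHIKLMNP", "EL", 1.0, allele_name="AL0"),
            PeptideRecord("LMNPQRSTVWYAC", "EL", 1.0, allele_name="AL0"),
        ]
        ds = Dataset(records=records, alleles=alleles)
        reports = per_allele_report(ds, np.array([0.9, 0.8]))
        assert reports == {"AL0": None}
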