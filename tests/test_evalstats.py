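import math

import numpy as np
import pytest
from scipy import stats

from renalwsi.evalstats import (
    anova_tukey,
    average_precision_11pt,
    confusion_metrics,
    icc_absolute_single,
    icc_consistency_single,
    map_over_classes,
    match_detections,
    pr_curve,
    review_triage,
    roc_auc,
    spearman,
)
from renalwsi.fuse import iou
from renalwsi.slideio import Instance


def box_instance(x, y, w, h, score=None, label="artery"):
    poly = np.array([[x, y], [x + w, y], [x + w, y + h], [x, y + h]], float)
    return Instance.from_polygon(label, poly, score=score)


def random_scene(rng, n_gt=10, n_det=30, extent=120.0):
    gts = [box_instance(*rng.uniform(0, extent, 2), *rng.uniform(8, 30, 2))
           for _ in range(n_gt)]
    dets = []
    for _ in range(n_det):
        if rng.uniform() < 0.6 and gts:
            base = gts[int(rng.integers(len(gts)))]
            x, y, w, h = base.bbox
            jitter = rng.uniform(-6, 6, 4)
            dets.append(box_instance(x + jitter[0], y + jitter[1],
                                     max(w + jitter[2], 2),
                                     max(h + jitter[3], 2),
                                     score=float(rng.uniform(0.01, 1))))
        else:
            dets.append(box_instance(*rng.uniform(0, extent, 2),
                                     *rng.uniform(5, 25, 2),
                                     score=float(rng.uniform(0.01, 1))))
    return dets, gts


def match_oracle(dets, gts, threshold=0.5):
    """Explicit score-ordered greedy matching, written independently."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    taken = set()
    flags = []
    for i in order:
        ious = [(iou(dets[i].bbox, g.bbox), j) for j, g in enumerate(gts)
                if j not in taken]
        ious.sort(key=lambda t: (-t[0], t[1]))
        if ious and ious[0][0] >= threshold:
            taken.add(ious[0][1])
            flags.append(True)
        else:
            flags.append(False)
    return flags


def ap_oracle(flags, n_gt):
    """Literal 11-point interpolation from rank-wise precision/recall."""
    precisions, recalls = [], []
    tp = 0
    for rank, flag in enumerate(flags, start=1):
        tp += int(flag)
        precisions.append(tp / rank)
        recalls.append(tp / n_gt)
    total = 0.0
    for level in [i / 10 for i in range(11)]:
        attained = [p for p, r in zip(precisions, recalls)
                    if r >= level - 1e-12]
        total += max(attained) if attained else 0.0
    return total / 11.0


class TestMatching:
    def test_identical_detections_all_tp(self, rng):
        gts = [box_instance(i * 40, 0, 20, 20) for i in range(5)]
        dets = [box_instance(i * 40, 0, 20, 20, score=0.9) for i in range(5)]
        match = match_detections(dets, gts)
        assert match.n_tp == 5 and match.n_fp == 0 and match.n_fn == 0

    def test_double_detection_rule(self):
        gts = [box_instance(0, 0, 20, 20)]
        dets = [box_instance(0, 0, 20, 20, score=0.9),
                box_instance(1, 0, 20, 20, score=0.7)]
        match = match_detections(dets, gts)
        assert list(match.is_tp) == [True, False]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            dets, gts = random_scene(rng)
            match = match_detections(dets, gts)
            assert list(match.is_tp) == match_oracle(dets, gts)

    def test_mixed_classes_rejected(self):
        with pytest.raises(ValueError, match="class"):
            match_detections([box_instance(0, 0, 5, 5, score=0.5)],
                             [box_instance(0, 0, 5, 5, label="nucleus")])


class TestAveragePrecision:
    def test_perfect_detector_ap_1(self):
        gts = [box_instance(i * 40, 0, 20, 20) for i in range(8)]
        dets = [box_instance(i * 40, 0, 20, 20, score=1 - i * 0.05)
                for i in range(8)]
        assert average_precision_11pt(match_detections(dets, gts)) == 1.0

    def test_no_detections_ap_0(self):
        gts = [box_instance(0, 0, 20, 20)]
        assert average_precision_11pt(match_detections([], gts)) == 0.0

    def test_zero_gt_rejected(self):
        match = match_detections([box_instance(0, 0, 5, 5, score=0.5)], [])
        with pytest.raises(ValueError, match="zero ground truth"):
            average_precision_11pt(match)

    def test_matches_literal_oracle_on_random_scenes(self, rng):
        for _ in range(50):
            dets, gts = random_scene(rng, n_gt=int(rng.integers(1, 21)),
                                     n_det=int(rng.integers(0, 41)))
            match = match_detections(dets, gts)
            ap = average_precision_11pt(match)
            assert 0.0 <= ap <= 1.0
            assert ap == pytest.approx(
                ap_oracle(list(match.is_tp), len(gts)))

    def test_interpolated_precision_monotone(self, rng):
        dets, gts = random_scene(rng)
        curve = pr_curve(match_detections(dets, gts))
        assert (np.diff(curve.interp_precisions) <= 1e-12).all()

    def test_low_score_zero_iou_detection_never_increases_ap(self, rng):
        for _ in range(10):
            dets, gts = random_scene(rng, n_gt=6, n_det=12)
            base = average_precision_11pt(match_detections(dets, gts))
            min_score = min(d.score for d in dets) if dets else 1.0
            spurious = box_instance(5000, 5000, 10, 10,
                                    score=max(min_score / 2, 1e-6))
            worse = average_precision_11pt(
                match_detections(dets + [spurious], gts))
            assert worse <= base + 1e-12


class TestMapAndConfusion:
    def test_map_examples(self):
        assert map_over_classes({"a": 1.0}) == 1.0
        assert map_over_classes({"a": 0.8, "b": 0.6}) == pytest.approx(0.7)

    def test_map_mean_matches_manual(self, rng):
        values = rng.uniform(size=5)
        assert map_over_classes(list(values)) == pytest.approx(
            values.sum() / 5)

    def test_map_empty_rejected(self):
        with pytest.raises(ValueError):
            map_over_classes({})

    def test_confusion_examples(self):
        assert confusion_metrics(10, 10, 0, 0) == (1.0, 1.0, 1.0)
        sens, _spec, prec = confusion_metrics(8, 0, 2, 2)
        assert sens == pytest.approx(0.8)
        assert prec == pytest.approx(0.8)

    def test_confusion_undefined_reported_as_nan(self):
        sens, spec, prec = confusion_metrics(0, 5, 0, 0)
        assert math.isnan(sens)
        assert spec == 1.0
        assert math.isnan(prec)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        _pts, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _pts, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=40)
            labels = rng.uniform(size=40) < 0.5
            if labels.all() or not labels.any():
                continue
            _pts, auc = roc_auc(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(size=30)
        labels = rng.uniform(size=30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        _p1, a1 = roc_auc(scores, labels)
        _p2, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSpearman:
    def test_monotone_gives_one(self):
        x = [1, 2, 5, 9, 12]
        r, p = spearman(x, [v ** 3 for v in x])
        assert r == 1.0 and p == 0.0

    def test_reversed_gives_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _p = spearman(x, x[::-1])
        assert r == -1.0

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue

            def ranks(v):  # explicit mean-rank computation
                order = np.argsort(v, kind="stable")
                out = np.empty(len(v))
                i = 0
                sorted_v = v[order]
                while i < len(v):
                    j = i
                    while j < len(v) and sorted_v[j] == sorted_v[i]:
                        j += 1
                    out[order[i:j]] = np.mean(np.arange(i, j) + 1)
                    i = j
                return out

            rx, ry = ranks(x), ranks(y)
            expected = (np.mean((rx - rx.mean()) * (ry - ry.mean()))
                        / (rx.std() * ry.std()))
            r, _p = spearman(x, y)
            assert r == pytest.approx(expected)

    def test_agrees_with_scipy(self, rng):
        x = rng.uniform(size=20)
        y = x + rng.normal(0, 0.3, size=20)
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_vector_reported_undefined(self):
        r, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


def icc_oracle(table):
    """Two-way ANOVA sums of squares from first principles."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    msr = k * sum((row.mean() - grand) ** 2 for row in table) / (n - 1)
    msc = n * sum((table[:, j].mean() - grand) ** 2
                  for j in range(k)) / (k - 1)
    sse = sum((table[i, j] - table[i].mean() - table[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_duplicated_rater_gives_one(self):
        x = np.array([3.0, 7.0, 1.0, 9.0, 5.0])
        result = icc_absolute_single(np.column_stack([x, x]))
        assert result.icc == pytest.approx(1.0)
        assert result.ci_low <= result.icc <= result.ci_high

    def test_offset_penalized_vs_consistency(self):
        x = np.array([3.0, 7.0, 1.0, 9.0, 5.0, 6.0])
        table = np.column_stack([x, x + 30.0])
        absolute = icc_absolute_single(table).icc
        consistency = icc_consistency_single(table)
        assert absolute < consistency

    def test_matches_first_principles_oracle(self, rng):
        for _ in range(25):
            table = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1)) * 2
            result = icc_absolute_single(table)
            assert result.icc == pytest.approx(icc_oracle(table))
            assert result.ci_low <= result.icc <= result.ci_high

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        table = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 1.5
        result = icc_absolute_single(table)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 3),
            "rater": np.tile(np.arange(3), 12),
            "score": table.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        row = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert result.icc == pytest.approx(row.ICC, abs=1e-9)
        assert result.ci_low == pytest.approx(row[ci_col][0], abs=0.01)
        assert result.ci_high == pytest.approx(row[ci_col][1], abs=0.01)

    def test_shift_invariance(self, rng):
        table = rng.normal(size=(8, 2))
        a = icc_absolute_single(table)
        b = icc_absolute_single(table + 100.0)
        assert a.icc == pytest.approx(b.icc)

    def test_missing_cells_rejected(self):
        table = np.ones((5, 2))
        table[2, 1] = np.nan
        with pytest.raises(ValueError, match="complete"):
            icc_absolute_single(table)

    def test_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_single(np.ones((2, 2)))


class TestAnovaTukey:
    def test_identical_groups_f_zero_p_one(self):
        group = np.array([1.0, 2.0, 3.0, 4.0])
        result = anova_tukey([group, group.copy(), group.copy()])
        assert result.f_statistic == 0.0
        assert result.p_value == 1.0

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.8, 1, size=9)
        result = anova_tukey([a, b])
        t_stat, t_p = stats.ttest_ind(a, b)
        assert result.f_statistic == pytest.approx(t_stat ** 2)
        assert result.p_value == pytest.approx(t_p)

    def test_sums_of_squares_match_oracle(self, rng):
        groups = [rng.normal(m, 1, size=int(rng.integers(4, 9)))
                  for m in (0.0, 0.5, 1.0, 2.0)]
        result = anova_tukey(groups)
        # from-scratch decomposition
        alldata = np.concatenate(groups)
        grand = alldata.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_expected = (ssb / 3) / (ssw / (len(alldata) - 4))
        assert result.f_statistic == pytest.approx(f_expected)

    def test_pairwise_matches_scipy_tukey(self, rng):
        groups = [rng.normal(m, 1, size=n)
                  for m, n in ((0, 8), (1, 6), (2.5, 7))]
        result = anova_tukey(groups)
        ref = stats.tukey_hsd(*groups)
        for (i, j, _diff, p_adj) in result.pairwise:
            assert p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_shift_invariance_of_f(self, rng):
        groups = [rng.normal(m, 1, size=6) for m in (0, 1, 2)]
        f1 = anova_tukey(groups).f_statistic
        f2 = anova_tukey([g + 50 for g in groups]).f_statistic
        assert f1 == pytest.approx(f2)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([np.array([1.0]), np.array([1.0, 2.0])])


class TestReviewTriage:
    def test_lowest_two_of_ten(self):
        maps = {f"img{i}": 0.5 + 0.05 * i for i in range(10)}
        assert review_triage(maps, 0.2) == ["img0", "img1"]

    def test_total_tie_selects_all(self):
        maps = {f"img{i}": 0.7 for i in range(6)}
        assert sorted(review_triage(maps, 0.2)) == sorted(maps)

    def test_matches_sort_and_slice_oracle(self, rng):
        for _ in range(20):
            maps = {f"i{j}": float(rng.choice([0.2, 0.4, 0.6, 0.8]))
                    for j in range(100)}
            selected = review_triage(maps, 0.2)
            ordered = sorted(maps.items(), key=lambda kv: (kv[1], kv[0]))
            m = math.ceil(0.2 * len(ordered))
            cutoff = ordered[m - 1][1]
            expected = [k for k, v in ordered if v <= cutoff]
            assert selected == expected
            assert len(selected) >= m

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            review_triage({"a": 0.5}, 0.0)
        with pytest.raises(ValueError):
            review_triage({}, 0.2)
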