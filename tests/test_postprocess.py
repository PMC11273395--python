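"""Segmentation post-processing and evaluation metrics against brute-force
oracles (pairwise AUROC, PR-step AP, flood-fill components, confusion tally)."""

from collections import deque

import numpy as np
import pytest

from octa_anomaly.postprocess import (PostprocessConfig, auroc,
                                      average_precision, binarize, dice,
                                      f1_at_youden, iou_sens_spec, pixel_eval,
                                      refine, scan_eval, scanwise_from_map)


@pytest.fixture
def rng():
    return np.random.default_rng(99)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def _auroc_pairs(scores, labels):
    """O(n^2) Mann-Whitney probability with half-weight ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _flood_fill_components(grid):
    """8-connected component labelling by BFS."""
    grid = np.asarray(grid, dtype=bool)
    seen = np.zeros_like(grid)
    comps = []
    for r0, c0 in zip(*np.nonzero(grid)):
        if seen[r0, c0]:
            continue
        comp = []
        q = deque([(r0, c0)])
        seen[r0, c0] = True
        while q:
            r, c = q.popleft()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < grid.shape[0] and 0 <= cc < grid.shape[1]
                            and grid[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        q.append((rr, cc))
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# binarize / refine
# ---------------------------------------------------------------------------

def test_binarize_is_strict():
    out = binarize(np.array([0.04, 0.05, 0.06]), 0.05)
    assert out.tolist() == [False, False, True]


def test_binarize_zero_threshold_flags_positives_only():
    out = binarize(np.array([0.0, 0.2, 0.0, 1e-9]), 0.0)
    assert out.tolist() == [False, True, False, True]


def test_binarize_above_max_gives_empty(rng):
    m = rng.random((8, 8))
    assert not binarize(m, m.max() + 1).any()


def test_refine_all_zero_passthrough():
    cfg = PostprocessConfig(opening_radius=1, dilation_radius=2, min_area=5)
    assert not refine(np.zeros((16, 16), bool), cfg).any()


def test_refine_small_area_rule():
    grid = np.zeros((20, 20), bool)
    grid[1:2, 1:4] = True                  # area 3
    grid[10:15, 5:15] = True               # area 50
    cfg = PostprocessConfig(opening_radius=0, dilation_radius=0, min_area=10)
    out = refine(grid, cfg)
    assert not out[1, 1] and out[12, 10]
    assert out.sum() == 50


def test_refine_component_survival_matches_flood_fill(rng):
    cfg = PostprocessConfig(opening_radius=0, dilation_radius=0, min_area=6)
    for _ in range(100):
        grid = rng.random((24, 24)) < 0.25
        out = refine(grid, cfg)
        expect = np.zeros_like(grid)
        for comp in _flood_fill_components(grid):
            if len(comp) >= 6:
                for r, c in comp:
                    expect[r, c] = True
        assert np.array_equal(out, expect)


def test_refine_monotone_in_min_area(rng):
    grid = rng.random((40, 40)) < 0.3
    prev = None
    for s in (0, 4, 16, 64):
        cfg = PostprocessConfig(opening_radius=1, dilation_radius=1, min_area=s)
        cur = refine(grid, cfg).sum()
        if prev is not None:
            assert cur <= prev
        prev = cur


# ---------------------------------------------------------------------------
# pixel metrics
# ---------------------------------------------------------------------------

def test_dice_identical_disjoint_and_half(rng):
    a = rng.random((10, 10)) < 0.4
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    p = np.zeros((4, 4), bool); p[0, :4] = True
    g = np.zeros((4, 4), bool); g[0, 2:] = True; g[1, :2] = True
    assert dice(p, g) == 0.5                     # |A|=|B|=4, overlap 2


def test_dice_both_empty_convention():
    z = np.zeros((5, 5), bool)
    assert dice(z, z) == 1.0
    assert iou_sens_spec(z, z)[0] == 1.0


def test_iou_sens_spec_matches_confusion_tally(rng):
    for _ in range(20):
        p = rng.random((12, 12)) < 0.5
        g = rng.random((12, 12)) < 0.5
        iou, sens, spec = iou_sens_spec(p, g)
        tp = np.sum(p & g); fp = np.sum(p & ~g)
        fn = np.sum(~p & g); tn = np.sum(~p & ~g)
        assert iou == pytest.approx(tp / (tp + fp + fn))
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))


def test_iou_dice_identity_per_image(rng):
    for _ in range(20):
        p = rng.random((12, 12)) < 0.4
        g = rng.random((12, 12)) < 0.4
        d = dice(p, g)
        iou = iou_sens_spec(p, g)[0]
        assert iou == pytest.approx(d / (2.0 - d))


def test_all_ones_prediction_sens_one_spec_zero():
    g = np.zeros((6, 6), bool); g[:3] = True
    p = np.ones((6, 6), bool)
    _, sens, spec = iou_sens_spec(p, g)
    assert sens == 1.0 and spec == 0.0


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        dice(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# scan metrics
# ---------------------------------------------------------------------------

def test_auroc_perfect_and_ties():
    assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5


def test_auroc_matches_pairwise_oracle(rng):
    for _ in range(10):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        if len(set(y)) < 2:
            continue
        assert auroc(s, y) == pytest.approx(_auroc_pairs(s, y), abs=1e-9)


def test_auroc_complement_identity_no_ties(rng):
    s = rng.permutation(40).astype(float)
    y = rng.integers(0, 2, size=40)
    y[0], y[1] = 0, 1
    assert auroc(s, y) + auroc(-s, y) == pytest.approx(1.0)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        auroc([1.0, 2.0], [1, 1])


def test_average_precision_hand_cases(rng):
    assert average_precision([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0
    # positive ranked second of two: only recall step has precision 1/2
    assert average_precision([2.0, 1.0], [0, 1]) == pytest.approx(0.5)
    s = rng.normal(size=25)
    y = rng.integers(0, 2, size=25)
    y[:2] = [0, 1]
    assert average_precision(s, y) == pytest.approx(
        average_precision(np.exp(s), y))      # monotone-transform invariance


def test_f1_at_youden_forced_cases(rng):
    f1, thr = f1_at_youden([1, 2, 3, 4], [0, 0, 1, 1])
    assert f1 == 1.0 and 2 < thr < 3
    f1, _ = f1_at_youden([1, 2, 9, 10], [0, 0, 1, 1])
    assert f1 == 1.0


def test_f1_at_youden_matches_threshold_scan(rng):
    for _ in range(10):
        s = rng.normal(size=24)
        y = rng.integers(0, 2, size=24)
        y[:2] = [0, 1]
        _, thr = f1_at_youden(s, y)

        def youden(t):
            pred = s > t
            sens = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
            spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
            return sens + spec - 1
        # brute-force scan over a dense threshold grid never beats it
        grid = np.linspace(s.min() - 1, s.max() + 1, 400)
        assert youden(thr) >= max(youden(t) for t in grid) - 1e-12


def test_scanwise_from_map_cases():
    assert scanwise_from_map(np.array([1.0, 8.0, 9.0]), 7.0) == 17.0
    assert scanwise_from_map(np.array([1.0, 2.0]), 5.0) == 0.0
    assert scanwise_from_map(np.array([0.1, 0.2]), 0.0) == pytest.approx(0.3)
    assert scanwise_from_map(np.zeros((4, 4)), 0.0) == 0.0


def test_scan_eval_report_fields(rng):
    s = list(rng.normal(size=20)) + list(rng.normal(3.0, 1.0, size=20))
    y = [0] * 20 + [1] * 20
    rep = scan_eval(s, y)
    assert 0.0 <= rep.auroc <= 1.0
    assert 0.0 <= rep.average_precision <= 1.0
    assert 0.0 <= rep.f1_at_youden <= 1.0


def test_metrics_invariant_to_sample_order(rng):
    s = rng.normal(size=30)
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    perm = rng.permutation(30)
    assert auroc(s, y) == pytest.approx(auroc(s[perm], y[perm]))
    assert average_precision(s, y) == pytest.approx(
        average_precision(s[perm], y[perm]))


def test_pixel_eval_summary_and_identity(rng):
    pairs = []
    for i in range(5):
        pairs.append((f"img{i}", rng.random((16, 16)) < 0.3,
                      rng.random((16, 16)) < 0.3))
    rep = pixel_eval(pairs)
    assert len(rep.per_image) == 5
    for _, row in rep.per_image.iterrows():
        assert row.iou == pytest.approx(row.dice / (2 - row.dice))
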