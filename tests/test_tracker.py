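"""Association: IoU metric, gating, dummy-augmented matching, tracking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatchtrack.core import (
    BBox,
    Detection,
    FrameDetections,
    StageLabel,
    TrackerConfig,
)
from hatchtrack.tracker import (
    FORBIDDEN,
    AssociationMatrix,
    TrackerState,
    admissible,
    build_association_matrix,
    iou,
    solve_matching,
    step,
    track_sequence,
)

L, FP, EP, A = StageLabel.LARVA, StageLabel.FULL_PUPA, StageLabel.EMPTY_PUPA, StageLabel.ADULT


def box(x0, y0, x1, y1):
    return BBox(x0, y0, x1, y1)


def det(b, stage=FP, conf=1.0):
    return Detection(bbox=b, stage=stage, confidence=conf)


# ---------------------------------------------------------------------------
# IoU


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (box(0, 0, 10, 10), box(0, 0, 10, 10), 1.0),
        (box(0, 0, 10, 10), box(20, 20, 30, 30), 0.0),
        (box(0, 0, 10, 10), box(10, 0, 20, 10), 0.0),  # touching edges: empty interior
        (box(0, 0, 10, 10), box(5, 0, 15, 10), 1 / 3),  # inter 50 / union 150
    ],
)
def test_iou_examples(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)


boxes_st = st.tuples(
    st.floats(0, 500), st.floats(0, 500), st.floats(1, 200), st.floats(1, 200)
).map(lambda t: BBox(t[0], t[1], t[0] + t[2], t[1] + t[3]))


@given(boxes_st, boxes_st)
@settings(max_examples=200, deadline=None)
def test_iou_symmetric_bounded(a, b):
    v = iou(a, b)
    assert 0.0 <= v <= 1.0 + 1e-12
    assert v == pytest.approx(iou(b, a))
    assert iou(a, a) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# admissibility gate


def test_admissible_requires_both_conditions(cfg):
    b = box(0, 0, 10, 10)
    near = box(0.2, 0, 10.2, 10)  # IoU ~ 0.96
    assert admissible(b, FP, det(near, EP), cfg)  # adjacent stages, high IoU
    assert not admissible(b, L, det(near, EP), cfg)  # non-adjacent stages
    far = box(5, 0, 15, 10)  # IoU = 1/3
    assert not admissible(b, FP, det(far, FP), cfg)


def test_iou_exactly_at_threshold_is_rejected(cfg):
    # overlap 75 of union 125 -> IoU = 0.6 exactly: "more than 60%" is strict
    a = box(0, 0, 10, 10)
    b = box(0, 2.5, 10, 12.5)
    assert iou(a, b) == pytest.approx(0.6)
    assert not admissible(a, FP, det(b, FP), cfg)


# ---------------------------------------------------------------------------
# association matrix


def test_matrix_shape_and_blocks(cfg):
    tracks = [(box(0, 0, 10, 10), FP), (box(100, 0, 110, 10), FP)]
    dets = [det(box(0.2, 0, 10.2, 10), FP)]
    m = build_association_matrix(tracks, dets, cfg)
    assert m.scores.shape == (3, 3)  # (m+n) x (n+m) with m=2, n=1
    assert m.scores[0, 0] > 0.9  # admissible real pair: gated IoU
    assert m.scores[1, 0] == FORBIDDEN  # disjoint -> inadmissible
    # dummy blocks zero; dummy-dummy block zero
    assert np.all(m.scores[:, 1:] == 0.0)
    assert np.all(m.scores[2:, 1:] == 0.0)


def test_matrix_no_tracks(cfg):
    m = build_association_matrix([], [det(box(0, 0, 1, 1))] * 3, cfg)
    assert m.scores.shape == (3, 3)
    assert np.all(m.scores == 0.0)
    assert solve_matching(m) == set()


def test_matrix_real_entry_is_iou(cfg):
    a, b = box(0, 0, 10, 10), box(0, 2, 10, 12)  # IoU = 80/120 = 2/3
    m = build_association_matrix([(a, FP)], [det(b, FP)], cfg)
    assert m.scores[0, 0] == pytest.approx(2 / 3)


# ---------------------------------------------------------------------------
# matching vs exhaustive oracle


def brute_force_best_total(scores_real: np.ndarray) -> float:
    """Oracle: best total over all injective partial track->detection
    assignments, where leaving anything unmatched contributes 0."""
    m, n = scores_real.shape
    best = 0.0
    for k in range(0, min(m, n) + 1):
        for rows in itertools.combinations(range(m), k):
            for cols in itertools.permutations(range(n), k):
                best = max(best, sum(scores_real[i, j] for i, j in zip(rows, cols)))
    return best


def augment(scores_real: np.ndarray) -> AssociationMatrix:
    m, n = scores_real.shape
    scores = np.zeros((m + n, n + m))
    scores[:m, :n] = scores_real
    return AssociationMatrix(m=m, n=n, scores=scores)


def test_matching_two_by_two_diagonal():
    real = np.array([[0.9, FORBIDDEN], [FORBIDDEN, 0.8]])
    assert solve_matching(augment(real)) == {(0, 0), (1, 1)}


def test_matching_all_forbidden_empty():
    real = np.full((3, 2), FORBIDDEN)
    assert solve_matching(augment(real)) == set()


@given(
    st.integers(1, 4),
    st.integers(1, 4),
    st.randoms(use_true_random=False),
)
@settings(max_examples=150, deadline=None)
def test_matching_equals_exhaustive_oracle(m, n, rnd):
    """Optimal total of the augmented matching equals brute-force search
    over all injective partial assignments."""
    real = np.array(
        [[FORBIDDEN if rnd.random() < 0.4 else round(rnd.uniform(0.61, 1.0), 3) for _ in range(n)] for _ in range(m)]
    )
    pairs = solve_matching(augment(real))
    total = sum(real[i, j] for i, j in pairs)
    assert total == pytest.approx(brute_force_best_total(real))
    # validity: injective, admissible scores only
    assert len({i for i, _ in pairs}) == len(pairs)
    assert len({j for _, j in pairs}) == len(pairs)
    assert all(real[i, j] > FORBIDDEN for i, j in pairs)


# ---------------------------------------------------------------------------
# stepping and sequences


def stationary_frames(n_frames, boxes, stage=FP, skip=()):
    frames = []
    for t in range(n_frames):
        dets = [] if t in skip else [det(b, stage) for b in boxes]
        frames.append(FrameDetections(frame_index=t, time_min=10.0 * t, detections=dets))
    return frames


def test_single_stationary_box_single_track(cfg):
    tracks = track_sequence(stationary_frames(50, [box(0, 0, 10, 10)]), cfg)
    assert len(tracks) == 1
    assert tracks[0].length == 50
    assert all(r.observed for _, r in tracks[0])


def test_two_separated_boxes_two_tracks(cfg):
    tracks = track_sequence(
        stationary_frames(40, [box(0, 0, 10, 10), box(100, 100, 110, 110)]), cfg
    )
    assert len(tracks) == 2
    assert all(t.length == 40 for t in tracks)


def test_gap_bridging_fills_inferred_frames(cfg):
    """A detection missing at t-1, t-2 re-associates at t (window reaches
    back to t-4) and the gap is filled with held, inferred records."""
    tracks = track_sequence(stationary_frames(20, [box(0, 0, 10, 10)], skip={7, 8}), cfg)
    assert len(tracks) == 1
    tr = tracks[0]
    assert tr.length == 20
    assert not tr.records[7].observed and not tr.records[8].observed
    assert tr.records[7].bbox == tr.records[6].bbox  # held box
    assert tr.records[9].observed


def test_track_closed_after_max_gap(cfg):
    """Unobserved for max_gap_frames consecutive frames -> closed; a later
    identical detection founds a fresh track."""
    frames = stationary_frames(20, [box(0, 0, 10, 10)], skip={5, 6, 7, 8})
    tracks = track_sequence(frames, cfg)
    assert len(tracks) == 2
    assert tracks[0].last_frame == 4
    assert tracks[1].first_frame == 9


def test_gap_equal_to_window_still_bridged(cfg):
    # last seen at t-4 is still a candidate at t
    frames = stationary_frames(20, [box(0, 0, 10, 10)], skip={5, 6, 7})
    tracks = track_sequence(frames, cfg)
    assert len(tracks) == 1
    assert tracks[0].length == 20


def test_stage_transition_keeps_identity(cfg):
    """Full pupa -> empty pupa at the same location stays one track."""
    frames = [
        FrameDetections(t, 10.0 * t, [det(box(0, 0, 10, 10), FP if t < 25 else EP)])
        for t in range(50)
    ]
    tracks = track_sequence(frames, cfg)
    assert len(tracks) == 1
    assert tracks[0].stages()[24] is FP and tracks[0].stages()[25] is EP


def test_adult_over_pupa_site_is_new_track(cfg):
    """An adult appearing on an empty pupa's box cannot inherit its identity."""
    frames = [
        FrameDetections(t, 10.0 * t, [det(box(0, 0, 10, 10), EP if t < 25 else A)])
        for t in range(50)
    ]
    tracks = track_sequence(frames, cfg)
    assert len(tracks) == 2


def test_untracked_classes_dropped():
    cfg = TrackerConfig(tracked_classes={FP, EP})
    frames = [
        FrameDetections(
            t,
            10.0 * t,
            [
                det(box(0, 0, 10, 10), FP),
                det(box(50, 50, 60, 60), L),
                det(box(100, 100, 110, 110), StageLabel.OUT_OF_FOCUS),
            ],
        )
        for t in range(10)
    ]
    tracks = track_sequence(frames, cfg)
    assert len(tracks) == 1


def test_out_of_order_frame_rejected(cfg):
    state = TrackerState()
    step(state, FrameDetections(5, 50.0, []), cfg)
    with pytest.raises(ValueError, match="out-of-order"):
        step(state, FrameDetections(5, 50.0, []), cfg)


def test_detection_conservation(cfg):
    """Every tracked-class detection lands in exactly one track record."""
    rng = np.random.default_rng(3)
    frames = []
    centers = rng.uniform(50, 450, (6, 2))
    for t in range(30):
        centers = centers + rng.normal(0, 0.5, centers.shape)
        dets = [det(box(c[0] - 5, c[1] - 5, c[0] + 5, c[1] + 5), FP) for c in centers]
        frames.append(FrameDetections(t, 10.0 * t, dets))
    tracks = track_sequence(frames, cfg)
    n_observed = sum(sum(r.observed for _, r in tr) for tr in tracks)
    assert n_observed == 30 * 6


def test_raising_threshold_never_increases_matches():
    """Monotonicity: a stricter IoU gate can only reduce associations,
    measured as the number of observed track extensions."""
    rng = np.random.default_rng(7)
    frames = []
    centers = rng.uniform(50, 450, (8, 2))
    for t in range(40):
        centers = centers + rng.normal(0, 1.5, centers.shape)
        dets = [det(box(c[0] - 6, c[1] - 6, c[0] + 6, c[1] + 6), FP) for c in centers]
        frames.append(FrameDetections(t, 10.0 * t, dets))

    def n_matches(threshold):
        tracks = track_sequence(frames, TrackerConfig(iou_threshold=threshold))
        return sum(sum(r.observed for _, r in tr) for tr in tracks) - len(tracks)

    counts = [n_matches(th) for th in (0.3, 0.5, 0.6, 0.8)]
    assert counts == sorted(counts, reverse=True)


def test_track_ids_first_appearance_order(cfg):
    frames = [
        FrameDetections(0, 0.0, [det(box(0, 0, 10, 10), FP)]),
        FrameDetections(1, 10.0, [det(box(0, 0, 10, 10), FP), det(box(50, 0, 60, 10), FP)]),
    ]
    tracks = track_sequence(frames, cfg)
    assert [t.track_id for t in tracks] == [0, 1]
    assert tracks[0].first_frame == 0 and tracks[1].first_frame == 1
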