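import numpy as np
import pytest
from scipy import ndimage

from fishtrack.centerline import (build_skeleton_graph, centerline_graph,
                                  extract_centerline, parameterize_boundary,
                                  propagate_arrival_times, thin_centerline,
                                  CenterlineParams)


def _field(mask):
    return propagate_arrival_times(parameterize_boundary(mask))


# ------------------------------------------------- boundary parameterization

def test_boundary_single_pixel():
    m = np.zeros((5, 5), bool)
    m[2, 2] = True
    f = parameterize_boundary(m)
    assert f.u[2, 2] == 1
    assert f.boundary_lengths == {1: 1}


def test_boundary_3x3_square():
    m = np.zeros((5, 5), bool)
    m[1:4, 1:4] = True
    f = parameterize_boundary(m)
    border = sorted(f.u[f.boundary].tolist())
    assert border == list(range(1, 9))
    assert np.isnan(f.u[2, 2])  # center is interior


def test_boundary_rectangle_is_permutation():
    m = np.zeros((20, 50), bool)
    m[5:15, 5:45] = True
    # brute-force boundary count: foreground with a 4-neighbor outside
    inner = ndimage.binary_erosion(m, ndimage.generate_binary_structure(2, 1))
    expected_l = int((m & ~inner).sum())
    assert expected_l == 96
    f = parameterize_boundary(m)
    assert f.boundary_lengths == {1: 96}
    assert np.array_equal(np.sort(f.u[f.boundary]), np.arange(1, 97))


def test_empty_mask_gives_empty_field():
    f = parameterize_boundary(np.zeros((4, 4), bool))
    assert f.boundary_lengths == {}
    assert not extract_centerline(propagate_arrival_times(f), 5).any()


# ---------------------------------------------------------- U propagation

def test_propagation_3x3_center_inherits_a_neighbor():
    m = np.zeros((5, 5), bool)
    m[1:4, 1:4] = True
    f = _field(m)
    boundary_us = set(f.u[f.boundary].tolist())
    assert f.u[2, 2] in boundary_us


def test_propagation_matches_nearest_boundary_oracle():
    """On convex masks every pixel inherits U from (within 1 px of) its true
    Euclidean nearest boundary point — exhaustive brute-force check."""
    masks = []
    m = np.zeros((30, 64), bool)
    m[8:22, 4:60] = True
    masks.append(m)
    yy, xx = np.mgrid[0:40, 0:40]
    masks.append((xx - 20) ** 2 + (yy - 20) ** 2 <= 14 ** 2)
    for m in masks:
        f = _field(m)
        by, bx = np.nonzero(f.boundary)
        u_of_boundary = f.u[by, bx]
        iy, ix = np.nonzero(m & ~f.boundary)
        for y, x in zip(iy, ix):
            d = np.hypot(by - y, bx - x)
            nearest = d.min()
            src = d[u_of_boundary == f.u[y, x]].min()
            assert src <= nearest + 1.0


# ------------------------------------------------------- centerline (Eq 3)

def test_disk_centerline_collapses_to_center():
    yy, xx = np.mgrid[0:50, 0:50]
    disk = (xx - 25) ** 2 + (yy - 25) ** 2 <= 400
    f = _field(disk)
    cl = extract_centerline(f, 40)
    ys, xs = np.nonzero(cl)
    assert len(ys) >= 1
    assert np.max(np.hypot(ys - 25.0, xs - 25.0)) <= 3.0


def test_rectangle_centerline_lies_on_midline():
    m = np.zeros((30, 80), bool)
    m[9:21, 10:70] = True  # 60x12, midline row 14.5
    f = _field(m)
    cl = extract_centerline(f, 40)
    ys, xs = np.nonzero(cl)
    assert len(ys) > 0
    # over the unambiguous central span the centerline is the medial line
    span = (xs >= 10 + 12) & (xs <= 70 - 1 - 12)
    assert np.all(np.abs(ys[span] - 14.5) <= 1.5)
    # cross-check with the exact medial-axis distance-transform oracle
    edt = ndimage.distance_transform_edt(m)
    assert np.all(edt[ys[span], xs[span]] >= edt[m].max() - 1.0)


def test_large_threshold_empties_centerline(capsule_mask):
    f = _field(capsule_mask)
    L = max(f.boundary_lengths.values())
    assert not extract_centerline(f, L / 2).any()


@pytest.mark.parametrize("shape", ["disk", "capsule"])
def test_monotone_pruning(shape, capsule_mask):
    if shape == "disk":
        yy, xx = np.mgrid[0:60, 0:60]
        m = (xx - 30) ** 2 + (yy - 30) ** 2 <= 625
    else:
        m = capsule_mask
    f = _field(m)
    prev = None
    for tu in (10, 20, 40, 70):
        cur = extract_centerline(f, tu)
        if prev is not None:
            assert np.all(cur <= prev)
        prev = cur


def test_rotation_robustness(capsule_mask):
    a = extract_centerline(_field(capsule_mask), 30)
    b = extract_centerline(_field(np.rot90(capsule_mask, k=-1)), 30)
    assert np.array_equal(np.rot90(a, k=-1), b)


def test_capsule_endpoints_near_rendered_tips(capsule_mask):
    """At a low pruning threshold the two branch endpoints land within 3 px
    of the head/tail cap centers used to render the capsule."""
    skel, g, _ = centerline_graph(capsule_mask, 8)
    H, T = np.array([150, 100]), np.array([100, 100])
    d_h = min(np.hypot(*(np.array(ep) - H)) for ep in g.endpoints)
    d_t = min(np.hypot(*(np.array(ep) - T)) for ep in g.endpoints)
    assert d_h <= 3.0 and d_t <= 3.0


def test_centerline_stability_in_segmentation_threshold(fish_model):
    """The influence of the segmentation threshold T_g on the centerline
    decreases (Hausdorff) as T_u grows: a faint burr that only a low T_g
    attaches to the moving region perturbs the low-T_u centerline but is
    pruned away at high T_u."""
    from fishtrack.metrics import GroundTruthRecord
    from fishtrack.segmentation import SegmentationParams, clean_mask, segment_frame
    from fishtrack.synthetic import render_frame

    rec = GroundTruthRecord(0, 150.0, 100.0, 0.0, False)
    frame = render_frame([rec], fish_model, (200, 300), 0.0).astype(float)
    yy, xx = np.mgrid[0:200, 0:300]
    burr = (xx - 125) ** 2 + (yy - 113) ** 2 <= 36  # faint lump on the flank
    frame[burr] = np.minimum(frame[burr], 120.0)
    bg = np.full((200, 300), 200.0)
    params = SegmentationParams(min_blob_area=30, median_kernel=3)
    m1 = clean_mask(segment_frame(frame, bg, 60), params)  # burr included
    m2 = clean_mask(segment_frame(frame, bg, 90), params)  # burr rejected
    assert m1.sum() > m2.sum()
    f1, f2 = _field(m1), _field(m2)

    def hausdorff(a, b):
        da = ndimage.distance_transform_edt(~a)
        db = ndimage.distance_transform_edt(~b)
        return max(da[b].max(), db[a].max())

    dists = []
    for tu in (5, 10, 20, 30):
        c1, c2 = extract_centerline(f1, tu), extract_centerline(f2, tu)
        assert c1.any() and c2.any()
        dists.append(hausdorff(c1, c2))
    assert all(b <= a for a, b in zip(dists, dists[1:]))
    assert dists[-1] < dists[0]


def test_params_reject_threshold_at_or_below_two():
    with pytest.raises(ValueError):
        CenterlineParams(t_u=2.0)


# ---------------------------------------------------------- skeleton graph

def test_graph_simple_segment():
    m = np.zeros((5, 30), bool)
    m[2, 4:24] = True
    g = build_skeleton_graph(m)
    assert len(g.endpoints) == 2
    assert g.junctions == []
    assert len(g.branches) == 1
    assert g.branches[0].length == 20


def test_graph_y_shape():
    pix = set()
    for i in range(10):
        pix.add((15, 15 - i))        # up arm
        pix.add((15 - i, 15 + i))    # down-left diagonal
        pix.add((15 + i, 15 + i))    # down-right diagonal
    g = build_skeleton_graph(pix)
    assert len(g.endpoints) == 3
    assert len(g.junctions) == 1
    assert len(g.branches) == 3


def test_graph_crossed_capsules():
    m = np.zeros((80, 80), bool)
    m[36:44, 10:70] = True
    m[10:70, 36:44] = True
    skel, g, _ = centerline_graph(m, 20)
    assert len(g.endpoints) == 4
    assert len(g.junctions) >= 1


def test_graph_empty():
    g = build_skeleton_graph(set())
    assert g.pixels == set() and g.endpoints == [] and g.branches == []


def test_thinning_yields_unit_width(capsule_mask):
    f = _field(capsule_mask)
    skel = thin_centerline(extract_centerline(f, 20))
    # no 2x2 block fully set
    blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
    assert not blocks.any()
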