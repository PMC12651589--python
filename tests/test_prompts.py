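"""Prompt construction: centroids, size terciles, quadrants, templates, and
the mask-free location bootstrap."""

import numpy as np
import pytest

from busseg.prompts import (
    Centroid,
    EmptyMaskError,
    LesionMetadata,
    SizeBins,
    build_global_prompt,
    build_local_prompt,
    build_prompt_pair,
    compute_centroid,
    estimate_location_from_probmap,
    fit_size_bins,
    quadrant_token,
    size_token,
)

# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------


def test_centroid_single_pixel():
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[5, 3] = 1
    c = compute_centroid(mask)
    assert (c.cx, c.cy) == (3.0, 5.0)


def test_centroid_full_mask_is_geometric_center():
    c = compute_centroid(np.ones((7, 11), dtype=np.uint8))
    assert (c.cx, c.cy) == (5.0, 3.0)


def test_centroid_equals_foreground_mean_on_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(500):
        mask = (rng.random((16, 16)) > 0.6).astype(np.uint8)
        if not mask.any():
            continue
        c = compute_centroid(mask)
        rows, cols = np.nonzero(mask)
        assert abs(c.cx - cols.mean()) < 1e-9
        assert abs(c.cy - rows.mean()) < 1e-9


def test_centroid_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        compute_centroid(np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# size bins
# ---------------------------------------------------------------------------


def test_terciles_split_one_to_nine_evenly():
    bins = fit_size_bins(range(1, 10))
    tokens = [size_token(v, bins) for v in range(1, 10)]
    assert tokens.count("small") == 3
    assert tokens.count("medium") == 3
    assert tokens.count("large") == 3


def test_degenerate_sizes_all_map_to_medium():
    bins = fit_size_bins([5.0, 5.0, 5.0, 5.0])
    assert bins.lower_edge == bins.upper_edge == 5.0
    assert size_token(5.0, bins) == "medium"


def test_edges_are_ordered_for_spread_sizes():
    bins = fit_size_bins([10, 20, 30, 40, 50, 60])
    assert bins.lower_edge < bins.upper_edge


def test_too_few_sizes_rejected():
    with pytest.raises(ValueError):
        fit_size_bins([1.0, 2.0])


def test_size_token_edge_ties_go_to_medium():
    bins = SizeBins(lower_edge=100, upper_edge=200)
    assert size_token(50, bins) == "small"
    assert size_token(150, bins) == "medium"
    assert size_token(250, bins) == "large"
    assert size_token(100, bins) == "medium"
    assert size_token(200, bins) == "medium"


def test_tercile_partition_balanced_for_distinct_divisible_sets():
    rng = np.random.default_rng(3)
    for _ in range(20):
        sizes = rng.choice(10_000, size=27, replace=False).astype(float)
        bins = fit_size_bins(sizes)
        counts = {t: 0 for t in ("small", "medium", "large")}
        for v in sizes:
            counts[size_token(v, bins)] += 1
        assert max(counts.values()) - min(counts.values()) <= 1


# ---------------------------------------------------------------------------
# quadrants and templates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("cx,cy,lat,expected", [
    (10, 10, "unknown", "upper inner"),
    (90, 90, "unknown", "lower outer"),
    (50, 50, "unknown", "upper inner"),  # exact midline tie rule
    (10, 10, "right", "upper outer"),
    (90, 10, "right", "upper inner"),
    (10, 90, "left", "lower inner"),
])
def test_quadrant_mapping(cx, cy, lat, expected):
    assert quadrant_token(Centroid(cx, cy), 100, 100, lat) == expected


def test_global_prompt_templates():
    assert build_global_prompt("small", "upper inner") == \
        "a small lesion in the upper inner quadrant"
    assert build_global_prompt("large", "lower outer") == \
        "a large lesion in the lower outer quadrant"
    assert build_global_prompt("small", None) == "a small lesion"


def test_local_prompt_verbalization():
    md = LesionMetadata(shape="irregular", margin="microlobulated", birads=4)
    assert build_local_prompt(md) == "irregular shape, microlobulated margin, BI-RADS 4"
    assert build_local_prompt(LesionMetadata()) == "breast lesion"
    md = LesionMetadata(shape="oval", margin="circumscribed", birads=3)
    assert build_local_prompt(md) == "oval shape, circumscribed margin, BI-RADS 3"


def test_partial_metadata_omits_missing_fields():
    assert build_local_prompt(LesionMetadata(shape="round")) == "round shape"
    assert build_local_prompt(LesionMetadata(birads=5)) == "BI-RADS 5"


def test_prompt_construction_is_pure():
    md = LesionMetadata(size_value=40.0, shape="oval", margin="circumscribed",
                        birads=3, laterality="left")
    bins = SizeBins(20, 60)
    pairs = [build_prompt_pair(md, bins, Centroid(10, 10), 96, 96) for _ in range(5)]
    assert len({(p.global_prompt, p.local_prompt) for p in pairs}) == 1


def test_metadata_vocabulary_enforced():
    with pytest.raises(ValueError):
        LesionMetadata(shape="blobby")
    with pytest.raises(ValueError):
        LesionMetadata(birads=7)
    with pytest.raises(ValueError):
        LesionMetadata(size_value=-1.0)


# ---------------------------------------------------------------------------
# location bootstrap
# ---------------------------------------------------------------------------


def _flood_fill_components(binary):
    """Independent 8-connected labeling oracle (BFS)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                pix = []
                while stack:
                    a, b = stack.pop()
                    pix.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if 0 <= na < h and 0 <= nb < w and binary[na, nb] \
                                    and not seen[na, nb]:
                                seen[na, nb] = True
                                stack.append((na, nb))
                comps.append(pix)
    return comps


def test_largest_component_centroid_two_blobs():
    prob = np.zeros((12, 12))
    prob[1:2, 1:6] = 0.9   # 5 px
    prob[6:9, 6:9] = 0.8   # 9 px
    c = estimate_location_from_probmap(prob, 0.3)
    assert (c.cx, c.cy) == (7.0, 7.0)


def test_no_pixel_above_threshold_gives_no_proposal():
    assert estimate_location_from_probmap(np.full((8, 8), 0.29), 0.30) is None


def test_threshold_is_inclusive_point_mass():
    prob = np.zeros((10, 10))
    prob[2, 7] = 0.30
    c = estimate_location_from_probmap(prob, 0.30)
    assert (c.cx, c.cy) == (7.0, 2.0)


def test_bootstrap_agrees_with_flood_fill_oracle_on_random_grids():
    rng = np.random.default_rng(11)
    for _ in range(200):
        prob = rng.random((20, 20))
        prob = np.where(rng.random((20, 20)) < 0.8, 0.0, prob)
        c = estimate_location_from_probmap(prob, 0.5)
        comps = _flood_fill_components(prob >= 0.5)
        if not comps:
            assert c is None
            continue
        sizes = [len(p) for p in comps]
        best = max(sizes)
        cands = [p for p in comps if len(p) == best]
        # tie rule: smallest top-left flattened index
        chosen = min(cands, key=lambda p: min(a * 20 + b for a, b in p))
        ys = np.mean([a for a, _ in chosen])
        xs = np.mean([b for _, b in chosen])
        assert c.cx == pytest.approx(xs, abs=1e-9)
        assert c.cy == pytest.approx(ys, abs=1e-9)


def test_probmap_values_validated():
    with pytest.raises(ValueError):
        estimate_location_from_probmap(np.full((4, 4), 1.5), 0.3)
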