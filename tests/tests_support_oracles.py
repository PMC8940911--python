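"""Independent brute-force oracles shared by the end-to-end property tests.

These deliberately avoid the package's own code paths: percentiles via
explicit sorting and interpolation, suppression and matching via exhaustive
best-first loops.
"""

import numpy as np

from somatrace.core import BoundingBox
from somatrace.detection import intersection_over_min, pair_overlap


def random_boxes(rng, n, fov=100, max_side=20):
    boxes = []
    for _ in range(n):
        x0 = rng.uniform(0, fov - 2)
        y0 = rng.uniform(0, fov - 2)
        boxes.append(
            BoundingBox(
                x0, y0,
                x0 + rng.uniform(1, max_side),
                y0 + rng.uniform(1, max_side),
                score=float(rng.uniform(0, 1)),
            )
        )
    return boxes


def brute_force_nms(boxes, threshold):
    remaining = list(boxes)
    kept = []
    while remaining:
        best = min(remaining, key=lambda b: (-b.score, b.y_min, b.x_min))
        kept.append(best)
        remaining = [
            b
            for b in remaining
            if b is not best and all(pair_overlap(b, k) <= threshold for k in kept)
        ]
    return kept


def manual_percentile(sorted_vals, q):
    pos = q / 100.0 * (len(sorted_vals) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def segment_oracle(patch, p_low, p_high):
    flat = sorted(np.asarray(patch).ravel().tolist())
    lo = manual_percentile(flat, p_low)
    hi = manual_percentile(flat, p_high)
    return [v for v in flat if lo <= v <= hi]


def brute_force_match(pred, gt, cutoff=0.5):
    import itertools

    candidates = sorted(
        (
            (intersection_over_min(p, g), i, j)
            for (i, p), (j, g) in itertools.product(enumerate(pred), enumerate(gt))
            if intersection_over_min(p, g) > cutoff
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_p, used_g, tp = set(), set(), 0
    for _, i, j in candidates:
        if i not in used_p and j not in used_g:
            used_p.add(i)
            used_g.add(j)
            tp += 1
    return tp
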