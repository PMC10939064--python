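"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy/vectorised shortcuts: flood fill by explicit
BFS, overlap metrics by pixel counting loops, and run lengths by scanning.
They must stay independent of the code paths they check.
"""

from collections import deque

import numpy as np


def flood_fill_components(binary):
    """8-connected components of a boolean raster by breadth-first search."""
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            comp = []
            while queue:
                r, c = queue.popleft()
                comp.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            components.append(comp)
    return components


def remove_small_oracle(pixels, min_px):
    """Per-class small-component removal via the flood-fill oracle."""
    out = np.asarray(pixels).copy()
    for cls in (1, 2):
        for comp in flood_fill_components(pixels == cls):
            if len(comp) < min_px:
                for r, c in comp:
                    out[r, c] = 0
    return out


def endpoints_oracle(binary):
    """Extreme-column foreground pixels by exhaustive scan, ties by min row."""
    best_left = best_right = None
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if not binary[r, c]:
                continue
            if best_left is None or (c, r) < (best_left[1], best_left[0]):
                best_left = (r, c)
            if best_right is None or (c, -r) > (best_right[1], -best_right[0]):
                best_right = (r, c)
    return best_left, best_right


def dice_by_hand(a, b):
    """DSC by explicit pixel counting."""
    inter = total = 0
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    for av, bv in zip(a.ravel(), b.ravel()):
        inter += av and bv
        total += int(av) + int(bv)
    return 1.0 if total == 0 else 2.0 * inter / total


def iou_by_hand(a, b):
    """IoU by explicit pixel counting."""
    inter = union = 0
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    for av, bv in zip(a.ravel(), b.ravel()):
        inter += av and bv
        union += av or bv
    return 1.0 if union == 0 else inter / union


def longest_run_oracle(values):
    """Longest run of truthy values by linear scan."""
    best = cur = 0
    for v in values:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best
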