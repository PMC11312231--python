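"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive — per-pixel loops, flood fill,
fine-grid integration — and shares no code with the package, so each
serves as an independent oracle for the optimized implementation.
"""

import math

import numpy as np


def median_filter_bruteforce(image: np.ndarray, kernel: int) -> np.ndarray:
    """Per-window sort median with edge replication."""
    r = kernel // 2
    padded = np.pad(image, r, mode="edge")
    out = np.empty_like(image)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            win = padded[i:i + kernel, j:j + kernel].ravel()
            out[i, j] = int(np.sort(win)[win.size // 2])
    return out


def global_equalize_bruteforce(image: np.ndarray) -> np.ndarray:
    """Plain global histogram equalization, value-by-value."""
    n = image.size
    out = np.empty_like(image)
    flat = image.ravel()
    for v in range(256):
        count = int(np.sum(flat <= v))
        mapped = round(255.0 * count / n)
        out[image == v] = mapped
    return out


def count_components_floodfill(mask: np.ndarray, connectivity: int) -> int:
    """Flood-fill component count."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    count = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def dilate_square_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Any-neighbor-set dilation with a (2r+1)-square element."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            r0, r1 = max(0, i - radius), min(h, i + radius + 1)
            c0, c1 = max(0, j - radius), min(w, j + radius + 1)
            if np.any(mask[r0:r1, c0:c1]):
                out[i, j] = 1
    return out


def sweep_hits_bruteforce(comp: np.ndarray, kernel: int) -> set:
    """Exhaustive window inspection for the crest-hit predicate."""
    h, w = comp.shape
    r = kernel // 2
    hits = set()
    for i in range(h):
        for j in range(w):
            win = comp[max(0, i - r):i + r + 1, max(0, j - r):j + r + 1]
            if np.any(win == 1) and np.any(win == 3):
                hits.add((i, j))
    return hits


def dice_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    inter = sa = sb = 0
    for x, y in zip(a.ravel(), b.ravel()):
        sa += bool(x)
        sb += bool(y)
        inter += bool(x) and bool(y)
    return 2.0 * inter / (sa + sb)


def jaccard_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    inter = union = 0
    for x, y in zip(a.ravel(), b.ravel()):
        inter += bool(x) and bool(y)
        union += bool(x) or bool(y)
    return inter / union


def rmse_bruteforce(pairs, h, w, normalize):
    """Loop-and-accumulate landmark RMSE over (pred, annot) point pairs."""
    total = 0.0
    n = 0
    for (pr, pc), (ar, ac) in pairs:
        if normalize:
            total += ((pr - ar) / h) ** 2 + ((pc - ac) / w) ** 2
        else:
            total += (pr - ar) ** 2 + (pc - ac) ** 2
        n += 1
    return math.sqrt(total / (2 * n))


def ap_grid_bruteforce(curve, steps: int = 100000) -> float:
    """Fine-grid integration of the interpolated precision step function."""
    recalls = [p[0] for p in curve]
    precs = [p[1] for p in curve]
    total = 0.0
    dr = 1.0 / steps
    for k in range(steps):
        r = (k + 0.5) * dr
        best = 0.0
        for rr, pp in zip(recalls, precs):
            if rr >= r and pp > best:
                best = pp
        total += best * dr
    return total
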