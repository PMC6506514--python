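"""Independent reference implementations used as test oracles.

These are deliberately naive (per-pixel loops, exhaustive scans) and share
no code with the package; they exist so the optimized implementations can
be checked against a literal transcription of each algorithm's definition.
"""

import numpy as np


def otsu_brute_force(values: np.ndarray) -> int:
    """Exhaustive scan of all 256 thresholds, maximizing the between-class
    variance; ties broken toward the smallest threshold."""
    v = np.clip(np.round(np.asarray(values, dtype=float)), 0, 255).ravel()
    best_t, best_var = None, -1.0
    n = len(v)
    for t in range(256):
        c0 = v[v <= t]
        c1 = v[v > t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0 = len(c0) / n
        w1 = len(c1) / n
        var = w0 * w1 * (c0.mean() - c1.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    if best_t is None:
        raise ValueError("constant image")
    return best_t


def zhang_suen_reference(mask: np.ndarray) -> np.ndarray:
    """Literal per-pixel transcription of the two-subiteration thinning
    algorithm (neighbours P2..P9 clockwise from north)."""
    img = np.pad(np.asarray(mask, bool).astype(int), 1)

    def neighbours(r, c):
        return [img[r - 1, c], img[r - 1, c + 1], img[r, c + 1],
                img[r + 1, c + 1], img[r + 1, c], img[r + 1, c - 1],
                img[r, c - 1], img[r - 1, c - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_delete = []
            for r in range(1, img.shape[0] - 1):
                for c in range(1, img.shape[1] - 1):
                    if img[r, c] == 0:
                        continue
                    P = neighbours(r, c)  # P2..P9
                    B = sum(P)
                    if not (2 <= B <= 6):
                        continue
                    ring = P + [P[0]]
                    A = sum(1 for a, b in zip(ring, ring[1:])
                            if a == 0 and b == 1)
                    if A != 1:
                        continue
                    P2, P4, P6, P8 = P[0], P[2], P[4], P[6]
                    if step == 0:
                        if P2 * P4 * P6 != 0 or P4 * P6 * P8 != 0:
                            continue
                    else:
                        if P2 * P4 * P8 != 0 or P2 * P6 * P8 != 0:
                            continue
                    to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = 0
            if to_delete:
                changed = True
    return img[1:-1, 1:-1].astype(bool)
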