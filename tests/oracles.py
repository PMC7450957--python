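"""Independent brute-force oracles used to cross-check the implementation."""

from collections import deque

import numpy as np

NEIGHBOURS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
NEIGHBOURS_8 = NEIGHBOURS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(mask, connectivity):
    """Enumerate connected components of a boolean mask by BFS flood fill.

    Returns a list of lists of (row, col) pixel coordinates, one per
    component.  Written independently of any labelling library.
    """
    mask = np.asarray(mask, dtype=bool)
    offsets = NEIGHBOURS_4 if connectivity == 4 else NEIGHBOURS_8
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            comp = []
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                y, x = queue.popleft()
                comp.append((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            components.append(comp)
    return components


def size_filter_oracle(mask, min_size, connectivity):
    """Brute-force small-component removal built on the flood-fill oracle."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_size:
            for r, c in comp:
                out[r, c] = True
    return out


def ccc_oracle(x, y):
    """Lin's concordance coefficient straight from the moment formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx2 = sum((v - x.mean()) ** 2 for v in x) / n
    sy2 = sum((v - y.mean()) ** 2 for v in y) / n
    sxy = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


def random_blob_mask(rng, shape=(48, 48), n_blobs=3, r_max=6.0):
    """A small mask of a few round blobs, for grid-overlay comparisons."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(4, h - 4), rng.uniform(4, w - 4)
        r = rng.uniform(1.5, r_max)
        mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= r ** 2
    return mask
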