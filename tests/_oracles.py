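"""Brute-force reference implementations used only to verify the package.

Each oracle is written from the mathematical definition, independent of the
code paths it checks (no scipy.ndimage / skimage morphology calls).
"""

from __future__ import annotations

import numpy as np


def pcc_twopass(a, b) -> float:
    """Pearson r via the explicit two-pass covariance formula."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    da, db = a - a.mean(), b - b.mean()
    return float((da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum()))


def median_filter_bruteforce(img: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window median, square k x k window, symmetric edge padding."""
    img = np.asarray(img, float)
    pad = k // 2
    p = np.pad(img, pad, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(p[i : i + k, j : j + k])
    return out


def _minmax_filter(img: np.ndarray, footprint: np.ndarray, op) -> np.ndarray:
    pad = footprint.shape[0] // 2
    p = np.pad(np.asarray(img, float), pad, mode="symmetric")
    fp = footprint.astype(bool)
    out = np.empty_like(np.asarray(img, float))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = p[i : i + fp.shape[0], j : j + fp.shape[1]]
            out[i, j] = op(win[fp])
    return out


def white_tophat_bruteforce(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Image minus its opening: erode with min, dilate with max, subtract."""
    eroded = _minmax_filter(img, footprint, np.min)
    opened = _minmax_filter(eroded, footprint, np.max)
    return np.asarray(img, float) - opened


def label_components_3d(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Flood-fill connected-component labeling; connectivity 6, 18 or 26."""
    binary = np.asarray(binary, bool)
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                order = abs(dz) + abs(dy) + abs(dx)
                if order == 0:
                    continue
                if (connectivity == 6 and order > 1) or (connectivity == 18 and order > 2):
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(binary.shape, int)
    current = 0
    for idx in zip(*np.nonzero(binary)):
        if labels[idx]:
            continue
        current += 1
        stack = [idx]
        labels[idx] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[d] < binary.shape[d] for d in range(3)):
                    if binary[n] and not labels[n]:
                        labels[n] = current
                        stack.append(n)
    return labels


def pooled_t_statistic(a, b) -> float:
    """Student's two-sample t with pooled variance, from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
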