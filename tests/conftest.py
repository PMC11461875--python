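"""Shared fixtures and brute-force reference implementations.

The brute-force helpers here are deliberately naive (per-pixel distance
checks, BFS flood fill) so they stay independent of the scikit-image-backed
code paths they are used to verify.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from tendonquant import TwoChannelSection


def brute_force_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """A pixel is set iff any true source pixel lies within Euclidean radius."""
    out = np.zeros_like(mask, dtype=bool)
    pts = np.argwhere(mask)
    if not len(pts):
        return out
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            d2 = (pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2
            if (d2 <= radius * radius).any():
                out[i, j] = True
    return out


def brute_force_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """BFS flood-fill connected components, 8-connectivity."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            r, c = queue.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not labels[rr, cc]
                    ):
                        labels[rr, cc] = current
                        queue.append((rr, cc))
    return labels, current


def make_section(
    red: np.ndarray,
    blue: np.ndarray | None = None,
    stain_kind: str = "collagen1",
    **meta,
) -> TwoChannelSection:
    red = np.asarray(red, dtype=np.uint8)
    if blue is None:
        blue = np.zeros_like(red)
    return TwoChannelSection(red=red, blue=blue, stain_kind=stain_kind, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
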