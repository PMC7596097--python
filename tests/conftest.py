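"""Shared fixtures: small synthetic samples and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from papillae import easy_spec, generate_sample


@pytest.fixture(scope="session")
def easy_sample():
    """One high-contrast synthetic tongue (session-scoped: generation is slow)."""
    return generate_sample(easy_spec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent 8-connected component count by explicit BFS flood fill."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        count += 1
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr, dc in neighbours:
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                    if mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count
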