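"""Small shared helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path


def percent_round_half_away(count: int, n: int) -> int:
    """Integer percentage of ``count / n`` rounded to the nearest integer.

    Exact halves round away from zero (e.g. 3/200 -> 2%).  Computed in
    integer arithmetic so the result never depends on float representation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return (200 * count + n) // (2 * n)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_seed(*parts: int) -> int:
    """Deterministically derive a child seed (< 2**31) from integer parts."""
    import numpy as np

    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))
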