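"""Counter-based random streams keyed per (seed, stream, row).

Every gallery row and every probe's noise vector gets its own Philox
stream, so any row can be regenerated in isolation and chunked
generation is bit-identical regardless of chunk boundaries or
evaluation order.
"""

from __future__ import annotations

import numpy as np

# Domain tags keep gallery draws, probe noise and index sampling on
# disjoint streams even when the same user seed is passed to each.
GALLERY_STREAM = 1
PROBE_NOISE_STREAM = 2
INDEX_STREAM = 3

_ROW_BITS = 48  # rows occupy the low 48 bits of the second key word


def derive_seed(seed: int, *tags: int) -> int:
    """Mix a user seed with integer tags into a fresh 63-bit seed."""
    state = np.random.SeedSequence([int(seed) & (2**63 - 1), *[int(t) for t in tags]])
    return int(state.generate_state(1, np.uint64)[0] >> np.uint64(1))


def row_rng(seed: int, stream: int, row: int) -> np.random.Generator:
    """Generator for one logical row of one stream."""
    if row < 0 or row >= 1 << _ROW_BITS:
        raise ValueError(f"row index {row} outside keyable range")
    key = np.array(
        [np.uint64(seed & (2**64 - 1)), np.uint64((stream << _ROW_BITS) | row)],
        dtype=np.uint64,
    )
    return np.random.Generator(np.random.Philox(key=key))


def row_block_normal(
    seed: int, stream: int, start: int, stop: int, n_cols: int, scale: float = 1.0
) -> np.ndarray:
    """Standard-normal block for rows [start, stop), one keyed stream per row.

    Bit-identical to generating the same rows in any other chunking.
    """
    out = np.empty((stop - start, n_cols), dtype=np.float64)
    for i, row in enumerate(range(start, stop)):
        out[i] = row_rng(seed, stream, row).standard_normal(n_cols)
    if scale != 1.0:
        out *= scale
    return out


def rows_normal(seed: int, stream: int, rows: np.ndarray, n_cols: int) -> np.ndarray:
    """Standard-normal draws for an arbitrary set of row indices."""
    rows = np.asarray(rows, dtype=np.int64)
    out = np.empty((rows.size, n_cols), dtype=np.float64)
    for i, row in enumerate(rows):
        out[i] = row_rng(seed, stream, int(row)).standard_normal(n_cols)
    return out
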