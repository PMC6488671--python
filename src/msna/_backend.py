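"""Injectable map backends for the per-key parallel stages.

The parallel contract is a pure, deterministic map over an ordered key list
(segment keys for pairwise alignment, prefix keys for partitioned suffix-tree
construction); results are combined in key order, so the output is identical
for any degree of parallelism.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from typing import Callable, Iterable

__all__ = ["serial_backend", "ProcessPoolBackend", "make_backend"]


def serial_backend(func: Callable, items: Iterable) -> list:
    return [func(item) for item in items]


class ProcessPoolBackend:
    """Process-pool map preserving input order (results keyed by position)."""

    def __init__(self, workers: int):
        if workers < 1:
            raise ValueError("workers must be >= 1")
        self.workers = workers

    def __call__(self, func: Callable, items: Iterable) -> list:
        items = list(items)
        if not items:
            return []
        chunksize = max(1, len(items) // (4 * self.workers))
        with ProcessPoolExecutor(max_workers=self.workers) as pool:
            return list(pool.map(func, items, chunksize=chunksize))


def make_backend(workers: int) -> Callable[[Callable, Iterable], list]:
    return serial_backend if workers <= 1 else ProcessPoolBackend(workers)
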