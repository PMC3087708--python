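"""Virtual 1% agarose gel electrophoresis.

DNA migration in agarose is close to linear in the logarithm of fragment
size over the usual analytic range, so the model computes a relative
mobility ``r(L) = a + b*log10(L + c)`` with empirical constants fitted to
1% gels, anchors it to the measured migration of a known marker band
(the 2000 bp band of a standard ladder by default), and asks whether two
predicted products would land close enough (< ``m_min_mm``) to read as a
single band by eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, TypeVar

T = TypeVar("T")


@dataclass(frozen=True)
class GelConfig:
    """Empirical mobility model and resolution limit for a 1% agarose gel.

    ``a``, ``b``, ``c`` parameterize the semi-log mobility curve;
    ``marker_migration_mm`` is the observed migration of the
    ``marker_size_bp`` calibration band; ``m_min_mm`` is the smallest
    band separation distinguishable by eye.
    """

    a: float = 4.61
    b: float = -0.72
    c: float = 474.65
    marker_size_bp: int = 2000
    marker_migration_mm: float = 50.0
    m_min_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.m_min_mm <= 0:
            raise ValueError("m_min_mm must be positive")
        if self.marker_migration_mm <= 0:
            raise ValueError("marker_migration_mm must be positive")
        if self.marker_size_bp < 1:
            raise ValueError("marker_size_bp must be >= 1")
        # the relative-mobility curve must stay positive over the range of
        # amplifiable products, otherwise distances are meaningless
        for size in (50, 10_000, self.marker_size_bp):
            if self._r(size) <= 0:
                raise ValueError(
                    f"gel constants give non-positive mobility at {size} bp"
                )

    def _r(self, size_bp: float) -> float:
        return self.a + self.b * math.log10(size_bp + self.c)


DEFAULT_GEL = GelConfig()


def mobility(size_bp: int, cfg: GelConfig = DEFAULT_GEL) -> float:
    """Predicted migration distance (mm) of a fragment of ``size_bp``.

    Strictly decreasing in size; exactly ``cfg.marker_migration_mm`` at
    the calibration size.
    """
    if size_bp <= 0:
        raise ValueError(f"fragment size must be positive, got {size_bp}")
    return cfg.marker_migration_mm * cfg._r(size_bp) / cfg._r(cfg.marker_size_bp)


def migration_distance(size_i: int, size_j: int, cfg: GelConfig = DEFAULT_GEL) -> float:
    """Absolute difference (mm) between the two fragments' migrations."""
    return abs(mobility(size_i, cfg) - mobility(size_j, cfg))


def comigrating_groups(
    amplicons: Sequence[T],
    cfg: GelConfig = DEFAULT_GEL,
    size_of: Callable[[T], int] | None = None,
) -> list[list[T]]:
    """Partition fragments into bands indistinguishable by eye.

    Two fragments co-migrate when their migration distance is below
    ``cfg.m_min_mm``; groups are the connected components of the
    co-migration graph, so a chain of pairwise-close sizes collapses into
    one band. Singleton groups are cleanly resolvable bands. The
    partition is independent of input order; groups and members are
    returned in input order.
    """
    if size_of is None:
        size_of = lambda a: a.size if hasattr(a, "size") else int(a)  # noqa: E731
    n = len(amplicons)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sizes = [size_of(a) for a in amplicons]
    for i in range(n):
        for j in range(i + 1, n):
            if migration_distance(sizes[i], sizes[j], cfg) < cfg.m_min_mm:
                parent[find(i)] = find(j)
    groups: dict[int, list[T]] = {}
    order: list[int] = []
    for i in range(n):
        root = find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(amplicons[i])
    return [groups[r] for r in order]
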