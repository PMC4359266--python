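"""Canonical protein-pair handling.

An interaction is an unordered pair of distinct protein identifiers. Every
module in the package stores pairs canonically: as a 2-tuple whose first
element precedes the second in lexicographic order, so that ``(x, y)`` and
``(y, x)`` compare (and hash) equal. Self-pairs are never valid interactions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

ProteinPair = tuple[str, str]


class SelfPairError(ValueError):
    """Raised when a self-interaction is passed where a pair is required."""


def canonical_pair(a: str, b: str) -> ProteinPair:
    """Return the canonical (lexicographically ordered) form of a pair.

    Raises
    ------
    SelfPairError
        If ``a == b``; self-interactions are excluded throughout.
    """
    if a == b:
        raise SelfPairError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def iter_canonical(
    pairs: Iterable[tuple[str, str]], *, drop_self: bool = True
) -> Iterator[ProteinPair]:
    """Yield canonicalized pairs, dropping self-pairs with a logged warning.

    With ``drop_self=False`` a self-pair raises :class:`SelfPairError`
    instead of being skipped.
    """
    n_self = 0
    for a, b in pairs:
        if a == b:
            if not drop_self:
                raise SelfPairError(f"self-pair not allowed: {a!r}")
            n_self += 1
            continue
        yield (a, b) if a < b else (b, a)
    if n_self:
        logger.warning("dropped %d self-pair(s)", n_self)


def canonical_pair_set(
    pairs: Iterable[tuple[str, str]], *, drop_self: bool = True
) -> set[ProteinPair]:
    """Canonicalize and deduplicate a collection of pairs."""
    return set(iter_canonical(pairs, drop_self=drop_self))
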