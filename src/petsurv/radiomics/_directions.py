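"""The 13 unique distance-1 directions in 3D (half of the 26 neighbours)."""

from __future__ import annotations

import itertools

#: One representative per +/- direction pair, lexicographically positive.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

assert len(DIRECTIONS_13) == 13
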