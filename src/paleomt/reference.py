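"""Reference coordinate-system constants for the human mtDNA (rCRS).

All genomic positions in this package are 1-based coordinates on the
16,569-bp circular revised Cambridge Reference Sequence. The D-loop
(control region) wraps the origin; the default bounds below are the
conventional rCRS control-region intervals and are configurable wherever
they are consumed.
"""

from __future__ import annotations

MT_LENGTH = 16_569

#: Control-region (D-loop) intervals, 1-based inclusive. The region wraps
#: the circular origin, hence two intervals.
DLOOP_BOUNDS: tuple[tuple[int, int], ...] = ((16_024, 16_569), (1, 576))

BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def wrap_position(pos: int, length: int = MT_LENGTH) -> int:
    """Map an arbitrary integer onto the 1-based circular coordinate system."""
    return (pos - 1) % length + 1
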