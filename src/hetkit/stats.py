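"""Assembly length statistics (Nx values by the textbook definition)."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np


def nx(lengths: Sequence[int], x: float) -> int:
    """Smallest length L such that records >= L cover x% of the total."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if len(lengths) == 0:
        return 0
    lens = np.sort(np.asarray(lengths))[::-1]
    target = lens.sum() * (x / 100.0)
    cum = np.cumsum(lens)
    return int(lens[np.searchsorted(cum, target)])


def assembly_stats(lengths: Sequence[int]) -> Dict[str, int]:
    lens = list(lengths)
    return {
        "n_sequences": len(lens),
        "N90": nx(lens, 90),
        "N50": nx(lens, 50),
        "N10": nx(lens, 10),
        "sum_length": int(sum(lens)),
        "max_length": int(max(lens)) if lens else 0,
    }
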