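"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Python's built-in ``round`` rounds half to even; printed integer
    percentages in the literature almost always use half-away-from-zero,
    so every integer percent reported by this package goes through here.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def int_percent(numerator: float, denominator: float) -> int:
    """``round_half_away(100 * numerator / denominator)``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * numerator / denominator)


def sample_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for stream ``stream`` under top-level ``seed``.

    Streams are keyed by identity (e.g. a sample's column index), not by
    call order, so results do not depend on the order operations run in.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))
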