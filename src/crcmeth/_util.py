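"""Small shared numerics: logit transforms, RNG stream spawning, rounding."""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (re-exported)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into ``n`` independent deterministic streams."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (display convention for percentages)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class ValidationError(ValueError):
    """Invalid configuration or input data (CLI exits with code 2)."""
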