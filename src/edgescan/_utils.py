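"""Shared numerical helpers and seeded random-stream management."""

from __future__ import annotations

import numpy as np

# Stage names double as stable substream labels so that adding a stage never
# perturbs the draws of an existing one.
_STAGE_OFFSETS = {
    "genotypes": 1,
    "exposure": 2,
    "covariates": 3,
    "disease": 4,
    "sampling": 5,
    "noise": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named pipeline stage derived from one seed."""
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown rng stage {stage!r}")
    ss = np.random.SeedSequence([int(seed), _STAGE_OFFSETS[stage]])
    return np.random.default_rng(ss)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
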