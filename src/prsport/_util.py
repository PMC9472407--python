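"""Shared validation helpers and seeded RNG fan-out."""

from __future__ import annotations

import numpy as np

#: Stage names recognised by :func:`stage_rng`.  A single user-facing seed
#: fans out to independent per-stage streams through
#: ``SeedSequence(seed, spawn_key=(counter,))`` with the counters below, so
#: adding draws to one stage never perturbs another.
STAGE_COUNTERS = {
    "frequencies": 0,
    "genotypes": 1,
    "phenotypes": 2,
    "aggressiveness": 3,
    "missingness": 4,
    "haplotypes": 5,
    "ages": 6,
    "proxies": 7,
    "downsample": 8,
    "scores": 9,
}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Return the RNG for ``stage`` (and optional replicate ``index``).

    Deterministic: the same ``(seed, stage, index)`` triple always yields an
    identical stream.
    """
    try:
        counter = STAGE_COUNTERS[stage]
    except KeyError:
        raise ValidationError(
            f"unknown stage {stage!r}; known: {sorted(STAGE_COUNTERS)}"
        ) from None
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(counter, index))
    return np.random.default_rng(ss)


def check_probability(value: float, name: str, *, open_left: bool = False,
                      open_right: bool = False) -> float:
    """Validate a scalar probability-like parameter and return it as float."""
    value = float(value)
    if not np.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value}")
    lo_ok = value > 0.0 if open_left else value >= 0.0
    hi_ok = value < 1.0 if open_right else value <= 1.0
    if not (lo_ok and hi_ok):
        lo = "(" if open_left else "["
        hi = ")" if open_right else "]"
        raise ValidationError(f"{name} must lie in {lo}0, 1{hi}, got {value}")
    return value


def as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr
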