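"""Capped multinomial allocation of severity points across items."""

from __future__ import annotations

import numpy as np


def allocate_excess(
    budget: int, weights: np.ndarray, caps: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Distribute ``budget`` integer units over items with per-item caps,
    in expectation proportional to ``weights``.  Exact sum or ValueError."""
    weights = np.asarray(weights, dtype=float)
    caps = np.asarray(caps, dtype=int)
    if budget < 0 or budget > caps.sum():
        raise ValueError(f"budget {budget} infeasible for caps summing {caps.sum()}")
    if budget == 0:
        return np.zeros_like(caps)
    w = np.maximum(weights, 0.02)  # every item keeps a floor probability
    out = rng.multinomial(budget, w / w.sum())
    # push overflow above caps back onto items with headroom
    for _ in range(64):
        over = np.maximum(out - caps, 0)
        if not over.any():
            break
        out = np.minimum(out, caps)
        head = caps - out
        p = np.where(head > 0, w, 0.0)
        out += rng.multinomial(int(over.sum()), p / p.sum())
    out = np.minimum(out, caps)
    short = budget - int(out.sum())
    while short > 0:  # deterministic tidy-up
        head = np.flatnonzero(caps - out > 0)
        i = head[rng.integers(head.size)]
        out[i] += 1
        short -= 1
    return out


def bounded_adjust_sum(
    scores: np.ndarray,
    lows: np.ndarray,
    highs: np.ndarray,
    lo_target: int,
    hi_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Nudge scores within [lows, highs] until their sum lies in
    [lo_target, hi_target]; raises if the window is unreachable."""
    if lo_target > highs.sum() or hi_target < lows.sum():
        raise ValueError("target window unreachable within score bounds")
    scores = scores.copy()
    while scores.sum() > hi_target:
        cand = np.flatnonzero(scores > lows)
        scores[cand[rng.integers(cand.size)]] -= 1
    while scores.sum() < lo_target:
        cand = np.flatnonzero(scores < highs)
        scores[cand[rng.integers(cand.size)]] += 1
    return scores
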