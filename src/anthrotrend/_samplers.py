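"""Univariate slice sampling (stepping-out and shrinkage procedure)."""

from __future__ import annotations

import numpy as np


def slice_sample(logf, x0: float, rng: np.random.Generator,
                 width: float = 1.0, max_steps: int = 50) -> float:
    """One slice-sampling update of a univariate log-density ``logf``.

    ``logf`` may return ``-inf`` outside its support; ``x0`` must have
    finite density.
    """
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice sampler started outside the support")
    y = f0 - rng.exponential()
    left = x0 - width * rng.uniform()
    right = left + width
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and logf(left) > y:
        left -= width
        j -= 1
    while k > 0 and logf(right) > y:
        right += width
        k -= 1
    for _ in range(1000):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return float(x1)
        if x1 < x0:
            left = x1
        else:
            right = x1
    return float(x0)  # pathological shrinkage; keep current point
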