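"""Empirical extreme-value (Gumbel) calibration of alignment scores.

Raw local-alignment and profile scores are converted to E-values by fitting
a type-I extreme value distribution to scores of shuffled / random decoys:

    P(S >= s) = 1 - exp(-exp(-lambda * (s - mu)))
    E(s)      = n_comparisons * P(S >= s)

with ``lambda = 1/beta`` the inverse Gumbel scale. E-values are floored at
1e-200 so that -log10(E) edge weights stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gumbel_r

EVALUE_FLOOR = 1e-200


@dataclass(frozen=True)
class EVDParams:
    """Location/scale of a fitted Gumbel null-score distribution."""

    mu: float
    lam: float  # 1 / beta
    n_samples: int = 0
    seed: int | None = None

    @property
    def beta(self) -> float:
        return 1.0 / self.lam


def fit_gumbel(scores, n_samples: int | None = None, seed: int | None = None) -> EVDParams:
    """Maximum-likelihood Gumbel fit of a null score sample.

    Raises ``ValueError`` for a degenerate (constant) sample, which cannot
    anchor a scale parameter — draw more decoys.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        raise ValueError(
            "degenerate null score distribution (all scores equal); "
            "increase the number of decoys"
        )
    loc, scale = gumbel_r.fit(scores)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("Gumbel fit failed to produce a positive scale")
    return EVDParams(mu=float(loc), lam=1.0 / float(scale),
                     n_samples=n_samples or scores.size, seed=seed)


def evalue_from_score(score: float, evd: EVDParams, n_comparisons: int) -> float:
    """E-value of a score under a fitted Gumbel null.

    Strictly decreasing in ``score``; floored at 1e-200.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    x = -evd.lam * (score - evd.mu)
    # P(S >= s) = 1 - exp(-exp(x)); -expm1 keeps precision for tiny tails.
    tail = -np.expm1(-np.exp(x))
    return float(max(n_comparisons * tail, EVALUE_FLOOR))
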