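"""Correlating the %NAC docking statistic with experimental % reactivation.

With only a handful of oximes per enzyme (six here), asymptotic p-values for
Pearson's r are unreliable; the association is instead tested with a
permutation test on |r| — exact (all n! pairings enumerated) for small n,
seeded Monte-Carlo otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "correlate", "permutation_pvalue"]


@dataclass(frozen=True)
class CorrelationResult:
    """OLS line and Pearson r for paired (%NAC, %R) values."""

    n_pairs: int
    slope: float
    intercept: float
    pearson_r: float
    p_perm: Optional[float] = None
    degenerate: bool = False
    pairs: tuple = ()

    def __post_init__(self) -> None:
        if not self.degenerate and not abs(self.pearson_r) <= 1 + 1e-12:
            raise ValueError("|r| must be ≤ 1")


def _split(pairs: Sequence[Tuple[float, float]]):
    x = np.asarray([p[-2] for p in pairs], dtype=float)
    y = np.asarray([p[-1] for p in pairs], dtype=float)
    return x, y


def correlate(pairs: Sequence[Tuple[float, float]]) -> CorrelationResult:
    """OLS slope/intercept and Pearson r for ≥ 3 (x, y) pairs.

    Pairs may be (x, y) or (label, x, y); labels are carried through.  Zero
    variance in either variable makes r undefined — the result is flagged
    ``degenerate`` with r = nan rather than raising.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    x, y = _split(pairs)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pairs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            n_pairs=len(pairs),
            slope=float("nan"),
            intercept=float("nan"),
            pearson_r=float("nan"),
            degenerate=True,
            pairs=tuple(tuple(p) for p in pairs),
        )
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n_pairs=len(pairs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        pairs=tuple(tuple(p) for p in pairs),
    )


def _perm_rs(x: np.ndarray, y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson r of x against every row-permutation of y (vectorized).

    Permuting y changes neither its mean nor its norm, so
    r = Σ x_c·y_perm_c / (‖x_c‖‖y_c‖) with centred vectors.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    return (yc[perms] @ xc) / denom


def permutation_pvalue(
    pairs: Sequence[Tuple[float, float]],
    max_exact: int = 5040,
    n_mc: int = 10000,
    seed: Optional[int] = None,
) -> float:
    """Two-sided permutation p-value for |Pearson r|.

    All n! pairings are enumerated when n! ≤ ``max_exact`` (deterministic
    and order-independent); otherwise ``n_mc`` random permutations are drawn
    from a generator seeded with ``seed``, with the add-one correction
    (count+1)/(n_mc+1).  Degenerate variance yields p = 1.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x, y = _split(pairs)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0
    n = len(x)
    r_obs = abs(_perm_rs(x, y, np.arange(n)[None, :])[0])
    tol = 1e-12
    if math.factorial(n) <= max_exact:
        perms = np.array(list(itertools.permutations(range(n))))
        rs = np.abs(_perm_rs(x, y, perms))
        return float(np.sum(rs >= r_obs - tol) / len(perms))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_mc)])
    rs = np.abs(_perm_rs(x, y, perms))
    return float((np.sum(rs >= r_obs - tol) + 1) / (n_mc + 1))
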