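"""Abundance-based richness estimation and rarefaction/extrapolation.

Implements the Chao1 lower-bound richness estimator (bias-corrected by
default), the abundance-based sample-coverage estimate, and individual-based
interpolation/extrapolation of species accumulation with bootstrap
confidence bands.

Notation: for an abundance vector with total count n, S_obs observed taxa,
f1 singletons and f2 doubletons,

    S_chao1 = S_obs + f1 (f1 - 1) / (2 (f2 + 1))                (bias-corrected)
    coverage = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]
    E[S(m)]  = S_obs - sum_i C(n - x_i, m) / C(n, m)            (m <= n)
    S(n+m*)  = S_obs + f0 * [1 - (1 - f1 / (n f0 + f1))^{m*}]   (f0 = S_chao1 - S_obs)
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ContractError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AbundanceVector:
    counts: tuple[int, ...]

    @classmethod
    def from_counts(cls, counts: Iterable[int] | Mapping[str, int]) -> "AbundanceVector":
        if isinstance(counts, Mapping):
            counts = counts.values()
        vals = tuple(int(c) for c in counts if c > 0)
        return cls(vals)

    @classmethod
    def from_observations(cls, taxa: Iterable[str]) -> "AbundanceVector":
        return cls.from_counts(Counter(taxa))

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts if c == 2)


@dataclass(frozen=True)
class DiversityEstimate:
    s_obs: int
    s_chao1: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def observed_over_chao(self) -> float:
        """Observed richness as a fraction of the asymptotic estimate."""
        return self.s_obs / self.s_chao1 if self.s_chao1 else float("nan")


def chao1(v: AbundanceVector, bias_corrected: bool = True) -> DiversityEstimate:
    """Chao1 asymptotic richness with analytic variance and log-normal CI.

    The bias-corrected form f1(f1-1)/(2(f2+1)) is the default and remains
    finite when f2 = 0; ``bias_corrected=False`` selects the classic
    f1^2/(2 f2) form (falling back to the corrected one when f2 = 0).
    """
    if v.n < 1:
        raise ContractError("chao1: empty abundance vector")
    s, f1, f2 = v.s_obs, v.f1, v.f2
    if f1 == 0:
        return DiversityEstimate(s, float(s), 0.0, float(s), float(s))
    if bias_corrected or f2 == 0:
        t = f1 * (f1 - 1) / (2.0 * (f2 + 1))
        var = (f1 * (f1 - 1) / (2.0 * (f2 + 1))
               + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
               + f1 ** 2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4))
    else:
        r = f1 / f2
        t = f1 ** 2 / (2.0 * f2)
        var = f2 * (r ** 2 / 2.0 + r ** 3 + r ** 4 / 4.0)
    est = s + t
    if t > 0 and var > 0:
        k = np.exp(Z95 * np.sqrt(np.log1p(var / t ** 2)))
        lo, hi = s + t / k, s + t * k
    else:
        lo = hi = est
    return DiversityEstimate(s, est, float(np.sqrt(var)), float(lo), float(hi))


def sample_coverage(v: AbundanceVector) -> float:
    """Estimated fraction of individuals belonging to already-seen taxa."""
    n, f1, f2 = v.n, v.f1, v.f2
    if n < 2:
        raise ContractError("sample_coverage requires n >= 2")
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)


def _interpolate(counts: np.ndarray, n: int, m: np.ndarray) -> np.ndarray:
    """E[S(m)] for m <= n, vectorised over m via log-gamma ratios."""
    s_obs = counts.size
    # ratio C(n - x_i, m) / C(n, m), zero when m > n - x_i
    nx = (n - counts)[:, None].astype(float)  # (S, 1)
    mm = m[None, :].astype(float)  # (1, M)
    with np.errstate(invalid="ignore"):
        logratio = (gammaln(nx + 1) + gammaln(n - mm + 1)
                    - gammaln(n + 1) - gammaln(nx - mm + 1))
    ratio = np.where(mm <= nx, np.exp(logratio), 0.0)
    return s_obs - ratio.sum(axis=0)


def _extrapolate(v_sobs: int, f1: int, f0: float, n: int, mstar: np.ndarray) -> np.ndarray:
    if f1 == 0 or f0 <= 0:
        return np.full(mstar.shape, float(v_sobs))
    rate = 1.0 - f1 / (n * f0 + f1)
    return v_sobs + f0 * (1.0 - rate ** mstar.astype(float))


@dataclass
class RarefactionCurve:
    table: pd.DataFrame  # columns m, estimate, lo95, hi95, method

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rarefy_extrapolate(v: AbundanceVector, sizes: Sequence[int] | None = None,
                       n_bootstrap: int = 1000, seed: int = 0,
                       bias_corrected: bool = True) -> RarefactionCurve:
    """Accumulation curve with 95% bootstrap confidence band.

    Interpolation uses the exact hypergeometric expectation; extrapolation
    (default up to double the sample size) uses the Chao1 estimate of
    undetected richness. Sizes beyond 2n are computed with a warning in the
    log (outside the usual doubling rule).
    """
    n = v.n
    if n < 1:
        raise ContractError("rarefy_extrapolate: empty abundance vector")
    if sizes is None:
        sizes = range(1, 2 * n + 1)
    m = np.asarray(sorted(set(int(s) for s in sizes)), dtype=int)
    if (m < 1).any():
        raise ContractError("sizes must be >= 1")
    if (m > 2 * n).any():
        import logging

        logging.getLogger(__name__).warning(
            "extrapolating beyond double the collection size (max m=%d > 2n=%d)", m.max(), 2 * n)

    def curve(counts: np.ndarray) -> np.ndarray:
        counts = counts[counts > 0]
        nn = int(counts.sum())
        vv = AbundanceVector(tuple(int(c) for c in counts))
        f0 = chao1(vv, bias_corrected=bias_corrected).s_chao1 - vv.s_obs
        out = np.empty(m.shape, dtype=float)
        interp = m <= nn
        if interp.any():
            out[interp] = _interpolate(counts.astype(int), nn, m[interp])
        if (~interp).any():
            out[~interp] = _extrapolate(vv.s_obs, vv.f1, f0, nn, m[~interp] - nn)
        return out

    base_counts = np.asarray(v.counts, dtype=int)
    est = curve(base_counts)
    rng = np.random.default_rng(seed)
    p = base_counts / n
    boot = np.empty((n_bootstrap, m.size), dtype=float)
    for b in range(n_bootstrap):
        boot[b] = curve(rng.multinomial(n, p))
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    table = pd.DataFrame({
        "m": m,
        "estimate": est,
        "lo95": np.minimum(lo, est),
        "hi95": np.maximum(hi, est),
        "method": np.where(m <= n, "interp", "extrap"),
    })
    return RarefactionCurve(table)
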