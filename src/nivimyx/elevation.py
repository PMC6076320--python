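"""Elevational belts, per-taxon abundance profiles, and the inventory shift test.

Records are binned into 100 m belts spanning 1,100-1,900 m a.s.l. (eight
belts by default); observations outside the range are clamped to the first
or last belt. Per-taxon profiles are belt abundances optionally square-root
transformed and scaled to the per-taxon maximum. The fruit-vs-soil shift in
mean occurrence elevation is tested across shared taxa with a two-sided
paired t-test and, optionally, a seeded sign-flip permutation test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeltScheme:
    base: float = 1100.0
    width: float = 100.0
    n_belts: int = 8
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_belts < 1:
            raise ContractError("BeltScheme requires width > 0 and n_belts >= 1")

    def midpoint(self, belt: int) -> float:
        return self.base + (belt - 0.5) * self.width

    @property
    def midpoints(self) -> np.ndarray:
        return self.base + (np.arange(1, self.n_belts + 1) - 0.5) * self.width


def assign_belt(elevation: float, scheme: BeltScheme | None = None) -> int:
    """Belt index in 1..n_belts; half-open intervals [base+(k-1)w, base+kw)."""
    scheme = scheme or BeltScheme()
    if not np.isfinite(elevation):
        raise DataError(f"non-finite elevation {elevation}")
    k = int(np.floor((elevation - scheme.base) / scheme.width)) + 1
    if 1 <= k <= scheme.n_belts:
        return k
    if scheme.clamp:
        return 1 if k < 1 else scheme.n_belts
    raise DataError(f"elevation {elevation} outside belts and clamp=false")


@dataclass
class ElevationProfile:
    taxon: str
    abundance: np.ndarray  # raw per-belt abundance
    scaled: np.ndarray  # transformed then divided by the per-taxon maximum
    transform: str = "none"


def build_profiles(observations: pd.DataFrame, scheme: BeltScheme | None = None,
                   transform: str = "none") -> list[ElevationProfile]:
    """Per-taxon belt profiles from a tidy frame (taxon, elevation_m, abundance).

    ``transform`` in {"none", "sqrt"} is applied before scaling to the
    per-taxon maximum (so scaled values lie in [0, 1] with at least one 1).
    Taxa whose total abundance is zero are dropped with a warning.
    """
    scheme = scheme or BeltScheme()
    if transform not in ("none", "sqrt"):
        raise ContractError(f"unknown transform {transform!r}")
    req = {"taxon", "elevation_m", "abundance"}
    if not req <= set(observations.columns):
        raise ContractError(f"observations must have columns {sorted(req)}")
    profiles = []
    for taxon, grp in observations.groupby("taxon", sort=True):
        counts = np.zeros(scheme.n_belts)
        for elev, ab in zip(grp["elevation_m"], grp["abundance"]):
            counts[assign_belt(float(elev), scheme) - 1] += ab
        if counts.sum() <= 0:
            log.warning("taxon %s has zero abundance; dropped", taxon)
            continue
        x = np.sqrt(counts) if transform == "sqrt" else counts.copy()
        profiles.append(ElevationProfile(str(taxon), counts, x / x.max(), transform))
    return profiles


def profiles_to_frame(profiles: list[ElevationProfile], scheme: BeltScheme | None = None,
                      scaled: bool = False) -> pd.DataFrame:
    scheme = scheme or BeltScheme()
    cols = [f"belt_{k}" for k in range(1, scheme.n_belts + 1)]
    data = {p.taxon: (p.scaled if scaled else p.abundance) for p in profiles}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def weighted_mean_elevation(profile: ElevationProfile, scheme: BeltScheme | None = None) -> float:
    """Abundance-weighted mean of belt midpoints (raw abundances)."""
    scheme = scheme or BeltScheme()
    w = profile.abundance
    return float(np.average(scheme.midpoints, weights=w))


@dataclass
class ShiftTest:
    per_taxon: pd.DataFrame  # taxon, fruit_mean_m, soil_mean_m, shift_m
    fruit_mean: float
    fruit_sd: float
    soil_mean: float
    soil_sd: float
    mean_shift: float
    p_paired_t: float
    p_permutation: float | None = None
    n_taxa: int = 0


def mean_elevation_shift(fruit_profiles: list[ElevationProfile],
                         soil_profiles: list[ElevationProfile],
                         shared_taxa: list[str] | None = None,
                         scheme: BeltScheme | None = None,
                         method: str = "paired-t",
                         n_permutations: int = 10000,
                         seed: int = 0) -> ShiftTest:
    """Paired comparison of per-taxon mean elevations between inventories.

    ``method`` selects the headline p-value; both the paired t p-value and
    (when requested) the sign-flip permutation p-value are reported.
    """
    scheme = scheme or BeltScheme()
    fr = {p.taxon: p for p in fruit_profiles}
    so = {p.taxon: p for p in soil_profiles}
    taxa = sorted(shared_taxa if shared_taxa is not None else set(fr) & set(so))
    taxa = [t for t in taxa if t in fr and t in so]
    if len(taxa) < 2:
        raise ContractError("mean_elevation_shift requires >= 2 shared taxa")
    fmeans = np.array([weighted_mean_elevation(fr[t], scheme) for t in taxa])
    smeans = np.array([weighted_mean_elevation(so[t], scheme) for t in taxa])
    diffs = smeans - fmeans
    t_p = float(stats.ttest_rel(smeans, fmeans).pvalue) if np.ptp(diffs) > 0 else 1.0
    p_perm = None
    if method == "permutation" or n_permutations:
        rng = np.random.default_rng(seed)
        obs = abs(diffs.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, diffs.size))
        null = np.abs((signs * diffs).mean(axis=1))
        p_perm = float((np.sum(null >= obs - 1e-12) + 1) / (n_permutations + 1))
    table = pd.DataFrame({
        "taxon": taxa,
        "fruit_mean_m": fmeans,
        "soil_mean_m": smeans,
        "shift_m": diffs,
    })
    return ShiftTest(
        per_taxon=table,
        fruit_mean=float(fmeans.mean()), fruit_sd=float(fmeans.std(ddof=1)),
        soil_mean=float(smeans.mean()), soil_sd=float(smeans.std(ddof=1)),
        mean_shift=float(diffs.mean()),
        p_paired_t=t_p,
        p_permutation=p_perm,
        n_taxa=len(taxa),
    )


def correlate_with_elevation(values, elevations) -> tuple[float, float] | None:
    """Pearson r with two-sided t-distribution p; None when variance is zero."""
    x = np.asarray(values, dtype=float)
    e = np.asarray(elevations, dtype=float)
    if x.size != e.size or x.size < 3:
        raise ContractError("correlate_with_elevation requires >= 3 paired sites")
    if np.ptp(x) == 0 or np.ptp(e) == 0:
        return None
    r, p = stats.pearsonr(x, e)
    return float(r), float(p)
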