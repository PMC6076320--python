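"""Cross-inventory matching of fruit-body ribotypes to soil OTUs and summaries.

Each fruit-body ribotype is compared with every soil OTU representative and
classified as *exact* (best identity 1.0), *near* (>= the OTU-picking
threshold, 99.1%, but below 1.0) or *unmatched* (below the threshold); the
three categories partition the ribotype set. Cluster-level rollups, per-site
shared/unique counts, genus composition and year-overlap summaries mirror
the standard reporting of fruit-body vs metabarcoding comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import RibotypeCluster
from .errors import ContractError
from .otu import OtuTable
from .sequences import Ribotype, SequenceRecord, global_identity

EXACT = "exact"
NEAR = "near"
UNMATCHED = "unmatched"


@dataclass
class MatchResult:
    ribotype_id: str
    category: str
    best_soil_otu: str
    best_identity: float
    n_specimens: int


@dataclass
class MatchReport:
    results: list[MatchResult]
    n_exact: int
    n_near: int
    n_unmatched: int
    unmatched_identity_mean: float | None
    unmatched_identity_sd: float | None
    unmatched_identity_range: tuple[float, float] | None
    cluster_matched: dict[str, bool] = field(default_factory=dict)

    @property
    def n_ribotypes(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "ribotype_id": r.ribotype_id,
            "category": r.category,
            "best_soil_otu": r.best_soil_otu,
            "best_identity": r.best_identity,
            "n_specimens": r.n_specimens,
        } for r in self.results])


def _soil_seqs(soil: OtuTable | Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    if isinstance(soil, OtuTable):
        return [(o, soil.rep_seqs[o]) for o in soil.otu_ids]
    return list(soil)


def best_soil_match(sequence: str, soil_seqs: Sequence[tuple[str, str]]) -> tuple[str, float]:
    best_otu, best_ident = None, -1.0
    for otu_id, seq in sorted(soil_seqs):
        ident = global_identity(sequence, seq).identity
        if ident > best_ident:
            best_otu, best_ident = otu_id, ident
    return best_otu, best_ident


def match_inventories(fruit_ribotypes: Sequence[Ribotype],
                      soil: OtuTable | Sequence[tuple[str, str]],
                      near_threshold: float = 0.991,
                      clusters: Sequence[RibotypeCluster] | None = None) -> MatchReport:
    """Classify every fruit ribotype by its best identity to a soil OTU.

    Also reports mean +- sd and range of the best identity over unmatched
    ribotypes, and (when clusters are given) a cluster-level rollup where a
    cluster counts as matched if any member ribotype is exact or near.
    """
    soil_seqs = _soil_seqs(soil)
    if not fruit_ribotypes or not soil_seqs:
        raise ContractError("match_inventories: both inventories must be nonempty")
    results = []
    for rt in fruit_ribotypes:
        otu_id, ident = best_soil_match(rt.sequence, soil_seqs)
        if ident >= 1.0:
            cat = EXACT
        elif ident >= near_threshold:
            cat = NEAR
        else:
            cat = UNMATCHED
        results.append(MatchResult(rt.id, cat, otu_id, ident, rt.abundance))
    un = [r.best_identity for r in results if r.category == UNMATCHED]
    rollup: dict[str, bool] = {}
    if clusters is not None:
        by_rt = {r.ribotype_id: r.category for r in results}
        for cl in clusters:
            rollup[cl.cluster_id] = any(by_rt.get(m) in (EXACT, NEAR) for m in cl.member_ids)
    return MatchReport(
        results=results,
        n_exact=sum(r.category == EXACT for r in results),
        n_near=sum(r.category == NEAR for r in results),
        n_unmatched=len(un),
        unmatched_identity_mean=float(np.mean(un)) if un else None,
        unmatched_identity_sd=float(np.std(un, ddof=1)) if len(un) > 1 else None,
        unmatched_identity_range=(float(min(un)), float(max(un))) if un else None,
        cluster_matched=rollup,
    )


@dataclass
class SiteSharing:
    table: pd.DataFrame  # site, n_sequenced, n_unique_ribotypes, n_shared
    r_unique: float | None
    p_unique: float | None
    r_shared: float | None
    p_shared: float | None


def shared_unique_per_site(records: Sequence[SequenceRecord],
                           soil: OtuTable | Sequence[tuple[str, str]],
                           threshold: float = 0.991) -> SiteSharing:
    """Per-site unique vs soil-shared ribotype counts and their correlation
    with the number of specimens sequenced from the site."""
    soil_seqs = _soil_seqs(soil)
    sites = sorted({r.site for r in records if r.site is not None})
    if len(sites) < 3:
        raise ContractError("shared_unique_per_site requires >= 3 sites")
    shared_cache: dict[str, bool] = {}

    def is_shared(seq: str) -> bool:
        if seq not in shared_cache:
            _, ident = best_soil_match(seq, soil_seqs)
            shared_cache[seq] = ident >= threshold
        return shared_cache[seq]

    rows = []
    for site in sites:
        recs = [r for r in records if r.site == site]
        seqs = {r.sequence for r in recs}
        rows.append({
            "site": site,
            "n_sequenced": sum(r.abundance for r in recs),
            "n_unique_ribotypes": len(seqs),
            "n_shared": sum(1 for s in seqs if is_shared(s)),
        })
    tab = pd.DataFrame(rows)

    def corr(col: str):
        x, y = tab["n_sequenced"].to_numpy(float), tab[col].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return None, None
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_u, p_u = corr("n_unique_ribotypes")
    r_s, p_s = corr("n_shared")
    return SiteSharing(tab, r_u, p_u, r_s, p_s)


def genus_composition(items: Iterable[tuple[str, int]],
                      nivicolous: dict[str, bool] | None = None,
                      nivicolous_only: bool = False) -> pd.DataFrame:
    """Per-genus abundance table from (genus, abundance) pairs.

    ``nivicolous`` maps genus -> flag for the nivicolous-only option.
    Fractions sum to 1 for a nonempty table; rows sorted by decreasing count.
    """
    counts: dict[str, int] = {}
    for genus, ab in items:
        if genus is None:
            continue
        if nivicolous_only and nivicolous is not None and not nivicolous.get(genus, True):
            continue
        counts[genus] = counts.get(genus, 0) + int(ab)
    if not counts:
        return pd.DataFrame(columns=["genus", "count", "fraction"])
    tab = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                       columns=["genus", "count"])
    tab["fraction"] = tab["count"] / tab["count"].sum()
    return tab


def year_overlap(records: Sequence[SequenceRecord],
                 exclude_years: Sequence[int] = ()) -> dict:
    """Morphospecies sets per year plus Venn-style region counts.

    Returns ``{"per_year": {year: set}, "regions": {tuple(years): count}}``
    where a region holds species present in exactly that subset of years.
    Years with few records can be excluded (as survey years with almost no
    fruiting usually are).
    """
    per_year: dict[int, set[str]] = {}
    for r in records:
        if r.year is None or r.morphospecies is None or r.year in exclude_years:
            continue
        per_year.setdefault(r.year, set()).add(r.morphospecies)
    years = sorted(per_year)
    regions: dict[tuple[int, ...], int] = {}
    all_species = set().union(*per_year.values()) if per_year else set()
    for k in range(1, len(years) + 1):
        for combo in combinations(years, k):
            inside = set(all_species)
            for y in combo:
                inside &= per_year[y]
            for y in years:
                if y not in combo:
                    inside -= per_year[y]
            regions[combo] = len(inside)
    return {"per_year": per_year, "regions": regions}
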