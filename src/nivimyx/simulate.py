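"""Synthetic fixture generator with planted ground truth.

Emulates the data structure of a snowbank-myxomycete field study: a
reference pool of ~350 bp partial-SSU barcodes organised as genera >
morphospecies > ribotype clusters > ribotypes, a multi-year fruit-body
survey along a 1,100-1,900 m transect, a soil OTU read-count table over 16
sites, and winter soil-temperature / snow-height logger series. Every
planted fact (cluster partition, soil overlap category per cluster,
elevational optima, per-day suitability class, snow-cover days) is recorded
in a :class:`SyntheticTruth` so downstream stages can be tested end-to-end.

Sequence construction uses disjoint mutated position blocks so planted
identities are exact by arithmetic: every ribotype cluster receives
``ceil(between_divergence * L / 2)`` substitutions from a shared root at
cluster-private positions, and every additional ribotype one further private
substitution. Intra-cluster pairwise identity is therefore >= 1 - 2/L
(0.9943 at L = 350) and inter-cluster identity <= 1 - 2b/L (0.9657), which
brackets the 99.1% clustering threshold. The mutation model is
substitution-only by default so identity equals 1 - hamming/L exactly; an
optional per-specimen error rate exists for robustness experiments.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import thermal as _thermal
from .errors import ConfigError, DataError
from .otu import OtuTable
from .sequences import SequenceRecord, write_fasta, write_metadata

_BASES = np.array(list("ACGT"))

GENERA = ("Lamproderma", "Diderma", "Meriderma", "Physarum",
          "Didymium", "Lepidoderma", "Diacheopsis")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults reproduce the study's conditions."""

    seed: int = 42
    # --- reference pool -------------------------------------------------
    n_morphospecies: int = 28
    n_genera: int = 7
    n_soil_only_species: int = 2  # non-nivicolous species present only in soil
    mean_clusters_per_species: float = 45 / 28  # -> 45 planted clusters
    mean_ribotypes_per_cluster: float = 70 / 45  # -> 70 planted ribotypes
    within_species_divergence: float = 0.006  # max pairwise fraction inside a cluster
    between_species_divergence: float = 0.03
    seq_length: int = 350
    # --- fruit-body survey ----------------------------------------------
    n_specimens: int = 533
    survey_years: tuple[int, ...] = (2013, 2015, 2016, 2017)
    year_weights: tuple[float, ...] = (199, 194, 327, 12)
    specimen_error_rate: float = 0.0
    abundance_sigma: float = 1.2  # lognormal sd of cluster abundance weights
    genus_weight_decay: float = 0.45  # geometric genus dominance (first genera most abundant)
    # --- elevation ------------------------------------------------------
    elevation_range: tuple[float, float] = (1100.0, 1900.0)
    optimum_mean: float = 1570.0
    optimum_sd: float = 90.0
    elevation_breadth: float = 100.0  # specimen scatter around the taxon optimum
    shift_between_inventories: float = -130.0
    shift_sd: float = 40.0
    occupancy_sd: float = 250.0  # width of the soil occupancy kernel
    # --- soil OTU table -------------------------------------------------
    n_samples: int = 39
    reads_per_sample_range: tuple[int, int] = (5623, 55791)
    soil_overlap_fraction: float = 34 / 70  # clusters planted verbatim (exact)
    near_match_fraction: float = 19 / 70  # clusters planted as a 1-sub variant
    annotatable_read_fraction: float = 0.406
    n_genus_level_otus: int = 10
    n_unknown_otus: int = 80
    otu_lognormal_sigma: float = 1.2
    planted_presence_max: float = 0.45
    unknown_presence_low: float = 0.24  # at the transect base
    unknown_presence_high: float = 0.05  # at the transect top
    # --- winter temperature / snow --------------------------------------
    winter_start: str = "2015-10-01"
    winter_end: str = "2016-06-30"
    snow_onset_day: int = 45  # days after winter_start, at the transect base
    snow_melt_day: int = 180
    onset_elevation_slope: float = -0.02  # d/m: earlier onset higher up
    melt_elevation_slope: float = 0.05  # d/m: later melt higher up
    snow_gap_start_day: int = 95
    snow_gap_days: int = 6
    snow_gap_max_elevation: float = 1350.0  # unstable cover only low on the transect
    snow_depth_cm: float = 60.0
    vegetation_height_cm: float = 8.0
    snow_insulation_cm: float = 10.0
    insulated_mean_c: float = 0.5
    insulated_sd_c: float = 0.15
    air_coupling: float = 0.5  # damping of air temperature by bare soil
    soil_noise_sd_c: float = 0.2
    air_ar1_phi: float = 0.98  # per 30-min step
    air_ar1_sd: float = 2.5  # stationary sd of the AR(1) component
    air_diurnal_amp_c: float = 3.0

    def validate(self) -> None:
        L = self.seq_length
        for name in ("within_species_divergence", "between_species_divergence",
                     "soil_overlap_fraction", "near_match_fraction",
                     "annotatable_read_fraction", "specimen_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.within_species_divergence >= self.between_species_divergence:
            raise ConfigError("within_species_divergence must be < between_species_divergence")
        if self.soil_overlap_fraction + self.near_match_fraction > 1.0 + 1e-9:
            raise ConfigError("soil_overlap_fraction + near_match_fraction must be <= 1")
        if self.mean_ribotypes_per_cluster > 1.0 and self.within_species_divergence < 2.0 / L:
            raise ConfigError(
                f"within_species_divergence {self.within_species_divergence} cannot host "
                f"distinct ribotypes at seq_length {L} (needs >= {2.0 / L:.4f})")
        if self.n_genera > len(GENERA):
            raise ConfigError(f"at most {len(GENERA)} genera are available")
        lo, hi = self.reads_per_sample_range
        if not 0 < lo <= hi:
            raise ConfigError("reads_per_sample_range must be a positive (lo, hi) pair")

    @property
    def cluster_subs(self) -> int:
        """Substitutions from the root per cluster block."""
        return math.ceil(self.between_species_divergence * self.seq_length / 2)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class ClusterTruth:
    cluster_id: str
    species: str
    genus: str
    nivicolous: bool
    member_ids: list[str]
    fruit_optimum: float
    soil_optimum: float
    category: str | None = None  # exact | near | unmatched (fruit clusters)


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for verification by tests."""

    partition: dict[str, str] = field(default_factory=dict)  # ribotype id -> cluster id
    clusters: dict[str, ClusterTruth] = field(default_factory=dict)
    soil_otus: dict[str, dict] = field(default_factory=dict)  # otu -> kind/cluster/ref
    shift_m: float = 0.0
    annotatable_read_fraction: float = 0.0
    day_classes: dict[str, dict[str, str]] = field(default_factory=dict)
    snow_days: dict[str, int] = field(default_factory=dict)
    free_positions: list[int] = field(default_factory=list)  # unused mutation sites

    def fruit_cluster_ids(self) -> list[str]:
        return [c for c, t in self.clusters.items() if not c.startswith("SC")]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "partition": self.partition,
            "clusters": {c: dataclasses.asdict(t) for c, t in self.clusters.items()},
            "soil_otus": self.soil_otus,
            "shift_m": self.shift_m,
            "annotatable_read_fraction": self.annotatable_read_fraction,
            "day_classes": self.day_classes,
            "snow_days": self.snow_days,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# reference pool
# --------------------------------------------------------------------------

def _distribute(total_extra: int, n_bins: int, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Spread ``total_extra`` units over ``n_bins`` with at most ``cap`` each."""
    if total_extra > n_bins * cap:
        raise ConfigError("cannot distribute cluster/ribotype counts under the cap")
    out = np.zeros(n_bins, dtype=int)
    for _ in range(total_extra):
        open_bins = np.nonzero(out < cap)[0]
        out[rng.choice(open_bins)] += 1
    return out


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        out[p] = rng.choice([b for b in range(4) if b != out[p]])
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def generate_reference_pool(config: SimulationConfig) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Build the labelled barcode pool and its planted cluster partition."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    L = config.seq_length
    b = config.cluster_subs

    n_fruit_sp = config.n_morphospecies
    n_soil_sp = config.n_soil_only_species
    n_clusters_fruit = max(n_fruit_sp, round(n_fruit_sp * config.mean_clusters_per_species))
    extra_clusters = _distribute(n_clusters_fruit - n_fruit_sp, n_fruit_sp, cap=4, rng=rng)
    clusters_per_species = 1 + extra_clusters
    n_clusters = n_clusters_fruit + n_soil_sp
    n_ribos_fruit = max(n_clusters_fruit, round(n_clusters_fruit * config.mean_ribotypes_per_cluster))
    extra_ribos = _distribute(n_ribos_fruit - n_clusters_fruit, n_clusters_fruit, cap=4, rng=rng)

    needed = n_clusters * b + int(extra_ribos.sum())
    if needed > L:
        raise ConfigError(
            f"divergence constraints unsatisfiable for seq_length={L}: "
            f"{needed} private mutation sites needed")
    positions = rng.permutation(L)
    pos_iter = iter(positions.tolist())

    genera = list(GENERA[:config.n_genera])
    species = [f"{genera[i % len(genera)]} sp{i + 1:02d}" for i in range(n_fruit_sp)]
    soil_species = [f"{genera[(n_fruit_sp + i) % len(genera)]} autumnale{i + 1:02d}"
                    for i in range(n_soil_sp)]

    root = rng.integers(0, 4, size=L)
    truth = SyntheticTruth(shift_m=config.shift_between_inventories)
    records: list[SequenceRecord] = []
    rid = 0
    cid = 0

    def new_cluster(species_name: str, genus: str, nivicolous: bool, n_ribos: int,
                    prefix: str) -> None:
        nonlocal rid, cid
        cid += 1
        cluster_id = f"{prefix}{cid:03d}"
        block = np.array([next(pos_iter) for _ in range(b)])
        ancestor = _mutate(root, block, rng)
        fruit_opt = float(np.clip(rng.normal(config.optimum_mean, config.optimum_sd),
                                  config.elevation_range[0] + 50, config.elevation_range[1] - 50))
        soil_opt = fruit_opt + config.shift_between_inventories + rng.normal(0, config.shift_sd)
        members = []
        seqs = [ancestor]
        for k in range(1, n_ribos):
            seqs.append(_mutate(ancestor, np.array([next(pos_iter)]), rng))
        for s in seqs:
            rid += 1
            ref_id = f"REF{rid:03d}"
            members.append(ref_id)
            records.append(SequenceRecord(
                id=ref_id, sequence=_to_str(s), source="reference",
                morphospecies=species_name, genus=genus, abundance=1))
            truth.partition[ref_id] = cluster_id
        truth.clusters[cluster_id] = ClusterTruth(
            cluster_id=cluster_id, species=species_name, genus=genus,
            nivicolous=nivicolous, member_ids=members,
            fruit_optimum=fruit_opt, soil_optimum=soil_opt)

    ci = 0
    for si, sp in enumerate(species):
        genus = sp.split()[0]
        for _ in range(clusters_per_species[si]):
            new_cluster(sp, genus, nivicolous=True, n_ribos=1 + int(extra_ribos[ci]), prefix="C")
            ci += 1
    cid = 0  # soil-only clusters get their own prefix/counter
    for sp in soil_species:
        new_cluster(sp, sp.split()[0], nivicolous=False, n_ribos=1, prefix="SC")

    truth.free_positions = list(pos_iter)
    return records, truth


# --------------------------------------------------------------------------
# sites and samples
# --------------------------------------------------------------------------

def build_sites(config: SimulationConfig) -> pd.DataFrame:
    """16 study sites: one open and one closed-canopy site per 100 m belt."""
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.elevation_range
    n_belts = int(round((hi - lo) / 100))
    rows = []
    for belt in range(1, n_belts + 1):
        mid = lo + (belt - 0.5) * 100
        for canopy in ("cl", "op"):
            rows.append({
                "site": f"{belt}{canopy}",
                "belt": belt,
                "canopy": canopy,
                "elevation_m": float(np.round(mid + rng.normal(0, 15), 0)),
            })
    return pd.DataFrame(rows).set_index("site")


def build_samples(config: SimulationConfig, sites: pd.DataFrame) -> pd.DataFrame:
    """Soil samples cycled over the sites (three replicates ~10 m apart)."""
    rng = np.random.default_rng([config.seed, 3])
    site_ids = list(sites.index)
    rows = []
    for k in range(config.n_samples):
        site = site_ids[k % len(site_ids)]
        rows.append({
            "sample_id": f"S{k + 1:02d}",
            "site": site,
            "elevation_m": float(sites.loc[site, "elevation_m"] + np.round(rng.normal(0, 10), 0)),
            "canopy": sites.loc[site, "canopy"],
        })
    return pd.DataFrame(rows).set_index("sample_id")


# --------------------------------------------------------------------------
# fruit-body survey
# --------------------------------------------------------------------------

def generate_fruitbody_survey(config: SimulationConfig, pool: list[SequenceRecord],
                              truth: SyntheticTruth) -> list[SequenceRecord]:
    """Draw specimens from the nivicolous pool clusters.

    Specimen elevations follow the cluster's Gaussian fruit optimum
    (truncated to a window slightly wider than the belt range, so a few
    records fall outside and exercise belt clamping); abundances follow a
    lognormal cluster weight; years follow the configured survey weights.
    """
    if not pool:
        raise DataError("generate_fruitbody_survey: empty pool")
    rng = np.random.default_rng([config.seed, 4])
    fruit_clusters = [t for c, t in truth.clusters.items() if t.nivicolous]
    if config.n_specimens == 0:
        return []
    genus_rank = {g: k for k, g in enumerate(GENERA)}
    weights = rng.lognormal(0.0, config.abundance_sigma, size=len(fruit_clusters))
    weights *= np.array([config.genus_weight_decay ** genus_rank.get(t.genus, 0)
                         for t in fruit_clusters])
    weights /= weights.sum()
    counts = rng.multinomial(config.n_specimens, weights)
    seq_by_id = {r.id: r for r in pool}
    years = np.asarray(config.survey_years)
    yw = np.asarray(config.year_weights, dtype=float)
    yw /= yw.sum()
    lo, hi = config.elevation_range
    specimens: list[SequenceRecord] = []
    k = 0
    for t, n in zip(fruit_clusters, counts):
        for _ in range(n):
            k += 1
            ref = seq_by_id[t.member_ids[int(rng.integers(len(t.member_ids)))]]
            elev = float(np.clip(rng.normal(t.fruit_optimum, config.elevation_breadth),
                                 lo - 100, hi + 100))
            belt = int(np.clip(math.floor((elev - lo) / 100) + 1, 1, round((hi - lo) / 100)))
            seq = ref.sequence
            if config.specimen_error_rate > 0:
                arr = np.array([("ACGT").index(c) for c in seq])
                hits = np.nonzero(rng.random(arr.size) < config.specimen_error_rate)[0]
                seq = _to_str(_mutate(arr, hits, rng))
            specimens.append(SequenceRecord(
                id=f"FB{k:04d}", sequence=seq, source="fruit",
                morphospecies=t.species, genus=t.genus,
                year=int(rng.choice(years, p=yw)),
                site=f"{belt}{'op' if rng.random() < 0.5 else 'cl'}",
                elevation=round(elev, 1), abundance=1))
    return specimens


# --------------------------------------------------------------------------
# soil OTU table
# --------------------------------------------------------------------------

def _hamming_to_pool(seq: np.ndarray, pool_mat: np.ndarray) -> int:
    return int((pool_mat != seq[None, :]).sum(axis=1).min())


def generate_soil_otu_table(config: SimulationConfig, pool: list[SequenceRecord],
                            truth: SyntheticTruth) -> OtuTable:
    """Plant the soil inventory and its read-count table.

    Fruit clusters are assigned a category: *exact* clusters contribute all
    member ribotypes verbatim, *near* clusters one 1-substitution variant of
    their ancestor (identity to every member in [0.991, 1.0)), *unmatched*
    clusters contribute nothing. Soil-only species, genus-level OTUs
    (identity to the pool in [0.95, 0.98)) and unknown OTUs (< 0.95) fill in
    the rest. Per sample, round(total * annotatable_read_fraction) reads go
    to species-tier-capable OTUs, the remainder to the others, so the
    annotatable read fraction is planted exactly up to rounding.
    """
    config.validate()
    if not pool:
        raise DataError("generate_soil_otu_table: empty pool")
    rng = np.random.default_rng([config.seed, 5])
    L = config.seq_length
    seq_by_id = {r.id: r for r in pool}
    pool_mat = np.array([[("ACGT").index(c) for c in r.sequence] for r in pool])
    free = list(truth.free_positions)

    p_e, p_n = config.soil_overlap_fraction, config.near_match_fraction
    fruit_clusters = [t for t in truth.clusters.values() if t.cluster_id.startswith("C")]
    cats = rng.choice(["exact", "near", "unmatched"], size=len(fruit_clusters),
                      p=[p_e, p_n, max(0.0, 1.0 - p_e - p_n)])

    otus: list[tuple[str, np.ndarray, str, float, str | None]] = []  # id, seq, kind, optimum, cluster

    def add(seq: np.ndarray, kind: str, optimum: float, cluster: str | None, ref: str | None) -> None:
        oid = f"OTU{len(otus) + 1:03d}"
        otus.append((oid, seq, kind, optimum, cluster))
        truth.soil_otus[oid] = {"kind": kind, "cluster_id": cluster, "ref_id": ref}

    for t, cat in zip(fruit_clusters, cats):
        t.category = str(cat)
        if cat == "exact":
            for m in t.member_ids:
                add(np.array([("ACGT").index(c) for c in seq_by_id[m].sequence]),
                    "exact", t.soil_optimum, t.cluster_id, m)
        elif cat == "near":
            anc = np.array([("ACGT").index(c) for c in seq_by_id[t.member_ids[0]].sequence])
            if free:  # a globally private site keeps identities analytic
                variant = _mutate(anc, np.array([free.pop(0)]), rng)
            else:  # fall back to any site; still 1 sub from the ancestor
                variant = _mutate(anc, rng.choice(L, size=1, replace=False), rng)
            add(variant, "near", t.soil_optimum, t.cluster_id, t.member_ids[0])
    for t in truth.clusters.values():
        if t.cluster_id.startswith("SC"):
            t.category = "soil_only"
            m = t.member_ids[0]
            add(np.array([("ACGT").index(c) for c in seq_by_id[m].sequence]),
                "soil_only", t.soil_optimum, t.cluster_id, m)

    existing = [o[1] for o in otus]
    lo, hi = config.elevation_range

    def far_enough(seq: np.ndarray, dmin_pool: int, dmax_pool: int | None) -> bool:
        d = _hamming_to_pool(seq, pool_mat)
        if d < dmin_pool or (dmax_pool is not None and d > dmax_pool):
            return False
        return all(int((seq != e).sum()) >= 4 for e in existing)

    genus_d = 9  # identity 1 - 9/350 = 0.974, inside the genus tier [0.95, 0.98)
    for _ in range(config.n_genus_level_otus):
        for _try in range(50):
            ref = pool[int(rng.integers(len(pool)))]
            base = np.array([("ACGT").index(c) for c in ref.sequence])
            seq = _mutate(base, rng.choice(L, size=genus_d, replace=False), rng)
            dmax = math.floor((1 - 0.95) * L)  # stay below species tier, above genus floor
            if far_enough(seq, genus_d - 1, dmax) and int((seq != base).sum()) == genus_d \
                    and _hamming_to_pool(seq, pool_mat) >= math.ceil((1 - 0.98) * L) + 1:
                add(seq, "genus", truth.clusters[truth.partition[ref.id]].soil_optimum,
                    None, ref.id)
                existing.append(seq)
                break
        else:
            raise ConfigError("could not place a genus-level OTU; sequence space too tight")

    unknown_d = 40
    for _ in range(config.n_unknown_otus):
        for _try in range(50):
            ref = pool[int(rng.integers(len(pool)))]
            base = np.array([("ACGT").index(c) for c in ref.sequence])
            seq = _mutate(base, rng.choice(L, size=unknown_d, replace=False), rng)
            if far_enough(seq, math.floor(0.05 * L) + 1, None):
                add(seq, "unknown", float(rng.uniform(lo + 50, hi - 150)), None, None)
                existing.append(seq)
                break
        else:
            raise ConfigError("could not place an unknown OTU; sequence space too tight")

    # ---- read counts ----------------------------------------------------
    sites = build_sites(config)
    samples = build_samples(config, sites)
    otu_ids = [o[0] for o in otus]
    kinds = np.array([o[2] for o in otus])
    optima = np.array([o[3] for o in otus])
    annotatable = np.isin(kinds, ("exact", "near", "soil_only"))
    base_w = rng.lognormal(0.0, config.otu_lognormal_sigma, size=len(otus))
    genus_rank = {g: k for k, g in enumerate(GENERA)}
    for k, (oid, _, kind, _, cluster) in enumerate(otus):
        if cluster is not None:  # genus dominance mirrors the fruit inventory
            base_w[k] *= config.genus_weight_decay ** genus_rank.get(
                truth.clusters[cluster].genus, 0)

    elev = samples["elevation_m"].to_numpy(float)
    span = hi - lo
    # presence probabilities: occupancy kernel for planted OTUs, a declining
    # background for unknown OTUs (the planted richness-elevation trend)
    p_planted = config.planted_presence_max * np.exp(
        -0.5 * ((elev[None, :] - optima[:, None]) / config.occupancy_sd) ** 2)
    p_unknown = (config.unknown_presence_low
                 + (config.unknown_presence_high - config.unknown_presence_low)
                 * (elev[None, :] - lo) / span)
    presence_p = np.where((kinds == "unknown")[:, None], p_unknown, p_planted)
    present = rng.random(presence_p.shape) < presence_p
    # every OTU occurs somewhere: force it into the closest-elevation sample
    nearest = np.abs(elev[None, :] - optima[:, None]).argmin(axis=1)
    present[np.arange(len(otus)), nearest] = True

    counts = np.zeros((len(otus), len(samples)), dtype=int)
    rlo, rhi = config.reads_per_sample_range
    theta = config.annotatable_read_fraction
    for j in range(len(samples)):
        total = int(rng.integers(rlo, rhi + 1))
        n_annot = int(round(total * theta))
        for is_annot in (True, False):
            n_reads = n_annot if is_annot else total - n_annot
            if n_reads == 0:
                continue
            idx = np.nonzero((annotatable == is_annot) & present[:, j])[0]
            if idx.size == 0:  # force the nearest candidate of that group
                grp = np.nonzero(annotatable == is_annot)[0]
                idx = grp[[np.abs(optima[grp] - elev[j]).argmin()]]
            w = base_w[idx] * np.maximum(presence_p[idx, j], 1e-3)
            counts[idx, j] += rng.multinomial(n_reads, w / w.sum())
    # guarantee >= 1 read per OTU without touching sample totals or theta
    for i in np.nonzero(counts.sum(axis=1) == 0)[0]:
        j = nearest[i]
        grp = np.nonzero((annotatable == annotatable[i]) & (counts[:, j] > 1))[0]
        if grp.size == 0:
            continue
        donor = grp[counts[grp, j].argmax()]
        counts[donor, j] -= 1
        counts[i, j] += 1

    truth.annotatable_read_fraction = theta
    table = pd.DataFrame(counts, index=otu_ids, columns=list(samples.index))
    reps = {oid: _to_str(o[1]) for oid, o in zip(otu_ids, otus)}
    return OtuTable(counts=table, rep_seqs=reps, samples=samples)


# --------------------------------------------------------------------------
# winter temperature and snow
# --------------------------------------------------------------------------

def generate_temperature_series(
    config: SimulationConfig,
) -> tuple[dict[str, _thermal.LoggerSeries], dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-site winter soil-temperature (30-min) and snow-height (hourly) series.

    While the planted snow depth exceeds the insulation cutoff the soil sits
    at Normal(insulated_mean, insulated_sd); snow-free soil follows damped
    air temperature (seasonal Gaussian cold dip + AR(1) noise + a diurnal
    cycle) and can freeze. Ground-truth day classes are obtained by applying
    the suitability rule to the generated readings, so truth and classifier
    are self-consistent by construction.
    """
    config.validate()
    start = pd.Timestamp(config.winter_start)
    end = pd.Timestamp(config.winter_end)
    if end <= start:
        raise ConfigError("winter_end must be after winter_start")
    sites = build_sites(config)
    times = pd.date_range(start, end + pd.Timedelta(days=1), freq="30min", inclusive="left")
    if not times.is_monotonic_increasing:
        raise DataError("generated timestamps are not monotone")
    day_index = ((times - start) / pd.Timedelta(days=1)).astype(int).to_numpy()
    n_days = day_index.max() + 1
    hours = times.hour.to_numpy() + times.minute.to_numpy() / 60.0

    loggers: dict[str, _thermal.LoggerSeries] = {}
    snows: dict[str, pd.DataFrame] = {}
    truth = SyntheticTruth(shift_m=config.shift_between_inventories)
    lo = config.elevation_range[0]
    for si, (site, row) in enumerate(sites.iterrows()):
        rng = np.random.default_rng([config.seed, 6, si])
        elev = float(row["elevation_m"])
        onset = config.snow_onset_day + config.onset_elevation_slope * (elev - lo)
        melt = config.snow_melt_day + config.melt_elevation_slope * (elev - lo)
        depth = np.where((day_index >= onset) & (day_index < melt), config.snow_depth_cm, 0.0)
        if config.snow_gap_days > 0 and elev <= config.snow_gap_max_elevation:
            gap = ((day_index >= config.snow_gap_start_day)
                   & (day_index < config.snow_gap_start_day + config.snow_gap_days))
            depth = np.where(gap, 0.0, depth)
        # air temperature: seasonal cold dip + AR(1) + diurnal cycle
        seasonal = 8.0 - 18.0 * np.exp(-((day_index - 105.0) / 60.0) ** 2) - 0.004 * (elev - lo)
        eps = rng.normal(0.0, config.air_ar1_sd * math.sqrt(1 - config.air_ar1_phi ** 2),
                         size=times.size)
        ar = np.empty(times.size)
        ar[0] = rng.normal(0.0, config.air_ar1_sd)
        for k in range(1, times.size):
            ar[k] = config.air_ar1_phi * ar[k - 1] + eps[k]
        air = seasonal + ar + config.air_diurnal_amp_c * np.sin(2 * np.pi * (hours - 9) / 24)
        insulated = depth > config.snow_insulation_cm
        soil = np.where(
            insulated,
            rng.normal(config.insulated_mean_c, config.insulated_sd_c, size=times.size),
            config.air_coupling * air + rng.normal(0.0, config.soil_noise_sd_c, size=times.size),
        )
        series = _thermal.LoggerSeries(
            site=site, elevation=elev,
            readings=pd.DataFrame({"timestamp": times, "temp_C": np.round(soil, 3)}))
        loggers[site] = series
        veg = np.clip(rng.normal(config.vegetation_height_cm, 1.5, size=n_days), 0.0, None)
        daily_height = np.where(depth[::48][:n_days] > 0, depth[::48][:n_days], veg)
        snow_times = pd.date_range(start, periods=n_days * 24, freq="1h")
        height = np.repeat(daily_height, 24) + np.round(
            np.random.default_rng([config.seed, 7, si]).normal(0, 0.3, n_days * 24), 2)
        snows[site] = pd.DataFrame({"timestamp": snow_times, "height_cm": np.round(height, 1)})
        daily = _thermal.daily_aggregate(series)
        truth.day_classes[site] = {
            d.date().isoformat(): c for d, c in zip(daily["date"], daily["class"])}
        truth.snow_days[site] = int((depth[::48][:n_days] > config.snow_insulation_cm).sum())
    return loggers, snows, truth


# --------------------------------------------------------------------------
# one-call bundle
# --------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    pool: list[SequenceRecord]
    specimens: list[SequenceRecord]
    otu_table: OtuTable
    loggers: dict[str, _thermal.LoggerSeries]
    snows: dict[str, pd.DataFrame]
    truth: SyntheticTruth
    sites: pd.DataFrame


def generate_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """Generate all four fixture datasets under one seed."""
    config = config or SimulationConfig()
    pool, truth = generate_reference_pool(config)
    specimens = generate_fruitbody_survey(config, pool, truth)
    otu_table = generate_soil_otu_table(config, pool, truth)
    loggers, snows, t2 = generate_temperature_series(config)
    truth.day_classes = t2.day_classes
    truth.snow_days = t2.snow_days
    return SyntheticBundle(config=config, pool=pool, specimens=specimens,
                           otu_table=otu_table, loggers=loggers, snows=snows,
                           truth=truth, sites=build_sites(config))


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text FASTA/TSV/CSV/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.pool, out / "pool.fasta")
    write_metadata(bundle.pool, out / "pool_meta.tsv")
    with open(out / "refdb.fasta", "w") as fh:
        truth = bundle.truth
        for r in bundle.pool:
            niv = int(truth.clusters[truth.partition[r.id]].nivicolous)
            fh.write(f">{r.id}|{r.morphospecies}|{r.genus}|{niv}\n{r.sequence}\n")
    write_fasta(bundle.specimens, out / "specimens.fasta")
    write_metadata(bundle.specimens, out / "specimens.tsv")
    bundle.otu_table.write(out / "otu_table.tsv", out / "otu_reps.fasta", out / "samples.tsv")
    tdir = out / "temperature"
    sdir = out / "snow"
    tdir.mkdir(exist_ok=True)
    sdir.mkdir(exist_ok=True)
    for site, series in bundle.loggers.items():
        series.write_csv(tdir / f"{site}.csv")
    for site, snow in bundle.snows.items():
        o = snow.copy()
        o["height_cm"] = o["height_cm"].map(lambda v: f"{v:.1f}")
        o.to_csv(sdir / f"{site}.csv", index=False)
    bundle.sites.to_csv(out / "sites.tsv", sep="\t")
    bundle.truth.to_json(out / "truth.json")
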