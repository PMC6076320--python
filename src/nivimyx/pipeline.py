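"""End-to-end orchestration of the synthetic study pipeline.

``run_synthetic`` generates one fixture bundle and pushes it through every
analysis stage — dedup, clustering, annotation, cross-inventory matching,
richness/coverage, elevational profiles and the winter-temperature
classification — returning a nested report of the quantities the study
design is about (match partition, annotated read fraction, Chao richness,
inventory elevation shift, suitable/unsuitable day counts).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import MatchPolicy, ReferenceDB, annotate_otus, annotations_to_frame
from .clustering import ClusterPolicy, clusters_to_frame, greedy_cluster, label_clusters
from .concordance import genus_composition, match_inventories, shared_unique_per_site, year_overlap
from .diversity import AbundanceVector, chao1, rarefy_extrapolate, sample_coverage
from .elevation import BeltScheme, build_profiles, correlate_with_elevation, mean_elevation_shift
from .sequences import dedup_ribotypes
from .simulate import SimulationConfig, generate_bundle, write_bundle
from .thermal import ThermalPolicy, daily_aggregate, season_stats, season_table, snow_cover_days


def fruit_observations(specimens) -> pd.DataFrame:
    return pd.DataFrame([
        {"taxon": r.morphospecies, "elevation_m": r.elevation, "abundance": r.abundance}
        for r in specimens if r.morphospecies and r.elevation is not None
    ])


def soil_observations(otu_table, annotations) -> pd.DataFrame:
    """Tidy (taxon, elevation_m, abundance) rows: reads of species-ranked OTUs."""
    name_by_otu = {a.otu_id: a.assigned_name for a in annotations
                   if a.assigned_rank == "species"}
    rows = []
    elev = otu_table.samples["elevation_m"]
    for otu_id, name in name_by_otu.items():
        for sample_id, reads in otu_table.counts.loc[otu_id].items():
            if reads > 0:
                rows.append({"taxon": name, "elevation_m": float(elev[sample_id]),
                             "abundance": int(reads)})
    return pd.DataFrame(rows)


def run_synthetic(config: SimulationConfig | None = None,
                  outdir: str | Path | None = None,
                  cluster_policy: ClusterPolicy | None = None,
                  match_policy: MatchPolicy | None = None,
                  belt_scheme: BeltScheme | None = None,
                  thermal_policy: ThermalPolicy | None = None,
                  n_bootstrap: int = 200,
                  n_permutations: int = 2000) -> dict:
    """Run the whole pipeline on a generated bundle; optionally write reports."""
    config = config or SimulationConfig()
    cluster_policy = cluster_policy or ClusterPolicy()
    match_policy = match_policy or MatchPolicy()
    belt_scheme = belt_scheme or BeltScheme(base=config.elevation_range[0])
    thermal_policy = thermal_policy or ThermalPolicy()
    seed = config.seed

    bundle = generate_bundle(config)
    report: dict = {"seed": seed, "version": __version__}

    # ---- fruit inventory: ribotypes and clusters ------------------------
    ribotypes = dedup_ribotypes(bundle.specimens)
    clusters = greedy_cluster(ribotypes, cluster_policy)
    clusters, conflicts = label_clusters(clusters, ribotypes, bundle.specimens)
    report["fruit"] = {
        "n_specimens": len(bundle.specimens),
        "n_unique_ribotypes": len(ribotypes),
        "n_ribotype_clusters": len(clusters),
        "n_label_conflicts": len(conflicts),
    }

    # ---- soil annotation -------------------------------------------------
    refdb = ReferenceDB.from_records(
        bundle.pool,
        nivicolous={t.species: t.nivicolous for t in bundle.truth.clusters.values()})
    annotations, ann_summary = annotate_otus(bundle.otu_table, refdb, match_policy, seed=seed)
    report["annotation"] = {
        "n_otus": ann_summary.n_otus,
        "n_species_rank": ann_summary.n_species_rank,
        "n_genus_rank": ann_summary.n_genus_rank,
        "n_unassigned": ann_summary.n_unassigned,
        "annotated_read_fraction": ann_summary.annotated_read_fraction,
        "n_morphospecies": ann_summary.n_morphospecies,
        "n_nivicolous_morphospecies": ann_summary.n_nivicolous_morphospecies,
        "nivicolous_read_fraction": ann_summary.nivicolous_read_fraction,
        "total_reads": bundle.otu_table.total_reads(),
    }

    # ---- cross-inventory matching ---------------------------------------
    match = match_inventories(ribotypes, bundle.otu_table,
                              near_threshold=match_policy.near, clusters=clusters)
    report["match"] = {
        "n_exact": match.n_exact,
        "n_near": match.n_near,
        "n_unmatched": match.n_unmatched,
        "n_ribotypes": match.n_ribotypes,
        "unmatched_identity_mean": match.unmatched_identity_mean,
        "unmatched_identity_sd": match.unmatched_identity_sd,
        "unmatched_identity_range": match.unmatched_identity_range,
        "n_clusters_unmatched": sum(not v for v in match.cluster_matched.values()),
    }
    sharing = shared_unique_per_site(bundle.specimens, bundle.otu_table,
                                     threshold=match_policy.near)
    report["site_sharing"] = {"r_unique": sharing.r_unique, "r_shared": sharing.r_shared,
                             "p_unique": sharing.p_unique, "p_shared": sharing.p_shared}

    # ---- diversity -------------------------------------------------------
    species_vec = AbundanceVector.from_observations(
        [r.morphospecies for r in bundle.specimens if r.morphospecies])
    cluster_label_by_rt = {m: cl.label for cl in clusters for m in cl.member_ids}
    rt_of_member = {mem: rt.id for rt in ribotypes for mem in rt.member_ids}
    cluster_vec = AbundanceVector.from_observations(
        [cluster_label_by_rt[rt_of_member[r.id]] for r in bundle.specimens])
    div = {}
    for name, vec in (("morphospecies", species_vec), ("ribotype_clusters", cluster_vec)):
        est = chao1(vec)
        div[name] = {
            "s_obs": est.s_obs,
            "chao1": est.s_chao1,
            "ci": [est.ci_low, est.ci_high],
            "sample_coverage": sample_coverage(vec),
            "observed_over_chao": est.observed_over_chao,
            "n": vec.n,
        }
    report["diversity"] = div
    curves = {
        name: rarefy_extrapolate(vec, n_bootstrap=n_bootstrap, seed=seed)
        for name, vec in (("morphospecies", species_vec), ("ribotype_clusters", cluster_vec))
    }

    # ---- inventory composition ------------------------------------------
    genus_tab = genus_composition((r.genus, r.abundance) for r in bundle.specimens)
    report["genus_composition"] = {
        "top2_fraction": float(genus_tab["fraction"].head(2).sum()) if len(genus_tab) else None,
        "table": genus_tab.to_dict("records"),
    }
    years = year_overlap(bundle.specimens, exclude_years=(2017,))
    report["year_overlap"] = {
        "n_years": len(years["per_year"]),
        "n_shared_all_years": years["regions"].get(tuple(sorted(years["per_year"])), 0),
    }

    # ---- elevational profiles and shift ---------------------------------
    fruit_prof = build_profiles(fruit_observations(bundle.specimens), belt_scheme)
    soil_prof = build_profiles(soil_observations(bundle.otu_table, annotations),
                               belt_scheme, transform="none")
    shift = mean_elevation_shift(fruit_prof, soil_prof, scheme=belt_scheme,
                                 n_permutations=n_permutations, seed=seed)
    report["elevation_shift"] = {
        "fruit_mean_m": shift.fruit_mean, "fruit_sd_m": shift.fruit_sd,
        "soil_mean_m": shift.soil_mean, "soil_sd_m": shift.soil_sd,
        "mean_shift_m": shift.mean_shift,
        "p_paired_t": shift.p_paired_t, "p_permutation": shift.p_permutation,
        "n_shared_taxa": shift.n_taxa,
        "planted_shift_m": bundle.truth.shift_m,
    }

    # ---- winter temperature regime --------------------------------------
    all_stats = []
    snow_days = {}
    for site, series in bundle.loggers.items():
        daily = daily_aggregate(series, thermal_policy)
        all_stats.extend(season_stats(daily, site=site))
        cover = snow_cover_days(bundle.snows[site])
        snow_days[site] = cover.n_days if cover else None
    stats_tab = season_table(all_stats,
                             elevations=bundle.sites["elevation_m"].to_dict())
    suit = stats_tab.groupby("site")["suitable_days"].sum()
    unsuit = stats_tab.groupby("site")["unsuitable_days"].sum()
    elevs = bundle.sites.loc[suit.index, "elevation_m"]
    corr_s = correlate_with_elevation(suit.to_numpy(), elevs.to_numpy())
    corr_u = correlate_with_elevation(unsuit.to_numpy(), elevs.to_numpy())
    report["thermal"] = {
        "suitable_days_mean": float(suit.mean()),
        "unsuitable_days_mean": float(unsuit.mean()),
        "suitable_vs_elevation_r": corr_s[0] if corr_s else None,
        "suitable_vs_elevation_p": corr_s[1] if corr_s else None,
        "unsuitable_vs_elevation_r": corr_u[0] if corr_u else None,
        "snow_cover_days_mean": float(np.mean([v for v in snow_days.values() if v is not None])),
        "n_sites": len(suit),
    }

    # ---- reports ---------------------------------------------------------
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_bundle(bundle, out / "data")
        clusters_to_frame(clusters, ribotypes).to_csv(out / "clusters.tsv", sep="\t", index=False)
        annotations_to_frame(annotations, bundle.otu_table).to_csv(
            out / "annotations.tsv", sep="\t", index=False)
        match.to_frame().to_csv(out / "matches.tsv", sep="\t", index=False)
        sharing.table.to_csv(out / "site_sharing.tsv", sep="\t", index=False)
        genus_tab.to_csv(out / "genus_composition.tsv", sep="\t", index=False)
        for name, curve in curves.items():
            curve.write(out / f"accumulation_{name}.tsv")
        shift.per_taxon.to_csv(out / "elevation_shift.tsv", sep="\t", index=False)
        stats_tab.to_csv(out / "season_stats.tsv", sep="\t", index=False)
        manifest = {
            "version": __version__,
            "seed": seed,
            "thresholds": {
                "cluster_threshold": cluster_policy.threshold,
                "species_identity": match_policy.species_identity,
                "species_confidence": match_policy.species_confidence,
                "genus_identity_low": match_policy.genus_identity_low,
                "near": match_policy.near,
                "belt_base_m": belt_scheme.base,
                "belt_width_m": belt_scheme.width,
                "thermal_mean_low_c": thermal_policy.mean_low,
                "thermal_mean_high_c": thermal_policy.mean_high,
                "thermal_max_fluctuation_c": thermal_policy.max_fluctuation,
                "thermal_frost_max_c": thermal_policy.frost_max,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
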