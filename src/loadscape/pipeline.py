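"""End-to-end run: simulate -> annotate -> load -> scan -> gea -> offset -> sdm.

Glues the modules together at desk scale, writing every declared output
file under one directory.  Returns the in-memory results so callers
(tests, the acceptance script) can inspect the numbers directly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, load, scan, sdm
from .gea import LatentFactorScan, RdaScan, VifPruner, genomic_inflation, intersect_gea
from .grids import ClimateGrid, write_csv_grid
from .offset import (
    DissimilaritySplineTurnover,
    GradientForestTurnover,
    forward_offset,
    local_offset,
    reverse_offset,
    rgb_composite,
    transform_climate,
)
from .polarize import polarize_result
from .simulate import (
    LandscapeParams,
    SimParams,
    embed_adaptive_cline,
    embed_sweep,
    simulate_genotypes,
    simulate_landscape,
    simulate_occurrences,
)

__all__ = ["run_all"]


def class_masks(seg: pd.DataFrame) -> dict[str, np.ndarray]:
    cls = seg["effect_class"].to_numpy()
    keep = ~seg["excluded"].to_numpy() if "excluded" in seg else np.ones(len(seg), bool)
    return {
        "synonymous": (cls == "synonymous") & keep,
        "harmful_missense": seg["deleterious_missense"].to_numpy() & keep,
        "lof": (cls == "lof") & keep,
        "intergenic": (cls == "intergenic") & keep,
    }


def site_frequencies(dosage: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, list]:
    """Derived-allele frequency per sampling site (rows) per SNP (cols)."""
    labels = pd.unique(groups)
    freqs = np.full((len(labels), dosage.shape[1]), np.nan)
    for i, lab in enumerate(labels):
        sub = dosage[groups == lab]
        called = sub >= 0
        n = 2 * called.sum(axis=0)
        d = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    return freqs, list(labels)


def pairwise_hudson_fst(dosage: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, list]:
    """Mean Hudson Fst between every pair of sampling sites."""
    labels = list(pd.unique(groups))
    P = len(labels)
    out = np.zeros((P, P))
    subs = [dosage[groups == lab] for lab in labels]
    for i in range(P):
        for j in range(i + 1, P):
            num, den = scan.hudson_fst_components(subs[i], subs[j])
            d = np.nansum(den)
            f = np.nansum(num) / d if d > 0 else 0.0
            out[i, j] = out[j, i] = max(float(f), 0.0)
    return out, labels


def run_all(
    outdir: str | Path,
    seed: int = 0,
    sim_params: SimParams | None = None,
    land_params: LandscapeParams | None = None,
    include_sweep: bool = True,
    n_occurrences: int = 300,
    n_background: int = 800,
    sdm_replicates: int = 10,
    dispersal_caps: tuple = (100.0, 250.0, 500.0, 1000.0, np.inf),
    rda_permutations: int = 249,
) -> dict:
    """Run the whole pipeline on the default bottleneck-on-a-cline scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sp = sim_params or SimParams(seed=seed)
    lp = land_params or LandscapeParams(seed=seed + 1)
    results: dict = {"seed": seed, "outputs": []}

    def emit(name, writer, *args):
        path = outdir / name
        writer(path, *args)
        results["outputs"].append(str(path))

    def _wg(path, grid):  # write_csv_grid takes (grid, path)
        write_csv_grid(grid, path)

    # --- simulate --------------------------------------------------------
    sim = simulate_genotypes(sp)
    present, futures, samples = simulate_landscape(lp, sim.samples)
    sim.samples = samples
    focal = lp.variables[0]
    env_focal = samples[f"env_{focal}"].to_numpy()
    sim, causal = embed_adaptive_cline(
        sim, env_focal, lp.n_causal_loci, lp.cline_steepness, seed=seed + 2
    )
    sweep_region = None
    if include_sweep:
        sim, sweep_region = embed_sweep(sim, seed=seed + 3)

    contigs = {f"chr{c}": sp.chrom_length_bp for c in range(1, sp.n_chromosomes + 1)}
    emit("genotypes.vcf", io.write_vcf, sim.genotypes, sim.seg_sites,
         list(sim.samples["id"]), contigs)
    emit("samples.tsv", io.write_sample_table, sim.samples)
    emit("annotation.tsv", io.write_annotation, sim.sites)
    for scen, layers in [("present", present)] + list(futures.items()):
        for var in layers.variables:
            emit(f"climate_{scen}_{var}.csv", _wg, layers[var])

    # --- polarize & annotate --------------------------------------------
    dosage, seg = polarize_result(sim)
    emit("polarized.vcf", io.write_vcf, dosage, seg, list(sim.samples["id"]), contigs)
    excl = seg[seg["excluded"]][["chrom", "pos"]]
    emit("excluded_sites.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), excl)
    results["n_excluded_sites"] = int(seg["excluded"].sum())

    # --- genetic load ----------------------------------------------------
    pop = sim.samples["population"].to_numpy()
    in_a = pop == "A"
    _, _, fA = load.derived_freqs(dosage, in_a)
    _, _, fB = load.derived_freqs(dosage, ~in_a)
    masks = class_masks(seg)
    order = np.lexsort((seg["pos"].to_numpy(), seg["chrom"].to_numpy()))
    order_rank = np.empty(len(seg), dtype=int)
    order_rank[order] = np.arange(len(seg))
    r_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cls in ("lof", "harmful_missense", "synonymous"):
            rj = load.r_ab(fA, fB, masks[cls], masks["intergenic"], order=order_rank)
            r_rows.append({"class": cls, "l_ab": rj.l_ab, "l_ba": rj.l_ba,
                           "r_ab": rj.ratio, "jackknife_sd": rj.sd,
                           "blocks": rj.n_blocks})
    r_table = pd.DataFrame(r_rows)
    counts = load.per_individual_counts(
        dosage, {k: masks[k] for k in ("lof", "harmful_missense")}, masks["synonymous"]
    )
    gl = load.gerp_load(dosage, seg["gerp"].to_numpy(),
                        seg["gerp_deleterious"].to_numpy() & ~seg["excluded"].to_numpy())
    ind_table = pd.concat([sim.samples[["id", "population"]], counts, gl], axis=1)
    emit("load_r_stats.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), r_table)
    emit("load_individuals.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), ind_table)
    t_hom_lof, p_hom_lof = load.group_ttest(counts["lof_hom_derived"].to_numpy(), in_a)
    summary = {
        "r_ab": {row["class"]: row["r_ab"] for row in r_rows},
        "hom_lof_ttest": {"t": t_hom_lof, "p": p_hom_lof},
        "mean_masked_load": {"A": float(gl["masked_load"][in_a].mean()),
                             "B": float(gl["masked_load"][~in_a].mean())},
        "mean_realized_load": {"A": float(gl["realized_load"][in_a].mean()),
                               "B": float(gl["realized_load"][~in_a].mean())},
    }
    emit("load_summary.json", lambda p, d: Path(p).write_text(json.dumps(d, indent=2)), summary)
    results["load"] = summary

    # --- selection scan --------------------------------------------------
    chrom_arr = seg["chrom"].to_numpy()
    pos_arr = seg["pos"].to_numpy()
    windows = scan.windowed_fst(dosage, chrom_arr, pos_arr, in_a, ~in_a,
                                chrom_lengths=contigs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fst_out = scan.top_quantile_outliers(windows["fst"].to_numpy(), 0.01)
        pi_out = scan.top_quantile_outliers(windows["pi_ratio"].to_numpy(), 0.01)
    windows["fst_top1"] = fst_out
    windows["pi_ratio_top1"] = pi_out
    wid = windows["chrom"].astype(str) + ":" + windows["start"].astype(str)
    cand, venn = scan.intersect_candidates(
        {"fst": set(wid[fst_out]), "pi_ratio": set(wid[pi_out])}, k=2
    )
    emit("scan_windows.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), windows)
    bed = windows.loc[fst_out, ["chrom", "start", "end"]]
    emit("scan_fst_top1.bed", lambda p, df: df.to_csv(p, sep="\t", index=False, header=False), bed)
    emit("scan_venn.json", lambda p, d: Path(p).write_text(json.dumps(d, indent=2)), venn)
    results["scan"] = {"n_windows": len(windows), "n_fst_top1": int(fst_out.sum()),
                       "sweep_region": sweep_region,
                       "n_two_method_windows": len(cand)}

    # --- genotype-environment association --------------------------------
    env_cols = [c for c in samples.columns if c.startswith("env_")]
    env_df = samples[env_cols].rename(columns=lambda c: c[4:])
    pruner = VifPruner().fit(env_df)
    env_kept = pruner.transform(env_df).to_numpy()
    rda = RdaScan(n_permutations=rda_permutations,
                  random_state=int(rng.integers(2**31 - 1))).fit(env_kept, dosage)
    lfs = LatentFactorScan(k=2).fit(env_kept, dosage)
    inter = intersect_gea(rda.outlier_mask_, lfs.candidate_mask_)
    gea_table = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_arr,
        "rda_outlier": rda.outlier_mask_,
        "lf_pvalue": lfs.pvalues_, "lf_qvalue": lfs.qvalues_,
        "lf_candidate": lfs.candidate_mask_,
        "candidate": inter["candidate_mask"],
    })
    emit("gea_results.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), gea_table)
    cand_snps = gea_table[gea_table["candidate"]][["chrom", "pos"]]
    emit("gea_candidates.tsv", lambda p, df: df.to_csv(p, sep="\t", index=False), cand_snps)
    truth = set(zip(causal["chrom"], causal["pos"]))
    called = set(zip(cand_snps["chrom"], cand_snps["pos"]))
    results["gea"] = {
        "retained_variables": pruner.retained_,
        "n_rda": inter["n_rda"], "n_latent_factor": inter["n_latent_factor"],
        "n_candidates": inter["n_candidates"],
        "inflation": genomic_inflation(lfs.pvalues_),
        "causal_recovery": len(truth & called) / max(len(truth), 1),
        "false_discovery": (len(called - truth) / len(called)) if called else 0.0,
    }

    # --- genomic offset --------------------------------------------------
    cand_mask = inter["candidate_mask"]
    if cand_mask.sum() < 3:  # fall back to the strongest latent-factor hits
        cand_mask = lfs.qvalues_ <= np.sort(lfs.qvalues_)[min(9, len(lfs.qvalues_) - 1)]
    site_labels = samples["site"].to_numpy()
    freqs, site_names = site_frequencies(dosage[:, cand_mask], site_labels)
    site_env = np.vstack([
        env_kept[site_labels == lab].mean(axis=0) for lab in site_names
    ])
    gf = GradientForestTurnover(random_state=seed).fit(
        site_env, np.nan_to_num(freqs), variables=pruner.retained_
    )
    fstm, _ = pairwise_hudson_fst(dosage[:, cand_mask], site_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gdm = DissimilaritySplineTurnover().fit(fstm, site_env, variables=pruner.retained_)
    grid0 = present.geometry_grid()
    lon_g, lat_g = grid0.cell_centers()
    offsets_summary = {}
    for model_name, model in (("forest", gf), ("spline", gdm)):
        t_now = transform_climate(model, present)
        for scen, fut in futures.items():
            t_fut = transform_climate(model, fut)
            loc = local_offset(t_now, t_fut)
            rev = reverse_offset(t_now, t_fut)
            fwd_maps = {}
            for cap in dispersal_caps:
                fwd_maps[cap] = forward_offset(t_now, t_fut, lon_g, lat_g, cap)
            rgb = rgb_composite(loc, fwd_maps[dispersal_caps[-1]], rev)
            def as_grid(arr):
                return ClimateGrid(arr, grid0.xll, grid0.yll, grid0.cellsize)
            emit(f"offset_{model_name}_{scen}_local.csv", _wg, as_grid(loc))
            emit(f"offset_{model_name}_{scen}_reverse.csv", _wg, as_grid(rev))
            for cap, fw in fwd_maps.items():
                tag = "inf" if np.isinf(cap) else f"{int(cap)}km"
                emit(f"offset_{model_name}_{scen}_forward_{tag}.csv",
                     _wg, as_grid(fw))
            for b, band in enumerate("rgb"):
                emit(f"offset_{model_name}_{scen}_rgb_{band}.csv",
                     _wg, as_grid(rgb[..., b]))
            offsets_summary[f"{model_name}_{scen}"] = {
                "mean_local": float(np.nanmean(loc)),
                "mean_forward_inf": float(np.nanmean(fwd_maps[dispersal_caps[-1]])),
                "mean_reverse": float(np.nanmean(rev)),
            }
    results["offset"] = offsets_summary
    emit("offset_manifest.json",
         lambda p, d: Path(p).write_text(json.dumps(d, indent=2)), offsets_summary)

    # --- SDM & ecological vulnerability ----------------------------------
    occ = simulate_occurrences(present, n=n_occurrences, seed=seed + 4)
    pb = sdm.make_presence_background(occ, present, n_background=n_background,
                                      seed=seed + 5)
    Xs = pb[[f"env_{v}" for v in present.variables]].to_numpy()
    ys = (pb["label"] == "presence").to_numpy().astype(int)
    ens = sdm.EnsembleSDM(n_replicates=sdm_replicates, random_state=seed).fit(Xs, ys)
    emit("sdm_member_metrics.tsv",
         lambda p, df: df.to_csv(p, sep="\t"), ens.member_metrics_)
    s_present = sdm.suitability_map(ens, present, present.variables)
    areas = sdm.cell_areas_km2(grid0)
    sdm_summary = {"members_accepted": ens.accepted_,
                   "threshold": ens.threshold_, "scenarios": {}}
    emit("suitability_present.csv", _wg,
         ClimateGrid(s_present, grid0.xll, grid0.yll, grid0.cellsize))
    for scen, fut in futures.items():
        s_fut = sdm.suitability_map(ens, fut, present.variables)
        ve = sdm.ecological_vulnerability(s_fut, s_present)
        change = sdm.habitat_area_change(s_present, s_fut, ens.threshold_, areas)
        emit(f"suitability_{scen}.csv", _wg,
             ClimateGrid(s_fut, grid0.xll, grid0.yll, grid0.cellsize))
        emit(f"vulnerability_{scen}.csv", _wg,
             ClimateGrid(ve, grid0.xll, grid0.yll, grid0.cellsize))
        sdm_summary["scenarios"][scen] = {
            "habitat_area_change_pct": change,
            "mean_vulnerability": float(np.nanmean(ve)),
        }
    results["sdm"] = sdm_summary
    emit("run_manifest.json",
         lambda p, d: Path(p).write_text(json.dumps(
             {k: v for k, v in d.items() if k != "outputs"}, indent=2, default=str)),
         results)
    return results
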