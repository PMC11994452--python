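"""Stage orchestration: each stage reads/writes TSV/MTX artifacts.

``run_pipeline`` executes an ordered subset of stages against one
artifact directory.  Every stage writes its outputs plus a manifest
(parameters, seed, package version, input artifacts); re-running with
the same config and seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import afmap.io as aio
from afmap import __version__
from afmap.association import (
    correlate_with_signature,
    rank_tfs_by_specificity,
    select_driver_tfs,
)
from afmap.datamodel import MotifPeakMembership, SparseCountMatrix
from afmap.de import (
    assign_degs_to_celltypes,
    concordant_degs,
    nb_glm_de,
    pseudobulk_aggregate,
    strand_artifact_check,
)
from afmap.metacell import (
    aggregate_matrix,
    assignment_table,
    make_metacells,
    metacell_metadata,
    pca_embed,
)
from afmap.motif import (
    footprint_profile,
    motif_deviations,
    peak_bias,
    sample_background_peaks,
)
from afmap.network import (
    detect_modules,
    prefilter_genes,
    residualize_covariates,
    signed_adjacency,
    topological_overlap,
)
from afmap.peaks import (
    atlas_match_fraction,
    classify_by_ccre,
    specificity_by_celltype_counts,
)
from afmap.signature import (
    ModuleScoreParams,
    build_af_signature,
    module_score,
    rank_target_genes,
)
from afmap.simulate import (
    SimConfig,
    driver_motif_sites,
    generate_bulk_cohorts,
    generate_fragments,
    generate_multiome,
    peak_intervals,
)
from afmap.stats import auc_specificity_all_groups, log_normalize

DEFAULT_PARAMS: dict = {
    # signature thresholds
    "auc_min": 0.5,
    "spec_fdr": 0.05,
    "de_fdr": 0.05,
    "lfc_min": 0.25,
    # DE / concordance
    "concordance_fdr": 0.05,
    "concordance_mode": "both",
    "min_frac": 0.05,
    "assign_fdr": 0.05,
    # meta-cells
    "k": 30,
    "max_shared": 10,
    "n_pcs": 10,
    # module score
    "n_bins": 24,
    "n_ctrl": 100,
    # motif deviations
    "bias_bins": 10,
    "n_bg": 50,
    # driver TF selection
    "driver_fdr": 0.01,
    # peak annotation
    "atlas_threshold": 0.25,
    # coexpression
    "power": 9,
    "min_module_size": 50,
    "cut_height": 0.8,  # fraction of the merge-height range
    "merge_cut_height": 0.25,
    "prefilter_base_mean": 1.0,
    "prefilter_lfc": 0.05,
    "prefilter_p": 0.05,
    # footprinting
    "footprint_window": 250,
    "flank_lo": 200,
    "flank_hi": 250,
}

STAGE_DEPS: dict[str, list[str]] = {
    "simulate": [],
    "specificity": ["simulate"],
    "pseudobulk": ["simulate"],
    "de": ["simulate", "pseudobulk"],
    "concordance": ["de"],
    "assign-celltypes": ["concordance", "de"],
    "strand-check": ["de"],
    "signature": ["specificity", "de"],
    "metacell": ["simulate"],
    "signature-score": ["signature", "metacell"],
    "motif-dev": ["simulate", "metacell"],
    "footprint": ["simulate"],
    "rank-targets": ["signature", "metacell", "specificity"],
    "associate": ["signature-score", "motif-dev", "metacell", "specificity"],
    "annotate-peaks": ["simulate"],
    "coexpress": ["simulate"],
}

ALL_STAGES = list(STAGE_DEPS)

#: artifact that proves a stage has run
STAGE_SENTINEL: dict[str, str] = {
    "simulate": "truth.json",
    "specificity": "specificity_auc.tsv",
    "pseudobulk": "pseudobulk_manifest.json",
    "de": "de_cohort1.tsv",
    "concordance": "concordant_degs.tsv",
    "assign-celltypes": "deg_celltypes.tsv",
    "strand-check": "strand_flags.tsv",
    "signature": "signature.tsv",
    "metacell": "metacells.tsv",
    "signature-score": "signature_scores.tsv",
    "motif-dev": "motif_z.tsv",
    "footprint": "footprint.tsv",
    "rank-targets": "target_rank.tsv",
    "associate": "driver_tfs.tsv",
    "annotate-peaks": "peak_annotation.tsv",
    "coexpress": "modules.tsv",
}


class StageDependencyError(RuntimeError):
    pass


def load_config(config: str | Path | dict | None, seed: int | None = None) -> dict:
    """Merge a YAML config (sections ``sim`` and ``params``) with defaults."""
    raw: dict = {}
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(config, dict):
        raw = dict(config)
    sim_kwargs = dict(raw.get("sim", {}))
    if seed is not None:
        sim_kwargs["seed"] = seed
    if "seed" not in sim_kwargs:
        raise ValueError("a seed is mandatory (config sim.seed or --seed)")
    valid = {f.name for f in fields(SimConfig)}
    unknown = set(sim_kwargs) - valid
    if unknown:
        raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
    params = dict(DEFAULT_PARAMS)
    unknown = set(raw.get("params", {})) - set(params)
    if unknown:
        raise ValueError(f"unknown params keys: {sorted(unknown)}")
    params.update(raw.get("params", {}))
    return {"sim": SimConfig(**sim_kwargs), "params": params}


def _manifest(outdir: Path, stage: str, cfg: dict, inputs: list[str], outputs: list[str]):
    man = {
        "stage": stage,
        "seed": cfg["sim"].seed,
        "sim": cfg["sim"].to_dict(),
        "params": cfg["params"],
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
        "version": __version__,
    }
    with open(outdir / f"manifest_{stage.replace('-', '_')}.json", "w") as fh:
        json.dump(man, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _require(outdir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        if not (outdir / STAGE_SENTINEL[dep]).exists():
            raise StageDependencyError(
                f"stage {stage!r} requires stage {dep!r} to have run first "
                f"(missing {STAGE_SENTINEL[dep]})"
            )


# ---------------------------------------------------------------- stages


def stage_simulate(outdir: Path, cfg: dict) -> None:
    sim: SimConfig = cfg["sim"]
    gene_counts, peak_counts, nuclei, peaks, peak_gc, membership, truth = (
        generate_multiome(sim)
    )
    aio.write_matrix_triple(gene_counts, outdir / "rna")
    aio.write_matrix_triple(peak_counts, outdir / "atac")
    aio.write_table(nuclei, outdir / "nuclei.tsv")
    aio.write_bed(peaks, outdir / "peaks.bed")
    aio.write_table(
        pd.DataFrame({"peak_id": sim.peak_ids, "gc": peak_gc}), outdir / "peak_gc.tsv"
    )
    rows = [
        {"motif_id": m, "peak_id": p}
        for m in membership.motif_ids
        for p in sorted(membership.peaks[m])
    ]
    aio.write_table(pd.DataFrame(rows), outdir / "motif_membership.tsv")

    cohorts, truth = generate_bulk_cohorts(sim)
    for name, c in cohorts.items():
        aio.write_matrix_triple(c["counts"], outdir / f"bulk_{name}")
        aio.write_matrix_triple(c["counts_unstranded"], outdir / f"bulk_{name}_unstranded")
        aio.write_table(c["samples"], outdir / f"samples_{name}.tsv")

    sites = driver_motif_sites(sim, membership, truth)
    aio.write_bed(sites, outdir / "driver_motif_sites.bed")
    frags = generate_fragments(sim, sites, nuclei)
    aio.write_fragments(frags, outdir / "fragments.tsv")

    _write_reference_annotations(outdir, cfg, peaks, membership, truth)

    truth_json = {
        "marker_map": {k: sorted(v) for k, v in truth.marker_map.items()},
        "af_up": sorted(truth.af_up),
        "af_down": sorted(truth.af_down),
        "driver_motif_id": truth.driver_motif_id,
        "driver_tf_gene": truth.driver_tf_gene,
        "motif_tf": truth.motif_tf,
        "antisense_pair": list(truth.antisense_pair),
        "bulk_deg_map": {g: list(v) for g, v in sorted(truth.bulk_deg_map.items())},
        "private_degs": {c: dict(sorted(d.items())) for c, d in truth.private_degs.items()},
        "sex_genes": sorted(truth.sex_genes),
        "batch_genes": sorted(truth.batch_genes),
        "module_map": dict(sorted(truth.module_map.items())),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _manifest(outdir, "simulate", cfg, [], ["rna", "atac", "nuclei.tsv", "peaks.bed"])


def _write_reference_annotations(outdir, cfg, peaks, membership, truth) -> None:
    """Synthetic cCREs, per-cell-type peak calls and an enhancer atlas.

    Derived deterministically from the simulation seed: cCREs cover a
    subset of peaks with class labels; each cell type "calls" a random
    subset of the unified peaks (driver peaks always called in CM); the
    atlas holds a jittered copy of each cell type's calls so analogous
    cell types match best.
    """
    sim: SimConfig = cfg["sim"]
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 5]))
    n = len(peaks)
    classes = np.array(["prom", "enhP", "enhD", "K4m3", "CTCF"])
    covered = rng.random(n) < 0.73  # fraction of peaks with a cCRE
    ccre_rows = peaks.loc[covered].copy()
    ccre_rows["label"] = rng.choice(classes, size=int(covered.sum()), p=[0.2, 0.2, 0.4, 0.1, 0.1])
    aio.write_bed(ccre_rows, outdir / "ccres.bed")

    driver_idx = sorted(
        int(p[4:]) for p in membership.peaks[truth.driver_motif_id]
    )
    for ct in sim.celltypes:
        called = rng.random(n) < 0.3
        if ct == "CM":
            called[driver_idx] = True
        sub = peaks.loc[called, ["chrom", "start", "end"]].copy()
        aio.write_bed(sub, outdir / f"calls_{ct}.bed")
        jitter = rng.integers(-50, 51, size=len(sub))
        atlas = sub.copy()
        atlas["start"] = np.maximum(atlas["start"] + jitter, 0)
        atlas["end"] = atlas["end"] + jitter
        # atlas keeps ~80% of the cell type's peaks
        atlas = atlas.loc[rng.random(len(atlas)) < 0.8]
        aio.write_bed(atlas, outdir / f"atlas_{ct}.bed")


def _load_multiome(outdir: Path):
    rna = aio.read_matrix_triple(outdir / "rna")
    nuclei = aio.read_table(outdir / "nuclei.tsv")
    return rna, nuclei


def stage_specificity(outdir: Path, cfg: dict) -> None:
    _require(outdir, "specificity")
    rna, nuclei = _load_multiome(outdir)
    norm = log_normalize(rna)
    auc = auc_specificity_all_groups(norm, nuclei["cell_type"].to_numpy())
    aio.write_table(auc, outdir / "specificity_auc.tsv")
    _manifest(outdir, "specificity", cfg, ["rna", "nuclei.tsv"], ["specificity_auc.tsv"])


def stage_pseudobulk(outdir: Path, cfg: dict) -> None:
    _require(outdir, "pseudobulk")
    rna, nuclei = _load_multiome(outdir)
    pb = pseudobulk_aggregate(rna, nuclei, min_frac=cfg["params"]["min_frac"])
    written = []
    for ct, d in pb.items():
        aio.write_matrix_triple(d["counts"], outdir / f"pseudobulk_{ct}")
        aio.write_table(d["samples"], outdir / f"pseudobulk_{ct}_samples.tsv")
        written.append({"cell_type": ct, "testable": d["testable"]})
    with open(outdir / "pseudobulk_manifest.json", "w") as fh:
        json.dump(written, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _manifest(outdir, "pseudobulk", cfg, ["rna", "nuclei.tsv"],
              [f"pseudobulk_{w['cell_type']}" for w in written])


def stage_de(outdir: Path, cfg: dict) -> None:
    _require(outdir, "de")
    outputs = []
    for cohort in ("cohort1", "cohort2"):
        samples = aio.read_table(outdir / f"samples_{cohort}.tsv")
        for suffix in ("", "_unstranded"):
            counts = aio.read_matrix_triple(outdir / f"bulk_{cohort}{suffix}")
            de = nb_glm_de(counts, samples, covariates=["sex"])
            aio.write_table(de, outdir / f"de_{cohort}{suffix}.tsv")
            outputs.append(f"de_{cohort}{suffix}.tsv")
    # merged-cohort DE with a dataset dummy (feeds coexpression)
    c1 = aio.read_matrix_triple(outdir / "bulk_cohort1")
    c2 = aio.read_matrix_triple(outdir / "bulk_cohort2")
    merged = SparseCountMatrix(
        __import__("scipy.sparse", fromlist=["vstack"]).vstack([c1.matrix, c2.matrix]),
        c1.obs_ids + c2.obs_ids,
        c1.feature_ids,
    )
    s1 = aio.read_table(outdir / "samples_cohort1.tsv")
    s2 = aio.read_table(outdir / "samples_cohort2.tsv")
    samples = pd.concat([s1, s2], ignore_index=True)
    samples["dataset"] = (samples["cohort"] == "cohort2").astype(int)
    de_merged = nb_glm_de(merged, samples, covariates=["sex", "dataset"])
    aio.write_table(de_merged, outdir / "de_merged.tsv")
    outputs.append("de_merged.tsv")
    # per-cell-type pseudobulk DE
    with open(outdir / "pseudobulk_manifest.json") as fh:
        pbman = json.load(fh)
    for entry in pbman:
        ct = entry["cell_type"]
        if not entry["testable"]:
            continue
        counts = aio.read_matrix_triple(outdir / f"pseudobulk_{ct}")
        samples_ct = aio.read_table(outdir / f"pseudobulk_{ct}_samples.tsv")
        de = nb_glm_de(counts, samples_ct)
        aio.write_table(de, outdir / f"de_celltype_{ct}.tsv")
        outputs.append(f"de_celltype_{ct}.tsv")
    _manifest(outdir, "de", cfg, ["bulk_cohort1", "bulk_cohort2"], outputs)


def stage_concordance(outdir: Path, cfg: dict) -> None:
    _require(outdir, "concordance")
    de1 = aio.read_table(outdir / "de_cohort1.tsv")
    de2 = aio.read_table(outdir / "de_cohort2.tsv")
    conc = concordant_degs(
        de1, de2, fdr=cfg["params"]["concordance_fdr"], mode=cfg["params"]["concordance_mode"]
    )
    aio.write_table(conc, outdir / "concordant_degs.tsv")
    _manifest(outdir, "concordance", cfg, ["de_cohort1.tsv", "de_cohort2.tsv"],
              ["concordant_degs.tsv"])


def stage_assign_celltypes(outdir: Path, cfg: dict) -> None:
    _require(outdir, "assign-celltypes")
    conc = aio.read_table(outdir / "concordant_degs.tsv")
    per_ct = {
        p.stem.replace("de_celltype_", ""): aio.read_table(p)
        for p in sorted(outdir.glob("de_celltype_*.tsv"))
    }
    table = assign_degs_to_celltypes(conc, per_ct, fdr=cfg["params"]["assign_fdr"])
    aio.write_table(table, outdir / "deg_celltypes.tsv")
    _manifest(outdir, "assign-celltypes", cfg, ["concordant_degs.tsv"], ["deg_celltypes.tsv"])


def stage_strand_check(outdir: Path, cfg: dict) -> None:
    _require(outdir, "strand-check")
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    pair = tuple(truth["antisense_pair"])
    frames = []
    for cohort in ("cohort1", "cohort2"):
        s = aio.read_table(outdir / f"de_{cohort}.tsv")
        u = aio.read_table(outdir / f"de_{cohort}_unstranded.tsv")
        t = strand_artifact_check(s, u, [pair], fdr=cfg["params"]["concordance_fdr"])
        t.insert(0, "cohort", cohort)
        frames.append(t)
    aio.write_table(pd.concat(frames, ignore_index=True), outdir / "strand_flags.tsv")
    _manifest(outdir, "strand-check", cfg, ["de_cohort1.tsv"], ["strand_flags.tsv"])


def stage_signature(outdir: Path, cfg: dict, target_celltype: str = "CM") -> None:
    _require(outdir, "signature")
    p = cfg["params"]
    auc = aio.read_table(outdir / "specificity_auc.tsv")
    spec = auc.loc[auc["group"] == target_celltype]
    de1 = aio.read_table(outdir / "de_cohort1.tsv")
    de2 = aio.read_table(outdir / "de_cohort2.tsv")
    sig = build_af_signature(
        spec, de1, de2, name=f"AF_{target_celltype}",
        auc_min=p["auc_min"], spec_fdr=p["spec_fdr"],
        de_fdr=p["de_fdr"], lfc_min=p["lfc_min"],
    )
    aio.write_signature(sig, outdir / "signature.tsv")
    _manifest(outdir, "signature", cfg, ["specificity_auc.tsv", "de_cohort1.tsv"],
              ["signature.tsv"])


def stage_metacell(outdir: Path, cfg: dict) -> None:
    _require(outdir, "metacell")
    p = cfg["params"]
    rna, nuclei = _load_multiome(outdir)
    atac = aio.read_matrix_triple(outdir / "atac")
    emb = pca_embed(log_normalize(rna), n_components=p["n_pcs"])
    assignment = make_metacells(
        emb.coords, nuclei, k=p["k"], max_shared=p["max_shared"], seed=cfg["sim"].seed
    )
    aio.write_table(assignment_table(assignment), outdir / "metacells.tsv")
    aio.write_table(metacell_metadata(assignment), outdir / "metacell_meta.tsv")
    aio.write_matrix_triple(aggregate_matrix(rna, assignment), outdir / "rna_metacell")
    aio.write_matrix_triple(aggregate_matrix(atac, assignment), outdir / "atac_metacell")
    _manifest(outdir, "metacell", cfg, ["rna", "atac", "nuclei.tsv"],
              ["metacells.tsv", "rna_metacell", "atac_metacell"])


def stage_signature_score(outdir: Path, cfg: dict) -> None:
    _require(outdir, "signature-score")
    p = cfg["params"]
    sig = aio.read_signature(outdir / "signature.tsv")
    mc_rna = aio.read_matrix_triple(outdir / "rna_metacell")
    norm = log_normalize(mc_rna)
    params = ModuleScoreParams(n_bins=p["n_bins"], n_ctrl=p["n_ctrl"], seed=cfg["sim"].seed)
    out = pd.DataFrame({"metacell_id": mc_rna.obs_ids})
    for direction, genes in (("up", sig.up_genes), ("down", sig.down_genes)):
        if genes:
            out[f"score_{direction}"] = module_score(norm, genes, params).to_numpy()
        else:
            out[f"score_{direction}"] = np.nan
    aio.write_table(out, outdir / "signature_scores.tsv")
    _manifest(outdir, "signature-score", cfg, ["signature.tsv", "rna_metacell"],
              ["signature_scores.tsv"])


def _load_membership(outdir: Path) -> MotifPeakMembership:
    mm = aio.read_table(outdir / "motif_membership.tsv")
    return MotifPeakMembership(
        {m: set(g["peak_id"]) for m, g in mm.groupby("motif_id")}
    )


def stage_motif_dev(outdir: Path, cfg: dict) -> None:
    _require(outdir, "motif-dev")
    p = cfg["params"]
    mc_atac = aio.read_matrix_triple(outdir / "atac_metacell")
    gc = aio.read_table(outdir / "peak_gc.tsv")["gc"].to_numpy()
    membership = _load_membership(outdir)
    bias = peak_bias(mc_atac, gc, n_bins=p["bias_bins"])
    bg = sample_background_peaks(bias, n_bg=p["n_bg"], seed=cfg["sim"].seed)
    dev = motif_deviations(mc_atac, membership, bg)
    z = dev.z.reset_index().rename(columns={"obs_id": "metacell_id"})
    aio.write_table(z, outdir / "motif_z.tsv")
    _manifest(outdir, "motif-dev", cfg, ["atac_metacell", "peak_gc.tsv"], ["motif_z.tsv"])


def stage_footprint(outdir: Path, cfg: dict) -> None:
    _require(outdir, "footprint")
    p = cfg["params"]
    frags = aio.read_fragments(outdir / "fragments.tsv")
    sites = aio.read_bed(outdir / "driver_motif_sites.bed")
    nuclei = aio.read_table(outdir / "nuclei.tsv")
    groups = {
        "AF_CM": set(nuclei.loc[(nuclei.condition == "AF") & (nuclei.cell_type == "CM"),
                                "nucleus_id"]),
        "SR_CM": set(nuclei.loc[(nuclei.condition == "SR") & (nuclei.cell_type == "CM"),
                                "nucleus_id"]),
        "other": set(nuclei.loc[nuclei.cell_type != "CM", "nucleus_id"]),
    }
    prof = footprint_profile(
        frags, sites, groups, window=p["footprint_window"],
        flank=(p["flank_lo"], p["flank_hi"]),
    )
    aio.write_table(prof.reset_index(), outdir / "footprint.tsv")
    _manifest(outdir, "footprint", cfg, ["fragments.tsv", "driver_motif_sites.bed"],
              ["footprint.tsv"])


def _cm_condition_auc(outdir: Path, cfg: dict) -> pd.DataFrame:
    """AF-vs-SR expression AUC across CM meta-cells."""
    mc_rna = aio.read_matrix_triple(outdir / "rna_metacell")
    meta = aio.read_table(outdir / "metacell_meta.tsv")
    cm = meta.loc[meta["cell_type"] == "CM"]
    cond = np.where(cm["donor_id"].str.startswith("AF"), "AF", "SR")
    keep = [mc_rna.obs_ids.index(m) for m in cm["metacell_id"]]
    sub = mc_rna.subset_obs(np.array(keep))
    norm = log_normalize(sub)
    auc = auc_specificity_all_groups(norm, cond)
    return auc.loc[auc["group"] == "AF"].reset_index(drop=True)


def stage_rank_targets(outdir: Path, cfg: dict) -> None:
    _require(outdir, "rank-targets")
    sig = aio.read_signature(outdir / "signature.tsv")
    auc = aio.read_table(outdir / "specificity_auc.tsv")
    ct_auc = auc.loc[auc["group"] == "CM"].reset_index(drop=True)
    cond_auc = _cm_condition_auc(outdir, cfg)
    ranked = rank_target_genes(ct_auc, cond_auc, sig)
    aio.write_table(ranked, outdir / "target_rank.tsv")
    _manifest(outdir, "rank-targets", cfg, ["signature.tsv", "rna_metacell"],
              ["target_rank.tsv"])


def stage_associate(outdir: Path, cfg: dict, exclude: set[str] | None = None) -> None:
    _require(outdir, "associate")
    p = cfg["params"]
    with open(outdir / "truth.json") as fh:
        motif_tf = json.load(fh)["motif_tf"]
    meta = aio.read_table(outdir / "metacell_meta.tsv")
    cm_ids = list(meta.loc[meta["cell_type"] == "CM", "metacell_id"])
    scores = aio.read_table(outdir / "signature_scores.tsv").set_index("metacell_id")
    score_up = scores.loc[cm_ids, "score_up"]
    motif_z = aio.read_table(outdir / "motif_z.tsv").set_index("metacell_id").loc[cm_ids]
    corr_motif = correlate_with_signature(score_up, motif_z, exclude=exclude)

    mc_rna = aio.read_matrix_triple(outdir / "rna_metacell")
    norm = log_normalize(mc_rna)
    tf_genes = sorted(set(motif_tf.values()))
    gidx = [norm.feature_ids.index(g) for g in tf_genes]
    expr = pd.DataFrame(
        norm.to_dense()[:, gidx], index=norm.obs_index(), columns=tf_genes
    ).loc[cm_ids]
    corr_expr = correlate_with_signature(score_up, expr, exclude=exclude)
    drivers = select_driver_tfs(corr_motif, corr_expr, motif_tf, fdr_max=p["driver_fdr"])
    aio.write_table(drivers, outdir / "driver_tfs.tsv")

    # cell-type-level TF prioritization: expression AUC x motif-activity AUC
    gene_auc = aio.read_table(outdir / "specificity_auc.tsv")
    meta_ct = meta.set_index("metacell_id").loc[
        aio.read_table(outdir / "motif_z.tsv")["metacell_id"]
    ]
    motif_all = aio.read_table(outdir / "motif_z.tsv").set_index("metacell_id")
    motif_auc = auc_specificity_all_groups(
        motif_all.to_numpy(), meta_ct["cell_type"].to_numpy(),
        feature_ids=list(motif_all.columns),
    )
    tf_rank = rank_tfs_by_specificity(gene_auc, motif_auc, motif_tf)
    aio.write_table(tf_rank, outdir / "tf_rank.tsv")
    _manifest(outdir, "associate", cfg,
              ["signature_scores.tsv", "motif_z.tsv", "specificity_auc.tsv"],
              ["driver_tfs.tsv", "tf_rank.tsv"])


def stage_annotate_peaks(outdir: Path, cfg: dict) -> None:
    _require(outdir, "annotate-peaks")
    sim: SimConfig = cfg["sim"]
    peaks = aio.read_bed(outdir / "peaks.bed")
    ccres = aio.read_bed(outdir / "ccres.bed")
    classes = classify_by_ccre(peaks, ccres)
    calls = {ct: aio.read_bed(outdir / f"calls_{ct}.bed") for ct in sim.celltypes}
    peak_table, summary = specificity_by_celltype_counts(calls, peaks, classes)
    peak_table.insert(0, "peak_id", peaks["label"])
    aio.write_table(peak_table, outdir / "peak_annotation.tsv")
    aio.write_table(summary, outdir / "peak_annotation_summary.tsv")
    atlas = {ct: aio.read_bed(outdir / f"atlas_{ct}.bed") for ct in sim.celltypes}
    mat, filtered = atlas_match_fraction(calls, atlas, threshold=cfg["params"]["atlas_threshold"])
    aio.write_table(mat.reset_index().rename(columns={"index": "cell_type"}),
                    outdir / "atlas_fractions.tsv")
    aio.write_table(filtered, outdir / "atlas_pairs.tsv")
    _manifest(outdir, "annotate-peaks", cfg, ["peaks.bed", "ccres.bed"],
              ["peak_annotation.tsv", "atlas_fractions.tsv"])


def stage_coexpress(outdir: Path, cfg: dict) -> None:
    _require(outdir, "coexpress")
    p = cfg["params"]
    de_path = outdir / "de_merged.tsv"
    if not de_path.exists():
        raise StageDependencyError("stage 'coexpress' requires stage 'de' (missing de_merged.tsv)")
    de_merged = aio.read_table(de_path)
    keep = prefilter_genes(
        de_merged, base_mean_min=p["prefilter_base_mean"],
        lfc_min=p["prefilter_lfc"], p_max=p["prefilter_p"],
    )
    c1 = aio.read_matrix_triple(outdir / "bulk_cohort1")
    c2 = aio.read_matrix_triple(outdir / "bulk_cohort2")
    import scipy.sparse as sp

    merged = SparseCountMatrix(
        sp.vstack([c1.matrix, c2.matrix]), c1.obs_ids + c2.obs_ids, c1.feature_ids
    )
    s1 = aio.read_table(outdir / "samples_cohort1.tsv")
    s2 = aio.read_table(outdir / "samples_cohort2.tsv")
    samples = pd.concat([s1, s2], ignore_index=True)
    norm = log_normalize(merged, scale=1e6)
    gidx = [merged.feature_ids.index(g) for g in keep]
    expr = pd.DataFrame(norm.to_dense()[:, gidx], index=merged.obs_ids, columns=keep)
    covs = pd.DataFrame(
        {"sex": samples["sex"].to_numpy(),
         "dataset": (samples["cohort"] == "cohort2").astype(int).to_numpy()},
        index=expr.index,
    )
    corrected = residualize_covariates(expr, covs)
    adj = signed_adjacency(corrected, power=p["power"])
    tom = topological_overlap(adj)
    part = detect_modules(
        tom, corrected, min_module_size=p["min_module_size"],
        cut_height=p["cut_height"], merge_cut_height=p["merge_cut_height"],
    )
    aio.write_table(
        part.labels.rename("module").rename_axis("gene_id").reset_index(),
        outdir / "modules.tsv",
    )
    aio.write_table(
        part.eigengenes.rename_axis("sample_id").reset_index(), outdir / "eigengenes.tsv"
    )
    _manifest(outdir, "coexpress", cfg, ["de_merged.tsv", "bulk_cohort1", "bulk_cohort2"],
              ["modules.tsv", "eigengenes.tsv"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "specificity": stage_specificity,
    "pseudobulk": stage_pseudobulk,
    "de": stage_de,
    "concordance": stage_concordance,
    "assign-celltypes": stage_assign_celltypes,
    "strand-check": stage_strand_check,
    "signature": stage_signature,
    "metacell": stage_metacell,
    "signature-score": stage_signature_score,
    "motif-dev": stage_motif_dev,
    "footprint": stage_footprint,
    "rank-targets": stage_rank_targets,
    "associate": stage_associate,
    "annotate-peaks": stage_annotate_peaks,
    "coexpress": stage_coexpress,
}


def run_pipeline(
    config: str | Path | dict | None,
    outdir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
) -> Path:
    """Run an ordered subset of stages (default: all) into ``outdir``."""
    cfg = load_config(config, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or ALL_STAGES)
    unknown = set(stages) - set(STAGE_FUNCS)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        STAGE_FUNCS[stage](outdir, cfg)
    return outdir
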