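"""Synthetic multiome, bulk-cohort and fragment data with planted truth.

The generator emulates the structure of a left-atrial-appendage study:
a small 10x-multiome cohort (a few donors per rhythm condition, 6-12
cell types with planted marker genes, a cardiomyocyte-restricted AF
up/down expression program, a "driver" transcription-factor motif whose
peaks gain accessibility in AF cardiomyocytes) and two bulk RNA-seq
cohorts that share a subset of planted differentially expressed genes,
carry a sex covariate and a cohort batch effect, contain planted
coexpression modules, and include one overlapping antisense gene pair
whose counts collapse to their sum when strand information is dropped.

Counts are negative binomial with mean ``mu`` and dispersion ``alpha``
(variance ``mu + alpha * mu**2``); per-observation library sizes are
log-normal.  Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from afmap.datamodel import (
    MotifPeakMembership,
    SparseCountMatrix,
    make_interval_set,
    make_nucleus_table,
)

CELLTYPE_POOL = [
    "CM", "FB", "EC", "Pericyte", "Myeloid", "Endocardial", "Adipo", "SMC",
    "Lymphoid", "Neuronal", "Mesothelial", "Mast",
]

PEAK_SPACING = 600
PEAK_WIDTH = 500


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """All knobs of the synthetic world.

    Defaults emulate the study design at desk scale: 4 donors per
    rhythm condition, 8 cell types with cardiomyocytes and fibroblasts
    most abundant (25% / 23%), and two bulk cohorts of 40 AF + 40 SR
    samples each.
    """

    seed: int
    # multiome
    n_donors_per_condition: int = 4
    n_celltypes: int = 8
    nuclei_per_donor: int = 400
    n_genes: int = 2000
    n_peaks: int = 3000
    n_motifs: int = 20
    peaks_per_motif: int = 30
    markers_per_celltype: int = 20
    marker_effect: float = 3.0  # multiplicative mean uplift in own cell type
    n_planted_up: int = 30
    n_planted_down: int = 30
    af_effect: float = 2.0  # condition effect on the CM AF program
    af_celltype_uplift: float = 3.0  # CM-specific baseline of program genes
    driver_motif_effect: float = 2.0  # accessibility gain in AF CM
    driver_celltype_effect: float = 2.0  # accessibility gain in all CM
    nb_dispersion: float = 0.2
    libsize_sigma: float = 0.3
    # bulk cohorts
    bulk_n_samples: int = 40  # per cohort per condition
    bulk_mean_scale: float = 100.0
    shared_lfc: tuple[float, float] = (1.0, 0.8)  # per-cohort log2fc of shared DEGs
    n_extra_shared: int = 20
    n_private_degs: int = 20  # per cohort
    private_lfc: float = 1.0
    n_sex_genes: int = 50
    sex_effect: float = 1.0  # additive log2 shift in male samples
    n_batch_genes: int = 100
    batch_effect: float = 1.0  # additive log2 shift in cohort 2
    # planted coexpression modules (bulk)
    n_modules: int = 3
    module_size: int = 60
    module_loading: float = 0.7  # natural-log loading on the latent factor
    module_condition_shift: float = 1.0  # latent-factor shift in AF samples
    # fragments / footprinting
    bg_insertions_per_nucleus: float = 100.0
    footprint_rate: float = 2.0  # site-directed insertions per CM nucleus per site
    footprint_af_effect: float = 2.0  # AF-CM rate multiplier
    footprint_core: int = 10  # protected half-width, bp
    footprint_enrich: int = 150  # half-width of the enriched region, bp
    footprint_window: int = 250  # flank half-width, bp

    def __post_init__(self) -> None:
        for name in (
            "n_donors_per_condition", "n_celltypes", "nuclei_per_donor",
            "n_genes", "n_peaks", "n_motifs", "peaks_per_motif",
            "markers_per_celltype", "bulk_n_samples",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (2 <= self.n_celltypes <= len(CELLTYPE_POOL)):
            raise ConfigError(f"n_celltypes must be in [2, {len(CELLTYPE_POOL)}]")
        n_special = (
            self.n_celltypes * self.markers_per_celltype
            + self.n_planted_up + self.n_planted_down
            + self.n_extra_shared + 2 * self.n_private_degs
            + self.n_sex_genes + self.n_modules * self.module_size + 2
        )
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ConfigError("planted AF program larger than the gene universe")
        if n_special > self.n_genes:
            raise ConfigError(
                f"planted gene sets need {n_special} genes but n_genes={self.n_genes}"
            )
        if self.bulk_n_samples < 2:
            raise ConfigError("need at least 2 samples per condition per cohort")
        if not np.isfinite(
            [self.marker_effect, self.af_effect, self.driver_motif_effect]
        ).all():
            raise ConfigError("effect sizes must be finite")

    @property
    def celltypes(self) -> list[str]:
        return CELLTYPE_POOL[: self.n_celltypes]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    @property
    def peak_ids(self) -> list[str]:
        return [f"peak{i:05d}" for i in range(self.n_peaks)]

    @property
    def chrom_length(self) -> int:
        return self.n_peaks * PEAK_SPACING + PEAK_SPACING

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Truth:
    """Index of every planted effect, keyed by generated identifiers."""

    marker_map: dict[str, set[str]] = field(default_factory=dict)
    af_up: set[str] = field(default_factory=set)
    af_down: set[str] = field(default_factory=set)
    driver_motif_id: str = ""
    driver_tf_gene: str = ""
    motif_tf: dict[str, str] = field(default_factory=dict)
    antisense_pair: tuple[str, str] = ("", "")
    bulk_deg_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    private_degs: dict[str, dict[str, float]] = field(default_factory=dict)
    sex_genes: set[str] = field(default_factory=set)
    batch_genes: set[str] = field(default_factory=set)
    module_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.af_up & self.af_down:
            raise ConfigError("af_up and af_down overlap")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2 (Poisson when alpha ~ 0)."""
    mu = np.asarray(mu, dtype=np.float64)
    if alpha < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / alpha
    # Gamma-Poisson mixture: lambda ~ Gamma(r, scale=mu/r)
    lam = rng.gamma(shape=r, scale=np.maximum(mu, 1e-300) / r)
    return rng.poisson(lam)


def _plant_gene_sets(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Deterministically carve disjoint planted gene sets out of the universe."""
    genes = np.array(cfg.gene_ids)
    perm = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(n):
        nonlocal cursor
        sel = genes[perm[cursor : cursor + n]]
        cursor += n
        return list(sel)

    sets = {}
    sets["markers"] = {ct: take(cfg.markers_per_celltype) for ct in cfg.celltypes}
    sets["af_up"] = take(cfg.n_planted_up)
    sets["af_down"] = take(cfg.n_planted_down)
    sets["extra_shared"] = take(cfg.n_extra_shared)
    sets["private1"] = take(cfg.n_private_degs)
    sets["private2"] = take(cfg.n_private_degs)
    sets["sex"] = take(cfg.n_sex_genes)
    sets["modules"] = {m + 1: take(cfg.module_size) for m in range(cfg.n_modules)}
    pair = take(2)
    sets["antisense"] = (pair[0], pair[1])
    return sets


def _base_gene_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return 0.5 * rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)


def _floor_planted_genes(base: np.ndarray, cfg: SimConfig, truth: "Truth") -> np.ndarray:
    """Planted markers and AF-program genes get at least median expression.

    Marker genes and disease-program members are, by construction of
    such lists in real data, well-detected genes; leaving them at the
    bottom of the expression distribution would plant effects that no
    method (nor the data) could carry.
    """
    planted = set().union(*truth.marker_map.values(), truth.af_up, truth.af_down)
    idx = [i for i, g in enumerate(cfg.gene_ids) if g in planted]
    out = base.copy()
    out[idx] = np.maximum(out[idx], np.median(base))
    return out


def make_truth(cfg: SimConfig) -> Truth:
    """Planted ground truth shared by all generators for one config."""
    ss = np.random.SeedSequence([cfg.seed, 0])
    rng = np.random.default_rng(ss)
    sets = _plant_gene_sets(cfg, rng)
    lfc1, lfc2 = cfg.shared_lfc
    bulk_deg_map: dict[str, tuple[float, float]] = {}
    for g in sets["af_up"]:
        bulk_deg_map[g] = (lfc1, lfc2)
    for g in sets["af_down"]:
        bulk_deg_map[g] = (-lfc1, -lfc2)
    extra_signs = rng.choice([-1.0, 1.0], size=len(sets["extra_shared"]))
    for g, s in zip(sets["extra_shared"], extra_signs):
        bulk_deg_map[g] = (s * lfc1, s * lfc2)
    gene_plus, gene_minus = sets["antisense"]
    bulk_deg_map[gene_plus] = (lfc1, lfc2)

    private = {
        "cohort1": {g: cfg.private_lfc * s for g, s in
                    zip(sets["private1"], rng.choice([-1.0, 1.0], len(sets["private1"])))},
        "cohort2": {g: cfg.private_lfc * s for g, s in
                    zip(sets["private2"], rng.choice([-1.0, 1.0], len(sets["private2"])))},
    }

    motif_ids = [f"motif{j:03d}" for j in range(cfg.n_motifs)]
    driver_motif = motif_ids[0]
    driver_tf = sets["af_up"][0]
    # TF genes behind the other motifs: ordinary genes outside all planted sets
    special = set().union(
        *sets["markers"].values(), sets["af_up"], sets["af_down"],
        sets["extra_shared"], sets["private1"], sets["private2"], sets["sex"],
        *sets["modules"].values(), set(sets["antisense"]),
    )
    plain = [g for g in cfg.gene_ids if g not in special]
    tf_pool = list(rng.choice(plain, size=cfg.n_motifs - 1, replace=False))
    motif_tf = {driver_motif: driver_tf}
    for m, g in zip(motif_ids[1:], tf_pool):
        motif_tf[m] = g

    module_map = {g: m for m, gl in sets["modules"].items() for g in gl}
    return Truth(
        marker_map={ct: set(v) for ct, v in sets["markers"].items()},
        af_up=set(sets["af_up"]),
        af_down=set(sets["af_down"]),
        driver_motif_id=driver_motif,
        driver_tf_gene=driver_tf,
        motif_tf=motif_tf,
        antisense_pair=(gene_plus, gene_minus),
        bulk_deg_map=bulk_deg_map,
        private_degs=private,
        sex_genes=set(sets["sex"]),
        batch_genes=set(),  # filled by the bulk generator
        module_map=module_map,
    )


def _celltype_proportions(cfg: SimConfig) -> np.ndarray:
    """CM and FB dominate (25% / 23%); remaining mass split evenly."""
    p = np.full(cfg.n_celltypes, np.nan)
    named = {"CM": 0.25, "FB": 0.23}
    rest = [i for i, ct in enumerate(cfg.celltypes) if ct not in named]
    used = 0.0
    for i, ct in enumerate(cfg.celltypes):
        if ct in named:
            p[i] = named[ct]
            used += named[ct]
    p[rest] = (1.0 - used) / len(rest)
    return p


def peak_intervals(cfg: SimConfig) -> pd.DataFrame:
    """Peak coordinates: tiled along one synthetic chromosome."""
    starts = np.arange(cfg.n_peaks) * PEAK_SPACING
    return make_interval_set(
        chrom=["chrS"] * cfg.n_peaks,
        start=starts,
        end=starts + PEAK_WIDTH,
        label=cfg.peak_ids,
    )


def generate_multiome(cfg: SimConfig):
    """Generate the paired snRNA/snATAC dataset.

    Returns ``(gene_counts, peak_counts, nucleus_table, peaks, peak_gc,
    membership, truth)``.  Gene counts carry cell-type marker uplifts
    and a CM-restricted AF program; peak counts carry the driver-motif
    accessibility gains; peak GC is Beta(5, 5) for all peaks so the
    bias-matched background is non-trivial.
    """
    truth = make_truth(cfg)
    ss = np.random.SeedSequence([cfg.seed, 1])
    rng = np.random.default_rng(ss)

    # nuclei
    donors = [f"AF{i+1}" for i in range(cfg.n_donors_per_condition)] + [
        f"SR{i+1}" for i in range(cfg.n_donors_per_condition)
    ]
    conditions = ["AF"] * cfg.n_donors_per_condition + ["SR"] * cfg.n_donors_per_condition
    props = _celltype_proportions(cfg)
    nuc_donor, nuc_cond, nuc_ct = [], [], []
    for d, c in zip(donors, conditions):
        cts = rng.choice(cfg.celltypes, size=cfg.nuclei_per_donor, p=props)
        nuc_donor += [d] * cfg.nuclei_per_donor
        nuc_cond += [c] * cfg.nuclei_per_donor
        nuc_ct += list(cts)
    n_nuclei = len(nuc_donor)
    nucleus_ids = [f"nuc{i:05d}" for i in range(n_nuclei)]
    nucleus_table = make_nucleus_table(nucleus_ids, nuc_donor, nuc_cond, nuc_ct)

    gene_pos = {g: i for i, g in enumerate(cfg.gene_ids)}
    base = _floor_planted_genes(
        _base_gene_means(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))),
        cfg, truth,
    )

    # per-cell-type mean multipliers
    ct_mult = np.ones((cfg.n_celltypes, cfg.n_genes))
    for k, ct in enumerate(cfg.celltypes):
        idx = [gene_pos[g] for g in truth.marker_map[ct]]
        ct_mult[k, idx] *= cfg.marker_effect
    cm_k = cfg.celltypes.index("CM")
    prog_idx = [gene_pos[g] for g in sorted(truth.af_up | truth.af_down)]
    ct_mult[cm_k, prog_idx] *= cfg.af_celltype_uplift

    ct_of = np.array([cfg.celltypes.index(ct) for ct in nuc_ct])
    is_af = np.array([c == "AF" for c in nuc_cond])
    mu = base[None, :] * ct_mult[ct_of]
    # AF program in CM only
    af_cm = is_af & (ct_of == cm_k)
    up_idx = [gene_pos[g] for g in sorted(truth.af_up)]
    dn_idx = [gene_pos[g] for g in sorted(truth.af_down)]
    mu[np.ix_(af_cm, up_idx)] *= cfg.af_effect
    mu[np.ix_(af_cm, dn_idx)] /= cfg.af_effect
    sizef = rng.lognormal(0.0, cfg.libsize_sigma, size=n_nuclei)
    mu *= sizef[:, None]
    gene_counts = SparseCountMatrix(
        sp.csr_matrix(_nb_draw(rng, mu, cfg.nb_dispersion)), nucleus_ids, cfg.gene_ids
    )
    del mu

    # peaks
    peak_base = 0.2 * rng.lognormal(0.0, 0.8, size=cfg.n_peaks)
    peak_gc = rng.beta(5.0, 5.0, size=cfg.n_peaks)
    membership = _sample_membership(cfg, rng)
    driver_idx = sorted(
        cfg.peak_ids.index(p) for p in membership.peaks[truth.driver_motif_id]
    )
    mu_p = np.tile(peak_base, (n_nuclei, 1))
    is_cm = ct_of == cm_k
    mu_p[np.ix_(is_cm, driver_idx)] *= cfg.driver_celltype_effect
    mu_p[np.ix_(af_cm, driver_idx)] *= cfg.driver_motif_effect
    sizef_p = rng.lognormal(0.0, cfg.libsize_sigma, size=n_nuclei)
    mu_p *= sizef_p[:, None]
    peak_counts = SparseCountMatrix(
        sp.csr_matrix(_nb_draw(rng, mu_p, cfg.nb_dispersion)), nucleus_ids, cfg.peak_ids
    )
    del mu_p

    peaks = peak_intervals(cfg)
    return gene_counts, peak_counts, nucleus_table, peaks, peak_gc, membership, truth


def _sample_membership(cfg: SimConfig, rng: np.random.Generator) -> MotifPeakMembership:
    motif_ids = [f"motif{j:03d}" for j in range(cfg.n_motifs)]
    peaks = {}
    for m in motif_ids:
        sel = rng.choice(cfg.n_peaks, size=min(cfg.peaks_per_motif, cfg.n_peaks), replace=False)
        peaks[m] = {cfg.peak_ids[i] for i in sorted(sel)}
    return MotifPeakMembership(peaks)


def generate_bulk_cohorts(cfg: SimConfig):
    """Generate the two bulk RNA-seq cohorts.

    Returns ``(cohorts, truth)`` where ``cohorts[name]`` holds
    ``counts`` (stranded), ``counts_unstranded`` (the antisense pair
    collapsed to its per-sample sum for both genes) and ``samples``
    (sample table with condition and sex).  Shared planted DEGs have
    concordant per-cohort log2 fold changes; each cohort also carries
    private DEGs, a sex-linked gene set, a cohort-2 batch shift and
    ``n_modules`` correlated gene modules whose latent factor is
    shifted in AF samples.
    """
    truth = make_truth(cfg)
    ss = np.random.SeedSequence([cfg.seed, 3])
    rng = np.random.default_rng(ss)
    base = cfg.bulk_mean_scale * _floor_planted_genes(
        _base_gene_means(cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))),
        cfg, truth,
    )
    gene_pos = {g: i for i, g in enumerate(cfg.gene_ids)}

    # cohort-2 batch genes: disjoint from every planted set by construction
    planted = (
        set(truth.bulk_deg_map) | truth.sex_genes | set(truth.module_map)
        | set(truth.antisense_pair)
        | set(truth.private_degs["cohort1"]) | set(truth.private_degs["cohort2"])
    )
    free = [g for g in cfg.gene_ids if g not in planted]
    batch_genes = list(rng.choice(free, size=min(cfg.n_batch_genes, len(free)), replace=False))
    truth.batch_genes = set(batch_genes)

    module_idx = {
        m: [gene_pos[g] for g in sorted(g for g, mm in truth.module_map.items() if mm == m)]
        for m in range(1, cfg.n_modules + 1)
    }
    module_sign = {m: (1.0 if m % 2 == 1 else -1.0) for m in module_idx}

    cohorts = {}
    for ci, cname in enumerate(["cohort1", "cohort2"], start=1):
        n = cfg.bulk_n_samples
        sample_ids = [f"{cname}_{c}{i:03d}" for c in ("AF", "SR") for i in range(n)]
        condition = ["AF"] * n + ["SR"] * n
        sex = rng.integers(0, 2, size=2 * n)  # 1 = male
        is_af = np.array([c == "AF" for c in condition])

        log2fc = np.zeros(cfg.n_genes)
        for g, (l1, l2) in truth.bulk_deg_map.items():
            log2fc[gene_pos[g]] = l1 if ci == 1 else l2
        for g, l in truth.private_degs[cname].items():
            log2fc[gene_pos[g]] = l

        logmu = np.log2(np.maximum(base, 1e-12))[None, :] + np.outer(is_af, log2fc)
        sex_idx = [gene_pos[g] for g in sorted(truth.sex_genes)]
        logmu[:, sex_idx] += cfg.sex_effect * sex[:, None]
        if ci == 2:
            batch_idx = [gene_pos[g] for g in sorted(truth.batch_genes)]
            logmu[:, batch_idx] += cfg.batch_effect
        # planted coexpression: shared latent factor per module, AF-shifted
        for m, idx in module_idx.items():
            z = rng.normal(0.0, 1.0, size=2 * n) + (
                module_sign[m] * cfg.module_condition_shift * is_af
            )
            logmu[:, idx] += cfg.module_loading * z[:, None] / np.log(2.0)

        sizef = rng.lognormal(0.0, cfg.libsize_sigma, size=2 * n)
        mu = np.exp2(logmu) * sizef[:, None]
        counts = _nb_draw(rng, mu, cfg.nb_dispersion)

        gp, gm = truth.antisense_pair
        unstranded = counts.copy()
        pair_sum = counts[:, gene_pos[gp]] + counts[:, gene_pos[gm]]
        unstranded[:, gene_pos[gp]] = pair_sum
        unstranded[:, gene_pos[gm]] = pair_sum

        samples = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "condition": condition,
                "sex": sex,
                "cohort": cname,
            }
        )
        cohorts[cname] = {
            "counts": SparseCountMatrix(sp.csr_matrix(counts), sample_ids, cfg.gene_ids),
            "counts_unstranded": SparseCountMatrix(
                sp.csr_matrix(unstranded), sample_ids, cfg.gene_ids
            ),
            "samples": samples,
        }
    return cohorts, truth


def driver_motif_sites(cfg: SimConfig, membership: MotifPeakMembership, truth: Truth,
                       width: int = 20) -> pd.DataFrame:
    """Motif site intervals: one centered site per driver-motif peak."""
    idx = sorted(cfg.peak_ids.index(p) for p in membership.peaks[truth.driver_motif_id])
    centers = np.array(idx) * PEAK_SPACING + PEAK_WIDTH // 2
    return make_interval_set(
        chrom=["chrS"] * len(idx),
        start=centers - width // 2,
        end=centers + width // 2,
        label=[truth.driver_motif_id] * len(idx),
    )


def generate_block_expression(
    n_samples: int = 100,
    block_sizes: tuple[int, ...] = (60, 60, 60),
    within_cor: float = 0.7,
    n_noise: int = 100,
    between_cor: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian expression with planted correlated blocks plus noise genes.

    Genes in block ``m`` share a latent factor giving pairwise
    correlation ``within_cor``; ``between_cor`` adds a global factor
    shared by all blocks.  Returns ``(samples x genes DataFrame,
    gene -> block labels)`` with noise genes labeled 0.
    """
    rng = np.random.default_rng(seed)
    lam = np.sqrt(within_cor)
    noise_sd = np.sqrt(1.0 - within_cor)
    cols, labels = [], []
    shared = rng.normal(size=n_samples)
    lam_g = np.sqrt(between_cor)
    for m, size in enumerate(block_sizes, start=1):
        z = rng.normal(size=n_samples)
        base = lam_g * shared + np.sqrt(max(lam**2 - lam_g**2, 0.0)) * z
        for _ in range(size):
            cols.append(base + noise_sd * rng.normal(size=n_samples))
            labels.append(m)
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_samples))
        labels.append(0)
    genes = [f"bg{i:04d}" for i in range(len(cols))]
    expr = pd.DataFrame(np.column_stack(cols), columns=genes)
    return expr, pd.Series(labels, index=genes)


def generate_fragments(
    cfg: SimConfig,
    motif_sites: pd.DataFrame,
    nucleus_table: pd.DataFrame,
) -> pd.DataFrame:
    """Simulate per-nucleus Tn5 insertion positions.

    A uniform background over the synthetic chromosome, plus, for CM
    nuclei, site-directed insertions in the flanks of each motif site
    with a protected (zero-rate) core of half-width
    ``footprint_core`` - the classical TF footprint.  AF CM nuclei get
    ``footprint_af_effect`` times the SR CM rate.  Windows clipped at
    the chromosome start produce a warning, not an error.

    Returns a fragment table (chrom, start, end, barcode), each row one
    insertion (end = start + 1), sorted by position.
    """
    import warnings

    ss = np.random.SeedSequence([cfg.seed, 4])
    rng = np.random.default_rng(ss)
    L = cfg.chrom_length
    centers = ((motif_sites["start"] + motif_sites["end"]) // 2).to_numpy()
    if (centers - cfg.footprint_window < 0).any():
        warnings.warn("footprint window extends past chromosome start; clipped")
    rows_pos, rows_bc = [], []
    core, enrich = cfg.footprint_core, cfg.footprint_enrich
    # site-directed insertions land near the motif (outside the protected
    # core but inside the enriched region), so the far flanks used for
    # normalization stay at background level
    flank_offsets = np.concatenate(
        [np.arange(-enrich, -core), np.arange(core + 1, enrich + 1)]
    )
    for _, nuc in nucleus_table.iterrows():
        n_bg = rng.poisson(cfg.bg_insertions_per_nucleus)
        pos = list(rng.integers(0, L, size=n_bg))
        if nuc.cell_type == "CM" and cfg.footprint_rate > 0:
            rate = cfg.footprint_rate * (
                cfg.footprint_af_effect if nuc.condition == "AF" else 1.0
            )
            for c in centers:
                k = rng.poisson(rate)
                if k:
                    off = rng.choice(flank_offsets, size=k)
                    pos.extend(int(x) for x in np.clip(c + off, 0, L - 1))
        rows_pos.extend(pos)
        rows_bc.extend([nuc.nucleus_id] * len(pos))
    frags = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.array(rows_pos, dtype=np.int64),
            "end": np.array(rows_pos, dtype=np.int64) + 1,
            "barcode": rows_bc,
        }
    )
    return frags.sort_values(["start", "barcode"], kind="mergesort").reset_index(drop=True)
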