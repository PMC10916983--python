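"""Seeded generators of synthetic inputs with planted structure.

Every analysis stage in the package can be exercised without any deposited
dataset: the generators here produce

* DE tables plus a miRNA–target interaction map where the targets of
  downregulated miRNAs carry a planted positive log2FC shift (the
  derepression signal the eCDF test must detect),
* a spatial field of deposits, nuclei and transcript spots where per-gene
  expression follows a piecewise profile of distance-to-deposit with a
  slope change at a configured breakpoint (20 μm by default, the distance
  at which phagocytic targets peak),
* a single-cell count matrix containing homeostatic microglia, two DAM
  subpopulations differing in a phagocytic gene signature, and
  non-microglial cells, with planted low-quality and high-mitochondrial
  cells to exercise QC.

All generators are pure functions of ``(config, seed)``; each returns a
truth record sufficient to compute every recovery metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirglia.exceptions import ConfigurationError

# ---------------------------------------------------------------------------
# configs


@dataclass
class DESimConfig:
    """Conditions for the DE-table / interaction generator.

    The derepression shift of 0.5 log2FC units on a unit-variance log2FC
    background matches the planted-effect conditions the shift test is
    evaluated under.
    """

    n_genes: int = 4000
    n_mirnas: int = 60
    targets_per_mirna: int = 50
    derepression_shift: float = 0.5
    de_fraction_mirnas_down: float = 0.4
    de_fraction_mirnas_up: float = 0.1
    mirna_lfc_mean: float = 2.0
    mirna_lfc_sd: float = 0.4
    mirna_null_sd: float = 0.3
    gene_de_fraction: float = 0.1
    gene_effect_mean: float = 1.5
    gene_effect_sd: float = 0.3
    gene_noise_sd: float = 0.5
    decoys_per_mirna: int = 20


@dataclass
class SpatialSimConfig:
    """Conditions for the spatial-field generator.

    Profile genes rise from ``level_at_zero`` at the deposit edge to
    ``level_at_break`` at the breakpoint (default 20 μm), then decline
    toward ``level_far`` at ``far_distance``; beyond that the mean is
    floored.  Spot jitter stays inside the 10 μm assignment radius so every
    transcript is recoverable to its true nucleus.
    """

    field_size: float = 500.0
    n_deposits: int = 10
    deposit_diameter_range: tuple[float, float] = (10.0, 60.0)
    n_cells: int = 400
    breakpoint: float = 20.0
    level_at_zero: float = 2.0
    level_at_break: float = 6.0
    level_far: float = 1.0
    far_distance: float = 60.0
    level_floor: float = 0.2
    noise_sd: float = 0.2
    jitter_radius: float = 8.0
    n_profile_genes: int = 8
    n_flat_genes: int = 10
    flat_level: float = 3.0
    microglia_fraction: float = 0.3
    aif1_level: float = 4.0
    min_nucleus_separation: float | None = None  # default: 2 * jitter + 0.5


@dataclass
class ScrnaSimConfig:
    """Conditions for the single-cell count generator.

    Population sizes put 40% of the DAM cells in the phagocytic
    subpopulation.  The phagocytic signature panel (28 genes, matching the
    size of the phagocytic target panel) is induced 5-fold there: the two
    DAM subpopulations are defined by expressing versus not expressing the
    panel, so the planted contrast is strong, not marginal.
    """

    n_homeostatic: int = 300
    n_dam_phagocytic: int = 120
    n_dam_nonphagocytic: int = 180
    n_other: int = 200
    n_genes: int = 600
    n_signature_genes: int = 28
    n_dam_markers: int = 20
    n_homeostatic_markers: int = 15
    n_other_markers: int = 15
    signature_factor: float = 5.0
    marker_factor: float = 4.0
    signature_base_mean: float = 2.0
    dispersion: float = 0.3
    mito_fraction: float = 0.02
    library_size_sd: float = 0.3
    n_low_quality_cells: int = 20
    n_high_mito_cells: int = 15


@dataclass
class SimConfig:
    """Aggregate configuration with one seed for all three generators."""

    seed: int = 0
    de: DESimConfig = field(default_factory=DESimConfig)
    spatial: SpatialSimConfig = field(default_factory=SpatialSimConfig)
    scrna: ScrnaSimConfig = field(default_factory=ScrnaSimConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        return cls(
            seed=int(data.get("seed", 0)),
            de=DESimConfig(**data.get("de", {})),
            spatial=SpatialSimConfig(**data.get("spatial", {})),
            scrna=ScrnaSimConfig(**data.get("scrna", {})),
        )


# ---------------------------------------------------------------------------
# DE tables + interactions


@dataclass
class DETruth:
    """Planted structure of one DE-dataset draw."""

    derepressed_mirnas: list[str]
    mirna_direction: dict[str, str]
    target_map: dict[str, list[str]]
    gene_true_effect: pd.Series


def _pvalues_from_lfc(lfc: np.ndarray, se: float) -> np.ndarray:
    from scipy import stats as sps

    z = np.abs(lfc) / se
    return np.clip(2.0 * sps.norm.sf(z), 1e-300, 1.0)


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def gen_de_dataset(
    config: DESimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, DETruth]:
    """Generate (gene DE table, miRNA DE table, interaction table, truth).

    miRNAs are split into planted down-regulated, up-regulated, and null
    classes.  Each miRNA owns a disjoint set of target genes with binding
    probabilities >= 0.99 (plus decoy interactions below the threshold);
    targets of down-miRNAs receive ``+derepression_shift`` on their gene
    log2FC.  FDRs are BH-adjusted p-values derived from the observed
    log2FCs, so downstream threshold classification behaves realistically.
    """
    cfg = config or DESimConfig()
    if cfg.targets_per_mirna * cfg.n_mirnas > cfg.n_genes:
        raise ConfigurationError("targets_per_mirna * n_mirnas exceeds n_genes")
    rng = np.random.default_rng(seed)

    genes = np.array([f"Gene{i:05d}" for i in range(cfg.n_genes)])
    mirnas = np.array([f"mmu-miR-{i:04d}" for i in range(cfg.n_mirnas)])

    n_down = int(round(cfg.de_fraction_mirnas_down * cfg.n_mirnas))
    n_up = int(round(cfg.de_fraction_mirnas_up * cfg.n_mirnas))
    direction = np.array(["down"] * n_down + ["up"] * n_up + ["ns"] * (cfg.n_mirnas - n_down - n_up))
    rng.shuffle(direction)
    mirna_lfc = np.where(
        direction == "down",
        -rng.normal(cfg.mirna_lfc_mean, cfg.mirna_lfc_sd, cfg.n_mirnas),
        np.where(
            direction == "up",
            rng.normal(cfg.mirna_lfc_mean, cfg.mirna_lfc_sd, cfg.n_mirnas),
            rng.normal(0.0, cfg.mirna_null_sd, cfg.n_mirnas),
        ),
    )
    # p-values use the null log2FC sd, so null features get uniform p-values
    mirna_p = _pvalues_from_lfc(mirna_lfc, cfg.mirna_null_sd)
    mirna_table = pd.DataFrame(
        {
            "feature_id": mirnas,
            "feature_kind": "mirna",
            "log2fc": mirna_lfc,
            "fdr": _bh(mirna_p),
        }
    )

    # disjoint target assignment
    perm = rng.permutation(cfg.n_genes)
    target_map: dict[str, list[str]] = {}
    for i, mid in enumerate(mirnas):
        idx = perm[i * cfg.targets_per_mirna : (i + 1) * cfg.targets_per_mirna]
        target_map[mid] = list(genes[idx])

    # gene true effects: symmetric planted DE background + derepression shift
    effect = np.zeros(cfg.n_genes)
    n_de_genes = int(round(cfg.gene_de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de_genes)
    effect[de_idx] = signs * rng.normal(cfg.gene_effect_mean, cfg.gene_effect_sd, n_de_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for mid in mirnas[direction == "down"]:
        for g in target_map[mid]:
            effect[gene_pos[g]] += cfg.derepression_shift
    gene_lfc = effect + rng.normal(0.0, cfg.gene_noise_sd, cfg.n_genes)
    gene_p = _pvalues_from_lfc(gene_lfc, cfg.gene_noise_sd)
    gene_table = pd.DataFrame(
        {
            "feature_id": genes,
            "feature_kind": "gene",
            "log2fc": gene_lfc,
            "fdr": _bh(gene_p),
        }
    )

    rows = []
    for mid in mirnas:
        for g in target_map[mid]:
            rows.append((mid, g, rng.uniform(0.99, 1.0),
                         "validated" if rng.random() < 0.3 else "predicted"))
        decoys = rng.choice(genes, size=cfg.decoys_per_mirna, replace=False)
        for g in decoys:
            if g not in target_map[mid]:
                rows.append((mid, g, rng.uniform(0.5, 0.989), "predicted"))
    interactions = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "binding_probability", "source"]
    )

    truth = DETruth(
        derepressed_mirnas=list(mirnas[direction == "down"]),
        mirna_direction=dict(zip(mirnas, direction)),
        target_map=target_map,
        gene_true_effect=pd.Series(effect, index=genes),
    )
    return gene_table, mirna_table, interactions, truth


# ---------------------------------------------------------------------------
# spatial field


@dataclass
class SpatialTruth:
    """Planted structure of one spatial draw."""

    nuclei: pd.DataFrame
    deposits: pd.DataFrame
    distances: pd.Series  # nucleus id -> edge distance to nearest deposit
    is_microglia: pd.Series
    counts: pd.DataFrame  # nucleus id x gene planted counts
    expected: pd.DataFrame  # nucleus id x profile gene mean expression
    breakpoint: float
    profile_genes: list[str]
    flat_genes: list[str]
    max_unclamped_distance: float


def _place_points(rng, n, field, min_sep, margin=0.0, max_tries=200):
    pts = []
    for _ in range(n):
        for _ in range(max_tries):
            cand = rng.uniform(margin, field - margin, size=2)
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
                break
        else:
            raise ConfigurationError("field too small to place points without overlap")
    return np.array(pts)


def profile_mean(d, cfg: SpatialSimConfig) -> np.ndarray:
    """Two-segment expression profile of distance, floored far from deposits."""
    d = np.asarray(d, dtype=float)
    rise = cfg.level_at_zero + (cfg.level_at_break - cfg.level_at_zero) * d / cfg.breakpoint
    fall = cfg.level_at_break + (cfg.level_far - cfg.level_at_break) * (
        (d - cfg.breakpoint) / (cfg.far_distance - cfg.breakpoint)
    )
    return np.maximum(np.where(d <= cfg.breakpoint, rise, fall), cfg.level_floor)


def gen_spatial_dataset(
    config: SpatialSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SpatialTruth]:
    """Generate (spots, nuclei, deposits, truth).

    Deposits and nuclei are placed uniformly (with separation constraints);
    profile-gene expected expression follows :func:`profile_mean` of the
    cell's edge distance to the nearest deposit, plus Gaussian noise of
    ``noise_sd``; transcript counts are Poisson draws from that mean, and
    each transcript is jittered uniformly within ``jitter_radius`` of its
    nucleus — strictly inside the 10 μm assignment radius.
    """
    cfg = config or SpatialSimConfig()
    if not 0 < cfg.breakpoint < cfg.far_distance:
        raise ConfigurationError("breakpoint must lie inside (0, far_distance)")
    rng = np.random.default_rng(seed)

    max_diam = cfg.deposit_diameter_range[1]
    dep_xy = _place_points(rng, cfg.n_deposits, cfg.field_size, min_sep=max_diam + 5.0,
                           margin=max_diam / 2)
    diam = rng.uniform(*cfg.deposit_diameter_range, size=cfg.n_deposits)
    deposits = pd.DataFrame(
        {"id": np.arange(cfg.n_deposits), "x": dep_xy[:, 0], "y": dep_xy[:, 1], "diameter": diam}
    )

    min_sep = cfg.min_nucleus_separation or (2 * cfg.jitter_radius + 0.5)
    nuc_xy = _place_points(rng, cfg.n_cells, cfg.field_size, min_sep=min_sep)
    nuclei = pd.DataFrame({"id": np.arange(cfg.n_cells), "x": nuc_xy[:, 0], "y": nuc_xy[:, 1]})

    center_d = np.sqrt(((nuc_xy[:, None, :] - dep_xy[None, :, :]) ** 2).sum(axis=2))
    edge_d = np.clip(center_d - diam[None, :] / 2.0, 0.0, None).min(axis=1)
    distances = pd.Series(edge_d, index=nuclei["id"], name="dist_to_deposit")

    is_mg = rng.random(cfg.n_cells) < cfg.microglia_fraction
    profile_genes = [f"Phag{i:02d}" for i in range(1, cfg.n_profile_genes + 1)]
    flat_genes = [f"Hk{i:02d}" for i in range(1, cfg.n_flat_genes + 1)]
    genes = profile_genes + flat_genes + ["Aif1"]

    base = profile_mean(edge_d, cfg)
    expected = np.empty((cfg.n_cells, len(profile_genes)))
    counts = np.zeros((cfg.n_cells, len(genes)), dtype=int)
    for j, _ in enumerate(profile_genes):
        e = np.clip(base + rng.normal(0.0, cfg.noise_sd, cfg.n_cells), 0.0, None)
        expected[:, j] = e
        counts[:, j] = rng.poisson(e)
    for j in range(len(flat_genes)):
        counts[:, len(profile_genes) + j] = rng.poisson(cfg.flat_level, cfg.n_cells)
    counts[:, -1] = np.where(is_mg, rng.poisson(cfg.aif1_level, cfg.n_cells) + 1, 0)

    spot_rows = []
    for ci in range(cfg.n_cells):
        total = counts[ci].sum()
        if total == 0:
            continue
        r = cfg.jitter_radius * np.sqrt(rng.random(total))
        theta = rng.uniform(0, 2 * np.pi, total)
        offs = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        gene_idx = np.repeat(np.arange(len(genes)), counts[ci])
        for k in range(total):
            spot_rows.append(
                (genes[gene_idx[k]], nuc_xy[ci, 0] + offs[k, 0], nuc_xy[ci, 1] + offs[k, 1], ci)
            )
    spots = pd.DataFrame(spot_rows, columns=["gene", "x", "y", "true_nucleus"])

    # distance at which the declining segment hits the floor (profile clamps)
    slope_fall = (cfg.level_far - cfg.level_at_break) / (cfg.far_distance - cfg.breakpoint)
    if slope_fall < 0:
        d_clamp = cfg.breakpoint + (cfg.level_floor - cfg.level_at_break) / slope_fall
    else:
        d_clamp = np.inf

    truth = SpatialTruth(
        nuclei=nuclei,
        deposits=deposits,
        distances=distances,
        is_microglia=pd.Series(is_mg, index=nuclei["id"]),
        counts=pd.DataFrame(counts, index=pd.Index(nuclei["id"], name="cell_id"), columns=genes),
        expected=pd.DataFrame(expected, index=pd.Index(nuclei["id"], name="cell_id"),
                              columns=profile_genes),
        breakpoint=cfg.breakpoint,
        profile_genes=profile_genes,
        flat_genes=flat_genes,
        max_unclamped_distance=float(d_clamp),
    )
    return spots[["gene", "x", "y", "true_nucleus"]], nuclei, deposits, truth


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class ScrnaTruth:
    """Planted structure of one single-cell draw."""

    labels: pd.Series  # cell -> population (incl. low_quality / high_mito flags)
    signature_genes: list[str]
    dam_markers: list[str]
    homeostatic_markers: list[str]
    other_markers: list[str]
    mito_genes: list[str]
    n_low_quality: int
    n_high_mito: int


MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Cytb"]


def gen_scrna_dataset(config: ScrnaSimConfig | None = None, seed: int = 0):
    """Generate a cells × genes count AnnData with planted populations.

    Counts are negative-binomial (gamma–Poisson) with per-cell library-size
    factors.  Four populations are planted (homeostatic microglia, two DAM
    subpopulations, non-microglial cells); the phagocytic DAM cells
    overexpress the signature panel by ``signature_factor``.  Additional
    low-depth and high-mitochondrial cells are appended to exercise the QC
    filters; their counts are known exactly in the truth record.
    """
    import anndata as ad

    cfg = config or ScrnaSimConfig()
    if cfg.dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    rng = np.random.default_rng(seed)

    n_panel = (cfg.n_signature_genes + cfg.n_dam_markers + cfg.n_homeostatic_markers
               + cfg.n_other_markers + len(MITO_GENES))
    if cfg.n_genes < n_panel:
        raise ConfigurationError("n_genes smaller than the marker panels")

    sig = [f"PhagoT{i:02d}" for i in range(1, cfg.n_signature_genes + 1)]
    dam = [f"DamM{i:02d}" for i in range(1, cfg.n_dam_markers + 1)]
    homeo = [f"HomeoM{i:02d}" for i in range(1, cfg.n_homeostatic_markers + 1)]
    other = [f"OtherM{i:02d}" for i in range(1, cfg.n_other_markers + 1)]
    n_bg = cfg.n_genes - n_panel
    bg = [f"Bg{i:04d}" for i in range(n_bg)]
    genes = sig + dam + homeo + other + MITO_GENES + bg

    base = rng.lognormal(mean=-0.2, sigma=0.6, size=cfg.n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    base[[gi[g] for g in sig]] = cfg.signature_base_mean
    base[[gi[g] for g in dam]] = 1.5
    base[[gi[g] for g in homeo]] = 1.5
    base[[gi[g] for g in other]] = 1.5
    # mito means sized so the expected mito fraction matches the config
    non_mito_total = base[[gi[g] for g in genes if g not in MITO_GENES]].sum()
    base[[gi[g] for g in MITO_GENES]] = (
        cfg.mito_fraction * non_mito_total / (1 - cfg.mito_fraction) / len(MITO_GENES)
    )

    pops = (
        ["homeostatic"] * cfg.n_homeostatic
        + ["dam_phagocytic"] * cfg.n_dam_phagocytic
        + ["dam_nonphagocytic"] * cfg.n_dam_nonphagocytic
        + ["other"] * cfg.n_other
        + ["low_quality"] * cfg.n_low_quality_cells
        + ["high_mito"] * cfg.n_high_mito_cells
    )
    n_cells = len(pops)
    mu = np.tile(base, (n_cells, 1))
    pops_arr = np.array(pops)
    dam_mask = np.isin(pops_arr, ["dam_phagocytic", "dam_nonphagocytic"])
    mu[np.ix_(dam_mask, [gi[g] for g in dam])] *= cfg.marker_factor
    mu[np.ix_(pops_arr == "dam_phagocytic", [gi[g] for g in sig])] *= cfg.signature_factor
    mu[np.ix_(pops_arr == "homeostatic", [gi[g] for g in homeo])] *= cfg.marker_factor
    mu[np.ix_(pops_arr == "other", [gi[g] for g in other])] *= cfg.marker_factor
    mu[pops_arr == "low_quality"] *= 0.05
    mito_cols = [gi[g] for g in MITO_GENES]
    mu[np.ix_(pops_arr == "high_mito", mito_cols)] *= 10.0

    size_factor = rng.lognormal(0.0, cfg.library_size_sd, n_cells)
    mu = mu * size_factor[:, None]
    lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    cell_names = [f"cell{i:05d}" for i in range(n_cells)]
    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame({"truth_label": pops}, index=cell_names),
        var=pd.DataFrame({"mito": [g in MITO_GENES for g in genes]}, index=genes),
    )
    truth = ScrnaTruth(
        labels=pd.Series(pops, index=cell_names, name="truth_label"),
        signature_genes=sig,
        dam_markers=dam,
        homeostatic_markers=homeo,
        other_markers=other,
        mito_genes=list(MITO_GENES),
        n_low_quality=cfg.n_low_quality_cells,
        n_high_mito=cfg.n_high_mito_cells,
    )
    return adata, truth
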