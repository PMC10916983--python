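"""Spatial transcriptomics pipeline: from transcript spots to distance profiles.

The stages mirror how a molecular-cartography dataset of an amyloid mouse
brain is processed once nuclei and deposit coordinates are available:

1. each transcript spot is assigned to the nearest nucleus closer than
   10 μm (:func:`assign_spots`; the same operation runs against deposits);
2. the per-nucleus counts form a cell × gene matrix
   (:func:`build_cell_matrix`), filtered to cells with at least 30
   transcripts and genes seen in at least 100 cells (:func:`filter_matrix`);
3. microglia are annotated by expression of the marker *Aif1*
   (:func:`annotate_microglia`);
4. each cell's distance to the closest deposit edge is computed
   (:func:`distance_to_nearest_deposit`), deposits are size-classed as
   small (5–40 μm diameter) or big (> 40 μm) (:func:`classify_deposits`);
5. expression contrasts use the Wilcoxon rank-sum test with
   Benjamini–Hochberg correction across genes (:func:`compare_groups`);
6. per-gene expression-versus-distance change points are estimated by
   segmented regression (:func:`mirglia.segmented.fit_breakpoint`), their
   density over distance summarized (:func:`breakpoint_density`), and cells
   are classified into the distance bins derived from that analysis —
   colocalized (0 μm), close (0–9], medium-close (9–17], medium-far
   (17–27], far (> 27 μm) (:func:`bin_cells`, :func:`bin_profile`).

All coordinates are planar micrometres; an optional z column is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirglia.exceptions import (
    ConfigurationError,
    IntegrityError,
    ParameterError,
    ValidationError,
)
from mirglia.segmented import BreakpointFit

logger = logging.getLogger(__name__)

BIN_LABELS = ("colocalized", "close", "medium_close", "medium_far", "far")
DEFAULT_BREAKS = (0.0, 9.0, 17.0, 27.0)
SMALL_DEPOSIT_MIN = 5.0
SMALL_DEPOSIT_MAX = 40.0


@dataclass
class CellTable:
    """Cell × gene counts with aligned per-cell annotations.

    ``counts`` is indexed by nucleus id with one column per gene; ``obs``
    shares the index and carries coordinates, totals, the microglia flag,
    distance to the nearest deposit and the distance bin as they are filled
    in by the pipeline stages.
    """

    counts: pd.DataFrame
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.obs.empty and len(self.counts):
            self.obs = pd.DataFrame(index=self.counts.index)
        if not self.counts.index.equals(self.obs.index):
            raise ValidationError("counts and obs must share the same cell index")
        self.obs["total_transcripts"] = self.counts.sum(axis=1).astype(int)

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "CellTable":
        return CellTable(self.counts.copy(), self.obs.copy())


# -- I/O ---------------------------------------------------------------------

def read_spots(path, sep: str = "\t") -> pd.DataFrame:
    spots = pd.read_csv(path, sep=sep)
    _require(spots, ("gene", "x", "y"), path)
    return spots


def read_nuclei(path, sep: str = "\t") -> pd.DataFrame:
    nuclei = pd.read_csv(path, sep=sep)
    _require(nuclei, ("id", "x", "y"), path)
    if nuclei["id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated nucleus ids")
    return nuclei


def read_deposits(path, sep: str = "\t") -> pd.DataFrame:
    deposits = pd.read_csv(path, sep=sep)
    _require(deposits, ("id", "x", "y", "diameter"), path)
    return deposits


def _require(table: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        from mirglia.exceptions import FormatError

        raise FormatError(f"{path}: missing required column(s) {missing}")


# -- assignment --------------------------------------------------------------

def assign_spots(
    spots: pd.DataFrame,
    anchors: pd.DataFrame,
    max_dist: float = 10.0,
    out_col: str = "nucleus_id",
    chunk_size: int = 2048,
) -> pd.DataFrame:
    """Assign each spot to the nearest anchor strictly closer than ``max_dist``.

    ``anchors`` is a nuclei- or deposits-style table with ``id``, ``x``,
    ``y``.  Distance is planar Euclidean; exact ties are broken toward the
    lowest anchor id.  Unassignable spots get a missing id.
    """
    if max_dist <= 0:
        raise ParameterError("max_dist must be positive")
    out = spots.copy()
    if anchors.empty:
        logger.warning("no anchors provided; all %d spots left unassigned", len(spots))
        out[out_col] = pd.array([pd.NA] * len(spots), dtype="Int64")
        return out
    anchors = anchors.sort_values("id")
    axy = anchors[["x", "y"]].to_numpy(dtype=float)
    ids = anchors["id"].to_numpy()
    sxy = out[["x", "y"]].to_numpy(dtype=float)

    assigned = np.full(len(out), -1, dtype=np.int64)
    for start in range(0, len(out), chunk_size):
        block = sxy[start : start + chunk_size]
        d2 = ((block[:, None, :] - axy[None, :, :]) ** 2).sum(axis=2)
        nearest = d2.argmin(axis=1)  # first occurrence -> lowest id on ties
        dist = np.sqrt(d2[np.arange(len(block)), nearest])
        ok = dist < max_dist
        assigned[start : start + chunk_size][ok] = ids[nearest[ok]]
    out[out_col] = pd.array([a if a >= 0 else pd.NA for a in assigned], dtype="Int64")
    return out


def build_cell_matrix(spots: pd.DataFrame, nuclei: pd.DataFrame,
                      id_col: str = "nucleus_id") -> CellTable:
    """Aggregate assigned spots into per-nucleus gene counts.

    Every nucleus appears, including those with zero assigned spots (they
    are removed later by the transcript filter, not here).  Unassigned
    spots are excluded from all counts.
    """
    assigned = spots.loc[spots[id_col].notna()]
    unknown = set(assigned[id_col].astype(int)) - set(nuclei["id"].astype(int))
    if unknown:
        raise IntegrityError(f"spots reference unknown nucleus id(s): {sorted(unknown)[:10]}")
    counts = (
        assigned.assign(**{id_col: assigned[id_col].astype(int)})
        .groupby([id_col, "gene"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(index=nuclei["id"].astype(int).sort_values(), fill_value=0)
    counts.index.name = "cell_id"
    counts.columns.name = None
    obs = nuclei.set_index(nuclei["id"].astype(int))[["x", "y"]]
    obs.index.name = "cell_id"
    return CellTable(counts.astype(int), obs.loc[counts.index].copy())


# -- filtering and annotation ------------------------------------------------

def filter_matrix(
    cells: CellTable,
    min_transcripts_per_cell: int = 30,
    min_cells_per_gene: int = 100,
) -> CellTable:
    """Filter cells, then genes, with inclusive ("at least") thresholds.

    Cells must carry at least ``min_transcripts_per_cell`` transcripts;
    among the surviving cells a gene must be expressed (count > 0) in at
    least ``min_cells_per_gene`` cells.  The order (cells first) is fixed;
    the operation is idempotent on its own output.
    """
    totals = cells.counts.sum(axis=1)
    kept_cells = cells.counts.loc[totals >= min_transcripts_per_cell]
    support = (kept_cells > 0).sum(axis=0)
    kept = kept_cells.loc[:, support >= min_cells_per_gene]
    if kept.empty:
        logger.warning("filter_matrix removed every cell or gene")
    return CellTable(kept.copy(), cells.obs.loc[kept.index].copy())


def annotate_microglia(cells: CellTable, marker: str = "Aif1", min_count: int = 1) -> CellTable:
    """Flag cells expressing the microglial marker at ``>= min_count`` copies."""
    if marker not in cells.counts.columns:
        raise ConfigurationError(
            f"marker {marker!r} is not in the retained gene list (filtered out?)"
        )
    out = cells.copy()
    out.obs["is_microglia"] = (out.counts[marker] >= min_count).to_numpy()
    return out


def classify_deposits(deposits: pd.DataFrame) -> pd.DataFrame:
    """Size-class deposits: small for 5–40 μm diameter, big above 40 μm."""
    d = deposits["diameter"].to_numpy(dtype=float)
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValidationError("deposit diameters must be positive and finite")
    out = deposits.copy()
    out["size_class"] = np.where(
        d > SMALL_DEPOSIT_MAX, "big",
        np.where(d >= SMALL_DEPOSIT_MIN, "small", "unclassified"),
    )
    return out


def distance_to_nearest_deposit(
    cells: CellTable,
    deposits: pd.DataFrame,
    mode: str = "edge",
) -> CellTable:
    """Distance from each cell to the closest deposit, in μm.

    ``edge`` mode (default) subtracts the deposit radius from the
    center-to-center distance and clamps at zero, so cells overlapping a
    deposit read 0 μm (colocalized); ``center`` mode uses raw center
    distances.
    """
    if mode not in ("edge", "center"):
        raise ParameterError("mode must be 'edge' or 'center'")
    out = cells.copy()
    if deposits.empty:
        logger.warning("no deposits; distances set to +inf")
        out.obs["dist_to_deposit"] = np.inf
        return out
    cxy = out.obs[["x", "y"]].to_numpy(dtype=float)
    dxy = deposits[["x", "y"]].to_numpy(dtype=float)
    dist = np.sqrt(((cxy[:, None, :] - dxy[None, :, :]) ** 2).sum(axis=2))
    if mode == "edge":
        dist = np.clip(dist - deposits["diameter"].to_numpy(dtype=float) / 2.0, 0.0, None)
    out.obs["dist_to_deposit"] = dist.min(axis=1)
    return out


def bin_cells(cells: CellTable, breaks=DEFAULT_BREAKS) -> CellTable:
    """Classify cells into distance bins.

    With the default breaks (0, 9, 17, 27 μm): colocalized at exactly 0,
    then left-open/right-closed intervals (0, 9], (9, 17], (17, 27], and far
    beyond the last break.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.size != 4 or (np.diff(breaks) <= 0).any():
        raise ParameterError("breaks must be 4 strictly increasing values")
    if "dist_to_deposit" not in cells.obs.columns:
        raise ParameterError("run distance_to_nearest_deposit first")
    out = cells.copy()
    d = out.obs["dist_to_deposit"].to_numpy(dtype=float)
    edges = np.concatenate([breaks, [np.inf]])
    idx = np.searchsorted(edges, d, side="left")  # d == break -> lower bin
    idx = np.clip(idx, 0, len(BIN_LABELS) - 1)
    labels = np.asarray(BIN_LABELS, dtype=object)[idx]
    labels[d == breaks[0]] = BIN_LABELS[0]
    out.obs["distance_bin"] = pd.Categorical(labels, categories=list(BIN_LABELS))
    return out


# -- statistics --------------------------------------------------------------

def compare_groups(
    cells: CellTable,
    grouping,
    genes=None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of per-cell counts between two groups.

    ``grouping`` is the name of a boolean/binary ``obs`` column or an
    aligned array with exactly two levels.  Returns one row per gene with
    the U statistic, the two-sided p-value, and the Benjamini–Hochberg
    adjusted p-value across the genes of this contrast.  An empty group
    skips the contrast with a warning.
    """
    labels = cells.obs[grouping] if isinstance(grouping, str) else pd.Series(
        np.asarray(grouping), index=cells.counts.index
    )
    levels = pd.unique(labels.dropna())
    if len(levels) != 2:
        raise ParameterError(f"grouping must have exactly 2 levels, got {list(levels)}")
    a_mask = (labels == levels[0]).to_numpy()
    b_mask = (labels == levels[1]).to_numpy()
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        logger.warning("one contrast group is empty; skipping")
        return pd.DataFrame(columns=["gene", "u_statistic", "p_value", "p_adjusted"])
    genes = list(genes) if genes is not None else cells.genes
    rows = []
    for gene in genes:
        vals = cells.counts[gene].to_numpy(dtype=float)
        a, b = vals[a_mask], vals[b_mask]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            u, p = float(len(a)) * len(b) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((gene, float(u), float(p)))
    table = pd.DataFrame(rows, columns=["gene", "u_statistic", "p_value"])
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def breakpoint_density(
    fits: list[BreakpointFit],
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of converged breakpoint locations.

    Bandwidth follows Silverman's rule; the returned density is normalized
    to integrate to 1 over the evaluation grid.  With no converged fits an
    empty density is returned with a warning.
    """
    psi = np.array(
        [f.psi_hat for f in fits if f.converged and f.n_breakpoints > 0 and np.isfinite(f.psi_hat)]
    )
    if psi.size == 0:
        logger.warning("no converged breakpoint fits; empty density")
        return np.empty(0), np.empty(0)
    spread = psi.std() if psi.size > 1 else 0.0
    if grid is None:
        pad = max(3.0 * spread, 5.0)
        grid = np.linspace(psi.min() - pad, psi.max() + pad, n_grid)
    if spread > 0:
        kde = stats.gaussian_kde(psi, bw_method="silverman")
        dens = kde(grid)
    else:  # degenerate point mass: smooth with a narrow fixed-width kernel
        dens = stats.norm.pdf(grid, loc=psi.mean(), scale=1.0)
    area = np.trapezoid(dens, grid)
    return grid, dens / area


def bin_profile(
    cells: CellTable,
    gene_panel,
    scaling: str = "row_z",
) -> pd.DataFrame:
    """Mean expression per distance bin for a gene panel, row-scaled.

    ``row_z`` z-scores each gene across bins (zero-variance rows become 0);
    ``unit_interval`` min-max rescales each gene to [0, 1].  Empty bins are
    emitted as missing with a warning.
    """
    if scaling not in ("row_z", "unit_interval"):
        raise ParameterError("scaling must be 'row_z' or 'unit_interval'")
    if "distance_bin" not in cells.obs.columns:
        raise ParameterError("run bin_cells first")
    missing_genes = [g for g in gene_panel if g not in cells.counts.columns]
    if missing_genes:
        raise ConfigurationError(f"panel gene(s) not retained: {missing_genes[:10]}")
    means = (
        cells.counts[list(gene_panel)]
        .groupby(cells.obs["distance_bin"], observed=False)
        .mean()
        .T
    )
    if means.isna().any().any():
        logger.warning("empty distance bin(s): %s",
                       [c for c in means.columns if means[c].isna().all()])
    values = means.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if scaling == "row_z":
            mu = np.nanmean(values, axis=1, keepdims=True)
            sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
            scaled = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        else:
            lo = np.nanmin(values, axis=1, keepdims=True)
            hi = np.nanmax(values, axis=1, keepdims=True)
            rng = hi - lo
            scaled = np.where(rng > 0, (values - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    scaled = np.where(np.isnan(values), np.nan, scaled)
    return pd.DataFrame(scaled, index=means.index, columns=means.columns)
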