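"""miRNA–gene interaction filtering and anticorrelation linking.

Interaction annotations (miRWalk-style) carry a binding probability per
(miRNA, gene) pair; the study keeps pairs with at least 99% binding
probability.  A DE miRNA is then linked to the DE genes among its annotated
targets whose log2 fold change has the opposite sign — the anticorrelation
expected when a repressor changes level.

Two backgrounds are materialized per miRNA, because they serve different
questions: ``anticorrelated_targets`` (DE genes, opposite sign) feed
enrichment, while the target / non-target partition over the *whole* tested
universe (DE or not) feeds the eCDF shift test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirglia.exceptions import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ("mirna_id", "gene_id", "binding_probability", "source")
VALID_SOURCES = ("validated", "predicted")


@dataclass
class MiRNATargetSet:
    """One DE miRNA with its anticorrelated DE targets and backgrounds."""

    mirna_id: str
    mirna_log2fc: float
    mirna_direction: str
    anticorrelated_targets: pd.DataFrame
    all_targets_in_de_universe: list[str] = field(default_factory=list)
    nontarget_universe: list[str] = field(default_factory=list)

    @property
    def n_anticorrelated(self) -> int:
        return len(self.anticorrelated_targets)


def read_interactions(path, sep: str | None = None) -> pd.DataFrame:
    """Read an interaction table (mirna_id, gene_id, binding_probability, source)."""
    table = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in INTERACTION_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "source" not in table.columns:
        table["source"] = "predicted"
    return validate_interactions(table[list(INTERACTION_COLUMNS)])


def validate_interactions(interactions: pd.DataFrame) -> pd.DataFrame:
    probs = interactions["binding_probability"].to_numpy(dtype=float)
    bad = ~np.isfinite(probs) | (probs < 0) | (probs > 1)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} interaction(s) with binding_probability outside [0, 1]"
        )
    return interactions


def filter_by_binding(
    interactions: pd.DataFrame,
    min_probability: float = 0.99,
    inclusive: bool = True,
    source: str | None = None,
) -> pd.DataFrame:
    """Retain interactions with binding probability >= ``min_probability``.

    The bound is inclusive by default ("at least 99%"); ``source`` optionally
    restricts to validated or predicted provenance.  Input row order is
    preserved.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ParameterError("min_probability must be in [0, 1]")
    validate_interactions(interactions)
    probs = interactions["binding_probability"].to_numpy(dtype=float)
    keep = probs >= min_probability if inclusive else probs > min_probability
    out = interactions.loc[keep]
    if source is not None:
        if source not in VALID_SOURCES:
            raise ParameterError(f"source must be one of {VALID_SOURCES}")
        out = out.loc[out["source"] == source]
    return out.reset_index(drop=True)


def dedup_interactions(interactions: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated (mirna, gene) pairs to their max binding probability."""
    return (
        interactions.sort_values("binding_probability", ascending=False)
        .drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )


def _targets_of(mirna_id: str, interactions: pd.DataFrame) -> set[str]:
    return set(interactions.loc[interactions["mirna_id"] == mirna_id, "gene_id"])


def link_anticorrelated(
    de_mirnas: pd.DataFrame,
    genes: pd.DataFrame,
    interactions: pd.DataFrame,
) -> list[MiRNATargetSet]:
    """Link each DE miRNA to its anticorrelated DE gene targets.

    Parameters
    ----------
    de_mirnas
        Classified miRNA DE table; only ``is_de`` rows produce a set.
    genes
        Classified gene DE table over the **full** tested universe (DE and
        non-DE rows), which also defines the non-target background.
    interactions
        Binding-filtered interaction table.

    Interaction partners absent from the tested universe are logged and
    ignored.  Output is invariant to interaction row order and duplication.
    """
    for required, tab in (("direction", de_mirnas), ("direction", genes)):
        if required not in tab.columns:
            raise ParameterError("DE tables must be classified before linking")
    universe = pd.Index(genes["feature_id"])
    known = set(universe)
    unknown = set(interactions["gene_id"]) - known
    if unknown:
        logger.warning("%d interaction gene id(s) not in tested universe; ignored", len(unknown))
    inter = dedup_interactions(interactions.loc[interactions["gene_id"].isin(known)])

    de_genes = genes.loc[genes["is_de"]] if "is_de" in genes else genes
    sets: list[MiRNATargetSet] = []
    for _, mirna in de_mirnas.loc[de_mirnas["is_de"]].iterrows():
        targets = _targets_of(mirna["feature_id"], inter)
        opposite = "down" if mirna["direction"] == "up" else "up"
        anti = de_genes.loc[
            de_genes["feature_id"].isin(targets) & (de_genes["direction"] == opposite)
        ].reset_index(drop=True)
        sets.append(
            MiRNATargetSet(
                mirna_id=str(mirna["feature_id"]),
                mirna_log2fc=float(mirna["log2fc"]),
                mirna_direction=str(mirna["direction"]),
                anticorrelated_targets=anti,
                all_targets_in_de_universe=sorted(targets),
                nontarget_universe=sorted(known - targets),
            )
        )
    return sets


def target_partition(
    mirna_id: str,
    interactions: pd.DataFrame,
    tested_genes: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the tested universe into target / non-target log2FC vectors.

    ``tested_genes`` must contain every gene in the DE analysis (DE and
    non-DE).  Duplicate interaction rows count a target once.  Returns the
    two log2FC vectors ``(targets, nontargets)``; an empty target vector
    flags a miRNA with no annotated targets in the universe (excluded from
    shift testing downstream).
    """
    targets = _targets_of(mirna_id, interactions)
    is_target = tested_genes["feature_id"].isin(targets).to_numpy()
    lfc = tested_genes["log2fc"].to_numpy(dtype=float)
    return lfc[is_target], lfc[~is_target]
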