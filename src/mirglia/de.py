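"""Differential-expression tables for genes and miRNAs.

DE tables are consumed as an input contract (the upstream count modeling is
not refit here): a table has one row per tested feature with its log2 fold
change and false-discovery-rate-adjusted p-value.  :func:`classify_de` turns
the statistics into DE calls with the study's thresholds — genes are called
at ``|log2FC| >= 0.7`` and ``FDR < 0.05`` (inclusive fold-change bound),
miRNAs at ``|log2FC| > 1`` and ``FDR < 0.01`` (strict bound).

Tables are plain :class:`pandas.DataFrame` objects with the columns
``feature_id``, ``feature_kind``, ``log2fc``, ``fdr`` and, once classified,
``is_de`` and ``direction`` (``up`` / ``down`` / ``ns``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from mirglia.exceptions import EmptyInputError, FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("feature_id", "log2fc", "fdr")

#: default (lfc_threshold, fdr_threshold, inclusive_lfc) per feature kind
DEFAULT_THRESHOLDS: Mapping[str, tuple[float, float, bool]] = {
    "gene": (0.7, 0.05, True),
    "mirna": (1.0, 0.01, False),
}


@dataclass(frozen=True)
class DESummary:
    """Counts of DE calls in one classified table.

    ``frac_down`` is ``None`` when there are no DE features.
    """

    n_total_de: int
    n_up: int
    n_down: int
    frac_down: float | None

    def __post_init__(self) -> None:
        if self.n_total_de != self.n_up + self.n_down:
            raise ValidationError("n_total_de must equal n_up + n_down")


def read_de_table(
    path,
    feature_kind: str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Read a delimited DE table into the canonical schema.

    Parameters
    ----------
    path
        Delimited text file with a header.  The delimiter is sniffed unless
        ``sep`` is given.
    feature_kind
        ``"gene"`` or ``"mirna"``; stored in the ``feature_kind`` column.
    column_map
        Optional mapping from canonical names (``feature_id``, ``log2fc``,
        ``fdr``) to the column names used in the file.
    strict
        If True (default), rows with non-finite ``log2fc`` or ``fdr``
        outside ``[0, 1]`` abort the load; otherwise they are dropped with
        a logged count.
    """
    if feature_kind not in DEFAULT_THRESHOLDS:
        raise ParameterError(f"feature_kind must be one of {sorted(DEFAULT_THRESHOLDS)}")
    column_map = dict(column_map or {})
    try:
        raw = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path}: header only, no data rows")
    rename = {column_map.get(name, name): name for name in REQUIRED_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    table = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()
    table["log2fc"] = pd.to_numeric(table["log2fc"], errors="coerce")
    table["fdr"] = pd.to_numeric(table["fdr"], errors="coerce")
    bad = ~np.isfinite(table["log2fc"]) | ~table["fdr"].between(0.0, 1.0)
    if bad.any():
        report = table.loc[bad, "feature_id"].tolist()
        if strict:
            raise ValidationError(
                f"{path}: {int(bad.sum())} row(s) with non-finite log2fc or fdr "
                f"outside [0, 1]: {report[:10]}"
            )
        logger.warning("%s: dropping %d invalid row(s)", path, int(bad.sum()))
        table = table.loc[~bad]
    table.insert(1, "feature_kind", feature_kind)
    return table.reset_index(drop=True)


def write_de_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a DE table (classified or not) as delimited text."""
    table.to_csv(path, sep=sep, index=False)


def classify_de(
    records: pd.DataFrame,
    lfc_threshold: float | None = None,
    fdr_threshold: float | None = None,
    inclusive_lfc: bool | None = None,
) -> pd.DataFrame:
    """Set ``is_de`` and ``direction`` on a DE table.

    A feature is called ``up`` when its log2FC passes the positive
    fold-change bound (``>=`` when inclusive, ``>`` when strict) and its FDR
    is strictly below ``fdr_threshold``; ``down`` symmetrically; otherwise
    ``ns``.  Thresholds default per ``feature_kind``
    (:data:`DEFAULT_THRESHOLDS`).  Rows with missing statistics are treated
    as not tested and dropped before classification.
    """
    kinds = records["feature_kind"].unique() if "feature_kind" in records else ["gene"]
    default = DEFAULT_THRESHOLDS.get(kinds[0] if len(kinds) == 1 else "gene", DEFAULT_THRESHOLDS["gene"])
    lfc_threshold = default[0] if lfc_threshold is None else lfc_threshold
    fdr_threshold = default[1] if fdr_threshold is None else fdr_threshold
    inclusive_lfc = default[2] if inclusive_lfc is None else inclusive_lfc
    if not (lfc_threshold > 0 and fdr_threshold > 0):
        raise ParameterError("thresholds must be positive")

    out = records.copy()
    na = out["log2fc"].isna() | out["fdr"].isna()
    if na.any():
        logger.warning("excluding %d row(s) with NA statistics from classification", int(na.sum()))
        out = out.loc[~na].copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    if inclusive_lfc:
        pass_up, pass_down = lfc >= lfc_threshold, lfc <= -lfc_threshold
    else:
        pass_up, pass_down = lfc > lfc_threshold, lfc < -lfc_threshold
    sig = fdr < fdr_threshold
    direction = np.where(pass_up & sig, "up", np.where(pass_down & sig, "down", "ns"))
    out["is_de"] = direction != "ns"
    out["direction"] = direction
    return out.reset_index(drop=True)


def summarize_de(records: pd.DataFrame) -> DESummary:
    """Count up/down DE calls in a classified table."""
    if "direction" not in records.columns:
        raise ParameterError("records must be classified first (missing 'direction')")
    n_up = int((records["direction"] == "up").sum())
    n_down = int((records["direction"] == "down").sum())
    total = n_up + n_down
    frac = n_down / total if total > 0 else None
    return DESummary(n_total_de=total, n_up=n_up, n_down=n_down, frac_down=frac)


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the delta-delta-Ct method.

    Returns ``2 ** -ddCt`` with
    ``ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator``,
    i.e. fold change of the sample over the calibrator after normalizing to
    the reference assay (e.g. U6 snRNA).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(float(c)) for c in cts):
        raise ParameterError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
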