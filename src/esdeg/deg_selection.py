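"""Differential-expression tables and foreground/background gene selection.

The enrichment contrast is defined on a DEG table (gene id, log2 fold
change, BH-adjusted p-value):

* foreground — significantly regulated genes in one direction
  (``p_adj < 0.1`` and fold change ``> 2.0`` by default, strict);
* background pool — clearly non-differential genes
  (``p_adj > 0.1`` and fold within [0.80, 1.25], inclusive),
  from which equally-sized background groups are resampled.

Fold bounds are strict for the foreground and inclusive for the pool; the
p-value criteria are complementary, so the two sets never intersect under
the defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "GeneGroups",
    "read_deg_table",
    "select_foreground",
    "select_background_pool",
    "build_gene_groups",
    "rank_upregulated",
    "load_example_deg_table",
]

# accepted header spellings, lowercased, for flexible input tables
_COLUMN_ALIASES = {
    "gene_id": ("gene_id", "gene", "symbol", "gene_symbol", "id", "name"),
    "log2_fold": ("log2_fold", "log2fold", "log2fc", "log2foldchange", "logfc", "lfc"),
    "p_adj": ("p_adj", "padj", "adj_p", "adjusted_p", "fdr", "qvalue", "q_value"),
}


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression summary.

    Positive ``log2_fold`` means upregulated in the condition of interest.
    """

    gene_id: str
    log2_fold: float
    p_adj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_adj <= 1.0):
            raise ValueError(f"{self.gene_id}: p_adj must be in [0, 1], got {self.p_adj}")
        if not math.isfinite(self.log2_fold):
            raise ValueError(f"{self.gene_id}: log2_fold must be finite")


@dataclass
class GeneGroups:
    """Foreground gene sets (both directions) and the background pool."""

    foreground_up: set[str]
    foreground_down: set[str]
    background_pool: set[str]

    def __post_init__(self) -> None:
        if (
            self.foreground_up & self.foreground_down
            or self.foreground_up & self.background_pool
            or self.foreground_down & self.background_pool
        ):
            raise ValueError("foreground and background gene sets must be pairwise disjoint")

    def foreground(self, direction: str) -> set[str]:
        if direction == "up":
            return self.foreground_up
        if direction == "down":
            return self.foreground_down
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def _resolve_column(columns: Sequence[str], role: str) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in _COLUMN_ALIASES[role]:
        if alias in lowered:
            return lowered[alias]
    return None


def read_deg_table(path, columns: dict[str, str] | None = None) -> list[DEGRecord]:
    """Parse a DEG TSV into records.

    Column names are matched case-insensitively against common spellings
    (``gene_id``/``symbol``, ``log2_fold``/``log2FC``, ``p_adj``/``padj``
    ...), or given explicitly via ``columns`` mapping the roles
    ``gene_id``, ``log2_fold``, ``p_adj`` to header names.  Rows with a
    missing fold or p-value are dropped with a warning.
    """
    table = pd.read_csv(path, sep="\t")
    if table.empty and table.columns.size == 0:
        logger.warning("%s: empty DEG table", path)
        return []
    resolved = {}
    for role in ("gene_id", "log2_fold", "p_adj"):
        name = (columns or {}).get(role) or _resolve_column(table.columns, role)
        if name is None or name not in table.columns:
            raise ValueError(
                f"{path}: could not find a column for {role!r} among {list(table.columns)}"
            )
        resolved[role] = name
    sub = table[[resolved["gene_id"], resolved["log2_fold"], resolved["p_adj"]]].copy()
    sub.columns = ["gene_id", "log2_fold", "p_adj"]
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        logger.warning("%s: dropped %d rows with missing values", path, n_before - len(sub))
    if sub.empty:
        logger.warning("%s: DEG table has no usable rows", path)
        return []
    return [
        DEGRecord(gene_id=str(g), log2_fold=float(f), p_adj=float(p))
        for g, f, p in sub.itertuples(index=False, name=None)
    ]


def select_foreground(
    records: Iterable[DEGRecord],
    p_max: float = 0.1,
    min_fold: float = 2.0,
    direction: str = "up",
) -> set[str]:
    """Genes significantly regulated in one direction (strict cutoffs).

    up:   p_adj < p_max and log2_fold >  log2(min_fold)
    down: p_adj < p_max and log2_fold < -log2(min_fold)
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    cut = math.log2(min_fold)
    if direction == "up":
        return {r.gene_id for r in records if r.p_adj < p_max and r.log2_fold > cut}
    return {r.gene_id for r in records if r.p_adj < p_max and r.log2_fold < -cut}


def select_background_pool(
    records: Iterable[DEGRecord],
    p_min: float = 0.1,
    fold_low: float = 0.80,
    fold_high: float = 1.25,
) -> set[str]:
    """Clearly non-differential genes: p_adj > p_min, fold in [fold_low, fold_high]."""
    if not (0 < fold_low < 1 < fold_high):
        raise ValueError("require 0 < fold_low < 1 < fold_high")
    lo, hi = math.log2(fold_low), math.log2(fold_high)
    return {r.gene_id for r in records if r.p_adj > p_min and lo <= r.log2_fold <= hi}


def build_gene_groups(
    records: Sequence[DEGRecord],
    p_max: float = 0.1,
    min_fold: float = 2.0,
    p_min: float | None = None,
    fold_low: float = 0.80,
    fold_high: float = 1.25,
    universe: Iterable[str] | None = None,
) -> GeneGroups:
    """Foreground (both directions) and background pool in one pass.

    If ``universe`` (promoter gene ids) is given, genes absent from it are
    dropped with a logged count — enrichment can only use genes that have
    a promoter.  Raises if the pool ends up smaller than a foreground.
    """
    if p_min is None:
        p_min = p_max
    up = select_foreground(records, p_max=p_max, min_fold=min_fold, direction="up")
    down = select_foreground(records, p_max=p_max, min_fold=min_fold, direction="down")
    pool = select_background_pool(records, p_min=p_min, fold_low=fold_low, fold_high=fold_high)
    if universe is not None:
        known = set(universe)
        for label, group in (("foreground_up", up), ("foreground_down", down), ("background_pool", pool)):
            missing = group - known
            if missing:
                logger.warning(
                    "%s: dropped %d genes without a promoter in the universe",
                    label,
                    len(missing),
                )
            group &= known
    largest_fg = max(len(up), len(down))
    if largest_fg and len(pool) < largest_fg:
        raise ValueError(
            f"background pool ({len(pool)} genes) is smaller than the foreground "
            f"({largest_fg} genes); relax the pool bounds (p_min/fold_low/fold_high)"
        )
    return GeneGroups(foreground_up=up, foreground_down=down, background_pool=pool)


def rank_upregulated(records: Iterable[DEGRecord]) -> pd.DataFrame:
    """Upregulated genes ranked by descending log2 fold change."""
    rows = sorted(
        (r for r in records if r.log2_fold > 0),
        key=lambda r: (-r.log2_fold, r.gene_id),
    )
    return pd.DataFrame(
        {
            "rank": range(1, len(rows) + 1),
            "gene_id": [r.gene_id for r in rows],
            "log2_fold": [r.log2_fold for r in rows],
            "p_adj": [r.p_adj for r in rows],
        }
    )


def load_example_deg_table() -> list[DEGRecord]:
    """Bundled example: 42 DEGs from a rat midbrain tame-vs-aggressive contrast.

    Positive log2 fold = upregulated in tame animals.  Useful for worked
    examples and as a realistic small input.
    """
    ref = resources.files("esdeg.data") / "rat_mt_tame_vs_aggressive_degs.tsv"
    with resources.as_file(ref) as path:
        return read_deg_table(path)
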