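"""Synthetic promoters, planted motif sites and DEG tables with ground truth.

Everything the enrichment pipeline consumes can be simulated here with
known truth: i.i.d. mononucleotide background promoters, motif sites
sampled from a PWM's probability columns and written over the sequence at
random offsets (replacement, not insertion, so promoter length — and
hence the scanning-window bookkeeping — is preserved), and DEG tables
whose foreground/background partition is recovered exactly by the default
selection thresholds.

All randomness flows from a single seed through named child streams, so
a configuration is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .promoters import PromoterRecord, PromoterSet

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "simulate_promoters",
    "plant_sites",
    "simulate_deg_table",
    "simulate_study",
    "SimulatedStudy",
    "random_pcm",
    "write_ground_truth_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    ``planting_rate_fg``/``planting_rate_bg`` are per-promoter
    probabilities of carrying one planted site in foreground and
    non-foreground promoters respectively.  ``effect_log2fold`` is the
    log2 fold change assigned to foreground genes in the DEG table.
    """

    n_genes: int
    seed: int
    promoter_length: int = 2001
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motif_id: str | None = None
    planting_rate_fg: float = 0.0
    planting_rate_bg: float = 0.0
    n_foreground: int = 0
    effect_log2fold: float = 2.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.background_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0):
            raise ValueError("background_freqs must be 4 non-negative probabilities")
        if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("background_freqs must sum to 1")
        for rate in (self.planting_rate_fg, self.planting_rate_bg):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("planting rates must lie in [0, 1]")
        if self.n_foreground > self.n_genes:
            raise ValueError("n_foreground cannot exceed n_genes")
        if self.n_genes < 1 or self.promoter_length < 1:
            raise ValueError("n_genes and promoter_length must be positive")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    offset: int
    site: str
    motif_id: str


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_promoters(config: SimulationConfig) -> PromoterSet:
    """I.i.d. mononucleotide promoters, gene ids g0001..., seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    bases = np.array(list(_BASES))
    records = []
    for gene_id in _gene_ids(config.n_genes):
        seq = "".join(
            bases[rng.choice(4, size=config.promoter_length, p=config.background_freqs)]
        )
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                chrom="sim",
                strand="+",
                window_start=0,
                window_end=config.promoter_length,
                sequence=seq,
            )
        )
    return PromoterSet(records)


def plant_sites(
    promoters: PromoterSet,
    motif,
    rate: float,
    seed: int | np.random.SeedSequence,
    gene_ids: Sequence[str] | None = None,
) -> tuple[PromoterSet, list[PlantedSite]]:
    """Write one PWM-sampled site into a random subset of promoters.

    Each promoter (optionally restricted to ``gene_ids``) is selected
    independently with probability ``rate``; a site is sampled
    base-by-base from the motif's probability columns and overwrites the
    sequence at a uniform random offset.  Returns the new set plus the
    ground-truth list of planted sites.
    """
    probs = np.asarray(motif.probabilities, dtype=float)
    L = probs.shape[0]
    if promoters.promoter_length < L:
        raise ValueError("promoters shorter than the motif")
    eligible = set(gene_ids) if gene_ids is not None else None
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASES))
    records = []
    truth: list[PlantedSite] = []
    for record in promoters:
        if (eligible is None or record.gene_id in eligible) and rng.random() < rate:
            offset = int(rng.integers(0, len(record.sequence) - L + 1))
            site = "".join(bases[rng.choice(4, p=probs[i])] for i in range(L))
            seq = record.sequence[:offset] + site + record.sequence[offset + L :]
            records.append(
                PromoterRecord(
                    gene_id=record.gene_id,
                    chrom=record.chrom,
                    strand=record.strand,
                    window_start=record.window_start,
                    window_end=record.window_end,
                    sequence=seq,
                )
            )
            truth.append(
                PlantedSite(
                    gene_id=record.gene_id,
                    offset=offset,
                    site=site,
                    motif_id=motif.motif_id,
                )
            )
        else:
            records.append(record)
    return PromoterSet(records), truth


def simulate_deg_table(config: SimulationConfig) -> pd.DataFrame:
    """DEG table whose planted partition the default selection recovers.

    The first ``n_foreground`` genes get ``log2_fold = effect_log2fold``
    and p_adj ~ U(0, 0.01); the rest get log2_fold ~ N(0, 0.1) truncated
    to fold in [0.80, 1.25] and p_adj ~ U(0.2, 1), i.e. they satisfy the
    background-pool criteria exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = _gene_ids(config.n_genes)
    n_fg = config.n_foreground
    n_bg = config.n_genes - n_fg
    log2_fold = np.empty(config.n_genes)
    p_adj = np.empty(config.n_genes)
    log2_fold[:n_fg] = config.effect_log2fold
    p_adj[:n_fg] = rng.uniform(0.0, 0.01, size=n_fg)
    lo, hi = math.log2(0.80), math.log2(1.25)
    draws = rng.normal(0.0, 0.1, size=n_bg)
    while True:  # rejection-sample the truncation
        bad = (draws < lo) | (draws > hi)
        if not bad.any():
            break
        draws[bad] = rng.normal(0.0, 0.1, size=int(bad.sum()))
    log2_fold[n_fg:] = draws
    p_adj[n_fg:] = rng.uniform(0.2, 1.0, size=n_bg)
    return pd.DataFrame({"gene_id": ids, "log2_fold": log2_fold, "p_adj": p_adj})


@dataclass
class SimulatedStudy:
    """A complete simulated input set with its ground truth."""

    promoters: PromoterSet
    deg_table: pd.DataFrame
    foreground_ids: list[str]
    planted: list[PlantedSite] = field(default_factory=list)


def simulate_study(config: SimulationConfig, motif=None) -> SimulatedStudy:
    """Promoter universe + DEG table, optionally with planted sites.

    Sites are planted at ``planting_rate_fg`` in the foreground genes and
    ``planting_rate_bg`` elsewhere.  The DEG foreground genes are the
    first ``n_foreground`` gene ids.
    """
    promoters = simulate_promoters(config)
    deg_table = simulate_deg_table(config)
    fg_ids = _gene_ids(config.n_genes)[: config.n_foreground]
    planted: list[PlantedSite] = []
    if motif is not None and (config.planting_rate_fg > 0 or config.planting_rate_bg > 0):
        promoters, planted_fg = plant_sites(
            promoters,
            motif,
            config.planting_rate_fg,
            np.random.SeedSequence([config.seed, 2]),
            gene_ids=fg_ids,
        )
        planted.extend(planted_fg)
        if config.planting_rate_bg > 0:
            bg_ids = _gene_ids(config.n_genes)[config.n_foreground :]
            promoters, planted_bg = plant_sites(
                promoters,
                motif,
                config.planting_rate_bg,
                np.random.SeedSequence([config.seed, 3]),
                gene_ids=bg_ids,
            )
            planted.extend(planted_bg)
    return SimulatedStudy(
        promoters=promoters,
        deg_table=deg_table,
        foreground_ids=fg_ids,
        planted=planted,
    )


def random_pcm(
    motif_id: str,
    length: int,
    seed: int | np.random.SeedSequence,
    concentration: float = 0.5,
    depth: int = 100,
):
    """A random position count matrix (Dirichlet columns, fixed depth).

    Small ``concentration`` gives informative (peaked) columns; large
    values approach uniform columns.
    """
    from .motifs import PositionCountMatrix

    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=length)
    return PositionCountMatrix(motif_id=motif_id, counts=probs * depth)


def write_ground_truth_tsv(planted: Sequence[PlantedSite], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in planted],
            "offset": [s.offset for s in planted],
            "site": [s.site for s in planted],
            "motif_id": [s.motif_id for s in planted],
        }
    ).to_csv(path, sep="\t", index=False)
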