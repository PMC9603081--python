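"""Monte-Carlo motif over-representation for small promoter sets.

Fisher-style contingency tests lose power when the foreground holds only
a couple of dozen promoters.  The approach here instead compares, per
motif and per calibrated threshold level, the foreground site frequency
AV_FOR against the distribution of site frequencies over many background
groups resampled (without replacement, same size as the foreground) from
a pool of non-differential genes:

    Z = (AV_FOR - AV_BACK) / SD_BACK

with AV_BACK and SD_BACK the mean and sample standard deviation of the
resampled frequencies; a one-sided upper-tail p-value comes from the
standard normal.  The per-level p-values are strongly dependent (the
levels are nested score cutoffs), so they are unified with Hartung's
inverse-normal method for correlated p-values, and the unified p-values
are Benjamini-Hochberg adjusted across the motif collection.

"Site frequency" of a group defaults to the fraction of its promoters
containing at least one hit; a per-window hit rate is available via
``frequency="per_window"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calibration import ThresholdTable, err_grid, thresholds_from_scores
from .motifs import PositionWeightMatrix, encode_sequence, window_scores
from .promoters import PromoterSet

logger = logging.getLogger(__name__)

__all__ = [
    "LevelStat",
    "EnrichmentResult",
    "site_frequency",
    "mc_enrichment",
    "hartung_combine",
    "bh_adjust",
    "rank_motifs",
    "enrich_collection",
    "results_table",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class LevelStat:
    """Enrichment statistics at one threshold level."""

    level: int
    err: float
    threshold: float
    av_for: float
    av_back: float
    sd_back: float
    z: float
    p: float


@dataclass
class EnrichmentResult:
    """Per-motif outcome: per-level stats, unified and adjusted p-values."""

    motif_id: str
    level_stats: list[LevelStat]
    unified_p: float
    p_adj: float = math.nan
    rank: int | None = None
    tf_family: str | None = None

    @property
    def minus_log10_p_adj(self) -> float:
        return -math.log10(self.p_adj)


# ---------------------------------------------------------------------------
# per-promoter hit counting


def _level_counts(
    pwm: PositionWeightMatrix,
    promoters: PromoterSet,
    thresholds: np.ndarray,
    both_strands: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Hit counts per promoter per threshold level, from one scan.

    Returns ``(counts, windows)``: counts has shape (n_promoters,
    n_levels); windows is the number of scored (N-free) windows per
    promoter.  Window scores are computed once per promoter and
    thresholded at every level.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    rc = pwm.reverse_complement() if both_strands else None
    counts = np.zeros((len(promoters), len(thresholds)), dtype=np.int64)
    windows = np.zeros(len(promoters), dtype=np.int64)
    for i, record in enumerate(promoters):
        encoded = encode_sequence(record.sequence)
        scores = window_scores(pwm, encoded)
        if rc is not None:
            scores = np.concatenate([scores, window_scores(rc, encoded)])
        scores = scores[np.isfinite(scores)]
        scores.sort()
        windows[i] = scores.size
        counts[i] = scores.size - np.searchsorted(scores, thresholds, side="left")
    return counts, windows


def _group_frequencies(
    counts: np.ndarray, windows: np.ndarray, member_rows: np.ndarray, frequency: str
) -> np.ndarray:
    """Site frequency of one or many groups, per level.

    ``member_rows`` is (k,) for one group or (R, k) for R resampled
    groups; the result has matching leading shape with n_levels last.
    """
    if frequency == "promoter":
        presence = counts > 0
        return presence[member_rows].mean(axis=-2, dtype=float)
    if frequency == "per_window":
        num = counts[member_rows].sum(axis=-2, dtype=float)
        den = windows[member_rows].sum(axis=-1, dtype=float)
        return num / den[..., None] if num.ndim > 1 else num / den
    raise ValueError(f"frequency must be 'promoter' or 'per_window', got {frequency!r}")


def site_frequency(
    pwm: PositionWeightMatrix,
    promoters_of_group: PromoterSet,
    threshold: float,
    frequency: str = "promoter",
    both_strands: bool = True,
) -> float:
    """Site frequency of one motif in one promoter group at one cutoff.

    Default: fraction of the group's promoters with at least one hit.
    ``frequency="per_window"``: total hits divided by total scored windows.
    """
    if len(promoters_of_group) == 0:
        raise ValueError("group is empty")
    counts, windows = _level_counts(
        pwm, promoters_of_group, np.array([threshold]), both_strands=both_strands
    )
    rows = np.arange(len(promoters_of_group))
    return float(_group_frequencies(counts, windows, rows, frequency)[0])


# ---------------------------------------------------------------------------
# Monte-Carlo machinery


def _resample_matrix(rng: np.random.Generator, n_pool: int, k: int, n_resamples: int) -> np.ndarray:
    """(n_resamples, k) row indices, each row drawn without replacement."""
    u = rng.random((n_resamples, n_pool))
    return np.argpartition(u, k - 1, axis=1)[:, :k] if k < n_pool else np.argsort(u, axis=1)


def level_stats_from_frequencies(
    av_for: np.ndarray,
    back_freqs: np.ndarray,
    errs: np.ndarray,
    thresholds: np.ndarray,
) -> list[LevelStat]:
    """Z-scores and one-sided normal p-values from resampled frequencies.

    ``back_freqs`` has shape (n_resamples, n_levels).  When SD_BACK is
    zero the normal fit is undefined: p falls back to 1 when the
    foreground does not exceed the background and to the Monte-Carlo
    floor ``1/(n_resamples+1)`` when it does.
    """
    n_resamples = back_freqs.shape[0]
    av_back = back_freqs.mean(axis=0)
    sd_back = back_freqs.std(axis=0, ddof=1)
    stats = []
    for lvl in range(back_freqs.shape[1]):
        if sd_back[lvl] > 0:
            z = (av_for[lvl] - av_back[lvl]) / sd_back[lvl]
            p = float(norm.sf(z))
        elif av_for[lvl] <= av_back[lvl]:
            logger.warning("level %d: zero background spread; p set to 1", lvl)
            z, p = 0.0, 1.0
        else:
            logger.warning(
                "level %d: zero background spread with enriched foreground; "
                "p floored at 1/(n_resamples+1)",
                lvl,
            )
            z, p = math.inf, 1.0 / (n_resamples + 1)
        stats.append(
            LevelStat(
                level=lvl,
                err=float(errs[lvl]),
                threshold=float(thresholds[lvl]),
                av_for=float(av_for[lvl]),
                av_back=float(av_back[lvl]),
                sd_back=float(sd_back[lvl]),
                z=float(z),
                p=p,
            )
        )
    return stats


def _mc_level_stats(
    counts: np.ndarray,
    windows: np.ndarray,
    fg_rows: np.ndarray,
    pool_rows: np.ndarray,
    table: ThresholdTable,
    n_resamples: int,
    rng: np.random.Generator,
    frequency: str,
) -> list[LevelStat]:
    av_for = _group_frequencies(counts, windows, fg_rows, frequency)
    idx = _resample_matrix(rng, len(pool_rows), len(fg_rows), n_resamples)
    back = _group_frequencies(counts, windows, pool_rows[idx], frequency)
    return level_stats_from_frequencies(av_for, back, table.err, table.thresholds)


def mc_enrichment(
    pwm: PositionWeightMatrix,
    foreground_ids: Sequence[str],
    background_pool_ids: Sequence[str],
    promoter_set: PromoterSet,
    threshold_table: ThresholdTable,
    n_resamples: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    frequency: str = "promoter",
    both_strands: bool = True,
) -> list[LevelStat]:
    """Per-level Monte-Carlo enrichment of one motif.

    Each of ``n_resamples`` background groups is a uniform draw without
    replacement of ``len(foreground_ids)`` genes from the pool; the same
    groups are reused across threshold levels (the group, not the hit
    set, is the unit of resampling).  Deterministic given ``seed``.
    """
    fg = list(foreground_ids)
    pool = list(background_pool_ids)
    if not fg:
        raise ValueError("foreground is empty")
    if len(pool) < len(fg):
        raise ValueError(
            f"background pool ({len(pool)}) smaller than foreground ({len(fg)})"
        )
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    members = fg + pool
    counts, windows = _level_counts(
        pwm, promoter_set.subset(members), threshold_table.thresholds, both_strands
    )
    rng = np.random.default_rng(seed)
    fg_rows = np.arange(len(fg))
    pool_rows = np.arange(len(fg), len(members))
    return _mc_level_stats(
        counts, windows, fg_rows, pool_rows, threshold_table, n_resamples, rng, frequency
    )


# ---------------------------------------------------------------------------
# p-value combination and ranking


def hartung_combine(p_values: Sequence[float], kappa: float = 0.2) -> float:
    """Unify dependent p-values with Hartung's inverse-normal method.

    Transforms t_i = Phi^-1(p_i), estimates the inter-statistic
    correlation rho from the spread of the t_i (rho_hat = 1 - var(t)),
    truncates it below at -1/(L-1), and returns

        Phi( sum(t) / sqrt(L + (L^2 - L) * [rho* + kappa*sqrt(2/(L+1))*(1 - rho*)]) )

    with the small positive bias term kappa guarding against an
    underestimated correlation.  Equal p-values are a fixed point (the
    perfect-dependence limit), and a single p-value is returned as-is.
    Inputs are clamped into [1e-300, 1 - 1e-16] before the transform.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.clip(p, _P_FLOOR, _P_CEIL)
    L = p.size
    if L == 1:
        return float(p[0])
    t = norm.ppf(p)
    tbar = t.mean()
    rho_hat = 1.0 - ((t - tbar) ** 2).sum() / (L - 1)
    rho_star = max(-1.0 / (L - 1), rho_hat)
    q = rho_star + kappa * math.sqrt(2.0 / (L + 1)) * (1.0 - rho_star)
    denom = math.sqrt(L + (L * L - L) * q)
    unified = float(norm.cdf(t.sum() / denom))
    return min(max(unified, _P_FLOOR), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def rank_motifs(results: Iterable[EnrichmentResult]) -> list[EnrichmentResult]:
    """Sort by p_adj (ties: unified_p, then motif id) and assign ranks 1..M."""
    ordered = sorted(results, key=lambda r: (r.p_adj, r.unified_p, r.motif_id))
    for rank, result in enumerate(ordered, start=1):
        result.rank = rank
    return ordered


# ---------------------------------------------------------------------------
# collection-level driver


def enrich_collection(
    pwms: Sequence[PositionWeightMatrix],
    foreground_ids: Iterable[str],
    background_pool_ids: Iterable[str],
    promoter_set: PromoterSet,
    errs: np.ndarray | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    frequency: str = "promoter",
    both_strands: bool = True,
    kappa: float = 0.2,
    tf_families: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Calibrate, resample and rank a whole motif collection.

    For each motif the promoter universe is scanned once: the pooled
    window scores yield the ERR threshold table, and the same scores give
    per-promoter hit counts per level for the Monte-Carlo step.  Each
    motif draws its resamples from an independent, deterministic child
    stream of ``seed``.  Returns results ranked by BH-adjusted unified p.
    """
    if errs is None:
        errs = err_grid()
    fg = sorted(set(foreground_ids))
    pool = sorted(set(background_pool_ids))
    if set(fg) & set(pool):
        raise ValueError("foreground and background pool overlap")
    if not fg:
        raise ValueError("foreground is empty")
    if len(pool) < len(fg):
        raise ValueError(
            f"background pool ({len(pool)}) smaller than foreground ({len(fg)})"
        )
    missing = [g for g in fg + pool if g not in promoter_set]
    if missing:
        raise KeyError(f"genes without promoters: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    gene_order = promoter_set.gene_ids
    row_of = {g: i for i, g in enumerate(gene_order)}
    fg_rows = np.array([row_of[g] for g in fg])
    pool_rows = np.array([row_of[g] for g in pool])
    child_seeds = np.random.SeedSequence(seed).spawn(len(pwms))
    results = []
    for pwm, child in zip(pwms, child_seeds):
        if pwm.length > promoter_set.promoter_length:
            raise ValueError(f"motif {pwm.motif_id!r} longer than the promoters")
        rc = pwm.reverse_complement() if both_strands else None
        # one scan of the whole universe per motif: pooled scores for
        # calibration, per-promoter counts for the resampling step
        per_promoter: list[np.ndarray] = []
        for record in promoter_set:
            encoded = encode_sequence(record.sequence)
            scores = window_scores(pwm, encoded)
            if rc is not None:
                scores = np.concatenate([scores, window_scores(rc, encoded)])
            scores = scores[np.isfinite(scores)]
            scores.sort()
            per_promoter.append(scores)
        pooled = np.concatenate(per_promoter)
        thresholds, realized, n_windows = thresholds_from_scores(pooled, errs)
        table = ThresholdTable(
            motif_id=pwm.motif_id,
            err=np.asarray(errs, dtype=float),
            thresholds=thresholds,
            realized_err=realized,
            universe_positions=n_windows,
        )
        counts = np.empty((len(per_promoter), len(thresholds)), dtype=np.int64)
        windows = np.empty(len(per_promoter), dtype=np.int64)
        for i, scores in enumerate(per_promoter):
            windows[i] = scores.size
            counts[i] = scores.size - np.searchsorted(scores, thresholds, side="left")
        rng = np.random.default_rng(child)
        stats = _mc_level_stats(
            counts, windows, fg_rows, pool_rows, table, n_resamples, rng, frequency
        )
        unified = hartung_combine([s.p for s in stats], kappa=kappa)
        results.append(
            EnrichmentResult(
                motif_id=pwm.motif_id,
                level_stats=stats,
                unified_p=unified,
                tf_family=(tf_families or {}).get(pwm.motif_id),
            )
        )
    adjusted = bh_adjust([r.unified_p for r in results])
    for result, p_adj in zip(results, adjusted):
        result.p_adj = float(p_adj)
    return rank_motifs(results)


def results_table(
    results: Sequence[EnrichmentResult],
    report_threshold: float | None = 0.05,
) -> pd.DataFrame:
    """Ranked result table (wide per-level Z columns).

    ``report_threshold`` drops motifs with p_adj above it, matching the
    printed-report convention; pass ``None`` to keep every motif.
    """
    rows = []
    for r in results:
        if report_threshold is not None and r.p_adj > report_threshold:
            continue
        row = {
            "rank": r.rank,
            "motif_id": r.motif_id,
            "tf_family": r.tf_family if r.tf_family is not None else "",
            "minus_log10_p_adj": r.minus_log10_p_adj,
            "p_adj": r.p_adj,
            "unified_p": r.unified_p,
        }
        for s in r.level_stats:
            row[f"z_{s.level:02d}"] = s.z
        rows.append(row)
    return pd.DataFrame(rows)
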