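"""Score-threshold calibration by expected recognition rate (ERR).

Raw log-odds scores are not comparable across motifs, so thresholds are
expressed in a common currency: the expected recognition rate, i.e. the
probability that a single scanned window of the promoter universe reaches
the threshold.  For each motif the whole universe is scanned (both strands
by default), all window scores are pooled, and for each nominal ERR on a
log-equidistant grid the smallest score threshold whose realized ERR does
not exceed the nominal level is recorded.

Defaults follow the enrichment procedure this package implements: 30
levels, log-equidistant between 5e-4 and 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import PositionWeightMatrix, encode_sequence, window_scores
from .promoters import PromoterSet

__all__ = ["ThresholdTable", "err_grid", "calibrate_thresholds", "thresholds_from_scores"]


@dataclass
class ThresholdTable:
    """Per-motif score cutoffs at each nominal ERR level.

    ``err`` is strictly decreasing; ``thresholds`` is non-decreasing (a
    rarer hit requires at least as high a score).  ``realized_err`` is the
    hit rate actually achieved at each cutoff on the calibration universe
    (always <= the nominal level; ties at the cutoff all count as hits).
    A ``+inf`` threshold marks a level no finite cutoff can satisfy.
    """

    motif_id: str
    err: np.ndarray
    thresholds: np.ndarray
    realized_err: np.ndarray
    universe_positions: int

    def __post_init__(self) -> None:
        self.err = np.asarray(self.err, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.realized_err = np.asarray(self.realized_err, dtype=float)
        if not (len(self.err) == len(self.thresholds) == len(self.realized_err)):
            raise ValueError("err, thresholds and realized_err must have equal length")
        if np.any(np.diff(self.err) >= 0):
            raise ValueError("err levels must be strictly decreasing")
        if not np.all(self.thresholds[1:] >= self.thresholds[:-1]):
            raise ValueError("thresholds must be non-decreasing as err decreases")

    @property
    def n_levels(self) -> int:
        return len(self.err)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_id": self.motif_id,
                "level_index": np.arange(self.n_levels),
                "nominal_err": self.err,
                "score_threshold": self.thresholds,
                "realized_err": self.realized_err,
                "universe_positions": self.universe_positions,
            }
        )

    @staticmethod
    def write_tsv(tables: Sequence["ThresholdTable"], path) -> None:
        pd.concat([t.to_frame() for t in tables]).to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_tsv(path) -> list["ThresholdTable"]:
        frame = pd.read_csv(path, sep="\t")
        out = []
        for motif_id, group in frame.groupby("motif_id", sort=False):
            group = group.sort_values("level_index")
            out.append(
                ThresholdTable(
                    motif_id=str(motif_id),
                    err=group["nominal_err"].to_numpy(),
                    thresholds=group["score_threshold"].to_numpy(),
                    realized_err=group["realized_err"].to_numpy(),
                    universe_positions=int(group["universe_positions"].iloc[0]),
                )
            )
        return out


def err_grid(err_max: float = 5e-4, err_min: float = 1e-4, n_levels: int = 30) -> np.ndarray:
    """Geometric (log-equidistant) grid of ERR levels, decreasing.

    Runs from ``err_max`` down to ``err_min`` inclusive with a constant
    ratio ``(err_min/err_max)**(1/(n_levels-1))`` between neighbours.
    """
    if not (0 < err_min < err_max <= 1):
        raise ValueError(f"require 0 < err_min < err_max <= 1, got ({err_min}, {err_max})")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    return np.geomspace(err_max, err_min, n_levels)


def thresholds_from_scores(
    scores: np.ndarray, errs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cutoffs over a pooled score sample at each nominal ERR.

    ``scores`` are all finite window scores of one motif over the universe.
    For each nominal level ``e`` the threshold is the smallest score value
    ``t`` with ``count(score >= t) / len(scores) <= e``; the realized ERR
    is that count fraction.  Returns (thresholds, realized, n_windows).
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    n = scores.size
    if n == 0:
        raise ValueError("no finite scores to calibrate on")
    values, counts = np.unique(scores, return_counts=True)  # ascending
    # count of scores >= values[i]
    count_ge = n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    count_ge_asc = count_ge[::-1]  # ascending in count
    thresholds = np.empty(len(errs))
    realized = np.empty(len(errs))
    for i, e in enumerate(errs):
        k = math.floor(e * n)
        pos = np.searchsorted(count_ge_asc, k, side="right")
        if pos == 0:
            # even the strictest cutoff (max score, with ties) overshoots
            thresholds[i] = np.inf
            realized[i] = 0.0
        else:
            j = len(values) - pos  # loosest value with count_ge <= k
            thresholds[i] = values[j]
            realized[i] = count_ge[j] / n
    return thresholds, realized, n


def calibrate_thresholds(
    pwm: PositionWeightMatrix,
    promoter_universe: PromoterSet,
    errs: np.ndarray | None = None,
    both_strands: bool = True,
) -> ThresholdTable:
    """Scan the whole universe and compile the motif's threshold table.

    The ERR denominator is the number of scanned windows (positions x
    strands); windows containing N are excluded from both numerator and
    denominator, which ``universe_positions`` reflects.
    """
    if errs is None:
        errs = err_grid()
    if len(promoter_universe) == 0:
        raise ValueError("promoter universe is empty")
    if pwm.length > promoter_universe.promoter_length:
        raise ValueError(
            f"motif {pwm.motif_id!r} (L={pwm.length}) longer than promoters "
            f"({promoter_universe.promoter_length} bp)"
        )
    rc = pwm.reverse_complement() if both_strands else None
    pooled = []
    for record in promoter_universe:
        encoded = encode_sequence(record.sequence)
        pooled.append(window_scores(pwm, encoded))
        if rc is not None:
            pooled.append(window_scores(rc, encoded))
    scores = np.concatenate(pooled)
    thresholds, realized, n = thresholds_from_scores(scores, errs)
    return ThresholdTable(
        motif_id=pwm.motif_id,
        err=np.asarray(errs, dtype=float),
        thresholds=thresholds,
        realized_err=realized,
        universe_positions=n,
    )
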