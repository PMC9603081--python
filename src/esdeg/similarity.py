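"""Pairwise motif similarity with a column-permutation significance test.

Two motifs are compared by the best ungapped alignment: over all offsets
and both orientations (second motif as-is or reverse-complemented), the
score is the mean Pearson correlation between aligned probability
columns, requiring at least 4 overlapping columns.  Significance comes
from a permutation null: the columns (positions) of the second motif are
shuffled uniformly and the best-alignment score recomputed; the p-value
is ``(1 + #null >= observed) / (n_perm + 1)``.  Pairs with p > 0.05 are
reported as distinct, matching the blank-cell convention of similarity
matrices alongside enrichment reports.

Zero-variance (uniform) columns correlate with nothing: their
contribution is 0, so a flat motif is never significantly similar to
anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityEntry",
    "motif_similarity_score",
    "motif_similarity_p",
    "similarity_matrix",
    "similarity_frame",
    "write_similarity_tsv",
]

_MIN_OVERLAP = 4


@dataclass(frozen=True)
class SimilarityEntry:
    motif_a: str
    motif_b: str
    best_score: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _normalized_columns(motif) -> np.ndarray:
    """Per-position probability columns, centered and L2-normalized.

    A uniform column (zero variance) becomes the zero vector, so its dot
    product — its correlation — with anything is 0.
    """
    p = np.asarray(motif.probabilities, dtype=float)
    centered = p - p.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norms > 1e-12, centered / norms, 0.0)
    return u


def _revcomp_columns(u: np.ndarray) -> np.ndarray:
    return u[::-1, ::-1]


def _offset_bands(la: int, lb: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index pairs (rows of a, rows of b) for every ungapped alignment."""
    bands = []
    for shift in range(-(lb - _MIN_OVERLAP), la - _MIN_OVERLAP + 1):
        i0, j0 = max(0, shift), max(0, -shift)
        k = min(la - i0, lb - j0)
        if k >= _MIN_OVERLAP:
            bands.append((np.arange(i0, i0 + k), np.arange(j0, j0 + k)))
    return bands


def _best_score(ua: np.ndarray, ub_variants: Sequence[np.ndarray]) -> float:
    best = -np.inf
    for ub in ub_variants:
        corr = ua @ ub.T  # (La, Lb) column correlations
        for ii, jj in _offset_bands(ua.shape[0], ub.shape[0]):
            best = max(best, float(corr[ii, jj].mean()))
    return best


def motif_similarity_score(motif_a, motif_b) -> float:
    """Best mean per-column correlation over offsets and orientations.

    Accepts any object with ``probabilities`` (count or weight matrices).
    """
    if min(motif_a.probabilities.shape[0], motif_b.probabilities.shape[0]) < _MIN_OVERLAP:
        raise ValueError(
            f"motifs must overlap by >= {_MIN_OVERLAP} columns; "
            f"{motif_a.motif_id!r} / {motif_b.motif_id!r} too short"
        )
    ua = _normalized_columns(motif_a)
    ub = _normalized_columns(motif_b)
    return _best_score(ua, [ub, _revcomp_columns(ub)])


def motif_similarity_p(
    motif_a,
    motif_b,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> SimilarityEntry:
    """Permutation-test similarity of two motifs.

    The null shuffles the column order of ``motif_b`` uniformly for each
    of ``n_perm`` permutations; the observed best-alignment score is
    referred to the null distribution of best scores.  Deterministic
    given ``seed``; the smallest attainable p is ``1/(n_perm+1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ua = _normalized_columns(motif_a)
    ub = _normalized_columns(motif_b)
    if min(ua.shape[0], ub.shape[0]) < _MIN_OVERLAP:
        raise ValueError(
            f"motifs must overlap by >= {_MIN_OVERLAP} columns; "
            f"{motif_a.motif_id!r} / {motif_b.motif_id!r} too short"
        )
    variants = [ub, _revcomp_columns(ub)]
    observed = _best_score(ua, variants)
    la, lb = ua.shape[0], ub.shape[0]
    rng = np.random.default_rng(seed)
    # the correlation matrix is fixed; permuting b's columns only permutes
    # its columns, so each permutation is pure indexing
    corrs = [ua @ v.T for v in variants]
    bands = _offset_bands(la, lb)
    perms = np.argsort(rng.random((n_perm, lb)), axis=1)
    null_best = np.full(n_perm, -np.inf)
    for corr in corrs:
        for ii, jj in bands:
            # rows: permutations; columns: aligned positions
            vals = corr[ii[None, :], perms[:, jj]].mean(axis=1)
            np.maximum(null_best, vals, out=null_best)
    p = (1.0 + int((null_best >= observed - 1e-12).sum())) / (n_perm + 1.0)
    return SimilarityEntry(
        motif_a=motif_a.motif_id,
        motif_b=motif_b.motif_id,
        best_score=observed,
        p_value=p,
    )


def similarity_matrix(
    motifs: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], SimilarityEntry]:
    """All unordered-pair similarity entries for a motif collection.

    Keyed symmetrically: both (a, b) and (b, a) map to the same entry.
    Each pair gets an independent deterministic child stream of ``seed``.
    """
    if len(motifs) < 2:
        raise ValueError("need at least 2 motifs")
    n = len(motifs)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    child_seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    entries: dict[tuple[str, str], SimilarityEntry] = {}
    for (i, j), child in zip(pairs, child_seeds):
        entry = motif_similarity_p(motifs[i], motifs[j], n_perm=n_perm, seed=child)
        entries[(entry.motif_a, entry.motif_b)] = entry
        entries[(entry.motif_b, entry.motif_a)] = entry
    return entries


def similarity_frame(
    motifs: Sequence,
    entries: dict[tuple[str, str], SimilarityEntry],
) -> pd.DataFrame:
    """Square labelled matrix of -log10(p) for significant pairs.

    Non-significant cells (p > 0.05) are empty strings — "distinct"
    motifs; the diagonal is marked with a dot.
    """
    ids = [m.motif_id for m in motifs]
    data = []
    for a in ids:
        row = []
        for b in ids:
            if a == b:
                row.append(".")
                continue
            entry = entries[(a, b)]
            row.append(f"{-np.log10(entry.p_value):.2f}" if entry.significant else "")
        data.append(row)
    return pd.DataFrame(data, index=ids, columns=ids)


def write_similarity_tsv(motifs: Sequence, entries, path) -> None:
    similarity_frame(motifs, entries).to_csv(path, sep="\t", index_label="motif_id")
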