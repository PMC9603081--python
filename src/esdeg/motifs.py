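"""Position count/weight matrices: parsing, log-odds construction and scanning.

The scanning model is the standard additive log-odds PWM: a window of the
same length as the motif gets the sum of per-position log-odds weights,
and a "site" is any window (on either strand) whose score reaches a
threshold.  Thresholds themselves are not chosen here — they come from
calibration against a promoter universe (see :mod:`esdeg.calibration`),
which is what makes scores comparable across motifs of different lengths
and information contents.

Windows containing ``N`` (or any non-ACGT base) can never be sites: they
score ``-inf``.  Masked or ambiguous sequence therefore never fabricates
matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PositionCountMatrix",
    "PositionWeightMatrix",
    "MotifHit",
    "parse_motif_library",
    "write_motif_library",
    "filter_motifs",
    "pcm_to_pwm",
    "score_window",
    "scan_promoter",
    "information_content",
    "encode_sequence",
]

_BASES = "ACGT"

# byte -> code table; anything that is not a/c/g/t (either case) codes to 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes A=0, C=1, G=2, T=3, other=4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class PositionCountMatrix:
    """Per-position nucleotide counts of a binding motif (columns A,C,G,T)."""

    motif_id: str
    counts: np.ndarray  # shape (L, 4), non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(
                f"motif {self.motif_id!r}: counts must be L x 4, got shape {counts.shape}"
            )
        if counts.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id!r}: motif length must be >= 1")
        if np.any(counts < 0):
            raise ValueError(f"motif {self.motif_id!r}: negative count")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError(f"motif {self.motif_id!r}: a position has zero total count")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized counts: per-position base probabilities."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds weight matrix (natural log) with a cached maximum score."""

    motif_id: str
    weights: np.ndarray  # shape (L, 4)
    background: np.ndarray  # 4 probabilities, sum 1
    pseudocount: float
    _ext: np.ndarray = field(init=False, repr=False, compare=False)
    max_score: float = field(init=False, compare=False)

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if weights.ndim != 2 or weights.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id!r}: weights must be L x 4")
        if not np.all(np.isfinite(weights)):
            raise ValueError(f"motif {self.motif_id!r}: non-finite weight")
        if background.shape != (4,) or np.any(background <= 0):
            raise ValueError("background must be 4 positive probabilities")
        if not math.isclose(background.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("background probabilities must sum to 1")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "background", background)
        # fifth column = N: -inf so that any window over masked sequence
        # can never reach a finite threshold
        ext = np.full((weights.shape[0], 5), -np.inf)
        ext[:, :4] = weights
        object.__setattr__(self, "_ext", ext)
        object.__setattr__(self, "max_score", float(weights.max(axis=1).sum()))

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Implied per-position base probabilities (inverts the log-odds)."""
        p = self.background[None, :] * np.exp(self.weights)
        return p / p.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "PositionWeightMatrix":
        """PWM scoring the reverse-complement strand of the same motif."""
        return PositionWeightMatrix(
            motif_id=self.motif_id,
            weights=self.weights[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class MotifHit:
    """A predicted site: motif occurrence within one promoter."""

    gene_id: str
    offset: int  # 0-based start within the promoter
    strand: str  # '+' or '-'
    score: float
    motif_id: str


# ---------------------------------------------------------------------------
# library parsing


def _blocks_from_lines(lines: Sequence[str], *, headered: bool) -> list[tuple[str, list[str]]]:
    blocks: list[tuple[str, list[str]]] = []
    name: str | None = None
    rows: list[str] = []
    for line in lines:
        stripped = line.strip()
        if headered and stripped.startswith(">"):
            if name is not None:
                blocks.append((name, rows))
            name = stripped[1:].strip().split()[0]
            rows = []
        elif not stripped:
            if not headered and name is not None:
                blocks.append((name, rows))
                name = None
                rows = []
        elif name is None:
            if headered:
                raise ValueError(f"matrix rows before any '>' header: {stripped!r}")
            name = stripped.split()[0]
            rows = []
        else:
            rows.append(stripped)
    if name is not None:
        blocks.append((name, rows))
    return blocks


def _block_to_pcm(name: str, rows: list[str]) -> PositionCountMatrix:
    parsed = []
    for row in rows:
        values = row.split()
        if len(values) != 4:
            raise ValueError(
                f"motif {name!r}: expected 4 columns (A C G T), got {len(values)} in row {row!r}"
            )
        parsed.append([float(v) for v in values])
    if not parsed:
        raise ValueError(f"motif {name!r}: no matrix rows")
    return PositionCountMatrix(motif_id=name, counts=np.array(parsed))


def parse_motif_library(path, format: str = "hocomoco_pcm") -> list[PositionCountMatrix]:
    """Parse a motif library file into position count matrices.

    Supported formats
    -----------------
    ``hocomoco_pcm``
        ``>`` id line followed by L whitespace-separated rows of 4 numbers
        in A C G T column order (the HOCOMOCO ``.pcm`` convention).
    ``jaspar_like``
        JASPAR-style blocks (``>`` header, one bracketed line per base);
        delegated to :mod:`Bio.motifs`.
    ``plain``
        Like ``hocomoco_pcm`` but the id line carries no ``>`` and blocks
        are separated by blank lines.
    """
    with open(path) as handle:
        if format == "jaspar_like":
            from Bio import motifs as bio_motifs

            records = bio_motifs.parse(handle, "jaspar")
            out = []
            for record in records:
                counts = np.array(
                    [[record.counts[b][i] for b in _BASES] for i in range(record.length)]
                )
                out.append(PositionCountMatrix(motif_id=record.matrix_id or record.name, counts=counts))
            if not out:
                raise ValueError(f"no motifs found in {path}")
            return out
        if format not in ("hocomoco_pcm", "plain"):
            raise ValueError(f"unknown motif library format {format!r}")
        lines = handle.readlines()
    blocks = _blocks_from_lines(lines, headered=(format == "hocomoco_pcm"))
    if not blocks:
        raise ValueError(f"no motifs found in {path}")
    return [_block_to_pcm(name, rows) for name, rows in blocks]


def write_motif_library(pcms: Iterable[PositionCountMatrix], path) -> None:
    """Write matrices in the ``>``-headered row-per-position text format."""
    with open(path, "w") as handle:
        for pcm in pcms:
            handle.write(f">{pcm.motif_id}\n")
            for row in pcm.counts:
                handle.write("\t".join(format(v, "g") for v in row) + "\n")


def information_content(pcm: PositionCountMatrix) -> float:
    """Total information content in bits, summed over positions.

    Per position: 2 + sum_b p_b * log2(p_b), with 0*log(0) taken as 0.
    """
    p = pcm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + terms.sum(axis=1)).sum())


def filter_motifs(
    matrices: Sequence[PositionCountMatrix],
    exclude: Iterable[str] | None = None,
    *,
    min_length: int = 6,
    min_bits: float = 5.0,
) -> list[PositionCountMatrix]:
    """Subset a motif collection, preserving order.

    If ``exclude`` is given (possibly empty), drop exactly the named ids.
    Otherwise apply a quality fallback: drop motifs shorter than
    ``min_length`` or with total information content below ``min_bits``.
    """
    if exclude is not None:
        excluded = set(exclude)
        return [m for m in matrices if m.motif_id not in excluded]
    return [
        m
        for m in matrices
        if m.length >= min_length and information_content(m) >= min_bits
    ]


# ---------------------------------------------------------------------------
# log-odds construction and scoring


def pcm_to_pwm(
    pcm: PositionCountMatrix,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float | None = None,
) -> PositionWeightMatrix:
    """Convert counts to natural-log odds weights.

    weight[i, b] = ln((counts[i, b] + pc * bg[b]) / (N_i + pc)) - ln(bg[b])

    where ``N_i`` is the total count at position ``i``.  The default
    pseudocount is ``0.25 * sqrt(N)`` with ``N`` the mean position total,
    a common motif-library regularization that scales with matrix depth.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,):
        raise ValueError("background must have 4 components")
    if np.any(background <= 0):
        raise ValueError("background components must be positive")
    if not math.isclose(background.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("background probabilities must sum to 1")
    counts = pcm.counts
    row_sums = counts.sum(axis=1)
    if pseudocount is None:
        pseudocount = 0.25 * math.sqrt(float(row_sums.mean()))
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    smoothed = (counts + pseudocount * background[None, :]) / (
        row_sums[:, None] + pseudocount
    )
    weights = np.log(smoothed) - np.log(background[None, :])
    return PositionWeightMatrix(
        motif_id=pcm.motif_id,
        weights=weights,
        background=background,
        pseudocount=float(pseudocount),
    )


def window_scores(pwm: PositionWeightMatrix, encoded: np.ndarray) -> np.ndarray:
    """Scores of all length-L windows of an encoded sequence (one strand).

    Returns an array of length ``len(encoded) - L + 1`` (empty if the
    sequence is shorter than the motif).  Windows covering any non-ACGT
    base score ``-inf``.
    """
    L = pwm.length
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    ext = pwm._ext
    for j in range(L):
        scores += ext[j, encoded[j : j + n]]
    return scores


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Score a single window of exactly the motif's length."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length} "
            f"for {pwm.motif_id!r}"
        )
    encoded = encode_sequence(window)
    return float(pwm._ext[np.arange(pwm.length), encoded].sum())


def scan_promoter(
    pwm: PositionWeightMatrix,
    promoter,
    threshold: float,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All hits (score >= threshold) of a motif in one promoter.

    ``promoter`` may be a :class:`~esdeg.promoters.PromoterRecord` or a
    plain ``(gene_id, sequence)`` pair.  Reverse-strand windows are scored
    as the reverse complement of the forward window at the same offset.
    Hits are sorted by offset, then strand ('+' before '-').
    """
    if hasattr(promoter, "gene_id"):
        gene_id, sequence = promoter.gene_id, promoter.sequence
    else:
        gene_id, sequence = promoter
    encoded = encode_sequence(sequence)
    hits: list[MotifHit] = []
    forward = window_scores(pwm, encoded)
    strands = [("+", forward)]
    if both_strands:
        strands.append(("-", window_scores(pwm.reverse_complement(), encoded)))
    for strand, scores in strands:
        for offset in np.flatnonzero(scores >= threshold):
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    offset=int(offset),
                    strand=strand,
                    score=float(scores[offset]),
                    motif_id=pwm.motif_id,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits
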