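"""Promoter universe construction: FASTA/BED I/O and TSS-window extraction.

A promoter here is a fixed window around a gene's transcription start
site: ``upstream`` bases before the TSS plus ``downstream`` bases starting
at the TSS itself (default 2000 + 1 = 2001 bp).  All windows in a universe
have identical length so that every promoter contributes the same number
of scanning windows, which is what makes per-window expected recognition
rates comparable across the universe.

Coordinates are 0-based half-open internally; BED output follows the BED
convention.  1-based TSS input is accepted via ``one_based=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterRecord",
    "PromoterSet",
    "read_fasta",
    "extract_promoters",
    "read_tss_table",
    "tss_table_from_gff",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """One gene's promoter window (strand-aware, fixed length).

    ``sequence`` is oriented so position 0 is the most upstream base: for
    '-' strand genes the genomic slice is reverse-complemented.
    """

    gene_id: str
    chrom: str
    strand: str
    window_start: int
    window_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.window_end - self.window_start != len(self.sequence):
            raise ValueError(
                f"{self.gene_id}: window [{self.window_start}, {self.window_end}) "
                f"does not match sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"{self.gene_id}: invalid characters {sorted(bad)} in sequence")


class PromoterSet:
    """An ordered collection of equal-length promoters, indexed by gene id."""

    def __init__(self, records: Sequence[PromoterRecord]):
        records = list(records)
        lengths = {len(r.sequence) for r in records}
        if len(lengths) > 1:
            raise ValueError(f"promoters have unequal lengths: {sorted(lengths)}")
        index: dict[str, PromoterRecord] = {}
        for record in records:
            if record.gene_id in index:
                raise ValueError(f"duplicate gene_id {record.gene_id!r}")
            index[record.gene_id] = record
        self.records = records
        self.index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.index

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self.index[gene_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, PromoterSet) and self.records == other.records

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def promoter_length(self) -> int:
        if not self.records:
            raise ValueError("empty promoter set has no length")
        return len(self.records[0].sequence)

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        """Sub-universe for the given genes, in the given order."""
        return PromoterSet([self.index[g] for g in gene_ids])

    # -- serialization ------------------------------------------------------

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
            for r in self.records
        ]
        SeqIO.write(records, str(path), "fasta")

    def to_bed(self, path) -> None:
        """BED6: chrom, start, end, gene_id, 0, strand."""
        with open(path, "w") as handle:
            for r in self.records:
                handle.write(
                    f"{r.chrom}\t{r.window_start}\t{r.window_end}\t{r.gene_id}\t0\t{r.strand}\n"
                )

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        """Promoters from a bare FASTA (no genomic coordinates available).

        Records get placeholder coordinates ``[0, len)`` on chrom '.' and
        '+' strand; sufficient for scanning and enrichment.
        """
        entries = read_fasta(path)
        return cls(
            [
                PromoterRecord(
                    gene_id=name,
                    chrom=".",
                    strand="+",
                    window_start=0,
                    window_end=len(seq),
                    sequence=seq,
                )
                for name, seq in entries
            ]
        )

    @classmethod
    def from_fasta_bed(cls, fasta_path, bed_path) -> "PromoterSet":
        """Rebuild a coordinate-aware set from paired FASTA + BED6 files."""
        sequences = dict(read_fasta(fasta_path))
        records = []
        with open(bed_path) as handle:
            for line in handle:
                if not line.strip():
                    continue
                chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
                records.append(
                    PromoterRecord(
                        gene_id=name,
                        chrom=chrom,
                        strand=strand,
                        window_start=int(start),
                        window_end=int(end),
                        sequence=sequences[name],
                    )
                )
        return cls(records)


def read_fasta(path, on_invalid: str = "map_to_n") -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, uppercase sequence)`` pairs, file order.

    ``on_invalid`` controls characters outside {A,C,G,T,N}: ``"map_to_n"``
    replaces them, ``"reject"`` raises.
    """
    if on_invalid not in ("map_to_n", "reject"):
        raise ValueError(f"on_invalid must be 'map_to_n' or 'reject', got {on_invalid!r}")
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} is not a '>' header"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        invalid = set(seq) - _VALID
        if invalid:
            if on_invalid == "reject":
                raise ValueError(
                    f"{path}: record {record.id!r} contains invalid characters {sorted(invalid)}"
                )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        out.append((record.id, seq))
    if not out:
        raise ValueError(f"{path}: empty FASTA file")
    return out


def read_tss_table(path) -> pd.DataFrame:
    """TSV with header ``gene_id  chrom  strand  tss`` (0-based by default)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    return table


def tss_table_from_gff(path, feature: str = "gene", id_attribute: str = "ID") -> pd.DataFrame:
    """Minimal GFF3 -> TSS table converter (gene features only).

    Takes the 5' end of each ``feature`` line as the TSS and reads the gene
    id from ``id_attribute`` in column 9.  Not a general GFF parser — it
    covers the common case of one gene feature per gene.
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            chrom, start, end, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
            gene_id = None
            for item in attrs.split(";"):
                key, _, value = item.strip().partition("=")
                if key == id_attribute:
                    gene_id = value
                    break
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1  # GFF is 1-based
            rows.append((gene_id, chrom, strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def extract_promoters(
    genome: Mapping[str, str],
    tss_table,
    upstream: int = 2000,
    downstream: int = 1,
    one_based: bool = False,
) -> PromoterSet:
    """Cut fixed TSS windows out of a genome.

    For '+' strand genes the window is ``[tss - upstream, tss + downstream)``;
    for '-' strand genes it is ``[tss - downstream + 1, tss + upstream + 1)``
    and the slice is reverse-complemented, so position 0 of every returned
    sequence is the most upstream base.  Genes whose window runs off the
    chromosome are dropped with a warning; only the first TSS per gene is
    kept (alternative transcripts collapsed).
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    if downstream < 1:
        raise ValueError("downstream must be >= 1")
    if isinstance(tss_table, pd.DataFrame):
        rows = list(
            tss_table[["gene_id", "chrom", "strand", "tss"]].itertuples(index=False, name=None)
        )
    else:
        rows = [tuple(row) for row in tss_table]
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for gene_id, chrom, strand, tss in rows:
        tss = int(tss)
        if one_based:
            tss -= 1
        if gene_id in seen:
            logger.warning("duplicate TSS for gene %s; keeping first occurrence", gene_id)
            continue
        if chrom not in genome:
            raise KeyError(f"gene {gene_id}: unknown chromosome {chrom!r}")
        if tss < 0:
            raise ValueError(f"gene {gene_id}: negative TSS {tss}")
        chrom_seq = genome[chrom]
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        elif strand == "-":
            start, end = tss - downstream + 1, tss + upstream + 1
        else:
            raise ValueError(f"gene {gene_id}: strand must be '+' or '-', got {strand!r}")
        if start < 0 or end > len(chrom_seq):
            logger.warning(
                "gene %s: window [%d, %d) exceeds chromosome %s bounds; dropped",
                gene_id,
                start,
                end,
                chrom,
            )
            n_dropped += 1
            continue
        seq = str(chrom_seq[start:end]).upper()
        if set(seq) - _VALID:
            seq = "".join(c if c in _VALID else "N" for c in seq)
        if strand == "-":
            seq = _revcomp(seq)
        seen.add(gene_id)
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                window_start=start,
                window_end=end,
                sequence=seq,
            )
        )
    if n_dropped:
        logger.warning("dropped %d genes with out-of-bounds windows", n_dropped)
    return PromoterSet(records)
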