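"""Tandem poly(A)-site tables and cleavage-site position files.

This module defines the two on-disk formats the toolkit consumes and the
in-memory records everything downstream operates on:

* the *tandem table* — one row per gene, listing the gene's ordered tandem
  poly(A) sites as three parallel, semicolon-separated vectors: 3'-UTR
  lengths (nt from the stop codon to each cleavage site) and the
  supporting-read counts observed in each of the two samples;
* the *cleavage-site file* — a BED6+1 file of per-position cleavage read
  counts (score column = sample-1 count, seventh column = sample-2 count)
  prior to clustering into poly(A) sites.

Coordinates in cleavage files follow the BED convention (0-based,
half-open); 3'-UTR lengths are 1-based distances in nt from the stop codon,
so for minus-strand genes the distance is measured in transcript
orientation. The reader accepts precomputed lengths; strand arithmetic is
never performed here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("apaswitch")

_VALID_STRANDS = ("+", "-", "unknown")

TANDEM_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "utr_lengths",
    "counts_sample1",
    "counts_sample2",
)


class TandemTableError(ValueError):
    """Malformed tandem table or cleavage file content."""


@dataclass(frozen=True)
class TandemGene:
    """One gene's ordered tandem poly(A) sites with two-sample read counts.

    Sites are ordered proximal to distal, i.e. ``utr_lengths`` is strictly
    increasing. ``counts_sample1[j]`` / ``counts_sample2[j]`` are the
    supporting reads for site *j* in each sample. A gene is *testable* when
    it retains at least two sites and at least one supporting read; site
    filtering may leave fewer sites, in which case the gene is carried along
    but excluded from testing.
    """

    gene_id: str
    utr_lengths: tuple[int, ...]
    counts_sample1: tuple[int, ...]
    counts_sample2: tuple[int, ...]
    chrom: str | None = None
    strand: str = "unknown"
    site_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "utr_lengths", tuple(int(x) for x in self.utr_lengths))
        object.__setattr__(self, "counts_sample1", tuple(int(x) for x in self.counts_sample1))
        object.__setattr__(self, "counts_sample2", tuple(int(x) for x in self.counts_sample2))
        if self.site_positions is not None:
            object.__setattr__(self, "site_positions", tuple(int(x) for x in self.site_positions))
        if not self.gene_id:
            raise TandemTableError("gene_id must be non-empty")
        if self.strand not in _VALID_STRANDS:
            raise TandemTableError(
                f"{self.gene_id}: strand must be one of {_VALID_STRANDS}, got {self.strand!r}"
            )
        k = len(self.utr_lengths)
        if len(self.counts_sample1) != k or len(self.counts_sample2) != k:
            raise TandemTableError(
                f"{self.gene_id}: lengths and per-sample counts must be parallel vectors"
            )
        if self.site_positions is not None and len(self.site_positions) != k:
            raise TandemTableError(f"{self.gene_id}: site_positions length mismatch")
        if any(l <= 0 for l in self.utr_lengths):
            raise TandemTableError(f"{self.gene_id}: 3'-UTR lengths must be positive")
        if any(b <= a for a, b in zip(self.utr_lengths, self.utr_lengths[1:])):
            raise TandemTableError(
                f"{self.gene_id}: utr_lengths must be strictly increasing (proximal to distal)"
            )
        if any(c < 0 for c in self.counts_sample1 + self.counts_sample2):
            raise TandemTableError(f"{self.gene_id}: read counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.utr_lengths)

    @property
    def total_sample1(self) -> int:
        return sum(self.counts_sample1)

    @property
    def total_sample2(self) -> int:
        return sum(self.counts_sample2)

    @property
    def grand_total(self) -> int:
        return self.total_sample1 + self.total_sample2

    @property
    def is_testable(self) -> bool:
        """A gene enters testing only with >= 2 sites and > 0 total reads."""
        return self.n_sites >= 2 and self.grand_total > 0

    @classmethod
    def from_unsorted(
        cls,
        gene_id: str,
        utr_lengths: Sequence[int],
        counts_sample1: Sequence[int],
        counts_sample2: Sequence[int],
        **kwargs,
    ) -> "TandemGene":
        """Build a gene from possibly unordered sites, preserving the
        pairing of each length with its two counts while sorting."""
        positions = kwargs.pop("site_positions", None)
        rows = list(zip(utr_lengths, counts_sample1, counts_sample2,
                        positions if positions is not None else [None] * len(utr_lengths)))
        rows.sort(key=lambda t: t[0])
        ls, c1, c2, pos = zip(*rows) if rows else ((), (), (), ())
        return cls(
            gene_id,
            ls,
            c1,
            c2,
            site_positions=None if positions is None else pos,
            **kwargs,
        )


@dataclass(frozen=True)
class CleavageSiteRecord:
    """A single cleavage position (0-based) with per-sample read counts."""

    chrom: str
    position: int
    strand: str
    count_sample1: int
    count_sample2: int
    name: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise TandemTableError(f"negative position {self.position} on {self.chrom}")
        if self.strand not in ("+", "-"):
            raise TandemTableError(f"unknown strand {self.strand!r} at {self.chrom}:{self.position}")
        if self.count_sample1 < 0 or self.count_sample2 < 0:
            raise TandemTableError(f"negative count at {self.chrom}:{self.position}")


# ---------------------------------------------------------------------------
# tandem table
# ---------------------------------------------------------------------------

def _parse_int_vector(text: str, what: str, line_no: int) -> tuple[int, ...]:
    parts = [p for p in text.strip().split(";") if p != ""]
    out = []
    for p in parts:
        try:
            out.append(int(p))
        except ValueError as exc:
            raise TandemTableError(
                f"line {line_no}: non-numeric {what} entry {p!r}"
            ) from exc
    return tuple(out)


def read_tandem_table(path: str | Path, sep: str = "\t") -> list[TandemGene]:
    """Read a tandem table into a list of :class:`TandemGene`.

    The file is ``sep``-delimited with a header row naming at least the
    columns ``gene_id, chrom, strand, utr_lengths, counts_sample1,
    counts_sample2`` (``site_positions`` optional); the three vector columns
    hold semicolon-separated integers. Sites are returned sorted by
    3'-UTR length regardless of file order (a warning is logged if sorting
    was needed). Files carrying additional ``counts_sample*`` columns are
    rejected: the statistics implemented here are strictly two-sample.
    """
    path = Path(path)
    genes: list[TandemGene] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise TandemTableError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        extra_samples = [h for h in header if h.startswith("counts_sample") and h not in
                         ("counts_sample1", "counts_sample2")]
        if extra_samples:
            raise TandemTableError(
                f"{path}: found {extra_samples}; only two samples are supported "
                "(run pairwise comparisons separately)"
            )
        missing = [c for c in TANDEM_COLUMNS if c not in header]
        if missing:
            raise TandemTableError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < len(TANDEM_COLUMNS):
                raise TandemTableError(f"{path}: line {line_no}: expected >= "
                                       f"{len(TANDEM_COLUMNS)} fields, got {len(row)}")
            gene_id = row[idx["gene_id"]].strip()
            if not gene_id:
                raise TandemTableError(f"{path}: line {line_no}: empty gene_id")
            if gene_id in seen:
                raise TandemTableError(f"{path}: line {line_no}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            lengths = _parse_int_vector(row[idx["utr_lengths"]], "utr_lengths", line_no)
            c1 = _parse_int_vector(row[idx["counts_sample1"]], "counts_sample1", line_no)
            c2 = _parse_int_vector(row[idx["counts_sample2"]], "counts_sample2", line_no)
            if not lengths:
                raise TandemTableError(f"{path}: line {line_no}: gene {gene_id!r} has no sites")
            if not (len(lengths) == len(c1) == len(c2)):
                raise TandemTableError(
                    f"{path}: line {line_no}: vector lengths differ "
                    f"({len(lengths)} lengths, {len(c1)}/{len(c2)} counts)"
                )
            positions = None
            if "site_positions" in idx and len(row) > idx["site_positions"]:
                raw = row[idx["site_positions"]].strip()
                if raw:
                    positions = _parse_int_vector(raw, "site_positions", line_no)
            chrom = row[idx["chrom"]].strip() or None
            strand = row[idx["strand"]].strip() or "unknown"
            if list(lengths) != sorted(lengths):
                logger.warning(
                    "%s: line %d: sites for %s not sorted by 3'-UTR length; sorting",
                    path, line_no, gene_id,
                )
                genes.append(TandemGene.from_unsorted(
                    gene_id, lengths, c1, c2, chrom=chrom, strand=strand,
                    site_positions=positions,
                ))
            else:
                genes.append(TandemGene(
                    gene_id, lengths, c1, c2, chrom=chrom, strand=strand,
                    site_positions=positions,
                ))
    return genes


def write_tandem_table(genes: Iterable[TandemGene], path: str | Path, sep: str = "\t") -> None:
    """Write genes as a tandem table, rows sorted by gene_id (deterministic:
    write-read-write produces byte-identical files)."""
    path = Path(path)
    genes = sorted(genes, key=lambda g: g.gene_id)
    has_positions = any(g.site_positions is not None for g in genes)
    columns = list(TANDEM_COLUMNS) + (["site_positions"] if has_positions else [])
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(columns)
        for g in genes:
            row = [
                g.gene_id,
                g.chrom or "",
                g.strand,
                ";".join(str(x) for x in g.utr_lengths),
                ";".join(str(x) for x in g.counts_sample1),
                ";".join(str(x) for x in g.counts_sample2),
            ]
            if has_positions:
                row.append("" if g.site_positions is None
                           else ";".join(str(x) for x in g.site_positions))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# cleavage-site BED6+1
# ---------------------------------------------------------------------------

def read_cleavage_bed(path: str | Path) -> list[CleavageSiteRecord]:
    """Read per-position cleavage counts from a BED6+1 file.

    Columns: chrom, start, end, name, score (= sample-1 count), strand,
    sample-2 count. Coordinates are BED 0-based half-open; the record's
    position is the start. Duplicate (chrom, position, strand) entries are
    an error.
    """
    path = Path(path)
    records: list[CleavageSiteRecord] = []
    seen: set[tuple[str, int, str]] = set()
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise TandemTableError(
                    f"{path}: line {line_no}: expected BED6+1 (7 fields), got {len(fields)}"
                )
            chrom, start, end, name, score, strand, extra = fields[:7]
            try:
                pos, end_i, c1, c2 = int(start), int(end), int(score), int(extra)
            except ValueError as exc:
                raise TandemTableError(f"{path}: line {line_no}: non-numeric field") from exc
            if pos < 0:
                raise TandemTableError(f"{path}: line {line_no}: negative position {pos}")
            if end_i != pos + 1:
                raise TandemTableError(
                    f"{path}: line {line_no}: cleavage records are single positions "
                    f"(end must equal start+1)"
                )
            if strand not in ("+", "-"):
                raise TandemTableError(f"{path}: line {line_no}: unknown strand {strand!r}")
            key = (chrom, pos, strand)
            if key in seen:
                raise TandemTableError(
                    f"{path}: line {line_no}: duplicate record for {chrom}:{pos}({strand})"
                )
            seen.add(key)
            records.append(CleavageSiteRecord(chrom, pos, strand, c1, c2, name=name))
    return records


def write_cleavage_bed(records: Iterable[CleavageSiteRecord], path: str | Path) -> None:
    """Write cleavage records as BED6+1, sorted by (chrom, position, strand)."""
    path = Path(path)
    records = sorted(records, key=lambda r: (r.chrom, r.position, r.strand))
    with path.open("w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.name}\t"
                f"{r.count_sample1}\t{r.strand}\t{r.count_sample2}\n"
            )
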