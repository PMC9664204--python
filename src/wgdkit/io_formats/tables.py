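"""Gene coordinate tables (BED-like TSV and a GFF3 subset).

Internal coordinates are 0-based half-open.  GFF3 rows (1-based closed)
are converted on read with ``start - 1`` and back on write; the mapping is
an exact bijection on integers.  Strand is carried but never consulted by
any algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List

VALID_STRANDS = {"+", "-", "."}
VALID_STATUS = {"coding", "pseudogene"}

BED_COLUMNS = ["chromosome", "start", "end", "gene_id", "family_id", "strand", "status"]


class ValidationError(ValueError):
    """Input failed validation; message lists the offending rows."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    family_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    status: str = "coding"

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.status not in VALID_STATUS:
            raise ValidationError(f"gene {self.gene_id!r}: bad status {self.status!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


class GeneTable:
    """Per-species gene records kept sorted by (chromosome, start)."""

    def __init__(self, species: str, records: Iterable[GeneRecord] = ()):
        self.species = species
        self._records: List[GeneRecord] = []
        self._by_id: Dict[str, GeneRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: GeneRecord) -> None:
        if record.gene_id in self._by_id:
            raise ValidationError(
                f"duplicate gene_id {record.gene_id!r} in table for {self.species}"
            )
        self._by_id[record.gene_id] = record
        # insertion keeping sort order; tables are built mostly in order
        key = (record.chromosome, record.start, record.end)
        lo, hi = 0, len(self._records)
        while lo < hi:
            mid = (lo + hi) // 2
            r = self._records[mid]
            if (r.chromosome, r.start, r.end) <= key:
                lo = mid + 1
            else:
                hi = mid
        self._records.insert(lo, record)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"no gene {gene_id!r} in table for {self.species}") from None

    def chromosomes(self) -> List[str]:
        seen = dict.fromkeys(r.chromosome for r in self._records)
        return list(seen)

    def on_chromosome(self, chromosome: str) -> List[GeneRecord]:
        return [r for r in self._records if r.chromosome == chromosome]

    def families(self) -> Dict[str, List[GeneRecord]]:
        fams: Dict[str, List[GeneRecord]] = {}
        for r in self._records:
            fams.setdefault(r.family_id, []).append(r)
        return fams


def _parse_int(token: str, what: str, row: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValidationError(f"row {row}: non-integer {what} {token!r}") from None


def read_gene_table(path, species: str, dialect: str = "bed_like_tsv") -> GeneTable:
    """Read a gene table; ``dialect`` is ``bed_like_tsv`` or ``gff3_subset``.

    BED-like columns: chromosome, start, end, gene_id, family_id, strand,
    status.  GFF3 rows use attributes ``ID=`` and ``family=`` and 1-based
    closed coordinates, converted to 0-based half-open on read.
    """
    if dialect not in {"bed_like_tsv", "gff3_subset"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    errors: List[str] = []
    records: List[GeneRecord] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed_like_tsv":
                    if len(fields) != 7:
                        raise ValidationError(
                            f"row {row_no}: expected 7 columns, got {len(fields)}"
                        )
                    chrom, start_s, end_s, gene_id, family_id, strand, status = fields
                    start = _parse_int(start_s, "start", row_no)
                    end = _parse_int(end_s, "end", row_no)
                else:
                    if len(fields) != 9:
                        raise ValidationError(
                            f"row {row_no}: expected 9 GFF3 columns, got {len(fields)}"
                        )
                    chrom = fields[0]
                    start = _parse_int(fields[3], "start", row_no) - 1
                    end = _parse_int(fields[4], "end", row_no)
                    strand = fields[6] if fields[6] in VALID_STRANDS else "."
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    if "ID" not in attrs:
                        raise ValidationError(f"row {row_no}: missing ID attribute")
                    gene_id = attrs["ID"]
                    family_id = attrs.get("family", gene_id)
                    status = attrs.get("status", "coding")
                records.append(
                    GeneRecord(
                        gene_id=gene_id,
                        species=species,
                        family_id=family_id,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        status=status,
                    )
                )
            except ValidationError as exc:
                msg = str(exc)
                errors.append(msg if msg.startswith("row") else f"row {row_no}: {msg}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    table = GeneTable(species)
    for rec in records:
        try:
            table.add(rec)
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return table


def write_gene_table(table: GeneTable, path, dialect: str = "bed_like_tsv") -> None:
    with open(path, "w") as fh:
        if dialect == "bed_like_tsv":
            for r in table:
                fh.write(
                    f"{r.chromosome}\t{r.start}\t{r.end}\t{r.gene_id}\t"
                    f"{r.family_id}\t{r.strand}\t{r.status}\n"
                )
        elif dialect == "gff3_subset":
            fh.write("##gff-version 3\n")
            for r in table:
                attrs = f"ID={r.gene_id};family={r.family_id};status={r.status}"
                fh.write(
                    f"{r.chromosome}\twgdkit\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
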