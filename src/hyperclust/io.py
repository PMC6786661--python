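"""Mutation catalogs and genome access.

Coordinate conventions used throughout the package:

* positions are 1-based and fully closed, on the forward (top/Watson) strand;
* ref/alt alleles are reported on the top strand, so "mutated C" means
  ``ref == "C"`` and "mutated G" means ``ref == "G"``;
* only single-nucleotide substitutions (SNVs) are admitted — multi-nucleotide
  and indel records are dropped with a logged count.

Catalogs are lists of :class:`MutationRecord`; genomes are wrapped in a
:class:`GenomeModel` that knows chromosome lengths, ploidy and how to fetch
sequence. Ploidy only scales ``total_bases`` (the denominator of the
genome-wide mutation probability pi); calls themselves are unphased.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: Default column names for MAF-like tab-delimited catalogs.
MAF_COLUMNS = {
    "sample_id": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}

#: Column order of the canonical per-sample TSV all modules consume.
CANONICAL_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic SNV on the top strand (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"non-SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


class GenomeModel:
    """Chromosome names/lengths, ploidy and bounds-checked sequence access.

    ``total_bases = ploidy * sum(chrom_lengths)`` is the denominator of the
    per-sample mutation probability pi used by the cluster statistic.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        sequence_access: Callable[[str, int, int], str] | None = None,
        ploidy: int = 1,
    ):
        if ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not chrom_lengths:
            raise ValueError("genome has no chromosomes")
        self.chrom_names: list[str] = list(chrom_lengths)
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self.ploidy = int(ploidy)
        self._fetch = sequence_access

    @classmethod
    def from_fasta(cls, path: str | Path, ploidy: int = 1) -> "GenomeModel":
        """Open an (indexed) FASTA; the .fai index is built if missing."""
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        lengths = {name: len(fasta[name]) for name in fasta.keys()}
        if not lengths:
            raise ValueError(f"empty FASTA: {path}")

        def fetch(chrom: str, start: int, end: int) -> str:
            return str(fasta[chrom][start - 1 : end])

        model = cls(lengths, fetch, ploidy)
        model._fasta = fasta  # keep handle alive
        return model

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str], ploidy: int = 1) -> "GenomeModel":
        """Build an in-memory genome from ``{chrom: sequence}``."""
        seqs = {name: seq.upper() for name, seq in sequences.items()}
        lengths = {name: len(seq) for name, seq in seqs.items()}

        def fetch(chrom: str, start: int, end: int) -> str:
            return seqs[chrom][start - 1 : end]

        return cls(lengths, fetch, ploidy)

    @property
    def total_bases(self) -> int:
        return self.ploidy * sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``chrom:start-end`` (1-based, closed)."""
        if self._fetch is None:
            raise ValueError("genome model has no sequence access")
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > self.chrom_lengths[chrom] or start > end:
            raise ValueError(f"{chrom}:{start}-{end} out of bounds (length {self.chrom_lengths[chrom]})")
        return self._fetch(chrom, start, end).upper()

    def window(self, chrom: str, center: int, flank: int) -> tuple[str, int]:
        """Sequence of ``center +/- flank`` truncated at chromosome ends.

        Returns ``(sequence, offset)`` where ``offset`` is the 0-based index
        of ``center`` within the returned string.
        """
        start = max(1, center - flank)
        end = min(self.chrom_lengths[chrom], center + flank)
        return self.sequence(chrom, start, end), center - start

    def chrom_rank(self, chrom: str) -> int:
        return self.chrom_names.index(chrom)


def _sort_records(records: Iterable[MutationRecord], genome: GenomeModel | None) -> list[MutationRecord]:
    if genome is not None:
        key = lambda r: (r.sample_id, genome.chrom_rank(r.chrom), r.pos)
    else:
        key = lambda r: (r.sample_id, r.chrom, r.pos)
    return sorted(records, key=key)


def _check_bounds(records: list[MutationRecord], genome: GenomeModel | None) -> None:
    if genome is None:
        return
    for rec in records:
        if rec.chrom not in genome:
            raise ValueError(f"record {rec.chrom}:{rec.pos} on chromosome absent from genome model")
        if rec.pos > genome.chrom_lengths[rec.chrom]:
            raise ValueError(
                f"position {rec.chrom}:{rec.pos} beyond chromosome end ({genome.chrom_lengths[rec.chrom]})"
            )


def _dedupe(records: list[MutationRecord], on_duplicate: str) -> list[MutationRecord]:
    seen: set[tuple[str, str, int]] = set()
    out: list[MutationRecord] = []
    for rec in records:
        site = (rec.sample_id, rec.chrom, rec.pos)
        if site in seen:
            if on_duplicate == "error":
                raise ValueError(f"duplicate site {rec.chrom}:{rec.pos} in sample {rec.sample_id}")
            logger.info("dropping duplicate site %s:%d (sample %s)", rec.chrom, rec.pos, rec.sample_id)
            continue
        seen.add(site)
        out.append(rec)
    return out


def load_mutations(
    path: str | Path,
    format: str | None = None,
    genome: GenomeModel | None = None,
    sample_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    on_duplicate: str = "error",
) -> list[MutationRecord]:
    """Read a mutation catalog from VCF or a MAF-like TSV.

    Non-SNV rows (indels, MNVs) are dropped and counted; multi-allelic VCF
    rows are split per ALT. Records are returned sorted by
    (sample, chrom, pos). ``on_duplicate`` is ``"error"`` or ``"dedup"``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz") else "maf_tsv"
    if format == "vcf":
        records, dropped = _load_vcf(path, sample_id)
    elif format == "maf_tsv":
        records, dropped = _load_maf(path, sample_id, column_map)
    else:
        raise ValueError(f"unknown catalog format {format!r}")
    if dropped:
        logger.info("%s: dropped %d non-SNV record(s)", path.name, dropped)
    _check_bounds(records, genome)
    return _dedupe(_sort_records(records, genome), on_duplicate)


def _load_vcf(path: Path, sample_id: str | None) -> tuple[list[MutationRecord], int]:
    import pysam

    default_sample = sample_id or path.name.split(".")[0]
    records: list[MutationRecord] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            ref = (row.ref or "").upper()
            for alt in row.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    dropped += 1
                    continue
                records.append(MutationRecord(default_sample, row.chrom, row.pos, ref, alt))
    return records, dropped


def _load_maf(
    path: Path, sample_id: str | None, column_map: Mapping[str, str] | None
) -> tuple[list[MutationRecord], int]:
    cols = dict(MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    # canonical TSVs are accepted transparently
    if set(CANONICAL_COLUMNS).issubset(table.columns):
        cols = {k: k for k in CANONICAL_COLUMNS}
    missing = [c for k, c in cols.items() if c not in table.columns and k != "sample_id"]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    have_sample_col = cols["sample_id"] in table.columns
    records: list[MutationRecord] = []
    dropped = 0
    for i, row in enumerate(table.itertuples(index=False), start=2):
        row = dict(zip(table.columns, row))
        ref = str(row[cols["ref"]]).upper()
        alt = str(row[cols["alt"]]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            dropped += 1
            continue
        sid = str(row[cols["sample_id"]]) if have_sample_col else (sample_id or path.name.split(".")[0])
        try:
            records.append(MutationRecord(sid, str(row[cols["chrom"]]), int(row[cols["pos"]]), ref, alt))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records, dropped


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt) for r in records],
        columns=CANONICAL_COLUMNS,
    )


def write_catalog(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write the canonical per-sample TSV (sample_id, chrom, pos, ref, alt)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def write_vcf(records: Sequence[MutationRecord], genome: GenomeModel, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with contig headers from the genome model."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.chrom_names:
            fh.write(f"##contig=<ID={name},length={genome.chrom_lengths[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = _sort_records(records, genome)
        for r in ordered:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\tSAMPLE={r.sample_id}\n")


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based, closed) into a tuple."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r} (expected chrom:start-end)")
    chrom, start, end = m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    if start > end:
        raise ValueError(f"region start > end in {text!r}")
    return chrom, start, end
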