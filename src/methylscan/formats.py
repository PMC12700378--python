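"""Readers and writers for the files the pipeline touches.

Reference FASTA, bedMethyl pileups in the modkit dialect, GFF3/BED gene
annotations and TSV result tables with ``#``-prefixed metadata headers.

Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based, inclusive) is converted on read.  Methylation frequencies are
fractions in [0, 1] internally and rendered as percent only in report
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GenomeSequence",
    "SiteRecord",
    "GeneFeature",
    "read_fasta",
    "read_bedmethyl",
    "write_bedmethyl",
    "filter_sites",
    "read_genes",
    "write_gff3",
    "write_tsv",
    "read_tsv",
    "reverse_complement",
]

VALID_ALPHABET = frozenset("ACGTN")

#: modkit single-letter modification codes handled by the pipeline.  Rows
#: with any other code (e.g. "h" for 5hmC) are skipped, not errored: real
#: pileups routinely contain extra codes.
MOD_CODES = {"a": "6mA", "m": "5mC"}
MOD_LETTERS = {v: k for k, v in MOD_CODES.items()}

#: reference base that must underlie a call of each modification type.
MOD_BASE = {"6mA": "A", "5mC": "C"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """An input file violates its dialect or an internal invariant."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a plain A/C/G/T/N sequence."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig; upper-cased, restricted to A/C/G/T/N."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.contig_id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int, strand: str = "+") -> str:
        """Strand-aware base: the minus strand reads the complement."""
        if not 0 <= position < len(self.sequence):
            raise FormatError(
                f"position {position} outside contig {self.contig_id!r} "
                f"(length {len(self.sequence)})"
            )
        base = self.sequence[position]
        return base if strand == "+" else base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class SiteRecord:
    """One bedMethyl row: a genomic base on a strand with mod counts."""

    contig: str
    position: int
    strand: str
    mod_code: str
    valid_coverage: int
    n_mod: int
    n_canonical: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"bad strand {self.strand!r}")
        if self.mod_code not in MOD_BASE:
            raise FormatError(f"unknown modification code {self.mod_code!r}")
        if min(self.valid_coverage, self.n_mod, self.n_canonical) < 0:
            raise FormatError("negative count in site record")
        if self.n_mod + self.n_canonical > self.valid_coverage:
            raise FormatError(
                f"{self.contig}:{self.position}{self.strand}: "
                f"n_mod + n_canonical ({self.n_mod}+{self.n_canonical}) "
                f"exceeds valid coverage {self.valid_coverage}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.strand, self.mod_code)

    @property
    def frequency(self) -> float:
        """n_mod / valid_coverage; a zero-coverage site has no frequency."""
        if self.valid_coverage == 0:
            raise FormatError(
                f"{self.contig}:{self.position}{self.strand}: zero coverage"
            )
        return self.n_mod / self.valid_coverage


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval, 0-based half-open, with a stable identifier."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"gene {self.gene_id!r}: start >= end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    Raises :class:`FormatError` on an empty file, duplicate contig ids or
    characters outside A/C/G/T/N.  Record order is preserved and sequences
    are upper-cased.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(genomes: Sequence[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for g in genomes:
            handle.write(f">{g.contig_id}\n")
            for i in range(0, len(g.sequence), width):
                handle.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedMethyl (modkit pileup dialect)

# modkit pileup columns (tab separated):
#   0 contig, 1 start, 2 end (= start+1), 3 mod code, 4 score, 5 strand,
#   6-8 thickStart/thickEnd/color, 9 valid coverage, 10 percent modified,
#   11 n_mod, 12 n_canonical, 13.. other counts (ignored).


def read_bedmethyl(
    path: str | Path, min_coverage: int = 0
) -> list[SiteRecord]:
    """Parse a modkit-pileup bedMethyl table.

    Rows whose modification code is not 6mA ("a") or 5mC ("m") are skipped
    and counted (logged); malformed rows raise :class:`FormatError` with
    their line number.  ``min_coverage`` drops rows below that coverage.
    """
    records: list[SiteRecord] = []
    skipped_codes = 0
    low_coverage = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise FormatError(
                    f"{path}:{lineno}: expected >=13 tab-separated columns, "
                    f"got {len(fields)}"
                )
            code = fields[3]
            if code not in MOD_CODES:
                skipped_codes += 1
                continue
            try:
                start = int(fields[1])
                end = int(fields[2])
                coverage = int(fields[9])
                n_mod = int(fields[11])
                n_canonical = int(fields[12])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count ({exc})") from exc
            if end != start + 1:
                raise FormatError(
                    f"{path}:{lineno}: end != start + 1 ({start}, {end})"
                )
            try:
                record = SiteRecord(
                    contig=fields[0],
                    position=start,
                    strand=fields[5],
                    mod_code=MOD_CODES[code],
                    valid_coverage=coverage,
                    n_mod=n_mod,
                    n_canonical=n_canonical,
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if coverage < min_coverage:
                low_coverage += 1
                continue
            records.append(record)
    if skipped_codes:
        logger.info(
            "%s: skipped %d rows with unhandled modification codes", path, skipped_codes
        )
    if low_coverage:
        logger.info(
            "%s: dropped %d rows below coverage %d", path, low_coverage, min_coverage
        )
    return records


def write_bedmethyl(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write records in the modkit pileup dialect (18 columns)."""
    with open(path, "w") as handle:
        for rec in records:
            pct = 100.0 * rec.n_mod / rec.valid_coverage if rec.valid_coverage else 0.0
            other = rec.valid_coverage - rec.n_mod - rec.n_canonical
            fields = [
                rec.contig,
                str(rec.position),
                str(rec.position + 1),
                MOD_LETTERS[rec.mod_code],
                str(rec.valid_coverage),
                rec.strand,
                str(rec.position),
                str(rec.position + 1),
                "255,0,0",
                str(rec.valid_coverage),
                f"{pct:.2f}",
                str(rec.n_mod),
                str(rec.n_canonical),
                str(other),
                "0",
                "0",
                "0",
                "0",
            ]
            handle.write("\t".join(fields) + "\n")


GenomeLike = Union[GenomeSequence, Mapping[str, GenomeSequence]]


def _as_contig_map(genome: GenomeLike) -> Mapping[str, GenomeSequence]:
    if isinstance(genome, GenomeSequence):
        return {genome.contig_id: genome}
    return genome


def filter_sites(records: Sequence[SiteRecord], genome: GenomeLike) -> list[SiteRecord]:
    """Keep records whose strand-aware reference base matches the mod type.

    A 6mA record survives only if the base read 5'->3' on its own strand is
    A (plus-strand A for "+", plus-strand T for "-"); 5mC analogously for C.
    N bases never yield retained sites.  Positions beyond the contig raise
    :class:`FormatError`.
    """
    contigs = _as_contig_map(genome)
    kept: list[SiteRecord] = []
    dropped = 0
    for rec in records:
        if rec.contig not in contigs:
            raise FormatError(f"record on unknown contig {rec.contig!r}")
        base = contigs[rec.contig].base_at(rec.position, rec.strand)
        if base == MOD_BASE[rec.mod_code]:
            kept.append(rec)
        else:
            dropped += 1
    if dropped:
        logger.info("filter_sites: dropped %d records off the target base", dropped)
    return kept


# ---------------------------------------------------------------------------
# gene annotations


def read_genes(path: str | Path) -> list[GeneFeature]:
    """Read gene intervals from GFF3 (``.gff``/``.gff3``) or BED.

    GFF3 coordinates are converted to 0-based half-open.  ``gene`` features
    are preferred; if absent, ``CDS`` features are used.  gene_ids must be
    unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _read_gff3(path)
    else:
        genes = _read_bed(path)
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise FormatError(f"duplicate gene ids in {path}")
    if not genes:
        raise FormatError(f"no gene features in {path}")
    return genes


def _read_gff3(path: Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feature_types = set(db.featuretypes())
    wanted = "gene" if "gene" in feature_types else "CDS"
    genes = []
    for feat in db.features_of_type(wanted, order_by=("seqid", "start")):
        attrs = feat.attributes
        gene_id = (
            attrs.get("ID", [None])[0]
            or attrs.get("Name", [None])[0]
            or attrs.get("locus_tag", [None])[0]
            or f"{wanted}_{feat.seqid}_{feat.start}"
        )
        annotation = (attrs.get("product") or attrs.get("annotation") or [None])[0]
        genes.append(
            GeneFeature(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                gene_id=gene_id,
                annotation=annotation,
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneFeature]:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 4:
        raise FormatError(f"{path}: BED gene input needs >=4 columns")
    genes = []
    for row in frame.itertuples(index=False):
        strand = row[5] if frame.shape[1] >= 6 else "+"
        annotation = str(row[6]) if frame.shape[1] >= 7 else None
        genes.append(
            GeneFeature(
                contig=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=str(strand),
                gene_id=str(row[3]),
                annotation=annotation,
            )
        )
    return genes


def write_gff3(
    genes: Sequence[GeneFeature],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    source: str = "methylscan",
) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                handle.write(f"##sequence-region {contig} 1 {length}\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id}"
            if gene.annotation:
                attrs += f";annotation={gene.annotation}"
            handle.write(
                "\t".join(
                    [
                        gene.contig,
                        source,
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV result tables


def write_tsv(
    frame: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a result table with ``#key=value`` metadata lines, then header."""
    with open(path, "w") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"#{key}={value}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_tsv`, ignoring metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")
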