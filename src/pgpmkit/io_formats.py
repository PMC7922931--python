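"""File formats and packaged reference tables.

Sequence I/O (FASTA references, Phred+33 FASTQ reads, gzip-transparent) goes
through Biopython.  The module also ships machine-readable transcriptions of
the printed strain, compatibility, biostimulant-response and consortium
tables, together with an alias map that reconciles the several spellings the
same strain goes by across those tables (e.g. *Pichia* vs *Komagataella*
*pastoris* PP59, or the LS136/LS163 *Azotobacter chroococcum* codes).
"""

from __future__ import annotations

import gzip
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .consortium import CompatibilityMatrix, Consortium, Strain

__all__ = [
    "Genome",
    "Read",
    "SampleMeta",
    "PublishedTables",
    "FastaFormatError",
    "FastqFormatError",
    "UnknownStrainError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_hits_tsv",
    "write_hits_tsv",
    "load_published_tables",
]

logger = logging.getLogger(__name__)

#: subsampling cap on reads taken from the start of each FASTQ file
DEFAULT_MAX_READS = 10_000_000

HITS_COLUMNS = ["read_id", "genome_id", "start", "end", "strand", "matches", "align_len", "identity"]

ENVIRONMENTS = ("soil", "root", "rhizosphere")


class FastaFormatError(ValueError):
    pass


class FastqFormatError(ValueError):
    pass


class UnknownStrainError(KeyError):
    pass


@dataclass(frozen=True)
class Genome:
    """A reference genome: id, free-text description, upper-case sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleMeta:
    """One metagenome sample: its environment and total read count T."""

    sample_id: str
    environment: str
    total_reads: int

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"sample {self.sample_id!r}: environment must be one of "
                f"{ENVIRONMENTS}, got {self.environment!r}"
            )
        if self.total_reads <= 0:
            raise ValueError(f"sample {self.sample_id!r}: total_reads must be positive")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[Genome]:
    """Read a FASTA file into Genome records (sequences upper-cased).

    CRLF line endings and wrapped sequences are tolerated.  A file whose first
    non-blank line is not a header, or a record with no sequence, raises
    :class:`FastaFormatError` naming the offending line.
    """
    path = Path(path)
    with _open_text(path) as handle:
        lines = handle.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.lstrip().startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected FASTA header, got {line[:40]!r}"
                )
            break
    else:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    genomes = []
    header_lineno = {}
    lineno = 0
    for line in lines:
        lineno += 1
        if line.startswith(">"):
            header_lineno[len(header_lineno)] = lineno
    with _open_text(path) as handle:
        for i, record in enumerate(SeqIO.parse(handle, "fasta")):
            seq = str(record.seq).upper()
            if not seq:
                raise FastaFormatError(
                    f"{path}: line {header_lineno.get(i, '?')}: record "
                    f"{record.id!r} has no sequence"
                )
            genomes.append(Genome(id=record.id, sequence=seq, description=record.description))
    return genomes


def write_fasta(genomes, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=g.description or "")
        for g in genomes
    ]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_fastq(path, max_reads: int | None = DEFAULT_MAX_READS):
    """Yield at most ``max_reads`` reads, in file order from the start.

    Mirrors the subsampling rule used for the metagenome screens: only the
    first reads of each file (10 million by default) enter recruitment.
    Truncated records or sequence/quality length mismatches raise
    :class:`FastqFormatError`.
    """
    if max_reads is not None and max_reads <= 0:
        raise ValueError("max_reads must be positive")
    with _open_text(path) as handle:
        try:
            it = FastqGeneralIterator(handle)
            if max_reads is not None:
                it = itertools.islice(it, max_reads)
            for title, seq, qual in it:
                yield Read(id=title.split()[0], sequence=seq.upper(), quality=qual)
        except ValueError as exc:
            raise FastqFormatError(f"{path}: {exc}") from exc


def write_fastq(reads, path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read the sample metadata TSV (sample_id, environment, total_reads)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "environment", "total_reads"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = [
        SampleMeta(row.sample_id, row.environment, int(row.total_reads))
        for row in df.itertuples()
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return metas


def write_sample_metadata(metas, path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.environment, m.total_reads) for m in metas],
        columns=["sample_id", "environment", "total_reads"],
    ).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HITS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit columns {sorted(missing)}")
    return df


def write_hits_tsv(hits, path) -> None:
    """Write recruitment hits as TSV (0-based start, exclusive end)."""
    rows = [
        (h.read_id, h.genome_id, h.start, h.end, h.strand, h.matches, h.align_len,
         f"{h.identity:.4f}")
        for h in hits
    ]
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged table fixtures


@dataclass
class PublishedTables:
    """The printed tables, loaded, canonicalized and symmetric-closed."""

    strains: dict[str, Strain]
    alias_map: dict[str, str]
    compat: CompatibilityMatrix  # merged bacteria/yeast + fungal relations
    compat_bacteria: pd.DataFrame  # full symmetric square, canonical names
    compat_fungi: pd.DataFrame  # strains x 2 Trichoderma columns, canonical
    biostimulants: pd.DataFrame  # strains x BS1..BS4
    consortia: dict[str, Consortium]
    notes: list[str] = field(default_factory=list)

    def canonicalize(self, name: str) -> str:
        key = " ".join(name.split())
        try:
            return self.alias_map[key]
        except KeyError:
            raise UnknownStrainError(
                f"strain name {name!r} is neither canonical nor a known alias"
            ) from None


def _default_fixture_dir():
    return resources.files("pgpmkit").joinpath("data")


def _build_alias_map(strains: dict[str, Strain]) -> dict[str, str]:
    alias_map: dict[str, str] = {}
    for strain in strains.values():
        for name in {strain.canonical_name, *strain.aliases}:
            key = " ".join(name.split())
            if key in alias_map and alias_map[key] != strain.canonical_name:
                raise ValueError(
                    f"alias {key!r} maps to both {alias_map[key]!r} and "
                    f"{strain.canonical_name!r}"
                )
            alias_map[key] = strain.canonical_name
    return alias_map


def load_published_tables(fixture_dir=None) -> PublishedTables:
    """Load the packaged strain/compatibility/biostimulant/consortium tables.

    Strain names are canonicalized through the alias map built from the strain
    table; the lower-triangular bacterial matrix is symmetric-closed; the
    fungal two-column matrix is merged into the same
    :class:`~pgpmkit.consortium.CompatibilityMatrix`.  Unknown strain names and
    conflicting duplicate entries raise.
    """
    fdir = Path(fixture_dir) if fixture_dir is not None else _default_fixture_dir()

    strains_df = pd.read_csv(fdir / "strains.csv", keep_default_na=False)
    strains: dict[str, Strain] = {}
    for row in strains_df.itertuples():
        aliases = frozenset(a for a in str(row.aliases).split(";") if a)
        functions = frozenset(f for f in str(row.functions).split(";") if f)
        strain = Strain(
            canonical_name=row.canonical_name,
            aliases=aliases,
            kingdom=row.kingdom,
            functions=functions,
            selected=bool(int(row.selected)),
            notes=str(row.notes),
        )
        if strain.canonical_name in strains:
            raise ValueError(f"duplicate canonical name {strain.canonical_name!r}")
        strains[strain.canonical_name] = strain
    alias_map = _build_alias_map(strains)

    def canon(name: str) -> str:
        key = " ".join(str(name).split())
        if key not in alias_map:
            raise UnknownStrainError(
                f"strain name {name!r} is neither canonical nor a known alias"
            )
        return alias_map[key]

    # bacteria/yeast matrix: printed lower triangle -> symmetric closure
    bact_raw = pd.read_csv(fdir / "compat_bacteria.csv", index_col=0, keep_default_na=False)
    row_names = [canon(n) for n in bact_raw.index]
    col_names = [canon(n) for n in bact_raw.columns]
    if row_names != col_names:
        raise ValueError("bacterial compatibility table rows and columns disagree")
    matrix = CompatibilityMatrix()
    n = len(row_names)
    square = pd.DataFrame("", index=row_names, columns=row_names)
    for i in range(n):
        square.iloc[i, i] = "+"
        for j in range(n):
            value = str(bact_raw.iloc[i, j]).strip()
            if not value:
                continue
            if j >= i:
                raise ValueError(
                    f"bacterial matrix entry above the diagonal at "
                    f"({row_names[i]}, {col_names[j]})"
                )
            matrix.set(row_names[i], col_names[j], value)
            square.iloc[i, j] = value
            square.iloc[j, i] = value

    # fungal matrix: 23 strains x 2 Trichoderma columns
    fungi_raw = pd.read_csv(fdir / "compat_fungi.csv", index_col=0, keep_default_na=False)
    fungi_rows = [canon(n) for n in fungi_raw.index]
    fungi_cols = [canon(n) for n in fungi_raw.columns]
    fungi = pd.DataFrame(fungi_raw.values, index=fungi_rows, columns=fungi_cols)
    for strain_name in fungi.index:
        for trich in fungi.columns:
            matrix.set(strain_name, trich, str(fungi.loc[strain_name, trich]).strip())

    bios_raw = pd.read_csv(fdir / "biostimulants.csv", index_col=0, keep_default_na=False)
    bios = pd.DataFrame(
        bios_raw.values, index=[canon(n) for n in bios_raw.index], columns=bios_raw.columns
    )

    cons_df = pd.read_csv(fdir / "consortia.csv")
    consortia: dict[str, Consortium] = {}
    for name, group in cons_df.groupby("consortium", sort=True):
        members = tuple(canon(m) for m in group["member"])
        unresolved = [m for m in members if m not in strains]
        if unresolved:
            raise UnknownStrainError(f"consortium {name}: unresolved members {unresolved}")
        consortia[name] = Consortium(name=name, members=members)

    notes = [
        "LS136 (bacterial matrix) and LS163 (strain and fungal tables) are "
        "recorded as one A. chroococcum strain; the identification is "
        "plausible but not certain.",
        "The printed bacterial matrix duplicates the B. ambifaria LMG 11351 "
        "column; the duplicate agrees with the retained column everywhere.",
    ]
    return PublishedTables(
        strains=strains,
        alias_map=alias_map,
        compat=matrix,
        compat_bacteria=square,
        compat_fungi=fungi,
        biostimulants=bios,
        consortia=consortia,
        notes=notes,
    )
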