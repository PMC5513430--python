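"""Genome ingest/export and basic genometrics.

Genomes are annotated phage (or host) nucleotide records. Internally all
coordinates are 0-based half-open; GenBank I/O converts to and from the
1-based inclusive convention of the flat-file format. CDS translations are
taken verbatim from the ``/translation`` qualifier when present and otherwise
recomputed with the bacterial/archaeal genetic code (translation table 11).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Gene",
    "Genome",
    "GenomeIOError",
    "UndefinedMetricError",
    "read_genbank",
    "read_fasta",
    "write_genbank",
    "write_fasta",
    "gc_content",
    "genome_metrics_table",
]

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")
_NT_VALID = set("ACGTNRYSWKMBDHV")


class GenomeIOError(ValueError):
    """Malformed or unreadable genome record."""


class UndefinedMetricError(ValueError):
    """A metric is undefined for this input (e.g. %GC of an all-N sequence)."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene: 0-based half-open interval plus translation.

    ``compound_location`` flags CDS features whose GenBank location was a
    ``join(...)`` collapsed to its envelope.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    translation: str = ""
    function_label: str = ""
    compound_location: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        bad = set(self.translation) - _AA_LETTERS
        if bad:
            raise ValueError(f"gene {self.gene_id}: invalid amino acids {sorted(bad)}")


@dataclass
class Genome:
    """One nucleotide sequence with its ordered gene annotations."""

    id: str
    sequence: str
    name: str = ""
    accession: str = ""
    genes: list[Gene] = field(default_factory=list)
    source_format: str = "fasta"  # "genbank" or "fasta"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise GenomeIOError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - _NT_VALID
        if bad:
            raise GenomeIOError(f"genome {self.id}: invalid nucleotide characters {sorted(bad)}")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > len(self.sequence):
                raise GenomeIOError(
                    f"genome {self.id}: gene {g.gene_id} interval [{g.start}, {g.end}) "
                    f"exceeds sequence length {len(self.sequence)}"
                )
        if not self.name:
            self.name = self.id

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene: Gene) -> str:
        """Nucleotide span of a gene, reverse-complemented for '-' strand."""
        span = self.sequence[gene.start : gene.end]
        if gene.strand == "-":
            span = str(Seq(span).reverse_complement())
        return span


def _translate_cds(nt: str) -> str:
    """Translate a CDS span with code table 11, trailing stop removed."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(trimmed).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa.replace("*", "X").replace("J", "X").replace("B", "X").replace("Z", "X").replace("U", "X")


def _gene_from_feature(feature: SeqFeature, record: SeqRecord, index: int) -> Gene:
    loc = feature.location
    if loc is None:
        raise GenomeIOError(f"{record.id}: CDS feature #{index} has no location")
    compound = len(loc.parts) > 1
    start, end = int(loc.start), int(loc.end)
    if end > len(record.seq):
        raise GenomeIOError(
            f"{record.id}: CDS feature #{index} [{start}, {end}) extends past sequence "
            f"end ({len(record.seq)} bp); record rejected"
        )
    strand = "-" if loc.strand == -1 else "+"
    gene_id = feature.qualifiers.get("locus_tag", feature.qualifiers.get("gene", [f"{record.id}_CDS_{index}"]))[0]
    translation = feature.qualifiers.get("translation", [""])[0].upper()
    if not translation:
        span = str(record.seq[start:end]).upper()
        if strand == "-":
            span = str(Seq(span).reverse_complement())
        translation = _translate_cds(span)
    function_label = feature.qualifiers.get("product", [""])[0]
    return Gene(
        gene_id=gene_id,
        start=start,
        end=end,
        strand=strand,
        translation=translation,
        function_label=function_label,
        compound_location=compound,
    )


def read_genbank(path: str | Path) -> Genome:
    """Read a single-record GenBank flat file into a :class:`Genome`.

    Every CDS feature becomes one :class:`Gene`; compound ``join(...)``
    locations are collapsed to their envelope and flagged.
    """
    path = Path(path)
    text = path.read_text()
    if "ORIGIN" not in text:
        raise GenomeIOError(f"{path}: no ORIGIN block; not a sequence-bearing GenBank record")
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise GenomeIOError(f"{path}: expected exactly 1 GenBank record, found {len(records)}")
    record = records[0]
    if len(record.seq) == 0:
        raise GenomeIOError(f"{path}: record {record.id} has an empty sequence")
    genes = [
        _gene_from_feature(f, record, i)
        for i, f in enumerate(record.features)
        if f.type == "CDS"
    ]
    accession = record.annotations.get("accessions", [""])[0] if record.annotations.get("accessions") else ""
    name = record.annotations.get("source", "") or record.name or record.id
    return Genome(
        id=record.id,
        sequence=str(record.seq),
        name=record.name or record.id,
        accession=accession or record.id.split(".")[0],
        genes=genes,
        source_format="genbank",
    )


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (multi-)FASTA of nucleotide sequences; lowercase is uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeIOError(f"{path}: empty FASTA file")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise GenomeIOError(f"{path}: duplicate record ids {sorted(dupes)}")
    return [
        Genome(id=r.id, sequence=str(r.seq).upper(), name=r.description or r.id, source_format="fasta")
        for r in records
    ]


def _to_seqrecord(genome: Genome) -> SeqRecord:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=re.sub(r"[^A-Za-z0-9_.-]", "_", genome.name)[:16] or genome.id[:16],
        description=genome.name,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "linear"
    record.annotations["data_file_division"] = "PHG"
    # fixed date keeps serialization byte-identical across runs
    record.annotations["date"] = "01-JAN-1980"
    if genome.accession:
        record.annotations["accessions"] = [genome.accession]
    for gene in genome.genes:
        loc = FeatureLocation(gene.start, gene.end, strand=-1 if gene.strand == "-" else 1)
        qualifiers: dict[str, list[str]] = {"locus_tag": [gene.gene_id]}
        if gene.translation:
            qualifiers["translation"] = [gene.translation]
        if gene.function_label:
            qualifiers["product"] = [gene.function_label]
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=qualifiers))
    return record


def write_genbank(genome: Genome, path: str | Path) -> None:
    """Write one genome as a GenBank flat file with CDS features."""
    SeqIO.write([_to_seqrecord(genome)], str(path), "genbank")


def write_fasta(genomes: Sequence[Genome] | Genome, path: str | Path) -> None:
    """Write genomes as nucleotide FASTA."""
    if isinstance(genomes, Genome):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def gc_content(genome: Genome | str) -> float:
    """%G+C over unambiguous bases, to one decimal.

    Ambiguity codes and N are excluded from numerator and denominator.
    Raises :class:`UndefinedMetricError` when no unambiguous base exists.
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise UndefinedMetricError("%GC undefined: sequence has no unambiguous A/C/G/T base")
    return round(100.0 * gc / (gc + at), 1)


def genome_metrics_table(genomes: Iterable[Genome]) -> pd.DataFrame:
    """Per-genome metrics: id, accession, length (bp), %GC, CDS gene count."""
    genomes = list(genomes)
    if not genomes:
        raise ValueError("genome_metrics_table requires at least one genome")
    rows = [
        {
            "id": g.id,
            "accession": g.accession,
            "length_bp": len(g.sequence),
            "gc_percent": gc_content(g),
            "n_genes": len(g.genes),
        }
        for g in genomes
    ]
    return pd.DataFrame(rows)
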