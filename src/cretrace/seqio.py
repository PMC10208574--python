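"""Sequence and annotation I/O.

Reads FASTA sequence files and BED/GFF3 gene annotations into the small set
of containers the screening pipeline operates on, and extracts the genomic
regions that are compared against template regulatory elements: the full
gene span (introns included) and, where configured, flanking intergenic
windows on either side of the gene.

All coordinates are 0-based half-open internally.  BED is native to that
convention; GFF3 (1-based inclusive) is converted on ingest.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GeneLocus",
    "Region",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "load_loci",
    "extract_screen_regions",
    "reverse_complement",
]

#: IUPAC nucleotide alphabet accepted on ingest.
ALPHABET = set("ACGTUSWRYKMBVHDN")

_COMPLEMENT = str.maketrans(
    "ACGTUSWRYKMBVHDN",
    "TGCAASWYRMKVBDHN",
)

GENE_CLASSES = ("svPAX2", "dacDACH1", "invEN2", "control")


class FormatError(ValueError):
    """Raised on malformed input files (FASTA/BED/GFF3)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, uppercase, over the IUPAC alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneLocus:
    """A gene homolog's genomic neighbourhood in one species.

    ``gene_span`` and every CDS interval are 0-based half-open on ``contig``.
    """

    species: str
    gene_class: str
    contig: SequenceRecord
    gene_span: tuple[int, int]
    cds_intervals: tuple[tuple[int, int], ...] = ()
    strand: str = "+"
    gene_id: str = ""

    def __post_init__(self) -> None:
        s, e = self.gene_span
        if not (0 <= s < e <= self.contig.length):
            raise FormatError(
                f"gene span [{s},{e}) outside contig {self.contig.id!r} "
                f"of length {self.contig.length}"
            )
        prev_end = None
        for cs, ce in self.cds_intervals:
            if not (s <= cs < ce <= e):
                raise FormatError(
                    f"CDS [{cs},{ce}) outside gene span [{s},{e})"
                )
            if prev_end is not None and cs < prev_end:
                raise FormatError("CDS intervals overlap or are unsorted")
            prev_end = ce
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class Region:
    """A slice of a locus contig submitted to the alignment screen."""

    label: str  # genic | upstream_flank | downstream_flank
    interval: tuple[int, int]
    sequence: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file; residues are uppercased."""
    records = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq).upper(),
                    description=rec.description,
                )
            )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            out.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def reverse_complement(sequence: str) -> str:
    """Reverse complement with IUPAC ambiguity codes mapped to complements."""
    bad = set(sequence.upper()) - ALPHABET
    if bad:
        raise FormatError(f"non-IUPAC residues {sorted(bad)}")
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def _parse_bed(handle, contigs: dict[str, SequenceRecord]) -> list[GeneLocus]:
    loci: list[GeneLocus] = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"BED line {lineno}: need >=4 columns")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5] if len(fields) >= 6 else "+"
        if chrom not in contigs:
            raise FormatError(f"BED line {lineno}: unknown sequence {chrom!r}")
        contig = contigs[chrom]
        if not (0 <= start < end <= contig.length):
            raise FormatError(
                f"BED line {lineno}: [{start},{end}) outside contig "
                f"{chrom!r} of length {contig.length}"
            )
        species, gene_class = _split_name(name)
        cds: tuple[tuple[int, int], ...] = ()
        # BED12 blocks, if present, are taken as CDS intervals.
        if len(fields) >= 12:
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            cds = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        loci.append(
            GeneLocus(
                species=species,
                gene_class=gene_class,
                contig=contig,
                gene_span=(start, end),
                cds_intervals=cds,
                strand=strand,
                gene_id=name,
            )
        )
    return loci


def _split_name(name: str) -> tuple[str, str]:
    """Interpret a feature name as species|gene_class where possible."""
    if "|" in name:
        species, gene_class, *_ = name.split("|")
        return species, gene_class if gene_class in GENE_CLASSES else "control"
    return name, "control"


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _parse_gff3(handle, contigs: dict[str, SequenceRecord]) -> list[GeneLocus]:
    genes: dict[str, dict] = {}
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GFF3 line {lineno}: need 9 tab-separated columns")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
        start0, end0 = int(start) - 1, int(end)  # 1-based inclusive -> half-open
        attributes = _gff3_attributes(attrs)
        if ftype == "gene":
            if seqid not in contigs:
                raise FormatError(f"GFF3 line {lineno}: unknown sequence {seqid!r}")
            contig = contigs[seqid]
            if not (0 <= start0 < end0 <= contig.length):
                raise FormatError(
                    f"GFF3 line {lineno}: gene outside contig bounds"
                )
            gid = attributes.get("ID", f"gene{lineno}")
            genes[gid] = {
                "contig": contig,
                "span": (start0, end0),
                "strand": strand if strand in "+-" else "+",
                "name": attributes.get("Name", gid),
            }
        elif ftype == "CDS":
            parent = attributes.get("Parent", attributes.get("ID", ""))
            cds_by_parent.setdefault(parent, []).append((start0, end0))
    loci = []
    for gid, info in genes.items():
        cds = sorted(cds_by_parent.get(gid, []))
        species, gene_class = _split_name(info["name"])
        loci.append(
            GeneLocus(
                species=species,
                gene_class=gene_class,
                contig=info["contig"],
                gene_span=info["span"],
                cds_intervals=tuple(cds),
                strand=info["strand"],
                gene_id=gid,
            )
        )
    return loci


def load_loci(
    fasta_path: str | Path,
    annotation_path: str | Path,
    annotation_format: str = "BED",
) -> list[GeneLocus]:
    """Load gene loci from a FASTA + BED/GFF3 annotation pair.

    Feature names of the form ``species|gene_class`` carry the screen
    metadata; anything else is treated as a control locus.
    """
    contigs = {rec.id: rec for rec in read_fasta(fasta_path)}
    fmt = annotation_format.upper()
    with _open_text(annotation_path) as handle:
        if fmt == "BED":
            return _parse_bed(handle, contigs)
        if fmt == "GFF3":
            return _parse_gff3(handle, contigs)
    raise ValueError(f"unknown annotation format {annotation_format!r}")


def extract_screen_regions(locus: GeneLocus, flank_bp: int | None = None) -> list[Region]:
    """Regions of a locus submitted to the alignment screen.

    The genic region (gene span, introns included) is always screened.  When
    ``flank_bp`` is positive, intergenic windows of up to that size on either
    side of the gene are screened as well, truncated at contig boundaries.
    The default follows the screen design: 5 kb flanks for engrailed-class
    (invEN2) loci, gene span only otherwise.
    """
    if flank_bp is None:
        flank_bp = 5000 if locus.gene_class == "invEN2" else 0
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    s, e = locus.gene_span
    seq = locus.contig.residues
    regions = []
    if flank_bp > 0 and s > 0:
        us = max(0, s - flank_bp)
        regions.append(Region("upstream_flank", (us, s), seq[us:s]))
    regions.append(Region("genic", (s, e), seq[s:e]))
    if flank_bp > 0 and e < len(seq):
        de = min(len(seq), e + flank_bp)
        regions.append(Region("downstream_flank", (e, de), seq[e:de]))
    return regions
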