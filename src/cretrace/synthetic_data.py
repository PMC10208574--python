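"""Synthetic datasets for exercising the screening pipeline end to end.

Real template CREs and genome loci are not redistributable, so every
pipeline stage is exercised on generated data instead: random template
elements at the study lengths (356/247/373 nt, GC 0.40), orthologous loci
carrying diverged copies of a template planted in noncoding sequence
(mid-intron for the intragenic classes, within the 5 kb flank for the
engrailed class), negative-control loci with no planted element, and a
tree-wide presence/absence scenario (single gain at a named ancestor with
losses on named branches).

The generator models divergence as per-column substitution plus small
geometric indels; it makes no attempt at repeat content, codon structure
or conserved synteny — it generates detection problems, not genomes.

All randomness flows from one master seed through per-purpose derived
streams, so any species/class locus is reproducible in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .aligner import waterman_eggert
from .homology_stats import TEMPLATE_LENGTHS, random_sequence
from .parsimony import CHARACTERS, CharacterMatrix, PhyloTree, load_packaged_tree, write_newick
from .seqio import GeneLocus, SequenceRecord, reverse_complement, write_fasta

import pandas as pd

__all__ = [
    "SyntheticConfig",
    "TruthEntry",
    "TruthManifest",
    "SyntheticDataset",
    "make_template",
    "mutate",
    "plant_locus",
    "make_species_set",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for generated data.

    Template lengths, GC and the screen geometry mirror the study; the
    locus architecture (three 200 nt exons, two 800 nt introns, 1 kb
    flanks) is a compact stand-in chosen so that every placement the
    screen must handle — intronic and flanking — exists, while keeping
    alignment work small.
    """

    template_lengths: dict = field(default_factory=lambda: dict(TEMPLATE_LENGTHS))
    gc_fraction: float = 0.40
    target_identity_pct: float = 80.0
    indel_rate: float = 0.02
    exon_lengths: tuple[int, ...] = (200, 200, 200)
    intron_lengths: tuple[int, ...] = (800, 800)
    flank_length: int = 1000
    gain_node: str = "PDA"
    loss_tips: tuple[str, ...] = ("S_kowalevskii", "P_caudatus")
    inaccessible: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_identity_pct <= 100):
            raise ValueError("target_identity_pct must lie in (0, 100]")
        if any(l <= 0 for l in self.template_lengths.values()):
            raise ValueError("template lengths must be positive")


def _rng(config_seed: int, *key: object) -> np.random.Generator:
    """Derived stream: stable across runs, independent per key."""
    tag = zlib.crc32("/".join(map(str, key)).encode())
    return np.random.default_rng([config_seed & 0x7FFFFFFF, tag])


def make_template(cre_class: str, config: SyntheticConfig) -> SequenceRecord:
    """A random template element at the class's configured length."""
    length = config.template_lengths[cre_class]
    rng = _rng(config.seed, "template", cre_class)
    return SequenceRecord(
        id=f"{cre_class}_template",
        residues=random_sequence(rng, length, config.gc_fraction),
        description=f"{cre_class}_template synthetic length={length}",
    )


def mutate(
    template: SequenceRecord,
    target_identity_pct: float,
    indel_rate: float = 0.02,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SequenceRecord:
    """A diverged copy: per-column substitutions plus geometric indels.

    Substitutions are uniform over the three alternative bases; at each
    column an indel starts with probability ``indel_rate``, its length
    geometric with mean 2, insertions drawing uniform random bases.  The
    substitution rate is set slightly below ``(100 - target) / 100`` to
    compensate for the gap columns indels add to the re-alignment, and the
    draw is repeated (advancing the same stream) until the realized
    identity — best local re-alignment against the template — falls within
    5 percentage points of the target, so the contract holds per element,
    not just in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    # gap columns dilute identity by ~2*indel_rate (mean indel length 2)
    sub_rate = 1.0 - (target_identity_pct / 100.0) / max(1e-9, 1.0 - 2.0 * indel_rate)
    sub_rate = min(max(sub_rate, 0.0), 0.75)
    bases = "ACGT"
    res = template.residues
    mutant = res
    for _attempt in range(30):
        out: list[str] = []
        i = 0
        while i < len(res):
            if indel_rate > 0 and rng.random() < indel_rate:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:
                    out.append("".join(bases[rng.integers(4)] for _ in range(length)))
                else:
                    i += length
                    continue
            c = res[i]
            i += 1
            if rng.random() < sub_rate:
                alternatives = bases.replace(c, "") if c in bases else bases
                out.append(alternatives[rng.integers(len(alternatives))])
            else:
                out.append(c)
        mutant = "".join(out)
        if not mutant:
            continue
        alns = waterman_eggert(mutant, res)
        if alns and abs(alns[0].pct_identity - target_identity_pct) <= 5.0:
            break
    return SequenceRecord(
        id=template.id + "_div",
        residues=mutant,
        description=f"{template.id} diverged target={target_identity_pct}",
    )


@dataclass
class TruthEntry:
    """Ground truth for one species x class cell."""

    species: str
    cre_class: str
    planted: bool
    contig_interval: tuple[int, int] | None = None
    strand: str | None = None
    realized_identity: float | None = None


@dataclass
class TruthManifest:
    entries: dict = field(default_factory=dict)  # (species, class) -> TruthEntry

    def add(self, entry: TruthEntry) -> None:
        self.entries[(entry.species, entry.cre_class)] = entry

    def to_json(self, path) -> None:
        payload = [
            {**asdict(e), "contig_interval": list(e.contig_interval) if e.contig_interval else None}
            for e in self.entries.values()
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


def plant_locus(
    species: str,
    cre_class: str,
    element: SequenceRecord | None,
    config: SyntheticConfig,
) -> tuple[GeneLocus, TruthEntry]:
    """Build one locus contig, optionally with a planted element.

    Intragenic classes (svPAX2, dacDACH1) place the element mid-intron;
    the engrailed class (invEN2) places it in a flank, within 5 kb of the
    gene span.  Strand is drawn at random.  With ``element=None`` a
    negative-control locus of identical architecture is emitted.
    """
    rng = _rng(config.seed, "locus", species, cre_class)
    flank = config.flank_length
    exons = list(config.exon_lengths)
    introns = list(config.intron_lengths)
    if element is not None:
        if cre_class in ("svPAX2", "dacDACH1", "control"):
            if element.length >= min(introns):
                raise ValueError(
                    f"element ({element.length} nt) does not fit the smallest "
                    f"intron ({min(introns)} nt)"
                )
        elif element.length >= flank:
            raise ValueError(f"element ({element.length} nt) does not fit the flank")

    strand = "+" if element is None or rng.random() < 0.5 else "-"
    planted_seq = None
    if element is not None:
        planted_seq = element.residues if strand == "+" else reverse_complement(element.residues)

    target_intron = int(rng.integers(len(introns))) if introns else 0
    target_flank = "upstream" if rng.random() < 0.5 else "downstream"

    parts: list[str] = []
    pos = 0
    cds: list[tuple[int, int]] = []
    element_interval: tuple[int, int] | None = None

    def emit_random(n: int) -> None:
        nonlocal pos
        parts.append(random_sequence(rng, n, config.gc_fraction))
        pos += n

    def emit_planted_into(n: int) -> None:
        """Random stretch of n nt with the element spliced into its middle."""
        nonlocal pos, element_interval
        left = (n - len(planted_seq)) // 2
        emit_random(left)
        element_interval = (pos, pos + len(planted_seq))
        parts.append(planted_seq)
        pos += len(planted_seq)
        emit_random(n - left - len(planted_seq))

    in_flank = planted_seq is not None and cre_class == "invEN2"
    if in_flank and target_flank == "upstream":
        emit_planted_into(flank)
    else:
        emit_random(flank)
    gene_start = pos
    for i, ex in enumerate(exons):
        cds.append((pos, pos + ex))
        emit_random(ex)
        if i < len(introns):
            if planted_seq is not None and not in_flank and i == target_intron:
                emit_planted_into(introns[i])
            else:
                emit_random(introns[i])
    gene_end = pos
    if in_flank and target_flank == "downstream":
        emit_planted_into(flank)
    else:
        emit_random(flank)

    contig = SequenceRecord(
        id=f"{species}_{cre_class}_contig", residues="".join(parts)
    )
    locus = GeneLocus(
        species=species,
        gene_class=cre_class,
        contig=contig,
        gene_span=(gene_start, gene_end),
        cds_intervals=tuple(cds),
        strand="+",
        gene_id=f"{species}|{cre_class}",
    )
    truth = TruthEntry(
        species=species,
        cre_class=cre_class,
        planted=element is not None,
        contig_interval=element_interval,
        strand=strand if element is not None else None,
    )
    return locus, truth


@dataclass
class SyntheticDataset:
    """Everything one screening run needs, plus its ground truth."""

    tree: PhyloTree
    templates: dict
    loci: dict  # (species, cre_class) -> GeneLocus
    manifest: TruthManifest
    truth_matrix: CharacterMatrix
    gain_node: str
    loss_tips: tuple[str, ...]

    @property
    def planted_loss_count(self) -> int:
        return len(self.loss_tips)


def make_species_set(
    tree: PhyloTree | None = None, config: SyntheticConfig | None = None
) -> SyntheticDataset:
    """Generate loci for every tree tip under a gain/loss scenario.

    Tips descending from the gain node carry diverged copies of all three
    templates, except loss tips (negative loci); tips outside the gain
    clade carry none.  Inaccessible tips get no locus and a ``?`` truth
    state.  The ground-truth matrix is what a perfectly specific and
    sensitive screen would recover.
    """
    if config is None:
        config = SyntheticConfig()
    if tree is None:
        tree = load_packaged_tree()
    gain = tree.node(config.gain_node)
    clade = set(PhyloTree.tip_labels(gain))
    unknown = set(config.loss_tips) - clade
    if unknown:
        raise ValueError(f"loss tips outside the gain clade: {sorted(unknown)}")

    templates = {cls: make_template(cls, config) for cls in CHARACTERS}
    loci: dict = {}
    manifest = TruthManifest()
    rows: dict[str, dict[str, str]] = {}
    for species in tree.tips:
        rows[species] = {}
        for cls in CHARACTERS:
            if species in config.inaccessible:
                rows[species][cls] = "?"
                continue
            planted = species in clade and species not in config.loss_tips
            element = None
            if planted:
                element = mutate(
                    templates[cls],
                    config.target_identity_pct,
                    config.indel_rate,
                    rng=_rng(config.seed, "mutate", species, cls),
                )
            locus, truth = plant_locus(species, cls, element, config)
            if planted:
                s, e = truth.contig_interval
                segment = locus.contig.residues[s:e]
                if truth.strand == "-":
                    segment = reverse_complement(segment)
                alns = waterman_eggert(segment, templates[cls].residues)
                truth.realized_identity = alns[0].pct_identity if alns else 0.0
            loci[(species, cls)] = locus
            manifest.add(truth)
            rows[species][cls] = "1" if planted else "0"
    truth_matrix = CharacterMatrix(
        pd.DataFrame.from_dict(rows, orient="index").loc[list(tree.tips), list(CHARACTERS)]
    )
    return SyntheticDataset(
        tree=tree,
        templates=templates,
        loci=loci,
        manifest=manifest,
        truth_matrix=truth_matrix,
        gain_node=config.gain_node,
        loss_tips=tuple(config.loss_tips),
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + BED + Newick + truth manifest under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "templates": outdir / "templates.fasta",
        "loci": outdir / "loci.fasta",
        "annotations": outdir / "loci.bed",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
        "truth_matrix": outdir / "truth_matrix.tsv",
    }
    write_fasta(dataset.templates.values(), paths["templates"])
    write_fasta((l.contig for l in dataset.loci.values()), paths["loci"])
    with open(paths["annotations"], "w") as bed:
        for locus in dataset.loci.values():
            s, e = locus.gene_span
            blocks = locus.cds_intervals
            sizes = ",".join(str(ce - cs) for cs, ce in blocks)
            offs = ",".join(str(cs - s) for cs, _ in blocks)
            bed.write(
                f"{locus.contig.id}\t{s}\t{e}\t{locus.gene_id}\t0\t{locus.strand}"
                f"\t{s}\t{e}\t0\t{len(blocks)}\t{sizes}\t{offs}\n"
            )
    Path(paths["tree"]).write_text(write_newick(dataset.tree) + "\n")
    dataset.manifest.to_json(paths["truth"])
    dataset.truth_matrix.to_tsv(paths["truth_matrix"])
    return paths
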