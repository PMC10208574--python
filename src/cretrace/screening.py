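"""Screening gene loci for CRE-like sequences.

Applies the four selection criteria to local alignments between a locus and
a template regulatory element: (ii) a minimum identity over a minimum
alignment length (defaults 60% over 55 bp, with an optional expect-value
cut), (iii) the hit must be noncoding (no CDS overlap), and (iv) not a
repetitive/low-complexity element.  Criterion (i) — same homologous gene —
is satisfied upstream by construction, since loci are supplied per gene
class.  The per-locus call vocabulary mirrors the presence/absence matrix
legend: ``no_gene_homolog``, ``gene_present_cre_absent``, ``cre_present``,
``not_accessible``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .aligner import LocalAlignment, ScoringScheme, alignment_evalue, waterman_eggert
from .seqio import GeneLocus, Region, SequenceRecord, extract_screen_regions, reverse_complement

__all__ = [
    "ScreeningCriteria",
    "CREHit",
    "ScreenResult",
    "CoreDomain",
    "CALLS",
    "passes_criteria",
    "is_low_complexity",
    "is_noncoding",
    "screen_locus",
    "core_domain",
]

CALLS = ("no_gene_homolog", "gene_present_cre_absent", "cre_present", "not_accessible")


@dataclass(frozen=True)
class ScreeningCriteria:
    """Selection thresholds for a CRE-like call."""

    min_identity_pct: float = 60.0
    min_length_bp: int = 55
    max_evalue: float = 0.1
    use_evalue: bool = False
    require_noncoding: bool = True
    require_non_repetitive: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must lie in (0, 100]")
        if self.min_length_bp < 1:
            raise ValueError("min_length_bp must be >= 1")


def passes_criteria(
    alignment: LocalAlignment,
    criteria: ScreeningCriteria,
    evalue: float | None = None,
) -> bool:
    """Identity/length thresholds, plus the E-value cut when enabled."""
    if alignment.pct_identity < criteria.min_identity_pct:
        return False
    if alignment.n_columns < criteria.min_length_bp:
        return False
    if criteria.use_evalue and evalue is not None and evalue > criteria.max_evalue:
        return False
    return True


def is_low_complexity(sequence: str, k: int = 2, entropy_threshold: float = 1.5) -> bool:
    """Low-complexity proxy for the repetitive-element criterion.

    True when the Shannon entropy (bits) of the k-mer frequency
    distribution falls below the threshold; simple repeats and
    homopolymers score far below random sequence (~3.9 bits for
    dinucleotides).
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts = Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))
    total = sum(counts.values())
    entropy = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return entropy < entropy_threshold


def is_noncoding(contig_interval: tuple[int, int], locus: GeneLocus) -> bool:
    """True iff the interval overlaps no CDS interval of the locus."""
    s, e = contig_interval
    return all(e <= cs or ce <= s for cs, ce in locus.cds_intervals)


@dataclass(frozen=True)
class CREHit:
    """One above-threshold alignment between a locus and a template."""

    species: str
    gene_class: str
    template_id: str
    region_label: str
    strand: str
    alignment: LocalAlignment
    contig_interval: tuple[int, int]
    noncoding: bool
    non_repetitive: bool
    evalue: float | None = None

    @property
    def template_interval(self) -> tuple[int, int]:
        return self.alignment.template_interval


@dataclass(frozen=True)
class ScreenResult:
    """Per species x template call, mirroring the matrix legend symbols."""

    species: str
    gene_class: str
    call: str
    best_hit: CREHit | None = None

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if (self.call == "cre_present") != (self.best_hit is not None):
            raise ValueError("call cre_present iff a passing best hit is recorded")


def _hit_from_alignment(
    locus: GeneLocus,
    template: SequenceRecord,
    region: Region,
    strand: str,
    aln: LocalAlignment,
    criteria: ScreeningCriteria,
    scheme: ScoringScheme | None,
) -> CREHit:
    rs, _re = region.interval
    qs, qe = aln.query_interval
    if strand == "+":
        interval = (rs + qs, rs + qe)
    else:
        n = len(region.sequence)
        interval = (rs + n - qe, rs + n - qs)
    hit_seq = locus.contig.residues[interval[0] : interval[1]]
    ev = None
    if criteria.use_evalue:
        ev = alignment_evalue(aln, len(region.sequence), template.length, scheme)
    return CREHit(
        species=locus.species,
        gene_class=locus.gene_class,
        template_id=template.id,
        region_label=region.label,
        strand=strand,
        alignment=aln,
        contig_interval=interval,
        noncoding=is_noncoding(interval, locus),
        non_repetitive=not is_low_complexity(hit_seq) if len(hit_seq) >= 2 else False,
        evalue=ev,
    )


def _hit_passes(hit: CREHit, criteria: ScreeningCriteria) -> bool:
    if not passes_criteria(hit.alignment, criteria, hit.evalue):
        return False
    if criteria.require_noncoding and not hit.noncoding:
        return False
    if criteria.require_non_repetitive and not hit.non_repetitive:
        return False
    return True


def screen_locus(
    locus: GeneLocus,
    template: SequenceRecord,
    criteria: ScreeningCriteria | None = None,
    scheme: ScoringScheme | None = None,
    flank_bp: int | None = None,
    k: int = 1,
    both_strands: bool = True,
) -> ScreenResult:
    """Screen every region of a locus (both strands) against a template.

    The call is ``cre_present`` when the best passing hit exists, ranked by
    score, then alignment length, then leftmost contig start, with
    forward-strand hits winning remaining ties; otherwise
    ``gene_present_cre_absent``.
    """
    if criteria is None:
        criteria = ScreeningCriteria()
    if template.length == 0:
        raise ValueError("template must be non-empty")
    strands = ("+", "-") if both_strands else ("+",)
    hits: list[CREHit] = []
    for region in extract_screen_regions(locus, flank_bp):
        if not region.sequence:
            continue
        for strand in strands:
            qseq = region.sequence if strand == "+" else reverse_complement(region.sequence)
            for aln in waterman_eggert(qseq, template.residues, scheme, k=k):
                hits.append(
                    _hit_from_alignment(locus, template, region, strand, aln, criteria, scheme)
                )
    passing = [h for h in hits if _hit_passes(h, criteria)]
    if not passing:
        return ScreenResult(locus.species, locus.gene_class, "gene_present_cre_absent")
    best = min(
        passing,
        key=lambda h: (
            -h.alignment.score,
            -h.alignment.n_columns,
            h.contig_interval[0],
            h.strand != "+",
        ),
    )
    return ScreenResult(locus.species, locus.gene_class, "cre_present", best)


@dataclass(frozen=True)
class CoreDomain:
    """Template sub-interval where hits cluster across species."""

    template_interval: tuple[int, int]
    coverage: int


def core_domain(hits: Sequence[CREHit] | Iterable[tuple[int, int]], template_length: int) -> CoreDomain:
    """Maximal-length template interval of maximal hit coverage (leftmost tie).

    Accepts either CREHit objects or bare template intervals.
    """
    intervals = [
        h.template_interval if isinstance(h, CREHit) else tuple(h) for h in hits
    ]
    if not intervals:
        raise ValueError("need at least one hit")
    cov = [0] * template_length
    for s, e in intervals:
        for p in range(max(0, s), min(template_length, e)):
            cov[p] += 1
    peak = max(cov)
    best_start, best_len = 0, 0
    run_start = None
    for p in range(template_length + 1):
        at_peak = p < template_length and cov[p] == peak
        if at_peak and run_start is None:
            run_start = p
        elif not at_peak and run_start is not None:
            if p - run_start > best_len:
                best_start, best_len = run_start, p - run_start
            run_start = None
    return CoreDomain((best_start, best_start + best_len), peak)
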