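"""Naive per-column SNV caller.

Screens every reference column of the target region and reports positions
where the aligned reads disagree on the base.  This is deliberately the
simplest "disagreement" rule — any position where at least two distinct
symbols each reach a minimum count, at a minimum depth — because the
co-occurrence model downstream is what weighs the evidence; a heavier variant
caller can always be substituted by supplying a VCF instead.  'N' bases carry
no allele information and are excluded from the disagreement test; deletions
are tallied as '-'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pysam

from .ingest import _iter_alignments
from .matrix import VariantPanel

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class ColumnSummary:
    """Base tally of one reference column."""

    position: int  # 1-based genomic coordinate
    base_tally: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_tally.values())

    def allele_counts(self) -> dict[str, int]:
        """Tallies that can support an allele (everything but 'N')."""
        return {s: c for s, c in self.base_tally.items() if s != "N"}


def scan_columns(
    alignment_source, contig: str, start: int, end: int
) -> list[ColumnSummary]:
    """Tally symbols at every column of [start, end] (1-based inclusive).

    Iterates primary alignments and reads symbols off their aligned pairs, so
    it works identically on plain SAM streams and indexed BAMs; deletions in
    a read are tallied as '-', ambiguous bases as 'N'.
    """
    if end < start:
        raise ValueError("empty region: end < start")
    tallies: dict[int, dict[str, int]] = {p: {} for p in range(start, end + 1)}
    for read in _iter_alignments(alignment_source, contig):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.reference_name != contig
        ):
            continue
        seq = read.query_sequence or ""
        for qpos, rpos in read.get_aligned_pairs():
            if rpos is None:
                continue
            pos = rpos + 1
            if not start <= pos <= end:
                continue
            if qpos is None:
                sym = "-"
            else:
                sym = seq[qpos].upper() if qpos < len(seq) else "N"
                if sym not in _BASES:
                    sym = "N"
            tally = tallies[pos]
            tally[sym] = tally.get(sym, 0) + 1
    return [ColumnSummary(p, tallies[p]) for p in range(start, end + 1) if tallies[p]]


def call_variants(
    alignment_source,
    contig: str,
    start: int,
    end: int,
    min_depth: int = 2,
    min_minor_count: int = 1,
) -> VariantPanel:
    """Emit the positions showing base disagreement across aligned reads.

    A column is a variant when its depth reaches ``min_depth`` and at least
    two distinct non-'N' symbols each reach ``min_minor_count``.  Raising
    ``min_minor_count`` can only shrink the panel.  Zero coverage everywhere
    yields an empty panel with a warning, not an error.
    """
    columns = scan_columns(alignment_source, contig, start, end)
    positions: list[int] = []
    for col in columns:
        if col.depth < min_depth:
            continue
        informative = [c for c in col.allele_counts().values() if c >= min_minor_count]
        if len(informative) >= 2:
            positions.append(col.position)
    if not positions:
        log.warning(
            "no variant positions called on %s:%d-%d", contig, start, end
        )
    return VariantPanel(contig, start, end, tuple(sorted(positions)))


def write_panel_vcf(
    columns: Iterable[ColumnSummary],
    panel: VariantPanel,
    path: str,
    source: str = "mihap",
) -> None:
    """Serialize called positions as a minimal VCF (REF = majority base,
    ALT = the other alleles, '-' rendered as the '*' allele, INFO/DP)."""
    by_pos = {c.position: c for c in columns}
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source={source}\n")
        out.write(
            f"##contig=<ID={panel.contig},length={panel.region_end}>\n"
        )
        out.write("##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Depth\">\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos in panel.positions:
            col = by_pos.get(pos)
            counts = col.allele_counts() if col else {}
            bases = sorted(counts, key=lambda s: (-counts[s], s))
            ref = next((b for b in bases if b in _BASES), "N")
            alts = [("*" if b == "-" else b) for b in bases if b != ref] or ["."]
            depth = col.depth if col else 0
            out.write(
                f"{panel.contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\tDP={depth}\n"
            )
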