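"""Alignment ingestion: SAM/BAM records → per-read site observations → H.

A read observation is a read reduced to its symbols at the contiguous run of
panel sites falling inside its aligned span: an aligned base gives A/C/G/T, a
deletion in the read gives '-', an ambiguous or quality-masked base gives 'N'.
Observations are folded into a co-occurrence matrix; the fold is additive, so
ingestion order cannot affect the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .matrix import (
    ALPHABET,
    TERMINAL,
    CooccurrenceMatrix,
    InvalidSymbolError,
    PanelMismatchError,
    VariantPanel,
)

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read reduced to its symbols at covered panel sites.

    ``first_index``/``last_index`` are 1-based panel site indices, inclusive;
    ``symbols`` has one entry per covered site and never contains the
    terminal sentinel.
    """

    read_id: str
    first_index: int
    last_index: int
    symbols: tuple[str, ...]

    def __post_init__(self):
        if self.first_index < 1 or self.first_index > self.last_index:
            raise PanelMismatchError(
                f"bad observation span {self.first_index}..{self.last_index}"
            )
        if len(self.symbols) != self.last_index - self.first_index + 1:
            raise PanelMismatchError("symbol count disagrees with span")
        for s in self.symbols:
            if s == TERMINAL or s not in ALPHABET:
                raise InvalidSymbolError(f"symbol {s!r} not allowed in an observation")

    @property
    def n_sites(self) -> int:
        return len(self.symbols)


@dataclass
class IngestStats:
    """Tally of kept and skipped alignment records."""

    kept: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_wrong_contig: int = 0
    skipped_no_overlap: int = 0
    skipped_mapq: int = 0
    skipped_few_sites: int = 0
    malformed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _iter_alignments(source, contig: str) -> Iterator[pysam.AlignedSegment]:
    """Yield records from a path or an open AlignmentFile, preferring an
    index-backed fetch on the contig and falling back to a full scan."""
    own = isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
    af = pysam.AlignmentFile(str(source)) if own else source
    try:
        if contig not in (af.references or ()):
            raise PanelMismatchError(
                f"contig {contig!r} absent from alignment header"
            )
        try:
            yield from af.fetch(contig)
        except ValueError:
            for rec in af.fetch(until_eof=True):
                yield rec
    finally:
        if own:
            af.close()


def observation_from_alignment(
    read: pysam.AlignedSegment,
    panel: VariantPanel,
    min_base_quality: int | None = None,
) -> ReadObservation | None:
    """Reduce one aligned record to its panel-site symbols.

    The covered sites are the contiguous run of panel positions inside the
    record's reference span.  A site where the alignment places a deletion
    (or skip) yields '-'; a non-ACGT or quality-masked base yields 'N'.
    Returns None when the record overlaps no panel site.
    """
    ref_start = read.reference_start + 1  # 1-based first aligned position
    ref_end = read.reference_end  # 1-based last aligned position
    covered = [
        k + 1
        for k, pos in enumerate(panel.positions)
        if ref_start <= pos <= ref_end
    ]
    if not covered:
        return None
    first, last = covered[0], covered[-1]

    base_at: dict[int, str] = {}
    seq = read.query_sequence or ""
    quals = read.query_qualities
    wanted = {panel.positions[k - 1] - 1 for k in covered}  # 0-based ref pos
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is None or rpos not in wanted:
            continue
        if qpos is None:
            base_at[rpos] = "-"  # deletion (or skip) in the read
            continue
        base = seq[qpos].upper() if qpos < len(seq) else "N"
        if base not in _BASES:
            base = "N"
        elif (
            min_base_quality is not None
            and quals is not None
            and quals[qpos] < min_base_quality
        ):
            base = "N"
        base_at[rpos] = base

    symbols = tuple(
        base_at.get(panel.positions[k - 1] - 1, "N") for k in range(first, last + 1)
    )
    return ReadObservation(
        read_id=read.query_name or "?",
        first_index=first,
        last_index=last,
        symbols=symbols,
    )


def extract_observations(
    alignment_source,
    panel: VariantPanel,
    min_mapq: int = 0,
    min_sites: int = 1,
    min_base_quality: int | None = None,
) -> tuple[list[ReadObservation], IngestStats]:
    """Extract one observation per primary alignment overlapping the panel.

    Unmapped, secondary and supplementary records are skipped, as are records
    below ``min_mapq`` or covering fewer than ``min_sites`` panel sites.
    Paired mates are treated as independent observations.  Malformed records
    are logged and tallied, never fatal.
    """
    if panel.n < 1:
        raise PanelMismatchError("empty panel")
    stats = IngestStats()
    observations: list[ReadObservation] = []
    for read in _iter_alignments(alignment_source, panel.contig):
        if read.is_unmapped:
            stats.skipped_unmapped += 1
            continue
        if read.is_secondary:
            stats.skipped_secondary += 1
            continue
        if read.is_supplementary:
            stats.skipped_supplementary += 1
            continue
        if read.reference_name != panel.contig:
            stats.skipped_wrong_contig += 1
            continue
        if read.mapping_quality < min_mapq:
            stats.skipped_mapq += 1
            continue
        try:
            obs = observation_from_alignment(read, panel, min_base_quality)
        except Exception:  # defensive: one bad record must not kill a run
            log.warning("malformed alignment record %s skipped", read.query_name)
            stats.malformed += 1
            continue
        if obs is None:
            stats.skipped_no_overlap += 1
            continue
        if obs.n_sites < min_sites:
            stats.skipped_few_sites += 1
            continue
        observations.append(obs)
        stats.kept += 1
    log.info(
        "ingest: kept %d observations over %d sites (%s)",
        stats.kept,
        panel.n,
        stats.as_dict(),
    )
    return observations, stats


def build_matrix(
    observations: Iterable[ReadObservation], panel: VariantPanel | int
) -> CooccurrenceMatrix:
    """Fold observations into a fresh co-occurrence matrix."""
    n = panel if isinstance(panel, int) else panel.n
    H = CooccurrenceMatrix(n)
    for obs in observations:
        H.observe_read(obs)
    return H
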