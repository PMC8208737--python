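"""Ground-truthed synthetic communities for exercising the whole pipeline.

Generates K haplotypes of a shared gene-scale region that differ only at
planted SNV sites, samples error-prone reads from them at configurable
abundances, and serializes everything as plain FASTA/SAM/VCF — reads are
emitted pre-aligned (their coordinates are known by construction), so no
aligner sits between the generator and the method under test.  The error
model is substitution-only; deletions enter through deletion *alleles*, which
exercise the '-' symbol via the alignment CIGAR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam
from scipy import stats as _scipy_stats

from .matrix import VariantPanel
from .traversal import TraversalResult

_BASES = ("A", "C", "G", "T")

_CIGAR_MATCH = 0
_CIGAR_DEL = 2


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic community.

    ``coverage`` is the mean read depth of one haplotype at equal abundance:
    the total read count is K × coverage × region_length / read_length and
    reads are apportioned by abundance.  ``deletion_prob`` is the chance a
    planted site's alternate allele is a deletion rather than a substitution.
    """

    region_length: int = 1000
    n_snvs: int = 15
    n_haplotypes: int = 2
    abundances: tuple[float, ...] | None = None
    snv_positions: tuple[int, ...] | None = None
    alleles: tuple[str, ...] | None = None
    read_length: int = 250
    coverage: float = 30.0
    error_rate: float = 0.01
    deletion_prob: float = 0.0
    seed: int = 0
    contig: str = "region"

    def __post_init__(self):
        if self.n_haplotypes < 1:
            raise ValueError("need at least one haplotype")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.read_length > self.region_length:
            raise ValueError("read_length exceeds region_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.abundances is not None:
            ab = tuple(float(a) for a in self.abundances)
            if len(ab) != self.n_haplotypes:
                raise ValueError("one abundance per haplotype required")
            if abs(sum(ab) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")
            object.__setattr__(self, "abundances", ab)
        if self.snv_positions is not None:
            pos = tuple(int(p) for p in self.snv_positions)
            if len(set(pos)) != len(pos) or sorted(pos) != list(pos):
                raise ValueError("snv_positions must be unique and sorted")
            if pos and (pos[0] < 1 or pos[-1] > self.region_length):
                raise ValueError("snv_positions outside region")
            if len(pos) != self.n_snvs:
                object.__setattr__(self, "n_snvs", len(pos))
            object.__setattr__(self, "snv_positions", pos)
        if self.alleles is not None:
            al = tuple(str(a).upper() for a in self.alleles)
            if len(al) != self.n_haplotypes or any(
                len(a) != self.n_snvs for a in al
            ):
                raise ValueError("alleles must be K strings of length n_snvs")
            object.__setattr__(self, "alleles", al)

    @property
    def effective_abundances(self) -> tuple[float, ...]:
        if self.abundances is not None:
            return self.abundances
        k = self.n_haplotypes
        return tuple(1.0 / k for _ in range(k))


@dataclass
class Community:
    """A generated community: reference backbone, haplotypes, planted sites."""

    spec: CommunitySpec
    reference: str
    haplotypes: tuple[str, ...]  # full-length sequences (deletions removed)
    hap_ref_positions: tuple[tuple[int, ...], ...]  # 0-based ref pos per base
    alleles: tuple[str, ...]  # per-haplotype symbols over the planted sites
    panel: VariantPanel


@dataclass
class SimulatedRead:
    """One pre-aligned read: sequence plus its reference placement."""

    name: str
    haplotype: int
    ref_start: int  # 0-based
    cigar: tuple[tuple[int, int], ...]
    sequence: str


@dataclass
class RecoveryReport:
    """How well a traversal result matches the planted truth."""

    identities: tuple[float, ...]  # per truth haplotype, best-match identity
    best_match_rank: tuple[int | None, ...]  # 1-based rank of that match
    n_exact: int  # truth haplotypes matched at 100% identity
    recovered_empty: bool
    rank_abundance_correlation: float | None

    def as_dict(self) -> dict:
        return {
            "identities": list(self.identities),
            "best_match_rank": list(self.best_match_rank),
            "n_exact": self.n_exact,
            "recovered_empty": self.recovered_empty,
            "rank_abundance_correlation": self.rank_abundance_correlation,
        }


def evenly_spaced_positions(region_length: int, n: int) -> tuple[int, ...]:
    """n interior positions at (roughly) equal spacing — handy for building
    fixtures whose adjacent sites are guaranteed to be co-spanned by reads."""
    return tuple(region_length * (k + 1) // (n + 1) for k in range(n))


def generate_community(spec: CommunitySpec) -> Community:
    """Build the reference backbone and K haplotypes differing from it only
    at the planted SNV positions; deterministic under the spec seed.

    Default allele tables make every site polymorphic *within* the community
    (some but not all haplotypes carry the alternate allele, except K = 1
    where the lone haplotype carries it) and all haplotype allele vectors
    pairwise distinct.
    """
    rng = np.random.default_rng([spec.seed, 0])
    k = spec.n_haplotypes
    reference = "".join(rng.choice(_BASES, size=spec.region_length))

    if spec.snv_positions is not None:
        positions = spec.snv_positions
    else:
        positions = tuple(
            sorted(rng.choice(spec.region_length, size=spec.n_snvs, replace=False) + 1)
        )
    n = len(positions)

    if spec.alleles is not None:
        alleles = spec.alleles
    else:
        for _ in range(100):
            table = [["" for _ in range(n)] for _ in range(k)]
            for s, pos in enumerate(positions):
                ref_base = reference[pos - 1]
                if rng.random() < spec.deletion_prob:
                    alt = "-"
                else:
                    alt = rng.choice([b for b in _BASES if b != ref_base])
                if k == 1:
                    carriers = {0}
                else:
                    size = int(rng.integers(1, k))  # some but not all
                    carriers = set(rng.choice(k, size=size, replace=False))
                for h in range(k):
                    table[h][s] = alt if h in carriers else ref_base
            alleles = tuple("".join(row) for row in table)
            if len(set(alleles)) == k:
                break
        else:  # pragma: no cover - vanishing probability at sane n
            raise RuntimeError("failed to draw pairwise-distinct haplotypes")

    haplotypes: list[str] = []
    ref_maps: list[tuple[int, ...]] = []
    allele_at = [
        {positions[s]: alleles[h][s] for s in range(n)} for h in range(k)
    ]
    for h in range(k):
        seq: list[str] = []
        ref_pos: list[int] = []
        for p0, base in enumerate(reference):
            sym = allele_at[h].get(p0 + 1, base)
            if sym == "-":
                continue
            seq.append(sym)
            ref_pos.append(p0)
        haplotypes.append("".join(seq))
        ref_maps.append(tuple(ref_pos))

    panel = VariantPanel(spec.contig, 1, spec.region_length, positions)
    return Community(
        spec=spec,
        reference=reference,
        haplotypes=tuple(haplotypes),
        hap_ref_positions=tuple(ref_maps),
        alleles=alleles,
        panel=panel,
    )


def simulate_reads(
    community: Community, rng: np.random.Generator | None = None
) -> list[SimulatedRead]:
    """Draw reads per haplotype in proportion to abundance, with uniform
    start positions and per-base substitution error; seed-deterministic."""
    spec = community.spec
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 1])
    abundances = spec.effective_abundances
    total = spec.n_haplotypes * spec.coverage * spec.region_length / spec.read_length
    reads: list[SimulatedRead] = []
    for h, hap in enumerate(community.haplotypes):
        n_reads = int(round(total * abundances[h]))
        if len(hap) < spec.read_length:
            raise ValueError("haplotype shorter than read_length")
        starts = rng.integers(0, len(hap) - spec.read_length + 1, size=n_reads)
        ref_map = community.hap_ref_positions[h]
        for idx, s in enumerate(sorted(starts.tolist())):
            bases = list(hap[s : s + spec.read_length])
            if spec.error_rate > 0.0:
                errs = np.nonzero(rng.random(spec.read_length) < spec.error_rate)[0]
                for e in errs:
                    bases[e] = rng.choice([b for b in _BASES if b != bases[e]])
            ref_pos = ref_map[s : s + spec.read_length]
            cigar: list[list[int]] = [[_CIGAR_MATCH, 1]]
            for prev, cur in zip(ref_pos, ref_pos[1:]):
                gap = cur - prev
                if gap == 1:
                    if cigar[-1][0] == _CIGAR_MATCH:
                        cigar[-1][1] += 1
                    else:
                        cigar.append([_CIGAR_MATCH, 1])
                else:
                    cigar.append([_CIGAR_DEL, gap - 1])
                    cigar.append([_CIGAR_MATCH, 1])
            reads.append(
                SimulatedRead(
                    name=f"hap{h}.{idx}",
                    haplotype=h,
                    ref_start=ref_pos[0],
                    cigar=tuple(tuple(c) for c in cigar),
                    sequence="".join(bases),
                )
            )
    return reads


# -- serialization ---------------------------------------------------------


def write_sam(
    reads: Iterable[SimulatedRead], community: Community, path: str
) -> None:
    spec = community.spec
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": spec.contig, "LN": spec.region_length}],
            "CO": [f"mihap simulate seed={spec.seed}"],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in sorted(reads, key=lambda r: (r.ref_start, r.name)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = read.ref_start
            seg.mapping_quality = 60
            seg.cigartuples = list(read.cigar)
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "I" * len(read.sequence)
            )
            seg.set_tag("HP", read.haplotype + 1)
            out.write(seg)


def write_fastq(reads: Iterable[SimulatedRead], path: str) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(
                f"@{read.name}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def write_fasta(records: Sequence[tuple[str, str, str]], path: str) -> None:
    """Write (id, description, sequence) triples via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=rid, description=desc) for rid, desc, seq in records],
        path,
        "fasta",
    )


def write_community(community: Community, outdir) -> dict[str, str]:
    """Serialize reference/truth FASTA and planted-site VCF into ``outdir``;
    returns the file paths written."""
    import os

    spec = community.spec
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "reference.fasta"),
        "truth": os.path.join(outdir, "truth.fasta"),
        "sites": os.path.join(outdir, "sites.vcf"),
        "meta": os.path.join(outdir, "community.json"),
    }
    write_fasta(
        [(spec.contig, f"reference seed={spec.seed}", community.reference)],
        paths["reference"],
    )
    write_fasta(
        [
            (
                f"hap{h}",
                f"abundance={community.spec.effective_abundances[h]:.4f} "
                f"alleles={community.alleles[h]} seed={spec.seed}",
                community.haplotypes[h],
            )
            for h in range(spec.n_haplotypes)
        ],
        paths["truth"],
    )
    with open(paths["sites"], "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source=mihap-simulate seed={spec.seed}\n")
        out.write(f"##contig=<ID={spec.contig},length={spec.region_length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s, pos in enumerate(community.panel.positions):
            ref_base = community.reference[pos - 1]
            alts = sorted(
                {
                    ("*" if a[s] == "-" else a[s])
                    for a in community.alleles
                    if a[s] != ref_base
                }
            ) or ["."]
            out.write(
                f"{spec.contig}\t{pos}\t.\t{ref_base}\t{','.join(alts)}\t.\tPASS\t.\n"
            )
    with open(paths["meta"], "w") as out:
        json.dump(
            {
                "seed": spec.seed,
                "contig": spec.contig,
                "region_length": spec.region_length,
                "n_haplotypes": spec.n_haplotypes,
                "abundances": list(spec.effective_abundances),
                "snv_positions": list(community.panel.positions),
                "alleles": list(community.alleles),
                "read_length": spec.read_length,
                "coverage": spec.coverage,
                "error_rate": spec.error_rate,
            },
            out,
            indent=2,
        )
    return paths


# -- scoring recovery ------------------------------------------------------


def site_identity(truth: str, recovered: str) -> float:
    if len(truth) != len(recovered):
        raise ValueError("haplotypes defined over different panels")
    if not truth:
        return 0.0
    return sum(t == r for t, r in zip(truth, recovered)) / len(truth)


def evaluate_recovery(
    truth_alleles: Sequence[str],
    result: TraversalResult | Sequence[tuple[str, float]],
    abundances: Sequence[float] | None = None,
) -> RecoveryReport:
    """Score a recovery against the planted truth.

    ``result`` is a TraversalResult or a pre-ranked list of
    (site-symbol string, log10 likelihood).  Identity is the fraction of
    matching SNV sites against the best-matching recovered haplotype.  The
    rank/abundance correlation (Spearman) is computed over truth haplotypes
    with a best match, when at least two are matched.
    """
    if isinstance(result, TraversalResult):
        ranked = [
            (p.symbols, p.log10_likelihood if p.log10_likelihood is not None else float("-inf"))
            for p in result.haplotypes
        ]
    else:
        ranked = [(sym, score) for sym, score in result]

    identities: list[float] = []
    ranks: list[int | None] = []
    if not ranked:
        return RecoveryReport(
            identities=tuple(0.0 for _ in truth_alleles),
            best_match_rank=tuple(None for _ in truth_alleles),
            n_exact=0,
            recovered_empty=True,
            rank_abundance_correlation=None,
        )
    for truth in truth_alleles:
        scored = [site_identity(truth, sym) for sym, _ in ranked]
        best = int(np.argmax(scored))
        identities.append(scored[best])
        ranks.append(best + 1)
    n_exact = sum(1 for x in identities if x == 1.0)

    corr = None
    if abundances is not None:
        matched = [
            (abundances[t], ranked[ranks[t] - 1][1])
            for t in range(len(truth_alleles))
            if identities[t] == 1.0
        ]
        if len(matched) >= 2:
            ab, sc = zip(*matched)
            if len(set(ab)) > 1 and len(set(sc)) > 1:
                corr = float(_scipy_stats.spearmanr(ab, sc).statistic)
    return RecoveryReport(
        identities=tuple(identities),
        best_match_rank=tuple(ranks),
        n_exact=n_exact,
        recovered_empty=False,
        rank_abundance_correlation=corr,
    )
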