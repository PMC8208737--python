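# Methods

## Problem setting

Given reads from a community sample aligned to a de novo assembled contig,
and the single-nucleotide-variant (SNV) positions over a gene-scale region
of that contig, recover the set of haplotypes — the allele sequences over
those SNV sites — present in the community, together with a likelihood
ranking. The number of haplotypes is unknown a priori; this distinguishes
the problem from diploid/polyploid phasing, whose algorithms assume a fixed
known ploidy. Assembly and alignment are upstream of this package: it
consumes SAM/BAM plus (optionally) a VCF of sites.

## The co-occurrence matrix

All read evidence is folded into `H[α, β, i, j]`: the number of reads
carrying symbol `α` at site `i` and `β` at site `j > i`, over the alphabet
`A, C, G, T, N, -` (`-` = deletion in the read; insertions are not
modelled). Only strictly upper-triangular `(i, j)` pairs exist — reversed
and self pairs carry no extra information and are unaddressable by
construction. Reads themselves are discarded after ingestion.

Two bookkeeping details matter:

* **Terminal sentinel.** After a read's last covered site `j`, an internal
  sentinel is linked at `(j, j+1)` in a virtual column `n+1`. The total
  evidence in the adjacent column `(j, j+1)` then always equals the number
  of reads spanning site `j`, which is exactly the denominator the marginal
  estimator needs — including at the last site. The sentinel never appears
  in any output.
* **Contiguous spans.** A read observation covers the contiguous run of
  panel sites inside its aligned span; a site under a deletion yields `-`,
  an ambiguous or quality-masked base yields `N`. This makes "spanning"
  well defined and means a read covering sites `i` and `j` also covers
  everything between.

Counts are stored as floats from the outset because reweighting (below)
makes them fractional; before any reweighting they are exact non-negative
integers. Storage is a dense `7 × 7 × (n+2) × (n+2)` array — O(|Σ|²n²)
memory, which is the intended trade-off for the gene-scale regions (tens of
sites) local haplotyping targets.

## Probability estimators

* Marginal: `P(v_j = β) = Σ_δ H[β, δ, j, j+1] / Σ_γ Σ_δ H[γ, δ, j, j+1]` —
  the fraction of reads spanning `j` that carry `β`. A zero denominator
  (no read spans the site) raises a no-evidence signal that the traversal
  surfaces as a hole.
* Conditional: `P(v_i = α | v_j = β) = (1 + H[α, β, i, j]) / (V_i + Σ_γ H[γ, β, i, j])`
  where `V_i` is the number of distinct symbols observed at site `i`.
  The Laplace term (one dummy read per symbol observed at `i`) keeps the
  estimate strictly positive for pairs never co-covered by any read, so
  long-range conditioning degrades gracefully rather than zeroing a path.

Both estimators satisfy exact normalization (marginals over the alphabet;
conditionals over the symbols observed at `i`), which the test suite checks
to 1e-12 on randomized matrices.

## Greedy traversal

A candidate next node is scored by its marginal times the conditionals of
the last `min(L, i)` path nodes given the candidate, in log10 space. `L`
(the lookback, default **5**) should be on the order of the number of sites
a read spans: pairs further apart than a read length are never co-observed,
so their conditionals contribute only smoothing noise. The walk starts at
site 1's highest-marginal symbol and appends the arg-max candidate until
site `n` is reached or no edge remains traversable.

Edge availability is per destination node: symbol `β` at `i+1` is
traversable when `Σ_α H[α, β, i, i+1]` exceeds a small epsilon (default
**1e-9**, to ignore float dust left by multiplicative reweighting — a
count depleted by factors of `(1−λ)` never reaches exact zero unless
`λ = 1`). An empty candidate set is a *hole*: the traversal aborts there
and reports the unreachable site.

Ties between equal-scoring candidates are broken by fixed symbol order
(`A < C < G < T < N < -`) and logged; together with deterministic
ingestion this makes every run reproducible bit for bit.

## Multi-haplotype loop

After each complete traversal `ĥ`:

1. `λ = min_i P(ĥ[i])` on the **current** matrix — the weakest site is an
   estimate of the abundance fraction the haplotype explains. (Evaluating λ
   on the current rather than the original matrix is a deliberate choice:
   λ is defined inside the iteration loop, where the current matrix
   reflects the evidence not yet attributed to earlier haplotypes.)
2. Every adjacent entry `H[ĥ[i], ĥ[i+1], i, i+1]` is scaled by `(1 − λ)`,
   clamped at zero. Only adjacent entries are touched; non-adjacent
   evidence for the same path intentionally survives, so lookback scoring
   on later iterations still sees it. This asymmetry is part of the method,
   not an oversight.
3. The path is scored against the **pre-reweighting** marginals,
   `log₁₀ L(ĥ) = Σ_i log₁₀ P(v_i = ĥ[i])`. Implementation note: only the
   per-site marginal vectors are snapshotted before iteration 1, which is
   equivalent to retaining a full copy of the matrix for this purpose and
   much cheaper; the equivalence is unit-tested. A zero marginal yields
   −inf: the path stays rankable but sinks to the bottom.

The loop halts when a traversal aborts or after `max_iterations` (default
**100** — the stopping rule needs a cap because with `λ < 1` evidence
decays geometrically but only reaches the epsilon floor after many
rounds). Duplicate paths re-found on later iterations are reported once,
keeping the first iteration index. `recover_all` works on an internal copy
of the matrix; the caller's `H` is never mutated (the lower-level
`reweight` operation does mutate, by design).

Termination is reported as `hole_at_start` when the very first traversal
aborts with an empty path, `evidence_exhausted` for any later abort, and
`max_iterations` when the cap binds.

Degenerate inputs: a single-site panel (`n = 1`) traverses trivially and
reweighting touches nothing (there are no adjacent pairs), so the loop runs
to the iteration cap; panels need `n ≥ 2` to be meaningful.

## Variant calling

When no VCF is supplied, a deliberately naive per-column caller screens the
region: a position is a variant when depth ≥ `min_depth` (default 2) and at
least two distinct non-`N` symbols each reach `min_minor_count` (default
1) — the literal "disagreement" rule, with thresholds exposed because raw
disagreement floods the panel as soon as reads carry sequencing error.
`N` carries no allele information and never counts toward disagreement;
deletions are tallied as `-`. The intended workflow on noisy data is either
a supplied VCF from a real caller or a raised `min_minor_count`.

## Ingestion defaults

Mapping-quality filter off (`min_mapq = 0`), minimum one covered site, no
base-quality masking by default (an optional threshold masks low-quality
bases to `N`): the evidence model is designed to absorb noise in aggregate,
so the ingest stage should not silently drop evidence. Unmapped, secondary
and supplementary records are skipped and tallied. Paired mates are treated
as two independent observations; overlapping mates therefore double-count
their shared sites — flagged here because the read model has no insert-size
concept.

## Synthetic communities

The generator emulates the target regime: `K` haplotypes of a shared
region differing only at planted SNV sites, sampled at configurable
abundances, fragmented into fixed-length reads with uniform starts and
i.i.d. substitution errors, serialized as reference/truth FASTA, planted-
site VCF and **pre-aligned** SAM (coordinates are known by construction, so
no aligner sits between generator and method; a FASTQ can be written for
users who want to run one). Deletion alleles exercise the `-` symbol
through real `D` CIGAR operations. Everything is deterministic under the
spec seed, which is embedded in output headers.

Defaults (the package's canonical study conditions): 1 kb region, 15 SNV
sites, 250 bp reads, 30× per-haplotype depth at equal abundances, 1%
substitution error. `coverage` means the depth of one haplotype at equal
abundance; total reads are `K · coverage · region / read_length`
apportioned by abundance.

What the generator does **not** emulate: platform-specific error profiles
(indel errors, quality decay, GC bias), chimeric reads, non-uniform
coverage, alignment artefacts, or contamination. Passing tests on these
fixtures therefore demonstrates the correctness of the evidence model and
search dynamics, not robustness to real-library pathologies — for those,
the alignment itself is the battleground, and it is upstream of this
package.

Test and acceptance problem sizes (a deliberate choice to keep fixtures
small and exhaustively checkable): regions of 0.3–1 kb, 4–15 SNV sites,
up to ~600 reads per community.

## Known limitations

* **Greedy search misses minor haplotypes as K grows.** At 5 equally
  abundant haplotypes over 15 sites, the traversal+reweighting loop
  reliably recovers 3–4 of 5 truths exactly; the rest are matched at
  ~87–93% site identity even with zero sequencing error and the iteration
  cap lifted. Reweighting depletes shared adjacent evidence of recovered
  haplotypes, after which per-node edge availability lets walks blend
  backbones instead of isolating the remaining minors. This is the
  heuristic's intrinsic trade-off, not a coverage or noise artefact.
* **Likelihood ranking favours majority blends.** The path score is a
  product of per-site marginals, so a blended path that takes the most
  frequent symbol at every site scores at least as high as any true
  haplotype; whenever such blends are recovered they outrank low-abundance
  truths. Ranking separates probable from improbable paths; it is not a
  truth oracle, and downstream filtering should treat near-tied scores as
  equivalent.
* **Insertions are invisible** (the alphabet has no insertion symbol) and
  deletions are only as good as the upstream alignment's gap placement.
* The naive caller is a screen, not a genotyper; with real error rates its
  default thresholds over-call and a proper caller should supply the VCF.
* All-pairs storage is quadratic in panel size; the implementation targets
  gene-scale regions, not whole-contig panels with thousands of sites.
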