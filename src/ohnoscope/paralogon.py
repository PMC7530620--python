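"""Paralogon detection and ghost-locus inference.

A paralogon is a set of chromosomes related by shared small paralog
families — the genomic footprint a whole-genome duplication leaves even
after the focal gene itself is lost.  Restricting to families of at
most four members keeps the signal dominated by 2R-derived quartets
rather than large promiscuous families; a "ghost" locus is then the
non-anchor chromosome unexpectedly rich in members of families anchored
on at least two of the known loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .io import DataError, GeneLocus


@dataclass
class FamilyIndex:
    """family_id → members, within one species' gene table."""

    members: dict = field(default_factory=dict)  # fam -> [(gene_id, chrom)]
    chromosome_sizes: dict = field(default_factory=dict)  # chrom -> gene count

    @classmethod
    def from_gene_table(cls, table: Sequence[GeneLocus]) -> "FamilyIndex":
        idx = cls()
        for g in table:
            idx.chromosome_sizes[g.chromosome] = (
                idx.chromosome_sizes.get(g.chromosome, 0) + 1
            )
            if g.family_id is not None:
                idx.members.setdefault(g.family_id, []).append(
                    (g.gene_id, g.chromosome)
                )
        return idx

    def size(self, family: str) -> int:
        return len(self.members[family])

    def chromosomes_of(self, family: str) -> set[str]:
        return {c for _, c in self.members[family]}

    @property
    def total_genes(self) -> int:
        return sum(self.chromosome_sizes.values())


@dataclass
class GhostReport:
    anchors: tuple
    candidate_families: set
    member_counts: dict                 # chromosome -> candidate members
    ranking: list                       # [(chromosome, count, p_inclusive)]

    @property
    def top_candidate(self) -> str | None:
        return self.ranking[0][0] if self.ranking else None


def shared_family_filter(index: FamilyIndex, anchors: Iterable[str],
                         max_size: int = 4, min_anchors: int = 2) -> set[str]:
    """Families of ≤ ``max_size`` members hitting ≥ ``min_anchors`` anchors.

    ``max_size`` counts genes genome-wide in this species, so only
    families small enough to plausibly be a WGD quartet survive.
    """
    anchors = tuple(anchors)
    if not anchors:
        raise DataError("anchor set must be non-empty")
    if min_anchors < 1 or max_size < min_anchors:
        raise DataError("need max_size >= min_anchors >= 1")
    missing = [a for a in anchors if a not in index.chromosome_sizes]
    if missing:
        raise DataError(f"anchor chromosomes absent from table: {missing}")
    out = set()
    for fam in index.members:
        if index.size(fam) <= max_size:
            if len(index.chromosomes_of(fam) & set(anchors)) >= min_anchors:
                out.add(fam)
    return out


def _inclusive_tail(a: int, n: int, p: float) -> float:
    return float(stats.binom.sf(a - 1, n, p)) if n > 0 else 1.0


def ghost_score(index: FamilyIndex, anchors: Iterable[str],
                candidates: Iterable[str] | None = None,
                max_size: int = 4, min_anchors: int = 2) -> GhostReport:
    """Rank non-anchor chromosomes as ghost-locus candidates.

    For each non-anchor chromosome the count of candidate-family members
    is tested against an inclusive binomial with success probability
    equal to that chromosome's share of non-anchor genes; ranking is by
    p-value, then raw count (descending), then chromosome name.
    """
    anchors = tuple(anchors)
    if candidates is None:
        candidates = shared_family_filter(index, anchors, max_size, min_anchors)
    candidates = set(candidates)
    counts: dict[str, int] = {}
    n_off_anchor = 0
    for fam in sorted(candidates):
        for _, chrom in index.members[fam]:
            if chrom not in anchors:
                counts[chrom] = counts.get(chrom, 0) + 1
                n_off_anchor += 1
    genes_off_anchor = sum(
        sz for ch, sz in index.chromosome_sizes.items() if ch not in anchors
    )
    ranking = []
    for chrom, size in index.chromosome_sizes.items():
        if chrom in anchors:
            continue
        a = counts.get(chrom, 0)
        p = size / genes_off_anchor if genes_off_anchor else 0.0
        ranking.append((chrom, a, _inclusive_tail(a, n_off_anchor, p)))
    ranking.sort(key=lambda t: (t[2], -t[1], t[0]))
    return GhostReport(anchors, candidates, counts, ranking)


def kfold_paralogons(index: FamilyIndex, seed_chromosome: str, k: int = 4,
                     p_stop: float = 0.05) -> list[str]:
    """Greedy k-fold paralogon detection starting from a seed chromosome.

    Iteratively adds the chromosome sharing the most ≤k-member families
    with the current set (ties by binomial p-value, then name), stopping
    at k chromosomes or when the best addition's inclusive binomial
    p-value exceeds ``p_stop``.
    """
    if k not in (2, 4, 8):
        raise DataError("k must be 2, 4 or 8")
    if seed_chromosome not in index.chromosome_sizes:
        raise DataError(f"seed chromosome {seed_chromosome!r} absent from table")
    small_fams = [f for f in index.members if index.size(f) <= k]
    current = [seed_chromosome]
    total_genes = index.total_genes
    while len(current) < k:
        shared_fams = [
            f for f in small_fams
            if index.chromosomes_of(f) & set(current)
        ]
        # per outside chromosome: shared-family count and member count
        fam_counts: dict[str, int] = {}
        mem_counts: dict[str, int] = {}
        n_out = 0
        for f in shared_fams:
            chroms_here = set()
            for _, chrom in index.members[f]:
                if chrom not in current:
                    mem_counts[chrom] = mem_counts.get(chrom, 0) + 1
                    chroms_here.add(chrom)
                    n_out += 1
            for chrom in chroms_here:
                fam_counts[chrom] = fam_counts.get(chrom, 0) + 1
        genes_out = sum(
            sz for ch, sz in index.chromosome_sizes.items() if ch not in current
        )
        scored = []
        for chrom, nfam in fam_counts.items():
            p = index.chromosome_sizes[chrom] / genes_out if genes_out else 0.0
            pval = _inclusive_tail(mem_counts[chrom], n_out, p)
            scored.append((-nfam, pval, chrom))
        if not scored:
            break
        _, pval, chrom = min(scored)
        if pval > p_stop:
            break
        current.append(chrom)
    return current
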