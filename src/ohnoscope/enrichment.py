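"""Per-chromosome ortholog enrichment statistics.

Given b orthologs mapped into a genome of d protein-coding genes, a
chromosome carrying c genes and a of the orthologs is tested for excess
ortholog content three ways:

* binomial tail on a successes in b trials at rate c/d — both the
  "exclusive" spreadsheet form P(X > a) and the conventional inclusive
  form P(X >= a);
* Barnard's unconditional exact test on the 2×2 table
  [[a, b−a], [c−a, (d−c)−(b−a)]] with the column margins (on/off the
  chromosome) fixed, a pooled-variance Wald z statistic, one-sided
  greater, and the nuisance success probability maximized over a closed
  grid;
* the one-sided Fisher/hypergeometric tail, kept as the conditional-test
  benchmark.

No multiple-testing adjustment is applied by the scan; a Bonferroni
column is attached for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import DataError, GeneLocus
from .orthology import OrthologMap


@dataclass(frozen=True)
class ContingencyTable:
    """Counts behind the enrichment tests.

    a: orthologs on the focal chromosome; b: total orthologs;
    c: protein-coding genes on the focal chromosome; d: total genes.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= min(self.b, self.c)):
            raise DataError(f"need 0 <= a <= min(b, c): {self}")
        if self.b > self.d or self.c > self.d:
            raise DataError(f"need b, c <= d: {self}")
        if self.x22 < 0:
            raise DataError(f"derived cell (d-c)-(b-a) negative: {self}")

    # 2x2 cells: columns = on/off chromosome, rows = ortholog yes/no
    @property
    def x11(self) -> int:
        return self.a

    @property
    def x12(self) -> int:
        return self.b - self.a

    @property
    def x21(self) -> int:
        return self.c - self.a

    @property
    def x22(self) -> int:
        return (self.d - self.c) - (self.b - self.a)

    @property
    def group_sizes(self) -> tuple[int, int]:
        """(n1, n2): genes on the chromosome, genes elsewhere."""
        return self.c, self.d - self.c


@dataclass(frozen=True)
class BarnardConfig:
    grid_step: float = 0.001
    tie_tol: float = 1e-12

    def __post_init__(self) -> None:
        if not (0 < self.grid_step <= 0.5):
            raise DataError("grid_step must be in (0, 0.5]")


@dataclass
class EnrichmentResult:
    chromosome: str
    table: ContingencyTable
    p_binomial_exclusive: float
    p_binomial_inclusive: float
    p_barnard: float
    p_fisher: float
    p_barnard_bonferroni: float = 1.0


def binomial_tail(a: int, b: int, p: float, variant: str = "inclusive") -> float:
    """Upper binomial tail for a successes in b trials at success rate p.

    ``exclusive`` is the spreadsheet form 1 − CDF(a) = P(X > a);
    ``inclusive`` is the conventional P(X >= a).
    """
    if not (0 <= a <= b):
        raise DataError(f"need 0 <= a <= b, got a={a}, b={b}")
    if not (0.0 <= p <= 1.0):
        raise DataError(f"success probability out of range: {p}")
    if variant == "exclusive":
        return float(stats.binom.sf(a, b, p))
    if variant == "inclusive":
        return float(stats.binom.sf(a - 1, b, p))
    raise ValueError(f"unknown variant {variant!r}")


def _wald_z(k1: np.ndarray, n1: int, k2: np.ndarray, n2: int) -> np.ndarray:
    """Pooled-variance one-sided z for p1 > p2; 0 where the pool degenerates."""
    p1 = k1 / n1
    p2 = k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def barnard_exact(table: ContingencyTable,
                  cfg: BarnardConfig | None = None) -> float:
    """One-sided Barnard unconditional exact test for ortholog excess.

    Success = being an ortholog; group sizes n1 = c (focal chromosome)
    and n2 = d − c are fixed, successes x1 = a and x2 = b − a.  The
    p-value is the maximum over a closed nuisance grid {0, step, …, 1}
    of the probability of all outcome pairs scoring at least the
    observed Wald z (within a tie tolerance).  All pmf work is in log
    space and vectorized over the outcome grid.
    """
    cfg = cfg or BarnardConfig()
    n1, n2 = table.group_sizes
    if n1 == 0 or n2 == 0:
        raise DataError("both groups must be non-empty")
    x1, x2 = table.x11, table.x12

    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)
    z = _wald_z(k1[:, None], n1, k2[None, :], n2)
    z_obs = float(_wald_z(np.array([x1]), n1, np.array([x2]), n2)[0])
    mask = z >= z_obs - cfg.tie_tol

    grid = np.arange(0.0, 1.0 + cfg.grid_step / 2, cfg.grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    best = 0.0
    # chunk the nuisance grid to bound the (grid × outcomes) intermediates
    chunk = max(1, int(5e6 // ((n1 + 1) * (n2 + 1) + 1)) or 1)
    for lo in range(0, grid.size, chunk):
        g = grid[lo:lo + chunk]
        lp1 = stats.binom.logpmf(k1[None, :], n1, g[:, None])
        lp2 = stats.binom.logpmf(k2[None, :], n2, g[:, None])
        # p(pi) = sum over masked (k1, k2) of pmf1 * pmf2
        probs = np.einsum("gi,gj,ij->g", np.exp(lp1), np.exp(lp2),
                          mask.astype(float))
        m = float(probs.max()) if probs.size else 0.0
        best = max(best, m)
    return min(best, 1.0)


def fisher_tail(table: ContingencyTable) -> float:
    """One-sided conditional (hypergeometric) upper tail P(X11 >= a)."""
    return float(stats.hypergeom.sf(table.a - 1, table.d, table.b, table.c))


def enrichment_scan(orthologs: OrthologMap,
                    focal_genes: list[GeneLocus],
                    target_table: list[GeneLocus],
                    cfg: BarnardConfig | None = None) -> list[EnrichmentResult]:
    """Per-chromosome enrichment of focal-neighborhood orthologs.

    b = number of focal genes with a mapped target partner, d = number of
    genes in the target table; per chromosome, a = ortholog partners on
    it, c = target genes on it.  Results are sorted by the Barnard
    p-value (unadjusted; a Bonferroni column is attached for reference).
    """
    target_chrom = {g.gene_id: g.chromosome for g in target_table}
    focal_ids = {g.gene_id for g in focal_genes}
    partner_chroms: list[str] = []
    for pair in orthologs.pairs:
        pair = set(pair)
        focal_side = pair & focal_ids
        target_side = pair - focal_ids
        if not focal_side or not target_side:
            continue
        for t in target_side:
            if t not in target_chrom:
                raise DataError(f"ortholog {t!r} missing from the target table")
            partner_chroms.append(target_chrom[t])
    b = len(partner_chroms)
    d = len(target_table)
    a_counts: dict[str, int] = {}
    for ch in partner_chroms:
        a_counts[ch] = a_counts.get(ch, 0) + 1
    c_counts: dict[str, int] = {}
    for g in target_table:
        c_counts[g.chromosome] = c_counts.get(g.chromosome, 0) + 1

    results = []
    for ch in sorted(c_counts):
        a, c = a_counts.get(ch, 0), c_counts[ch]
        table = ContingencyTable(a, b, c, d)
        p = c / d if d else 0.0
        results.append(
            EnrichmentResult(
                chromosome=ch,
                table=table,
                p_binomial_exclusive=binomial_tail(a, b, p, "exclusive"),
                p_binomial_inclusive=binomial_tail(a, b, p, "inclusive"),
                p_barnard=barnard_exact(table, cfg),
                p_fisher=fisher_tail(table),
            )
        )
    n_tests = len(results)
    for r in results:
        r.p_barnard_bonferroni = min(1.0, r.p_barnard * n_tests)
    results.sort(key=lambda r: (r.p_barnard, r.chromosome))
    return results
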