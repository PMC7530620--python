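"""Readers and writers for the formats the pipeline touches.

Gene coordinate tables travel as BED6+1 (the seventh column carries the
gene-family label), protein sets as FASTA, similarity searches as the
12-column blast tabular dialect, and trees as newick.  Coordinates are
0-based half-open throughout; any 1-based dialect is converted at parse
time so no other module ever sees an off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class DataError(ValueError):
    """Malformed or inconsistent input data."""


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "-X*")


@dataclass(frozen=True)
class GeneLocus:
    """One gene's genomic address.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+``, ``-`` or
    ``.``; ``family_id`` is the paralog-family label when known.
    """

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DataError("gene_id must be non-empty")
        if not self.chromosome:
            raise DataError(f"{self.gene_id}: chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise DataError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise DataError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """One query→subject similarity search hit (bit-score role)."""

    query_id: str
    subject_id: str
    score: float
    evalue: float | None = None
    rank: int = 1

    def __post_init__(self) -> None:
        if self.score < 0:
            raise DataError(f"{self.query_id}->{self.subject_id}: negative score")
        if self.rank < 1:
            raise DataError(f"{self.query_id}->{self.subject_id}: rank must be >= 1")


def validate_gene_table(loci: Sequence[GeneLocus]) -> None:
    seen: set[str] = set()
    for loc in loci:
        if loc.gene_id in seen:
            raise DataError(f"duplicate gene_id {loc.gene_id!r}")
        seen.add(loc.gene_id)


def read_gene_table(path: str | Path, dialect: str = "bed6+") -> list[GeneLocus]:
    """Read a gene coordinate table.

    ``bed6+`` columns: chrom, start, end, gene_id, score(ignored), strand,
    [family_id], [species]; 0-based half-open.  ``tsv`` columns: gene_id,
    species, chromosome, start, end, strand, [family_id]; 1-based inclusive
    coordinates, converted on input.
    """
    if dialect not in {"bed6+", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    species_default = path.stem
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "bed6+":
                    if len(parts) < 6:
                        raise DataError("expected >= 6 columns")
                    chrom, start, end, gid, _score, strand = parts[:6]
                    fam = parts[6] if len(parts) > 6 and parts[6] else None
                    sp = parts[7] if len(parts) > 7 and parts[7] else species_default
                    loci.append(
                        GeneLocus(gid, sp, chrom, int(start), int(end), strand, fam)
                    )
                else:
                    if len(parts) < 6:
                        raise DataError("expected >= 6 columns")
                    gid, sp, chrom, start, end, strand = parts[:6]
                    fam = parts[6] if len(parts) > 6 and parts[6] else None
                    loci.append(
                        GeneLocus(
                            gid, sp, chrom, int(start) - 1, int(end), strand, fam
                        )
                    )
            except (ValueError, DataError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    validate_gene_table(loci)
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path) -> None:
    """Write loci as BED6+2 (family_id, species in columns 7-8)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                "\t".join(
                    [
                        loc.chromosome,
                        str(loc.start),
                        str(loc.end),
                        loc.gene_id,
                        "0",
                        loc.strand,
                        loc.family_id or "",
                        loc.species,
                    ]
                )
                + "\n"
            )


def rank_hits(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Group by query and assign ranks by (-score, subject_id).

    The lexicographic subject tie-break makes the ranking a total order, so
    downstream best-hit logic is deterministic.
    """
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[SimilarityHit] = []
    for q in by_query:
        ordered = sorted(by_query[q], key=lambda h: (-h.score, h.subject_id))
        for i, h in enumerate(ordered, 1):
            out.append(SimilarityHit(h.query_id, h.subject_id, h.score, h.evalue, i))
    return out


def read_similarity_table(
    path: str | Path, score_cutoff: float = 0.0
) -> list[SimilarityHit]:
    """Read 12-column blast tabular output (outfmt-6 dialect).

    Columns: query, subject, pident, length, mismatches, gapopens, qstart,
    qend, sstart, send, evalue, bitscore.  Rows with bitscore below
    ``score_cutoff`` are dropped; survivors are ranked per query.
    """
    path = Path(path)
    raw: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise DataError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                evalue = float(parts[10])
                score = float(parts[11])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric evalue/score") from exc
            if score < score_cutoff:
                continue
            raw.append(SimilarityHit(parts[0], parts[1], score, evalue))
    return rank_hits(raw)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into an id→sequence map (id = header up to whitespace)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DataError(f"duplicate FASTA header {rec.id!r}")
        s = str(rec.seq).upper()
        if not s:
            raise DataError(f"record {rec.id!r} has no sequence")
        bad = set(s) - _VALID_RESIDUES
        if bad:
            raise DataError(f"record {rec.id!r}: invalid residues {sorted(bad)}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


class PhyloTree:
    """Rooted or unrooted tree with branch lengths and split supports.

    Thin wrapper over a :class:`dendropy.Tree`; leaf labels are plain
    strings, internal-node labels carry bootstrap supports on round trips.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool = False) -> None:
        self.tree = tree
        self.rooted = rooted

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parser error types
            raise DataError(f"malformed newick: {exc}") from exc
        return cls(tree, rooted=rooted)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def clone(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick(), rooted=self.rooted)

    # -- basic accessors --------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    @staticmethod
    def node_label(node: dendropy.Node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def find_node(self, label: str) -> dendropy.Node:
        for nd in self.tree:
            if self.node_label(nd) == label:
                return nd
        raise KeyError(label)

    # -- splits ------------------------------------------------------------
    def bipartitions(self) -> set[frozenset]:
        """Non-trivial leaf bipartitions, canonicalized for unrooted comparison.

        Each split is represented by the side that does NOT contain the
        lexicographically smallest leaf.
        """
        leaves = frozenset(self.leaf_labels)
        if len(leaves) < 4:
            return set()
        ref = min(leaves)
        splits: set[frozenset] = set()
        for nd in self.tree.preorder_node_iter():
            if nd is self.tree.seed_node or nd.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if ref in side:
                side = leaves - side
            if 1 < len(side) < len(leaves) - 1:
                splits.add(side)
        return splits

    def has_split(self, leaves: Iterable[str]) -> bool:
        """True if the given leaf set is one side of a bipartition."""
        all_leaves = frozenset(self.leaf_labels)
        side = frozenset(leaves)
        ref = min(all_leaves)
        if ref in side:
            side = all_leaves - side
        return side in self.bipartitions()

    def clades(self) -> set[frozenset]:
        """All leaf sets of internal nodes (rooted-tree view)."""
        out: set[frozenset] = set()
        for nd in self.tree.preorder_node_iter():
            out.add(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
        return out

    def path_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    # -- rooting -----------------------------------------------------------
    def root_at_outgroup(self, outgroup: str) -> "PhyloTree":
        """Return a copy rooted on the edge leading to ``outgroup``."""
        t = self.clone().tree
        og = None
        for lf in t.leaf_node_iter():
            if lf.taxon.label == outgroup:
                og = lf
                break
        if og is None:
            raise DataError(f"outgroup leaf {outgroup!r} not in tree")
        length = og.edge.length or 0.0
        t.reroot_at_edge(og.edge, length1=length / 2.0, length2=length / 2.0,
                         update_bipartitions=False)
        t.suppress_unifurcations()
        return PhyloTree(t, rooted=True)


def read_newick(text_or_path: str | Path, rooted: bool = False) -> PhyloTree:
    """Parse newick from a literal string or a file path."""
    text = str(text_or_path)
    if "(" not in text:
        text = Path(text_or_path).read_text()
    return PhyloTree.from_newick(text, rooted=rooted)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text)
    return text
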