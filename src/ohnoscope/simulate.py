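"""Genome-evolution simulator: duplication, loss, rearrangement, conversion.

The simulator evolves an ancestral genome down a labeled species tree.
Events are scripted per branch and fire at a fractional position ``at``
along the branch (structural events default to the branch start,
gene conversion to the branch end, so a converted segment is copied
*after* that branch's substitutions and is exactly identical at the tip).
Protein sequences evolve by a Poisson substitution process, uniform over
the 19 alternative residues — no indels, so every family stays aligned
for free and distance methods see an additive signal in expectation.

Every stochastic draw comes from a stream keyed by ``(seed, branch
label)``, so adding a lineage never perturbs the history of another.

Ground truth recorded per run: per-species gene tables, the proteome,
the true gene tree of every family (with duplication nodes tagged), and
the pairwise relation set (ortholog / ohnolog / tandem-paralog).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AMINO_ACIDS, DataError, GeneLocus, PhyloTree

N_AA = 20
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _branch_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

_EVENT_KINDS = {
    "tandem_duplication",
    "wgd",
    "loss",
    "translocation",
    "inversion",
    "fission",
    "fusion",
    "gene_conversion",
}


@dataclass(frozen=True)
class Event:
    kind: str
    at: float = 0.0  # fractional position along the branch, in [0, 1]
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise DataError(f"unknown event kind {self.kind!r}")
        if not (0.0 <= self.at <= 1.0):
            raise DataError(f"event position must be in [0,1], got {self.at}")

    @property
    def kw(self) -> dict:
        return dict(self.params)

    def __str__(self) -> str:
        kv = ", ".join(f"{k}={v}" for k, v in self.params)
        return f"{self.kind}({kv})@{self.at:g}"


def _ev(kind: str, at: float, **kw) -> Event:
    return Event(kind, at, tuple(sorted(kw.items())))


def tandem_duplication(gene: str, new_id: str | None = None, copies: int = 1,
                       at: float = 0.0) -> Event:
    return _ev("tandem_duplication", at, gene=gene, new_id=new_id, copies=copies)


def wgd(name: str, retention_prob: float = 1.0,
        protect: Sequence[str] = (), retain_at_least_one: bool = True,
        at: float = 0.0) -> Event:
    if not (0.0 <= retention_prob <= 1.0):
        raise DataError("retention_prob must be in [0,1]")
    return _ev("wgd", at, name=name, retention_prob=retention_prob,
               protect=tuple(sorted(protect)),
               retain_at_least_one=retain_at_least_one)


def loss(gene: str | None = None, family: str | None = None,
         chromosome: str | None = None, at: float = 0.0) -> Event:
    if gene is None and family is None:
        raise DataError("loss event needs a gene or a family")
    return _ev("loss", at, gene=gene, family=family, chromosome=chromosome)


def translocation(chromosome: str, start: int, end: int,
                  dest_chromosome: str, position: int, at: float = 0.0) -> Event:
    return _ev("translocation", at, chromosome=chromosome, start=start, end=end,
               dest_chromosome=dest_chromosome, position=position)


def inversion(chromosome: str, start: int, end: int, at: float = 0.0) -> Event:
    return _ev("inversion", at, chromosome=chromosome, start=start, end=end)


def fission(chromosome: str, breakpoint: int, at: float = 0.0) -> Event:
    return _ev("fission", at, chromosome=chromosome, breakpoint=breakpoint)


def fusion(chrom_a: str, chrom_b: str, at: float = 0.0) -> Event:
    return _ev("fusion", at, chrom_a=chrom_a, chrom_b=chrom_b)


def gene_conversion(donor: str, acceptor: str, start: int, end: int,
                    at: float = 1.0) -> Event:
    return _ev("gene_conversion", at, donor=donor, acceptor=acceptor,
               start=start, end=end)


# ---------------------------------------------------------------------------
# script, parameters, result
# ---------------------------------------------------------------------------

@dataclass
class SeqEvolParams:
    """Protein-evolution knobs: length, per-site rate, first-exon width."""

    length: int = 200                # residues per protein (gap-free)
    rate: float = 0.3                # substitutions / site / unit branch length
    exon1_sites: int = 60            # "first exon" = leading residues

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DataError("protein length must be positive")
        if self.rate < 0:
            raise DataError("substitution rate must be >= 0")


@dataclass
class EventScript:
    """A species tree plus ordered per-branch events and an ancestral genome.

    ``events`` is keyed by branch label (the label of the node *below* the
    branch); events keyed by the root label fire on a pseudo-branch of
    length ``root_branch_length`` before the first speciation.
    ``ancestor`` lists chromosomes as (name, [(gene_id, family_id), ...]).
    """

    species_newick: str
    ancestor: list
    events: dict = field(default_factory=dict)
    root_branch_length: float = 0.0

    def validate_branches(self) -> None:
        labels = {
            PhyloTree.node_label(nd)
            for nd in PhyloTree.from_newick(self.species_newick).tree
        }
        unknown = set(self.events) - labels
        if unknown:
            raise DataError(f"events reference unknown branches: {sorted(unknown)}")


@dataclass
class SimulationResult:
    species_newick: str
    gene_tables: dict            # species -> list[GeneLocus]
    proteome: dict               # gene_id -> str
    truth_pairs: list            # (gene_a, gene_b, relation)
    event_log: list
    gene_trees: dict             # family_id -> newick (duplication nodes labeled D)
    duplication_counts: dict     # family_id -> surviving duplication nodes

    def truth_relations(self, relation: str | None = None) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b, rel in self.truth_pairs
            if relation is None or rel == relation
        }

    def truth_orthologs(self, species_a: str | None = None,
                        species_b: str | None = None) -> set[frozenset]:
        """Ortholog pairs, optionally restricted to one species pair."""
        wanted = None
        if species_a is not None and species_b is not None:
            ids_a = {g.gene_id for g in self.gene_tables[species_a]}
            ids_b = {g.gene_id for g in self.gene_tables[species_b]}
            wanted = (ids_a, ids_b)
        out: set[frozenset] = set()
        for a, b, rel in self.truth_pairs:
            if rel != "ortholog":
                continue
            if wanted is not None:
                ia, ib = wanted
                if not ((a in ia and b in ib) or (a in ib and b in ia)):
                    continue
            out.add(frozenset((a, b)))
        return out

    def focal_counts(self, family: str = "MRF") -> dict:
        return {
            sp: sum(1 for g in tbl if g.family_id == family)
            for sp, tbl in self.gene_tables.items()
        }

    def true_tree(self, family: str) -> PhyloTree:
        return PhyloTree.from_newick(self.gene_trees[family], rooted=True)


# ---------------------------------------------------------------------------
# internal state
# ---------------------------------------------------------------------------

class _GTNode:
    __slots__ = ("children", "event", "length", "name")

    def __init__(self, event: str = "leaf", length: float = 0.0) -> None:
        self.children: list[_GTNode] = []
        self.event = event
        self.length = length
        self.name: str | None = None

    def add(self, child: "_GTNode") -> None:
        self.children.append(child)


class _Slot:
    __slots__ = ("lineage_id", "family_id", "birth", "strand", "seq", "node")

    def __init__(self, lineage_id, family_id, birth, strand, seq, node):
        self.lineage_id = lineage_id
        self.family_id = family_id
        self.birth = birth
        self.strand = strand
        self.seq = seq
        self.node = node


class _Genome:
    def __init__(self, species: str) -> None:
        self.species = species
        self.chromosomes: dict[str, list[_Slot]] = {}

    def all_slots(self) -> list[_Slot]:
        return [s for slots in self.chromosomes.values() for s in slots]

    def find(self, lineage_id: str) -> tuple[str, int, _Slot]:
        for cname, slots in self.chromosomes.items():
            for i, s in enumerate(slots):
                if s.lineage_id == lineage_id:
                    return cname, i, s
        raise DataError(f"gene {lineage_id!r} not present in genome")

    def gene_ids(self) -> set[str]:
        return {s.lineage_id for s in self.all_slots()}


def _speciate(genome: _Genome, species: str, species_node_label: str) -> _Genome:
    """Copy a genome into a daughter lineage, splitting every gene lineage."""
    child = _Genome(species)
    for cname, slots in genome.chromosomes.items():
        new_slots = []
        for s in slots:
            if s.node.event == "leaf":
                s.node.event = f"speciation:{species_node_label}"
            sub = _GTNode()
            s.node.add(sub)
            new_slots.append(
                _Slot(s.lineage_id, s.family_id, s.birth, s.strand,
                      None if s.seq is None else s.seq.copy(), sub)
            )
        child.chromosomes[cname] = new_slots
    return child


def evolve_sequence(seq: np.ndarray, branch_length: float, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Poisson(rate × t × L) substitutions, uniform over the 19 alternatives."""
    out = seq.copy()
    L = out.size
    n = int(rng.poisson(rate * branch_length * L)) if branch_length > 0 else 0
    if n:
        pos = rng.integers(0, L, size=n)
        step = rng.integers(1, N_AA, size=n)
        for p, st in zip(pos, step):
            out[p] = (out[p] + st) % N_AA
    return out


def _advance(genome: _Genome, seg: float, params: SeqEvolParams,
             rng: np.random.Generator, with_sequences: bool) -> None:
    if seg <= 0:
        for s in genome.all_slots():
            s.node.length += max(seg, 0.0)
        return
    for s in genome.all_slots():
        s.node.length += seg
        if with_sequences and s.seq is not None:
            s.seq = evolve_sequence(s.seq, seg, params.rate, rng)


# -- event application -------------------------------------------------------

def _split_lineage(slot: _Slot, tag: str) -> _GTNode:
    """Turn a live lineage into a duplication node; return the new copy's node."""
    slot.node.event = tag
    cont = _GTNode()
    copy = _GTNode()
    slot.node.add(cont)
    slot.node.add(copy)
    slot.node = cont
    return copy


def _apply_event(genome: _Genome, ev: Event, rng: np.random.Generator,
                 log: list, branch: str) -> None:
    kw = ev.kw
    try:
        if ev.kind == "tandem_duplication":
            cname, i, slot = genome.find(kw["gene"])
            existing = genome.gene_ids()
            for c in range(kw.get("copies", 1)):
                new_id = kw.get("new_id") if c == 0 and kw.get("new_id") else None
                if new_id is None:
                    k = 1
                    while f"{slot.lineage_id}.t{k}" in existing:
                        k += 1
                    new_id = f"{slot.lineage_id}.t{k}"
                if new_id in existing:
                    raise DataError(f"duplicate gene id {new_id!r}")
                existing.add(new_id)
                copy_node = _split_lineage(slot, "duplication:td")
                genome.chromosomes[cname].insert(
                    i + 1,
                    _Slot(new_id, slot.family_id, f"td@{branch}", slot.strand,
                          None if slot.seq is None else slot.seq.copy(), copy_node),
                )
        elif ev.kind == "wgd":
            name = kw["name"]
            protect = set(kw.get("protect", ()))
            retention = kw.get("retention_prob", 1.0)
            new_chroms: dict[str, list[_Slot]] = {}
            for cname, slots in genome.chromosomes.items():
                a_slots, b_slots = [], []
                for s in slots:
                    copy_node = _split_lineage(s, "duplication:wgd")
                    a_slots.append(s)
                    b_id = f"{s.lineage_id}-{name}"
                    b_slots.append(
                        _Slot(b_id, s.family_id, f"wgd:{name}@{branch}", s.strand,
                              None if s.seq is None else s.seq.copy(), copy_node)
                    )
                new_chroms[f"{cname}_a"] = a_slots
                new_chroms[f"{cname}_b"] = b_slots
            genome.chromosomes = new_chroms
            if retention < 1.0:
                by_family: dict[str, list[tuple[str, int]]] = {}
                for cname, slots in genome.chromosomes.items():
                    for i, s in enumerate(slots):
                        if s.family_id not in protect:
                            by_family.setdefault(s.family_id, []).append((cname, i))
                drop: list[tuple[str, int]] = []
                for fam, members in by_family.items():
                    keep = rng.random(len(members)) < retention
                    if kw.get("retain_at_least_one", True) and not keep.any():
                        keep[int(rng.integers(0, len(members)))] = True
                    drop.extend(m for m, k in zip(members, keep) if not k)
                for cname, i in sorted(drop, key=lambda x: (x[0], -x[1])):
                    del genome.chromosomes[cname][i]
        elif ev.kind == "loss":
            gene, family = kw.get("gene"), kw.get("family")
            chrom = kw.get("chromosome")
            if gene is not None:
                cname, i, _ = genome.find(gene)
                del genome.chromosomes[cname][i]
            else:
                hits = [
                    (cname, i)
                    for cname, slots in genome.chromosomes.items()
                    if chrom is None or cname == chrom
                    for i, s in enumerate(slots)
                    if s.family_id == family
                ]
                if not hits:
                    raise DataError(
                        f"no genes of family {family!r}"
                        + (f" on {chrom}" if chrom else "")
                    )
                for cname, i in sorted(hits, key=lambda x: (x[0], -x[1])):
                    del genome.chromosomes[cname][i]
        elif ev.kind == "translocation":
            src = kw["chromosome"]
            if src not in genome.chromosomes:
                raise DataError(f"chromosome {src!r} not present")
            dest = kw["dest_chromosome"]
            if dest not in genome.chromosomes:
                raise DataError(f"chromosome {dest!r} not present")
            slots = genome.chromosomes[src]
            seg = slots[kw["start"]:kw["end"]]
            if not seg:
                raise DataError("empty translocation segment")
            genome.chromosomes[src] = slots[: kw["start"]] + slots[kw["end"]:]
            pos = kw["position"]
            genome.chromosomes[dest][pos:pos] = seg
        elif ev.kind == "inversion":
            cname = kw["chromosome"]
            if cname not in genome.chromosomes:
                raise DataError(f"chromosome {cname!r} not present")
            slots = genome.chromosomes[cname]
            if not slots[kw["start"]:kw["end"]]:
                raise DataError("empty inversion segment")
            seg = slots[kw["start"]:kw["end"]][::-1]
            for s in seg:
                s.strand = "-" if s.strand == "+" else "+"
            genome.chromosomes[cname] = (
                slots[: kw["start"]] + seg + slots[kw["end"]:]
            )
        elif ev.kind == "fission":
            cname, bp = kw["chromosome"], kw["breakpoint"]
            if cname not in genome.chromosomes:
                raise DataError(f"chromosome {cname!r} not present")
            slots = genome.chromosomes.pop(cname)
            if not (0 < bp < len(slots)):
                raise DataError(f"breakpoint {bp} outside chromosome {cname!r}")
            genome.chromosomes[f"{cname}_p1"] = slots[:bp]
            genome.chromosomes[f"{cname}_p2"] = slots[bp:]
        elif ev.kind == "fusion":
            a, b = kw["chrom_a"], kw["chrom_b"]
            for c in (a, b):
                if c not in genome.chromosomes:
                    raise DataError(f"chromosome {c!r} not present")
            merged = genome.chromosomes.pop(a) + genome.chromosomes.pop(b)
            genome.chromosomes[f"{a}+{b}"] = merged
        elif ev.kind == "gene_conversion":
            _, _, donor = genome.find(kw["donor"])
            _, _, acceptor = genome.find(kw["acceptor"])
            if donor.seq is None or acceptor.seq is None:
                raise DataError("gene_conversion requires sequence simulation")
            s, e = kw["start"], kw["end"]
            if not (0 <= s < e <= donor.seq.size):
                raise DataError(f"conversion segment [{s},{e}) out of range")
            acceptor.seq[s:e] = donor.seq[s:e]
    except DataError as exc:
        raise DataError(f"branch {branch!r}, event {ev}: {exc}") from exc
    log.append(f"{branch}\t{ev}")


# -- gene-tree post-processing ----------------------------------------------

def _prune(node: _GTNode) -> _GTNode | None:
    """Drop lineages with no extant descendant; suppress unifurcations."""
    if not node.children:
        return node if node.name is not None else None
    kept = [c for c in (_prune(ch) for ch in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += node.length
        return kept[0]
    node.children = kept
    return node


def _newick(node: _GTNode) -> str:
    if not node.children:
        return f"{node.name}:{node.length:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    tag = "D" if node.event.startswith("duplication") else ""
    return f"({inner}){tag}:{node.length:.6f}"


def _count_dups(node: _GTNode) -> int:
    n = 1 if (node.children and node.event.startswith("duplication")) else 0
    return n + sum(_count_dups(c) for c in node.children)


def _classify_pairs(root: _GTNode) -> list[tuple[str, str, str]]:
    """Relation of every extant pair: via the event at their coalescent node."""
    rel_of = {
        "duplication:td": "tandem-paralog",
        "duplication:wgd": "ohnolog",
    }
    pairs: list[tuple[str, str, str]] = []

    def walk(node: _GTNode) -> list[str]:
        if not node.children:
            return [node.name] if node.name is not None else []
        groups = [walk(c) for c in node.children]
        rel = rel_of.get(node.event, "ortholog")
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        pairs.append((a, b, rel))
        return [g for grp in groups for g in grp]

    walk(root)
    return pairs


# ---------------------------------------------------------------------------
# the runner
# ---------------------------------------------------------------------------

def run_event_script(script: EventScript,
                     seq_params: SeqEvolParams | None = None,
                     seed: int = 0,
                     with_sequences: bool = True) -> SimulationResult:
    """Replay an event script deterministically; see module docstring."""
    params = seq_params or SeqEvolParams()
    script.validate_branches()
    sp_tree = PhyloTree.from_newick(script.species_newick)
    # auto-label anonymous internal nodes so branch streams are well keyed
    counter = 0
    for nd in sp_tree.tree.preorder_node_iter():
        if PhyloTree.node_label(nd) is None:
            nd.label = f"node{counter}"
        counter += 1

    # ancestral genome + one gene-tree root per ancestral gene
    root_label = PhyloTree.node_label(sp_tree.tree.seed_node)
    genome = _Genome(root_label)
    roots: dict[str, list[_GTNode]] = {}
    seen_ids: set[str] = set()
    for cname, genes in script.ancestor:
        slots = []
        for gid, fam in genes:
            if gid in seen_ids:
                raise DataError(f"ancestor gene id {gid!r} repeated")
            seen_ids.add(gid)
            node = _GTNode()
            roots.setdefault(fam, []).append(node)
            seq = None
            if with_sequences:
                rng = _branch_rng(seed, f"root:{fam}:{gid}")
                seq = rng.integers(0, N_AA, size=params.length).astype(np.int16)
            slots.append(_Slot(gid, fam, "ancestral", "+", seq, node))
        genome.chromosomes[cname] = slots

    log: list[str] = []
    tables: dict[str, list[GeneLocus]] = {}
    proteome: dict[str, str] = {}

    def process_branch(g: _Genome, label: str, length: float) -> None:
        rng = _branch_rng(seed, label)
        evs = sorted(script.events.get(label, ()), key=lambda e: e.at)
        pos = 0.0
        for ev in evs:
            _advance(g, (ev.at - pos) * length, params, rng, with_sequences)
            _apply_event(g, ev, rng, log, label)
            pos = ev.at
        _advance(g, (1.0 - pos) * length, params, rng, with_sequences)

    def emit_extant(g: _Genome) -> None:
        table: list[GeneLocus] = []
        for cname in sorted(g.chromosomes):
            for i, s in enumerate(g.chromosomes[cname]):
                gid = f"{g.species}_{s.lineage_id}"
                s.node.name = gid
                table.append(
                    GeneLocus(gid, g.species, cname, i * 1000, i * 1000 + 600,
                              s.strand, s.family_id)
                )
                if with_sequences:
                    proteome[gid] = "".join(AMINO_ACIDS[r] for r in s.seq)
        tables[g.species] = table

    def recurse(sp_node, g: _Genome) -> None:
        children = sp_node.child_nodes()
        if not children:
            emit_extant(g)
            return
        label = PhyloTree.node_label(sp_node)
        for child in children:
            clabel = PhyloTree.node_label(child)
            child_g = _speciate(g, clabel, label)
            process_branch(child_g, clabel, child.edge.length or 0.0)
            recurse(child, child_g)

    # pseudo-branch above the root lets presets diverge paralogs pre-speciation
    process_branch(genome, root_label, script.root_branch_length)
    recurse(sp_tree.tree.seed_node, genome)

    truth_pairs: list[tuple[str, str, str]] = []
    gene_trees: dict[str, str] = {}
    dup_counts: dict[str, int] = {}
    for fam in sorted(roots):
        fam_pairs: list[tuple[str, str, str]] = []
        pruned_roots = []
        for r in roots[fam]:
            fam_pairs.extend(_classify_pairs(r))
            p = _prune(r)
            if p is not None:
                pruned_roots.append(p)
        truth_pairs.extend(fam_pairs)
        if len(pruned_roots) == 1:
            gene_trees[fam] = _newick(pruned_roots[0]) + ";"
            dup_counts[fam] = _count_dups(pruned_roots[0])
        elif pruned_roots:
            inner = ",".join(_newick(r) for r in pruned_roots)
            gene_trees[fam] = f"({inner});"
            dup_counts[fam] = sum(_count_dups(r) for r in pruned_roots)

    return SimulationResult(
        species_newick=script.species_newick,
        gene_tables=tables,
        proteome=proteome,
        truth_pairs=truth_pairs,
        event_log=log,
        gene_trees=gene_trees,
        duplication_counts=dup_counts,
    )
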