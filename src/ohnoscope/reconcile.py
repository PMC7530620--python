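"""Gene-tree / species-tree LCA reconciliation and duplication timing.

Each gene-tree node is mapped to the last common ancestor of its leaves'
species.  A node is a duplication when its children's lineages overlap
in the species tree — at a binary species node this is the classic
"maps to the same node as a child" rule, and at a polytomy the overlap
test makes the polytomy soft: descending into different children of an
unresolved node never forces a duplication by itself.  Losses follow
from depth differences along each gene-tree edge.

On top of the reconciliation sit two study-specific calls: the timing
of the tandem duplication that split the focal family into early- and
late-acting classes (vertebrate stem / Olfactores stem / chordate stem,
or undetermined), and a test for whether a lineage-specific expansion
is independent (monophyletic with all duplications inside the clade).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .io import DataError, PhyloTree


@dataclass
class ReconciliationResult:
    """LCA reconciliation summary, keyed by gene-tree clades (leaf sets)."""

    events: dict          # frozenset(leaves) -> "speciation" | "duplication"
    mapping: dict         # frozenset(leaves) -> species-tree node label
    duplications: list    # [(clade, species branch label)]
    losses: int

    @property
    def duplication_count(self) -> int:
        return len(self.duplications)

    @property
    def cost(self) -> int:
        return self.duplication_count + self.losses


def _species_nodes(species_tree: PhyloTree):
    depth: dict[str, int] = {}
    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {}
    leafsets: dict[str, frozenset] = {}
    for nd in species_tree.tree.preorder_node_iter():
        lab = PhyloTree.node_label(nd)
        if lab is None:
            raise DataError("species tree nodes must all be labeled")
        plab = PhyloTree.node_label(nd.parent_node) if nd.parent_node else None
        parent[lab] = plab
        depth[lab] = 0 if plab is None else depth[plab] + 1
        children[lab] = [PhyloTree.node_label(c) for c in nd.child_nodes()]
        leafsets[lab] = frozenset(
            lf.taxon.label for lf in nd.leaf_iter()
        )
    return depth, parent, children, leafsets


def _species_lca(species: Iterable[str], leafsets, depth) -> str:
    species = set(species)
    best = None
    for lab, ls in leafsets.items():
        if species <= ls and (best is None or depth[lab] > depth[best]):
            best = lab
    if best is None:
        raise DataError(f"species {sorted(species)} not found in species tree")
    return best


def lca_reconcile(gene_tree: PhyloTree, species_tree: PhyloTree,
                  leaf_to_species: Mapping[str, str] | Callable[[str], str],
                  ) -> ReconciliationResult:
    """Map a rooted gene tree onto a rooted species tree (LCA parsimony)."""
    if not gene_tree.rooted or not species_tree.rooted:
        raise DataError("both trees must be rooted")
    if callable(leaf_to_species):
        get_sp = leaf_to_species
    else:
        get_sp = lambda g: leaf_to_species[g]
    depth, parent, children, leafsets = _species_nodes(species_tree)
    sp_leaves = {lab for lab, ch in children.items() if not ch}

    events: dict[frozenset, str] = {}
    mapping: dict[frozenset, str] = {}
    dups: list[tuple[frozenset, str]] = []
    losses = 0
    species_under: dict[int, set] = {}

    for nd in gene_tree.tree.postorder_node_iter():
        if nd.is_leaf():
            gname = nd.taxon.label
            try:
                sp = get_sp(gname)
            except KeyError:
                raise DataError(f"gene leaf {gname!r} has no species mapping")
            if sp not in sp_leaves:
                raise DataError(
                    f"gene leaf {gname!r} maps to unknown species {sp!r}"
                )
            species_under[id(nd)] = {sp}
            mapping[frozenset([gname])] = sp
            continue
        spset = set()
        for c in nd.child_nodes():
            spset |= species_under[id(c)]
        species_under[id(nd)] = spset
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        m = _species_lca(spset, leafsets, depth)
        mapping[clade] = m
        # duplication iff two children's lineages enter the same child
        # subtree of m (or touch m's own species when m is a leaf)
        slots = []
        for c in nd.child_nodes():
            cset = species_under[id(c)]
            if m in sp_leaves:
                slot = {m}
            else:
                slot = {
                    ch for ch in children[m]
                    if cset & leafsets[ch]
                }
            slots.append(slot)
        overlap = False
        for i in range(len(slots)):
            for j in range(i + 1, len(slots)):
                if slots[i] & slots[j]:
                    overlap = True
        if overlap:
            events[clade] = "duplication"
            dups.append((clade, m))
        else:
            events[clade] = "speciation"

    # losses along each gene-tree edge from depth differences
    for nd in gene_tree.tree.postorder_node_iter():
        if nd.parent_node is None:
            continue
        child_clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        parent_clade = frozenset(
            lf.taxon.label for lf in nd.parent_node.leaf_iter()
        )
        dd = depth[mapping[child_clade]] - depth[mapping[parent_clade]]
        if events[parent_clade] == "duplication":
            losses += dd
        else:
            losses += max(dd - 1, 0)

    return ReconciliationResult(events, mapping, dups, losses)


@dataclass(frozen=True)
class ScenarioCall:
    scenario: str                  # vertebrate-stem | olfactores-stem |
                                   # chordate-stem | undetermined
    duplication_clade: frozenset | None = None
    species_branch: str | None = None


def collapse_low_support(tree: PhyloTree, threshold: float = 50.0) -> PhyloTree:
    """Collapse internal edges whose support label falls below threshold."""
    t = tree.clone()
    to_collapse = []
    for nd in t.tree.preorder_node_iter():
        if nd is t.tree.seed_node or nd.is_leaf():
            continue
        if nd.label is not None:
            try:
                sup = float(nd.label)
            except ValueError:
                continue
            if sup < threshold:
                to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return t


def classify_td_timing(rec: ReconciliationResult,
                       early_genes: Iterable[str],
                       late_genes: Iterable[str],
                       scenario_branches: Mapping[str, str]) -> ScenarioCall:
    """Call the species-tree branch of the early/late tandem duplication.

    ``scenario_branches`` maps scenario names (e.g. ``vertebrate-stem``)
    to species-tree node labels.  The call is the scenario whose branch
    hosts the duplication node that is the LCA of the two gene classes
    and cleanly separates them; anything else is ``undetermined``.
    """
    early, late = set(early_genes), set(late_genes)
    if not early or not late:
        raise DataError("both gene classes must be non-empty")
    if early & late:
        raise DataError(f"gene classes overlap: {sorted(early & late)}")
    both = early | late
    # smallest gene-tree clade containing both classes
    cands = [cl for cl in rec.events if both <= cl]
    if not cands:
        raise DataError("no gene-tree clade contains both classes")
    clade = min(cands, key=len)
    if rec.events[clade] != "duplication":
        return ScenarioCall("undetermined", clade, rec.mapping[clade])
    # the duplication must separate the classes: check its child clades
    all_clades = list(rec.mapping)  # includes leaves
    subclades = [
        cl for cl in all_clades
        if cl < clade and not any(cl < c < clade for c in all_clades)
    ]
    separated = any(
        (early <= cl and not late & cl) or (late <= cl and not early & cl)
        for cl in subclades
    )
    if not separated:
        return ScenarioCall("undetermined", clade, rec.mapping[clade])
    branch = rec.mapping[clade]
    for scenario, lab in scenario_branches.items():
        if lab == branch:
            return ScenarioCall(scenario, clade, branch)
    return ScenarioCall("undetermined", clade, branch)


def test_clade_independence(gene_tree: PhyloTree,
                            rec: ReconciliationResult,
                            gene_subset: Iterable[str],
                            clade_label: str,
                            species_tree: PhyloTree,
                            leaf_to_species: Mapping[str, str] | Callable,
                            ) -> tuple[bool, list[str]]:
    """Did ``gene_subset`` expand independently within species clade C?

    True iff the subset is monophyletic in the gene tree and every
    duplication node inside it maps to C's stem or within C.  Returns
    the list of species branches hosting those duplications.
    """
    S = set(gene_subset)
    if not S:
        raise DataError("gene subset must be non-empty")
    if callable(leaf_to_species):
        get_sp = leaf_to_species
    else:
        get_sp = lambda g: leaf_to_species[g]
    depth, parent, children, leafsets = _species_nodes(species_tree)
    if clade_label not in leafsets:
        raise DataError(f"species clade {clade_label!r} not in species tree")
    allowed = leafsets[clade_label]
    for g in S:
        if get_sp(g) not in allowed:
            raise DataError(
                f"gene {g!r} belongs to a species outside clade {clade_label!r}"
            )
    # allowed mapping targets: C itself and everything below it
    within = {
        lab for lab, ls in leafsets.items()
        if ls <= allowed and (lab == clade_label or depth[lab] > depth[clade_label])
    } | {clade_label}
    if len(S) > 1 and frozenset(S) not in rec.events:
        return False, []
    branches = [
        branch for clade, branch in rec.duplications if clade <= frozenset(S)
    ]
    ok = all(b in within for b in branches)
    return ok, branches
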