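"""Canned evolution histories for the chordate MRF-style case study.

Each preset is a deterministic :class:`~ohnoscope.simulate.EventScript`
encoding one of the study conditions:

``fig2_chordate``
    Full chordate scenario: a single ancestral focal gene, a five-copy
    tandem expansion on the cephalochordate branch, a stem tandem
    duplication producing early/late gene classes, 2R on the vertebrate
    stem with scripted losses (leaving three occupied loci and a ghost),
    3R in teleosts and 4R in salmonids with their printed retained counts
    (amphioxus 5, human 4, gar 5, teleost 5, zebrafish 4, salmon 9).
``amphioxus_TD``
    Just the cephalochordate tandem expansion (five clustered genes).
``teleost_3R`` / ``salmonid_4R``
    Two-gene cluster ancestor taken through 2R (+3R, +4R) with the same
    loss pattern, giving 5 and 9 focal genes respectively.
``gene_conversion_MRF2``
    Three congeneric species, five tandem paralogs, and first-exon gene
    conversion between the two "MRF2" copies in each terminal lineage.
``ghost_2R``
    An amphioxus-like and a vertebrate-like lineage; 2R with stochastic
    background retention and scripted loss of the focal gene from one
    post-2R chromosome — the ghost locus.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .io import DataError, PhyloTree
from .simulate import (
    Event,
    EventScript,
    _Genome,
    _Slot,
    _GTNode,
    _apply_event,
    _branch_rng,
    _speciate,
    fusion,
    gene_conversion,
    inversion,
    loss,
    tandem_duplication,
    translocation,
    wgd,
)

FOCAL_FAMILY = "MRF"

#: anchor / ghost chromosome bookkeeping for the presets that have one
PRESET_INFO = {
    "fig2_chordate": {
        "human_species": "Human",
        "anchors": ("chrM_a_a", "chrM_a_b", "chrM_b_a"),
        "ghost": "chrM_b_b",
    },
    "ghost_2R": {
        "target_species": "Vertebrate",
        "focal_species": "Amphioxus",
        "focal_chromosome": "chrM",
        "anchors": ("chrM_a_a", "chrM_a_b", "chrM_b_a"),
        "ghost": "chrM_b_b",
    },
    "teleost_3R": {"target_species": "Teleost"},
    "salmonid_4R": {"target_species": "Salmon"},
}


def _bg(prefix: str, n: int, start: int = 1) -> list[tuple[str, str]]:
    return [(f"{prefix}{i:02d}", f"{prefix.upper()}{i:02d}")
            for i in range(start, start + n)]


def _focal_chromosome(n_background: int) -> list[tuple[str, str]]:
    half = n_background // 2
    genes = _bg("b", half)
    genes.append(("MRFa", FOCAL_FAMILY))
    genes.extend(_bg("b", n_background - half, start=half + 1))
    return genes


_FIG2_NEWICK = (
    "(Amphioxus:1.0,(Tunicate:0.9,(Human:0.8,(Gar:0.6,(Zebrafish:0.5,"
    "(Teleost:0.4,Salmon:0.4)Euteleostei:0.1)Teleostei:0.1)"
    "Actinopterygii:0.1)Vertebrata:0.3)Olfactores:0.2)Chordata;"
)

# 2R loss pattern: early gene lost at the third locus (late-only locus),
# both genes lost at the fourth (the ghost)
_2R_LOSSES = [loss(gene="MRFa-R1"), loss(gene="MRFa-R1-R2"),
              loss(gene="MRFl-R1-R2")]
# 3R loss pattern: only the early gene is kept in duplicate
_3R_LOSSES = [loss(gene="MRFa-R2-R3"), loss(gene="MRFl-R2-R3"),
              loss(gene="MRFl-R1-R3")]


def fig2_chordate(td_branch: str = "olfactores",
                  retention_prob: float = 0.8) -> EventScript:
    if td_branch not in {"olfactores", "vertebrate"}:
        raise DataError("td_branch must be 'olfactores' or 'vertebrate'")
    td = tandem_duplication("MRFa", new_id="MRFl")
    prot = [FOCAL_FAMILY]
    events: dict[str, list[Event]] = {
        # successive expansions spread along the cephalochordate stem
        "Amphioxus": [tandem_duplication("MRFa", at=a)
                      for a in (0.1, 0.3, 0.5, 0.7)]
        + [inversion("chrM", 2, 6)],
        "Vertebrata": [wgd("R1", retention_prob, prot),
                       wgd("R2", retention_prob, prot)] + list(_2R_LOSSES),
        "Human": [loss(gene="MRFl")],
        "Teleostei": [loss(gene="MRFl"), wgd("R3", retention_prob, prot)]
        + list(_3R_LOSSES),
        "Zebrafish": [loss(gene="MRFa-R3"),
                      fusion("chrX_a_a_a", "chrY_a_a_a")],
        "Salmon": [wgd("R4", retention_prob, prot), loss(gene="MRFl-R1-R4")],
    }
    if td_branch == "olfactores":
        events["Olfactores"] = [td]
        events["Tunicate"] = [loss(gene="MRFa")]
    else:
        events["Vertebrata"] = [td] + events["Vertebrata"]
    ancestor = [
        ("chrM", _focal_chromosome(24)),
        ("chrX", _bg("x", 20)),
        ("chrY", _bg("y", 20)),
    ]
    return EventScript(_FIG2_NEWICK, ancestor, events)


def amphioxus_td() -> EventScript:
    newick = "(Amphioxus:1.0,Outgroup:1.0)Chordata;"
    ancestor = [("chrM", _focal_chromosome(10))]
    events = {"Amphioxus": [tandem_duplication("MRFa", at=a)
                            for a in (0.1, 0.3, 0.5, 0.7)]}
    return EventScript(newick, ancestor, events)


def _fish_events(retention_prob: float, rounds: int) -> list[Event]:
    prot = [FOCAL_FAMILY]
    evs: list[Event] = [
        tandem_duplication("MRFa", new_id="MRFl"),
        wgd("R1", retention_prob, prot),
        wgd("R2", retention_prob, prot),
        *_2R_LOSSES,
        loss(gene="MRFl"),
        wgd("R3", retention_prob, prot),
        *_3R_LOSSES,
    ]
    if rounds == 4:
        evs += [wgd("R4", retention_prob, prot), loss(gene="MRFl-R1-R4")]
    return evs


def teleost_3r(retention_prob: float = 0.8) -> EventScript:
    newick = "(Outgroup:0.8,Teleost:0.8)Root;"
    ancestor = [("chrM", _focal_chromosome(10)), ("chrX", _bg("x", 10))]
    return EventScript(newick, ancestor,
                       {"Teleost": _fish_events(retention_prob, 3)})


def salmonid_4r(retention_prob: float = 0.8) -> EventScript:
    newick = "(Outgroup:0.8,Salmon:0.8)Root;"
    ancestor = [("chrM", _focal_chromosome(10)), ("chrX", _bg("x", 10))]
    return EventScript(newick, ancestor,
                       {"Salmon": _fish_events(retention_prob, 4)})


def gene_conversion_mrf2(exon1_sites: int = 60) -> EventScript:
    newick = ("((Bfloridae:0.25,Blanceolatum:0.25)Branchiostoma:0.1,"
              "Bbelcheri:0.35)Cephalochordata;")
    ancestor = [("chrM", [("n01", "N01"), ("MRF1", FOCAL_FAMILY),
                          ("n02", "N02")])]
    conv = gene_conversion("MRF2a", "MRF2b", 0, exon1_sites)
    events = {
        # tandem expansion on the stem; MRF2a and MRF2b end up non-adjacent
        "Cephalochordata": [
            tandem_duplication("MRF1", new_id="MRF3"),
            tandem_duplication("MRF3", new_id="MRF2a"),
            tandem_duplication("MRF1", new_id="MRF2b"),
            tandem_duplication("MRF1", new_id="MRF4"),
        ],
        "Bfloridae": [conv],
        "Blanceolatum": [conv],
        "Bbelcheri": [conv],
    }
    return EventScript(newick, ancestor, events, root_branch_length=1.0)


def ghost_2r(retention_prob: float = 0.8, lose_focal: bool = True,
             n_background: int = 24, n_other: int = 20) -> EventScript:
    newick = "(Amphioxus:1.0,Vertebrate:1.0)Chordata;"
    ancestor = [
        ("chrM", _focal_chromosome(n_background)),
        ("chrX", _bg("x", n_other)),
        ("chrY", _bg("y", n_other)),
    ]
    prot = [FOCAL_FAMILY]
    vert: list[Event] = [wgd("R1", retention_prob, prot),
                         wgd("R2", retention_prob, prot)]
    if lose_focal:
        vert.append(loss(gene="MRFa-R1-R2"))  # empties chrM_b_b: the ghost
    events = {
        "Amphioxus": [tandem_duplication("MRFa")] * 4,
        "Vertebrate": vert,
    }
    return EventScript(newick, ancestor, events)


_PRESETS = {
    "fig2_chordate": fig2_chordate,
    "amphioxus_TD": amphioxus_td,
    "teleost_3R": teleost_3r,
    "salmonid_4R": salmonid_4r,
    "gene_conversion_MRF2": gene_conversion_mrf2,
    "ghost_2R": ghost_2r,
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, **options) -> EventScript:
    """Build a named preset script; unknown names list the alternatives."""
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise DataError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    return builder(**options)


# ---------------------------------------------------------------------------
# tandem-duplication timing scenarios
# ---------------------------------------------------------------------------

TD_SCENARIO_BRANCH = {"i": "Vertebrata", "ii": "Olfactores", "iii": "Chordata"}


def td_timing_script(scenario: str) -> EventScript:
    """Scenario scripts for the timing of the early/late tandem duplication.

    (i) duplication on the vertebrate stem, (ii) on the Olfactores stem
    with the tunicate keeping a single descendant, (iii) on the chordate
    stem with amphioxus keeping both classes.  The duplication fires
    midway along its branch so it is temporally separated from the
    flanking speciations.
    """
    if scenario not in TD_SCENARIO_BRANCH:
        raise DataError("scenario must be one of 'i', 'ii', 'iii'")
    newick = (
        "(Outgroup:0.25,(Amphioxus:0.25,(Tunicate:0.25,"
        "(V1:0.25,V2:0.25)Vertebrata:0.25)Olfactores:0.25)Chordata:0.25)"
        "Bilateria;"
    )
    ancestor = [("chrM", [("MRFa", FOCAL_FAMILY)])]
    td = tandem_duplication("MRFa", new_id="MRFl", at=0.5)
    events: dict[str, list[Event]] = {TD_SCENARIO_BRANCH[scenario]: [td]}
    if scenario in {"ii", "iii"}:
        events["Tunicate"] = [loss(gene="MRFl")]
    return EventScript(newick, ancestor, events)


# ---------------------------------------------------------------------------
# random histories
# ---------------------------------------------------------------------------

DEFAULT_RATES = {"tandem_duplication": 0.0, "loss": 0.0,
                 "inversion": 0.0, "translocation": 0.0}


def sample_random_history(rates: dict, species_newick: str, seed: int,
                          wgd_branches: Iterable[str] = (),
                          wgd_retention: float = 0.8,
                          ancestor: list | None = None) -> EventScript:
    """Draw a concrete, replayable event script from per-branch event rates.

    ``rates`` maps event class to expected events per unit branch length;
    WGDs fire only on ``wgd_branches``, with per-copy retention sampled
    here and emitted as explicit loss events so the returned script is a
    pure record (replaying it involves no further structural randomness).
    """
    bad = set(rates) - set(DEFAULT_RATES)
    if bad:
        raise DataError(f"unknown rate keys: {sorted(bad)}")
    if any(v < 0 for v in rates.values()):
        raise DataError("rates must be >= 0")
    r = {**DEFAULT_RATES, **rates}
    wgd_branches = set(wgd_branches)
    if ancestor is None:
        ancestor = [("chr1", _bg("f", 10))]

    tree = PhyloTree.from_newick(species_newick)
    counter = 0
    for nd in tree.tree.preorder_node_iter():
        if PhyloTree.node_label(nd) is None:
            nd.label = f"node{counter}"
        counter += 1
    root_label = PhyloTree.node_label(tree.tree.seed_node)

    genome = _Genome(root_label)
    for cname, genes in ancestor:
        genome.chromosomes[cname] = [
            _Slot(gid, fam, "ancestral", "+", None, _GTNode())
            for gid, fam in genes
        ]

    events: dict[str, list[Event]] = {}

    def emit(g: _Genome, label: str, ev: Event,
             rng: np.random.Generator) -> None:
        _apply_event(g, ev, rng, [], label)
        events.setdefault(label, []).append(ev)

    def sample_branch(g: _Genome, label: str, t: float) -> None:
        rng = _branch_rng(seed, f"hist:{label}")
        if label in wgd_branches:
            emit(g, label, wgd(f"W{label}", 1.0), rng)
            by_fam: dict[str, list[str]] = {}
            for s in g.all_slots():
                by_fam.setdefault(s.family_id, []).append(s.lineage_id)
            for fam in sorted(by_fam):
                members = by_fam[fam]
                keep = rng.random(len(members)) < wgd_retention
                if not keep.any():
                    keep[int(rng.integers(0, len(members)))] = True
                for gid, k in zip(members, keep):
                    if not k:
                        emit(g, label, loss(gene=gid), rng)
        for _ in range(rng.poisson(r["tandem_duplication"] * t)):
            genes = sorted(g.gene_ids())
            if genes:
                emit(g, label,
                     tandem_duplication(genes[int(rng.integers(len(genes)))]),
                     rng)
        for _ in range(rng.poisson(r["loss"] * t)):
            genes = sorted(g.gene_ids())
            if genes:
                emit(g, label, loss(gene=genes[int(rng.integers(len(genes)))]),
                     rng)
        for _ in range(rng.poisson(r["inversion"] * t)):
            cands = sorted(c for c, s in g.chromosomes.items() if len(s) >= 2)
            if cands:
                c = cands[int(rng.integers(len(cands)))]
                n = len(g.chromosomes[c])
                i = int(rng.integers(0, n - 1))
                j = int(rng.integers(i + 2, n + 1))
                emit(g, label, inversion(c, i, j), rng)
        for _ in range(rng.poisson(r["translocation"] * t)):
            srcs = sorted(c for c, s in g.chromosomes.items() if s)
            if len(g.chromosomes) >= 2 and srcs:
                c = srcs[int(rng.integers(len(srcs)))]
                dests = sorted(set(g.chromosomes) - {c})
                d = dests[int(rng.integers(len(dests)))]
                n = len(g.chromosomes[c])
                i = int(rng.integers(0, n))
                j = int(rng.integers(i + 1, n + 1))
                p = int(rng.integers(0, len(g.chromosomes[d]) + 1))
                emit(g, label, translocation(c, i, j, d, p), rng)

    def recurse(sp_node, g: _Genome) -> None:
        for child in sp_node.child_nodes():
            clabel = PhyloTree.node_label(child)
            cg = _speciate(g, clabel, PhyloTree.node_label(sp_node))
            sample_branch(cg, clabel, child.edge.length or 0.0)
            recurse(child, cg)

    recurse(tree.tree.seed_node, genome)
    return EventScript(species_newick, ancestor, events)
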