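"""The demo pipeline: simulate → RBH → enrichment → ghost → trees → timing."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .enrichment import enrichment_scan
from .io import write_fasta, write_gene_table, write_newick
from .orthology import reciprocal_best_hits
from .paralogon import FamilyIndex, ghost_score
from .phylo import bootstrap_support
from .presets import FOCAL_FAMILY, PRESET_INFO, preset
from .simulate import SeqEvolParams, run_event_script

log = logging.getLogger("ohnoscope")


@dataclass
class PipelineReport:
    outdir: Path
    paths: dict = field(default_factory=dict)
    focal_counts: dict = field(default_factory=dict)
    top_ghost: str | None = None
    enrichment_rows: list = field(default_factory=list)
    summary_text: str = ""


def run_demo(preset_name: str, seed: int, outdir: str | Path) -> PipelineReport:
    """Run every stage of the pipeline on a preset history.

    Output is deterministic for a given (preset, seed): the same call
    twice writes byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(outdir)

    script = preset(preset_name)
    result = run_event_script(script, SeqEvolParams(), seed=seed)
    report.focal_counts = result.focal_counts(FOCAL_FAMILY)

    for sp, table in result.gene_tables.items():
        p = outdir / f"{sp}.bed"
        write_gene_table(table, p)
        report.paths[f"genes_{sp}"] = p
    p = outdir / "proteome.faa"
    write_fasta(result.proteome, p)
    report.paths["proteome"] = p

    info = PRESET_INFO.get(preset_name, {})
    lines = [f"# ohnoscope demo: {preset_name} (seed {seed})", ""]
    lines.append("## Focal gene counts")
    for sp in sorted(report.focal_counts):
        lines.append(f"- {sp}: {report.focal_counts[sp]}")

    focal_sp = info.get("focal_species")
    target_sp = info.get("target_species") or info.get("human_species")
    if focal_sp and target_sp:
        seqs_a = {
            g.gene_id: result.proteome[g.gene_id]
            for g in result.gene_tables[focal_sp]
        }
        seqs_b = {
            g.gene_id: result.proteome[g.gene_id]
            for g in result.gene_tables[target_sp]
        }
        omap = reciprocal_best_hits(seqs_a, seqs_b)
        p = outdir / "rbh_pairs.tsv"
        with open(p, "w") as fh:
            for pair in sorted(map(sorted, omap.pairs)):
                fh.write("\t".join(pair) + "\n")
        report.paths["rbh"] = p
        log.info("%d RBH pairs %s vs %s", len(omap), focal_sp, target_sp)

        focal_chrom = info.get("focal_chromosome", "chrM")
        focal_genes = [
            g for g in result.gene_tables[focal_sp]
            if g.chromosome == focal_chrom
        ]
        results = enrichment_scan(omap, focal_genes,
                                  result.gene_tables[target_sp])
        p = outdir / "enrichment.tsv"
        with open(p, "w") as fh:
            fh.write("chromosome\ta\tb\tc\td\tp_binom_excl\tp_binom_incl"
                     "\tp_barnard\tp_fisher\n")
            for r in results:
                t = r.table
                fh.write(
                    f"{r.chromosome}\t{t.a}\t{t.b}\t{t.c}\t{t.d}"
                    f"\t{r.p_binomial_exclusive:.3e}"
                    f"\t{r.p_binomial_inclusive:.3e}"
                    f"\t{r.p_barnard:.3e}\t{r.p_fisher:.3e}\n"
                )
        report.paths["enrichment"] = p
        report.enrichment_rows = results
        lines += ["", "## Ortholog enrichment (top chromosomes)"]
        for r in results[:4]:
            lines.append(
                f"- {r.chromosome}: a={r.table.a}/{r.table.b}, "
                f"Barnard p={r.p_barnard:.2e}"
            )

        anchors = info.get("anchors")
        if anchors:
            index = FamilyIndex.from_gene_table(result.gene_tables[target_sp])
            ghost = ghost_score(index, anchors)
            p = outdir / "ghost.tsv"
            with open(p, "w") as fh:
                fh.write("chromosome\tcandidate_members\tp_inclusive\n")
                for chrom, count, pval in ghost.ranking:
                    fh.write(f"{chrom}\t{count}\t{pval:.3e}\n")
            report.paths["ghost"] = p
            report.top_ghost = ghost.top_candidate
            lines += ["", f"## Ghost locus: top candidate {report.top_ghost}"]

    # focal-family NJ tree across all species
    focal_ids = [
        g.gene_id
        for tbl in result.gene_tables.values()
        for g in tbl
        if g.family_id == FOCAL_FAMILY
    ]
    if len(focal_ids) >= 4:
        aln = {gid: result.proteome[gid] for gid in sorted(focal_ids)}
        tree = bootstrap_support(aln, n_replicates=200, seed=seed)
        p = outdir / "focal_family_nj.nwk"
        write_newick(tree, p)
        report.paths["focal_tree"] = p
        lines += ["", "## Focal family NJ tree", "```",
                  tree.to_newick().strip(), "```"]

    report.summary_text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(report.summary_text)
    report.paths["report"] = outdir / "report.md"
    return report
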