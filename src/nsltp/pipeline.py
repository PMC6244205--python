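"""End-to-end orchestration: genome -> records -> duplication/phylogeny/
expression/promoter analyses, with TSV export helpers used by the CLI."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import classification, duplication, phylogeny
from .core_io import GeneModel, MaturationAnnotation, extract_spliced_cds, translate
from .motif_scan import DEFAULT_GAP_BOUNDS, GapBounds

log = logging.getLogger(__name__)


def derive_proteins(
    chromosomes: dict[str, str], models: list[GeneModel]
) -> tuple[dict[str, str], dict[str, str]]:
    """Spliced CDS and translated protein per gene; records with an internal
    stop codon are excluded with a warning."""
    cds_map, proteins = {}, {}
    for model in models:
        cds = extract_spliced_cds(model, chromosomes).residues
        pep = translate(cds)
        core = pep[:-1] if pep.endswith("*") else pep
        if "*" in core:
            log.warning("%s: internal stop codon; excluded", model.gene_id)
            continue
        cds_map[model.gene_id] = cds
        proteins[model.gene_id] = core
    return cds_map, proteins


def identify_records(
    chromosomes: dict[str, str],
    models: list[GeneModel],
    annotations: dict[str, MaturationAnnotation],
    bounds: GapBounds = DEFAULT_GAP_BOUNDS,
    deny_list: set[str] = frozenset(),
):
    """Run identification + classification; returns (records, cds_map)."""
    cds_map, proteins = derive_proteins(chromosomes, models)
    kept = [m for m in models if m.gene_id in proteins]
    records = classification.build_ltp_records(
        kept, proteins, annotations, bounds, deny_list=deny_list
    )
    return records, cds_map


def duplication_analysis(records, cds_map, cov_min=0.80, id_min=0.80, max_intervening=0):
    """Homology pairs, tandem clusters and Ka/Ks for homologous pairs."""
    family_cds = {r.gene_id: cds_map[r.gene_id] for r in records if r.gene_id in cds_map}
    pairs = duplication.all_pairs_homology(family_cds)
    homologous = {
        p.key for p in pairs if duplication.is_homologous_pair(p, cov_min, id_min)
    }
    order: dict[str, list[str]] = {}
    for rec in sorted(records, key=lambda r: (r.location.chrom, r.location.start)):
        order.setdefault(rec.location.chrom, []).append(rec.gene_id)
    clusters = duplication.find_tandem_clusters(order, homologous, max_intervening)
    kaks = []
    for p in pairs:
        if p.key not in homologous:
            continue
        _, _, codon_pairs = duplication.align_cds_pair(
            family_cds[p.gene_a], family_cds[p.gene_b]
        )
        if codon_pairs:
            kaks.append(duplication.ng86_kaks(codon_pairs, p.gene_a, p.gene_b))
    return pairs, clusters, kaks


def phylogeny_analysis(records, region: str = "full"):
    """Distance matrix + UPGMA tree over mature proteins.

    ``region="8cm"`` restricts distances to each record's 8CM span instead
    of the full mature peptide.
    """
    if region == "8cm":
        seqs = {
            r.gene_id: r.mature_sequence[r.match.start : r.match.end]
            for r in records if r.mature_sequence and r.match
        }
    else:
        seqs = {r.gene_id: r.mature_sequence for r in records if r.mature_sequence}
    dm = phylogeny.pairwise_distance_matrix(seqs)
    tree = phylogeny.upgma(dm)
    return dm, tree


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------

def records_tsv(records) -> str:
    lines = [
        "gene_id\ttype\tchrom\tstart\tend\tstrand\tgpi\thyprp\tintron_offsets\t"
        "gaps\tmw_da\tpi\tflags\tmature_sequence"
    ]
    for r in records:
        loc = r.location
        gaps = ",".join(map(str, r.match.gaps)) if r.match else ""
        lines.append(
            "\t".join(
                [
                    r.gene_id, r.type,
                    loc.chrom if loc else "", str(loc.start) if loc else "",
                    str(loc.end) if loc else "", loc.strand if loc else "",
                    str(int(r.gpi)), str(int(r.hyprp)),
                    ",".join(map(str, r.intron_offsets)), gaps,
                    f"{r.mw_da:.2f}" if r.mw_da is not None else "",
                    f"{r.pi:.2f}" if r.pi is not None else "",
                    ";".join(r.flags), r.mature_sequence,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def pairs_tsv(pairs) -> str:
    lines = ["gene_a\tgene_b\tcoverage\tidentity"]
    for p in pairs:
        lines.append(f"{p.gene_a}\t{p.gene_b}\t{p.coverage:.4f}\t{p.identity:.4f}")
    return "\n".join(lines) + "\n"


def clusters_tsv(clusters) -> str:
    lines = ["cluster\tchrom\tmembers"]
    for i, c in enumerate(clusters, 1):
        lines.append(f"{i}\t{c.chrom}\t{','.join(c.members)}")
    return "\n".join(lines) + "\n"


def kaks_tsv(results) -> str:
    lines = ["gene_a\tgene_b\tka\tks\tratio\tt_mya\tsyn_diffs\tnonsyn_diffs\tflags"]
    for r in results:
        fmt = lambda v: f"{v:.4f}" if v is not None else "NA"
        lines.append(
            f"{r.gene_a}\t{r.gene_b}\t{fmt(r.ka)}\t{fmt(r.ks)}\t{fmt(r.ratio)}\t"
            f"{fmt(r.t_mya)}\t{r.syn_diffs:.2f}\t{r.nonsyn_diffs:.2f}\t{';'.join(r.flags)}"
        )
    return "\n".join(lines) + "\n"


def enrichment_tsv(calls) -> str:
    lines = ["gene_id\tstatus\ttissue_mean\tmax_other_mean\tfold"]
    for c in calls:
        fold = "inf" if c.fold == float("inf") else f"{c.fold:.3f}"
        lines.append(
            f"{c.gene_id}\t{c.status}\t{c.tissue_mean:.3f}\t{c.max_other_mean:.3f}\t{fold}"
        )
    return "\n".join(lines) + "\n"


def discovered_tsv(motifs) -> str:
    lines = ["consensus\tp_value\te_value\tpos_hits\tneg_hits\tn_candidates\tn_sites"]
    for m in motifs:
        lines.append(
            f"{m.consensus}\t{m.p_value:.4g}\t{m.e_value:.4g}\t{m.pos_hits}\t"
            f"{m.neg_hits}\t{m.n_candidates}\t{len(m.sites)}"
        )
    return "\n".join(lines) + "\n"


def write_manifest(out_dir: Path, stage: str, seed, params: dict, outputs: list[str]):
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "outputs": outputs,
        "notes": [
            "one transcript kept per gene: longest CDS",
            "distances: pairwise global alignment (not progressive MSA)",
        ],
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
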