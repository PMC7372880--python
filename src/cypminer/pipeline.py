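"""End-to-end orchestration: simulate/load, mine, dedup, curate, classify,
profile motifs, detect SSRs, compare complements, build trees.

Stages run in a fixed order; every intermediate is written to the output
directory, every threshold is echoed into the run report, and identical
configurations (including the seed) give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import famstats, motifs_logo
from .cyp_detect import CurationConfig, CypCall, call_cyp, default_models
from .nomenclature import (
    DEFAULT_CUTOFFS,
    NomenclatureCall,
    PanelEntry,
    ReferencePanel,
    assign_nomenclature,
    tabulate_complement,
)
from .orfmine import find_orfs
from .phylo import distance_matrix, neighbor_joining, pairing_statistic
from .redundancy import ClusterConfig, MergeConfig, greedy_cluster, merge_assemblies
from .seqio import (
    NucleotideRecord,
    ProteinRecord,
    read_fasta,
    write_fasta,
    write_newick,
    write_tsv,
)
from .ssrfind import SsrConfig, find_ssrs, ssr_summary
from .synthgen import SimConfig, SimResult, emit_transcriptome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    outdir: str
    seed: int = 0
    input_fasta: str | None = None  # None -> simulate with `sim`
    sim: SimConfig | None = None
    curation: CurationConfig = CurationConfig()
    dedup_full: ClusterConfig = ClusterConfig(
        threshold=100.0, level="nucleotide", kmer_prefilter=True
    )
    dedup_redundant: ClusterConfig = ClusterConfig(
        threshold=97.0, level="nucleotide", kmer_prefilter=True
    )
    merge: MergeConfig = MergeConfig()
    ssr: SsrConfig = SsrConfig()
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS
    discovery_min_aa: int = 100
    run_merge: bool = True


def _species_of(rec_id: str) -> str:
    return rec_id.split("|", 1)[0] if "|" in rec_id else "NA"


def _config_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {
            f.name: _config_dict(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_config_dict(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _config_dict(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "stages": {}}

    # --- input -------------------------------------------------------------
    sim: SimResult | None = None
    if config.input_fasta is not None:
        transcripts = read_fasta(config.input_fasta, "nucleotide")
    else:
        sim_cfg = config.sim if config.sim is not None else SimConfig(
            seed=config.seed
        )
        sim = emit_transcriptome(sim_cfg)
        transcripts = sim.transcripts
        write_fasta(transcripts, out / "transcripts.fasta")
        write_fasta(sim.proteins, out / "truth_proteins.fasta")
        sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    report["stages"]["input"] = {"n_contigs": len(transcripts)}

    # --- dedup at 100 % and contig merging ---------------------------------
    clusters = greedy_cluster(transcripts, config.dedup_full)
    contigs = [c.representative for c in clusters]
    report["stages"]["dedup_full_identity"] = {
        "n_in": len(transcripts), "n_clusters": len(clusters),
    }
    if config.run_merge:
        contigs = merge_assemblies(contigs, (), config.merge)
    report["stages"]["merge"] = {"n_contigs": len(contigs)}

    # --- ORF mining --------------------------------------------------------
    orfs_by_contig = {
        c.id: find_orfs(c, min_aa=config.discovery_min_aa, mode="all")
        for c in sorted(contigs, key=lambda r: r.id)
    }
    n_orfs = sum(len(v) for v in orfs_by_contig.values())
    report["stages"]["orfs"] = {"n_orfs": n_orfs}
    write_tsv(
        (
            (o.contig_id, o.strand, o.frame, o.nt_start, o.nt_end,
             len(o.protein.seq), o.has_start, o.has_stop)
            for orfs in orfs_by_contig.values() for o in orfs
        ),
        out / "orfs.tsv",
        header=("contig_id", "strand", "frame", "start", "end", "aa_len",
                "has_start", "has_stop"),
    )

    # --- CYP detection and curation ---------------------------------------
    models = default_models()
    contig_by_id = {c.id: c for c in contigs}
    full_calls: dict[str, CypCall] = {}
    partial_contigs: list[NucleotideRecord] = []
    call_rows = []
    for contig_id, orfs in orfs_by_contig.items():
        calls = [
            call_cyp(o.protein, o, models, config.curation) for o in orfs
        ]
        best_full = next((c for c in calls if c.full_length), None)
        best_like = next((c for c in calls if c.cyp_like), None)
        if best_full is not None:
            full_calls[contig_id] = best_full
        elif best_like is not None:
            partial_contigs.append(contig_by_id[contig_id])
        for c in calls:
            call_rows.append((
                contig_id, c.protein.id, c.cyp_like, c.full_length,
                ",".join(c.failure_reasons),
                ";".join(f"{m}:{h.start}-{h.end}"
                         for m, h in sorted(c.selected.items())),
                f"{c.pI:.2f}" if c.pI is not None else "",
                f"{c.mw_kda:.2f}" if c.mw_kda is not None else "",
            ))
    write_tsv(call_rows, out / "cyp_calls.tsv",
              header=("contig_id", "orf_id", "cyp_like", "full_length",
                      "failure_reasons", "motifs", "pI", "mw_kda"))
    full_prot = [
        ProteinRecord(id=cid, seq=call.protein.seq)
        for cid, call in sorted(full_calls.items())
    ]
    write_fasta(full_prot, out / "full_length_proteins.fasta")
    write_fasta(sorted(partial_contigs, key=lambda r: r.id),
                out / "partial_cyp_contigs.fasta")
    partial_clusters = (
        greedy_cluster(partial_contigs, config.dedup_redundant)
        if partial_contigs else []
    )
    report["stages"]["curation"] = {
        "n_full_length": len(full_calls),
        "n_partial_contigs": len(partial_contigs),
        "n_partial_clusters": len(partial_clusters),
    }

    # --- nomenclature ------------------------------------------------------
    noms: dict[str, NomenclatureCall] = {}
    a_type_of: dict[str, str] = {}
    if sim is not None:
        panel = ReferencePanel(
            entries=tuple(
                PanelEntry(
                    protein=p,
                    clan=row["clan"], family=row["family"],
                    subfamily=row["subfamily"], name=row["name"],
                )
                for p, (_, row) in zip(sim.panel_proteins,
                                       sim.panel_table.iterrows())
            ),
            clan_map=sim.clan_map,
        )
    else:
        panel = None
    if panel is not None and full_calls:
        for cid, call in sorted(full_calls.items()):
            nom = assign_nomenclature(
                ProteinRecord(id=cid, seq=call.protein.seq), panel,
                config.cutoffs,
            )
            noms[cid] = nom
            a_type_of[call.protein.id] = (
                "A-type" if nom.a_type else "non-A-type"
            )
        write_tsv(
            ((n.query_id, n.best_ref, f"{n.identity_pct:.2f}", n.clan,
              n.family, n.subfamily, n.status, n.a_type)
             for n in noms.values()),
            out / "nomenclature.tsv",
            header=("query", "best_ref", "identity", "clan", "family",
                    "subfamily", "status", "a_type"),
        )
        by_species: dict[str, list[NomenclatureCall]] = {}
        for cid, nom in noms.items():
            by_species.setdefault(_species_of(cid), []).append(nom)
        complement = tabulate_complement(by_species, panel.clan_map)
        report["stages"]["nomenclature"] = {
            "n_calls": len(noms),
            "per_species": complement["per_species"],
        }
        complement["family_table"].to_csv(out / "family_by_species.tsv",
                                          sep="\t")
        complement["clan_table"].to_csv(out / "clan_by_species.tsv", sep="\t")
    else:
        complement = None

    # --- motif logos and consensus ----------------------------------------
    consensus: dict[str, dict[str, str]] = {}
    if a_type_of:
        for group in ("A-type", "non-A-type"):
            consensus[group] = {}
            for motif in ("I-helix", "ExxR", "PERF", "heme"):
                lf, rf = motifs_logo.GROUP_WINDOWS[(motif, group)]
                try:
                    aln = motifs_logo.build_motif_alignment(
                        full_calls.values(), motif, group, a_type_of,
                        left_flank=lf, right_flank=rf,
                    )
                except ValueError:
                    continue
                cols = motifs_logo.information_content(aln)
                consensus[group][motif] = motifs_logo.consensus_string(cols)
        report["stages"]["motifs"] = consensus
        (out / "consensus.json").write_text(
            json.dumps(consensus, indent=2, sort_keys=True)
        )

    # --- SSRs --------------------------------------------------------------
    hits_by_contig = {
        t.id: find_ssrs(t, config.ssr) for t in transcripts
    }
    summary = ssr_summary(hits_by_contig)
    report["stages"]["ssr"] = {
        k: v for k, v in summary.items() if k != "contigs_with_ssr"
    }
    write_tsv(
        ((h.contig_id, h.kind, h.unit, h.unit_len, h.repeats, h.start, h.end)
         for cid in sorted(hits_by_contig) for h in hits_by_contig[cid]),
        out / "ssr.tsv",
        header=("contig", "kind", "unit", "unit_len", "repeats", "start",
                "end"),
    )

    # --- published-table statistics ----------------------------------------
    stats = famstats.reproduce_published_stats()
    report["stages"]["table_stats"] = stats
    (out / "table_stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True)
    )

    # --- per-family trees and pairing statistic ----------------------------
    trees = {}
    if noms:
        # collapse allelic variants per species before tree building
        (out / "trees").mkdir(exist_ok=True)
        by_family: dict[str, list[ProteinRecord]] = {}
        for cid, call in sorted(full_calls.items()):
            fam = noms[cid].family
            by_family.setdefault(fam, []).append(
                ProteinRecord(id=cid, seq=call.protein.seq)
            )
        for fam in sorted(by_family):
            prots = by_family[fam]
            by_sp: dict[str, list[ProteinRecord]] = {}
            for p in prots:
                by_sp.setdefault(_species_of(p.id), []).append(p)
            reps: list[ProteinRecord] = []
            for sp in sorted(by_sp):
                cl = greedy_cluster(
                    by_sp[sp],
                    ClusterConfig(threshold=97.0, level="protein",
                                  kmer_prefilter=True),
                )
                reps.extend(c.representative for c in cl)
            if len(reps) < 4:
                continue
            dm = distance_matrix(sorted(reps, key=lambda p: p.id))
            tree = neighbor_joining(dm)
            write_newick(tree, out / "trees" / f"{fam}.nwk")
            species = {lbl: _species_of(lbl) for lbl in dm.labels}
            entry = {"n_leaves": len(dm.labels)}
            if {"spA", "spB"} <= set(species.values()):
                entry["pairing_spA_to_spB"] = pairing_statistic(
                    dm, species, "spA", "spB"
                )
            trees[fam] = entry
        report["stages"]["phylo"] = trees

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    return report
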