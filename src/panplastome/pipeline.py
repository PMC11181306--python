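"""End-to-end orchestration: structure -> annotation -> variants -> popgen
-> network -> markers, on real or simulated inputs, with one config and a
consolidated JSON report.

Stage outputs are pure functions of (inputs, config); the report body
contains no timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as pio
from .annotation import GeneModel, count_unique_genes, list_intron_genes, load_annotation
from .errors import ConfigError, InputError, PanPlastomeError
from .markers import clade_diagnostic_sites, rank_windows, sliding_window_diversity
from .network import annotate_composition, composition_shares, median_joining_network
from .popgen import (
    cluster_diversity,
    collapse_haplotypes,
    nj_tree,
    pairwise_distance_matrix,
    pairwise_fst,
    pca_coordinates,
)
from .structure import detect_quadripartite, structure_table_row
from .synthetic_data import (
    REFERENCE_ROW_ID,
    SimulationConfig,
    simulate_population,
    truth_check,
)
from .variants import (
    AlignmentMatrix,
    annotate_events,
    call_variant_events,
    collapse_ir_events,
    snv_matrix,
    summarize_variants,
)

logger = logging.getLogger("panplastome")

DEFAULT_PARAMS = {
    "min_ir_len": 1000,
    "ir_mismatch_rate": 0.0,
    "model": "tn93",
    "window": 600,
    "step": 200,
    "epsilon": 0,
    "collapse_ir": False,
    "rna_exon_separate": False,
}


@dataclass
class PipelineConfig:
    output_dir: str
    simulation: SimulationConfig | None = None
    fasta: str | None = None
    alignment: str | None = None
    annotation: str | None = None
    clusters: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_real = any([self.fasta, self.alignment, self.annotation, self.clusters])
        if (self.simulation is None) == (not has_real):
            raise ConfigError("specify exactly one of simulation or real inputs")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.get("simulation")
        inputs = raw.get("inputs", {})
        return cls(
            output_dir=raw.get("output_dir", "panplastome_out"),
            simulation=SimulationConfig(**sim) if sim is not None else None,
            fasta=inputs.get("fasta"),
            alignment=inputs.get("alignment"),
            annotation=inputs.get("annotation"),
            clusters=inputs.get("clusters"),
            params=raw.get("params", {}),
        )

    def canonical_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "inputs": {
                "fasta": self.fasta,
                "alignment": self.alignment,
                "annotation": self.annotation,
                "clusters": self.clusters,
            },
            "params": self.params,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.monotonic()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.monotonic() - self.t0
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all applicable stages in dependency order.

    Missing optional inputs (e.g. no cluster table) skip the dependent
    stages with a logged reason; hard input errors propagate.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    params = cfg.params
    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.simulation.seed if cfg.simulation else None,
        "skipped": {},
    }

    truth = None
    cluster_labels: dict[str, str] | None = None
    part = None
    model: GeneModel | None = None
    aln: AlignmentMatrix | None = None

    if cfg.simulation is not None:
        with _stage(report, "simulate"):
            sim = simulate_population(cfg.simulation)
        part, model, aln = sim.partition, sim.gene_model, sim.alignment
        cluster_labels = sim.cluster_labels
        truth = sim.truth
        sequences = [sim.ancestor]
        pio.write_fasta(
            [(REFERENCE_ROW_ID, sim.ancestor.residues)],
            os.path.join(cfg.output_dir, "ancestor.fasta"),
        )
        pio.write_fasta(
            [
                (sid, row.tobytes().decode().replace("-", ""))
                for sid, row in zip(aln.sample_ids, aln.matrix)
            ],
            os.path.join(cfg.output_dir, "sequences.fasta"),
        )
        pio.write_fasta(
            [(sid, row.tobytes().decode()) for sid, row in zip(aln.sample_ids, aln.matrix)],
            os.path.join(cfg.output_dir, "alignment.fasta"),
        )
        pio.write_gff3(model, os.path.join(cfg.output_dir, "annotation.gff3"))
        pio.write_clusters_tsv(
            cluster_labels, os.path.join(cfg.output_dir, "clusters.tsv")
        )
        with open(os.path.join(cfg.output_dir, "truth.json"), "w") as fh:
            fh.write(truth.to_json())
    else:
        sequences = (
            pio.read_fasta_sequences(cfg.fasta) if cfg.fasta else []
        )
        if cfg.alignment:
            aln = AlignmentMatrix.from_fasta(cfg.alignment)
        if cfg.clusters:
            cluster_labels = pio.read_clusters_tsv(cfg.clusters)

    # --- structure ---------------------------------------------------------
    if sequences:
        with _stage(report, "structure"):
            rows = []
            for seq in sequences:
                seq_part = detect_quadripartite(
                    seq, params["min_ir_len"], params["ir_mismatch_rate"]
                )
                rows.append(structure_table_row(seq, seq_part))
                if part is None:
                    part = seq_part
            report["structure"] = rows
    else:
        report["skipped"]["structure"] = "no input sequences"

    # --- annotation --------------------------------------------------------
    if cfg.simulation is None and cfg.annotation:
        if aln is None and not sequences:
            raise InputError("annotation requires a genome length source")
        genome_length = (
            len(sequences[0]) if sequences else aln.reference_length
        )
        model = load_annotation(cfg.annotation, genome_length, partition=part)
    if model is not None:
        with _stage(report, "annotation"):
            counts = count_unique_genes(model)
            report["annotation"] = {
                "unique_genes": {
                    k: counts[k] for k in ("total", "PCG", "tRNA", "rRNA")
                },
                "by_region": counts["by_region"],
                "intron_genes": list_intron_genes(model),
            }
    else:
        report["skipped"]["annotation"] = "no annotation provided"

    if aln is None:
        report["skipped"]["variants"] = "no alignment provided"
        _finalize(cfg, report)
        return report

    # --- variants ----------------------------------------------------------
    with _stage(report, "variants"):
        events = call_variant_events(aln)
        events = annotate_events(
            events, part, model, rna_exon_separate=params["rna_exon_separate"]
        )
        if params["collapse_ir"] and part is not None:
            events = collapse_ir_events(events, part)
        summary = summarize_variants(events)
        pio.write_events_tsv(events, os.path.join(cfg.output_dir, "events.tsv"))
        report["variants"] = {
            "total": summary.total,
            "by_category": summary.by_category,
            "category_shares": summary.category_shares,
            "by_region": summary.by_region,
            "region_shares": summary.region_shares,
            "by_context": summary.by_context,
            "context_shares": summary.context_shares,
            "per_gene": summary.per_gene,
        }
    if truth is not None:
        report["truth_check"] = truth_check(truth, events)

    # --- popgen ------------------------------------------------------------
    sample_ids = [s for s in aln.sample_ids if s != REFERENCE_ROW_ID]
    with _stage(report, "popgen"):
        hs = collapse_haplotypes(aln, sample_ids)
        pio.write_haplotypes_tsv(hs, os.path.join(cfg.output_dir, "haplotypes.tsv"))
        report["popgen"] = {
            "n_samples": len(sample_ids),
            "n_haplotypes": len(hs.haplotypes),
        }
        sub, _ = snv_matrix(aln)
        if sub.shape[1] >= 1 and len(sample_ids) >= 3:
            keep = [i for i, s in enumerate(aln.sample_ids) if s != REFERENCE_ROW_ID]
            coords, evr = pca_coordinates(sub[keep])
            report["popgen"]["pca_explained_variance"] = [
                round(float(v), 6) for v in evr[:5]
            ]
        if cluster_labels is not None:
            clusters: dict[str, list[str]] = {}
            for s in sample_ids:
                if s in cluster_labels:
                    clusters.setdefault(cluster_labels[s], []).append(s)
            stats = cluster_diversity(aln, clusters)
            report["popgen"]["clusters"] = {
                lbl: {"n": st.n, "h": st.h, "hd": round(st.hd, 6),
                      "pi": round(st.pi, 8)}
                for lbl, st in sorted(stats.items())
            }
            fst: dict[str, float | None] = {}
            labels = sorted(clusters)
            for i, a in enumerate(labels):
                for b in labels[i + 1:]:
                    if len(clusters[a]) < 2 or len(clusters[b]) < 2:
                        continue
                    value = pairwise_fst(aln, clusters[a], clusters[b],
                                         model=params["model"])
                    fst[f"{a}|{b}"] = (
                        None if np.isnan(value) else round(float(value), 6)
                    )
            report["popgen"]["fst"] = fst
        if len(hs.haplotypes) >= 3:
            reps = np.array(
                [np.frombuffer(h.sequence.encode(), dtype="S1")
                 for h in hs.haplotypes]
            )
            dm = pairwise_distance_matrix(
                reps, [h.haplotype_id for h in hs.haplotypes], model=params["model"]
            )
            tree = nj_tree(dm)
            newick = str(tree)
            with open(os.path.join(cfg.output_dir, "haplotypes.nwk"), "w") as fh:
                fh.write(newick)
            report["popgen"]["nj_newick"] = newick.strip()

    # --- network -----------------------------------------------------------
    with _stage(report, "network"):
        net = median_joining_network(hs, epsilon=params["epsilon"])
        if cluster_labels is not None:
            net = annotate_composition(
                net, {s: cluster_labels[s] for s in sample_ids}
            )
            compositions = {
                n: composition_shares(d.get("composition", {}))
                for n, d in net.graph.nodes(data=True)
                if not d["is_median"]
            }
        else:
            compositions = {}
        report["network"] = {
            "n_nodes": net.graph.number_of_nodes(),
            "n_medians": len(net.median_nodes),
            "edges": net.edge_list(),
            "total_cost": net.total_cost(),
            "compositions": compositions,
        }

    # --- markers -----------------------------------------------------------
    with _stage(report, "markers"):
        windows = sliding_window_diversity(
            aln, params["window"], params["step"], events
        )
        top = rank_windows(windows)[:10]
        report["markers"] = {
            "top_windows": [
                {"start": w.window_start, "end": w.window_end,
                 "pi": round(w.pi, 8), "variants": w.variant_count}
                for w in top
            ]
        }
        if cluster_labels is not None:
            sites = clade_diagnostic_sites(
                aln,
                {s: cluster_labels[s] for s in sample_ids},
                events=events,
                model=model,
            )
            report["markers"]["diagnostic_sites"] = [
                {"aln_column": s.aln_column, "ref_position": s.ref_position,
                 "kind": s.site_kind, "clades": list(s.target_clades),
                 "allele": s.allele, "locus": s.locus_label}
                for s in sites
            ]
        else:
            report["skipped"]["diagnostic_sites"] = "no cluster table"

    _finalize(cfg, report)
    return report


def _finalize(cfg: PipelineConfig, report: dict) -> None:
    pio.write_json(report, os.path.join(cfg.output_dir, "report.json"))
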