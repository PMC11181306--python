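"""Seeded generator of plastome populations with planted, machine-readable
truth.

Builds an ancestral quadripartite genome (LSC + IRb + SSC + revcomp(IRb)),
a non-overlapping gene model (with an IR-duplicated gene pair when room
allows), a star genealogy of genetic clusters, and a gapped "true alignment"
carrying planted variant events of all four categories. Event spacing is
enforced so the variant caller can recover the planted events exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import CONTEXT_NAMES, GeneFeature, GeneModel, genic_context_index
from .errors import ConfigError
from .structure import PlastomeSequence, QuadripartitePartition, revcomp
from .variants import AlignmentMatrix, VariantEvent

_BASES = np.array(list("ACGT"))

CATEGORY_ORDER = ("SNV", "InDel", "BlockSub", "Mixed")

REFERENCE_ROW_ID = "ancestor"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_clusters: int = 3
    samples_per_cluster: tuple[int, ...] = (4, 4, 4)
    region_lengths: tuple[int, int, int] = (6000, 1500, 1000)  # lsc, ir, ssc
    n_genes: int = 8
    events_per_branch: dict[str, int] = field(
        default_factory=lambda: {"SNV": 4, "InDel": 2, "BlockSub": 1, "Mixed": 1}
    )
    indel_length: tuple[float, int] = (0.5, 6)  # geometric p, max
    blocksub_length: tuple[float, int] = (0.5, 5)  # min 2
    min_event_spacing: int = 3
    within_cluster_extra_snvs: tuple[int, ...] | int = 0
    boundary_margin: int = 2
    allow_boundary_events: bool = False
    include_reference_row: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.samples_per_cluster, int):
            self.samples_per_cluster = (self.samples_per_cluster,) * self.n_clusters
        self.samples_per_cluster = tuple(self.samples_per_cluster)
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ConfigError("samples_per_cluster length != n_clusters")
        if isinstance(self.within_cluster_extra_snvs, int):
            self.within_cluster_extra_snvs = (
                self.within_cluster_extra_snvs,
            ) * self.n_clusters
        self.within_cluster_extra_snvs = tuple(self.within_cluster_extra_snvs)
        if len(self.within_cluster_extra_snvs) != self.n_clusters:
            raise ConfigError("within_cluster_extra_snvs length != n_clusters")
        lsc, ir, ssc = self.region_lengths
        if not (lsc > ssc > 0 and ir > 0):
            raise ConfigError("require lsc > ssc > 0 and ir > 0")
        if self.min_event_spacing < 3:
            raise ConfigError("min_event_spacing must be >= 3 for recoverability")
        for cat in self.events_per_branch:
            if cat not in CATEGORY_ORDER:
                raise ConfigError(f"unknown event category {cat!r}")

    @property
    def genome_length(self) -> int:
        lsc, ir, ssc = self.region_lengths
        return lsc + 2 * ir + ssc

    def max_event_span(self, category: str) -> int:
        if category == "SNV":
            return 1
        if category == "InDel":
            return self.indel_length[1]
        if category == "BlockSub":
            return self.blocksub_length[1]
        return 1 + self.indel_length[1]  # Mixed

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_clusters": self.n_clusters,
            "samples_per_cluster": list(self.samples_per_cluster),
            "region_lengths": list(self.region_lengths),
            "n_genes": self.n_genes,
            "events_per_branch": dict(self.events_per_branch),
            "indel_length": list(self.indel_length),
            "blocksub_length": list(self.blocksub_length),
            "min_event_spacing": self.min_event_spacing,
            "within_cluster_extra_snvs": list(self.within_cluster_extra_snvs),
            "boundary_margin": self.boundary_margin,
            "allow_boundary_events": self.allow_boundary_events,
            "include_reference_row": self.include_reference_row,
        }


@dataclass
class PlantedEvent:
    event_id: str
    category: str
    columns: tuple[int, int]  # half-open alignment columns
    carriers: tuple[str, ...]
    region: str | None = None
    context: str | None = None


@dataclass
class SimulationTruth:
    events: list[PlantedEvent]
    cluster_labels: dict[str, str]
    tree_newick: str
    config: SimulationConfig

    def expected_summary(self) -> dict[str, dict[str, int]]:
        by_cat: dict[str, int] = {c: 0 for c in CATEGORY_ORDER}
        by_region: dict[str, int] = {}
        by_context: dict[str, int] = {}
        for ev in self.events:
            by_cat[ev.category] += 1
            if ev.region:
                by_region[ev.region] = by_region.get(ev.region, 0) + 1
            if ev.context:
                by_context[ev.context] = by_context.get(ev.context, 0) + 1
        return {"by_category": by_cat, "by_region": by_region,
                "by_context": by_context}

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "cluster_labels": self.cluster_labels,
                "tree_newick": self.tree_newick,
                "events": [
                    {
                        "event_id": ev.event_id,
                        "category": ev.category,
                        "columns": list(ev.columns),
                        "carriers": list(ev.carriers),
                        "region": ev.region,
                        "context": ev.context,
                    }
                    for ev in self.events
                ],
                "expected_summary": self.expected_summary(),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SimulationResult:
    config: SimulationConfig
    ancestor: PlastomeSequence
    partition: QuadripartitePartition
    gene_model: GeneModel
    alignment: AlignmentMatrix
    cluster_labels: dict[str, str]
    truth: SimulationTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _bounded_geometric(rng: np.random.Generator, p: float, maximum: int,
                       minimum: int = 1) -> int:
    return int(min(max(rng.geometric(p), minimum), maximum))


def _build_gene_model(cfg: SimulationConfig, rng: np.random.Generator,
                      part: QuadripartitePartition) -> GeneModel:
    """Place non-overlapping genes region by region.

    One rRNA gene is duplicated across the IRs (same name, mirrored exons)
    when at least four genes are requested; one gene goes to the SSC; the
    rest fill the LSC.
    """
    features: list[GeneFeature] = []
    margin = cfg.boundary_margin + 20

    def place_in(interval: tuple[int, int], n: int, name_prefix: str,
                 categories: list[str]) -> list[GeneFeature]:
        placed: list[GeneFeature] = []
        cursor = interval[0] + margin
        for g in range(n):
            n_exons = int(rng.integers(1, 4))
            exon_lens = [int(rng.integers(60, 200)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(30, 80)) for _ in range(n_exons - 1)]
            gap = int(rng.integers(30, 120))
            start = cursor + gap
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el
                if i < len(intron_lens):
                    pos += intron_lens[i]
            if pos > interval[1] - margin:
                raise ConfigError("gene model does not fit in region; "
                                  "reduce n_genes or enlarge regions")
            cursor = pos
            placed.append(
                GeneFeature(
                    name=f"{name_prefix}{len(features) + len(placed) + 1:02d}",
                    category=categories[g % len(categories)],
                    strand="+",
                    exons=exons,
                )
            )
        return placed

    n = cfg.n_genes
    ir_gene = n >= 4
    ssc_genes = 1 if n >= 3 else 0
    lsc_genes = n - ssc_genes - (1 if ir_gene else 0)
    features.extend(place_in(part.lsc, lsc_genes, "pcg", ["PCG", "PCG", "tRNA"]))
    if ssc_genes:
        features.extend(place_in(part.ssc, ssc_genes, "sscg", ["PCG"]))
    if ir_gene:
        irb_feat = place_in(part.irb, 1, "rrn", ["rRNA"])[0]
        irb_s, irb_e = part.irb
        ira_s = part.ira[0]
        mirrored = [
            (ira_s + (irb_e - e), ira_s + (irb_e - s)) for s, e in irb_feat.exons
        ]
        features.append(
            GeneFeature(name=irb_feat.name, category="rRNA", strand="-",
                        exons=mirrored)
        )
        features.insert(len(features) - 1, irb_feat)
    return GeneModel(features=features, genome_length=part.total_length,
                     partition=part)


class _EventPlacer:
    """Non-overlapping event placement with spacing and boundary margins."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []
        total = cfg.genome_length
        self.forbidden: list[tuple[int, int]] = []
        if not cfg.allow_boundary_events:
            lsc, ir, ssc = cfg.region_lengths
            m = cfg.boundary_margin
            for b in (0, lsc, lsc + ir, lsc + ir + ssc, total):
                self.forbidden.append((max(0, b - m), min(total, b + m)))

    def place(self, length: int) -> int:
        total = self.cfg.genome_length
        spacing = self.cfg.min_event_spacing
        for _ in range(2000):
            start = int(self.rng.integers(0, total - length))
            end = start + length
            if any(start < fe and fs < end for fs, fe in self.forbidden):
                continue
            if any(start < oe + spacing and os_ < end + spacing
                   for os_, oe in self.occupied):
                continue
            self.occupied.append((start, end))
            return start
        raise ConfigError("could not place event; config too dense")


def simulate_population(cfg: SimulationConfig) -> SimulationResult:
    """Generate a plastome population with planted variant events.

    The same seed yields byte-identical outputs: a single RNG stream drawn
    in documented order (genome, genes, then events cluster by cluster in
    fixed category order, then per-sample private SNVs).
    """
    rng = np.random.default_rng(cfg.seed)
    total = cfg.genome_length
    # feasibility before any generation
    per_branch_span = sum(
        count * (cfg.max_event_span(cat) + cfg.min_event_spacing)
        for cat, count in cfg.events_per_branch.items()
    )
    needed = cfg.n_clusters * per_branch_span + sum(
        extra * (1 + cfg.min_event_spacing) * k
        for extra, k in zip(cfg.within_cluster_extra_snvs, cfg.samples_per_cluster)
    )
    if needed > 0.6 * total:
        raise ConfigError(
            f"events x spacing ({needed}) exceed 60% of genome ({total})"
        )

    lsc_len, ir_len, ssc_len = cfg.region_lengths
    lsc = _random_seq(rng, lsc_len)
    irb = _random_seq(rng, ir_len)
    ssc = _random_seq(rng, ssc_len)
    genome = lsc + irb + ssc + revcomp(irb)
    part = QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, total),
    )
    ancestor = PlastomeSequence(REFERENCE_ROW_ID, genome)
    model = _build_gene_model(cfg, rng, part)

    clusters = [f"cluster{i + 1}" for i in range(cfg.n_clusters)]
    samples: list[str] = []
    cluster_labels: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for label, size in zip(clusters, cfg.samples_per_cluster):
        members[label] = []
        for j in range(size):
            sid = f"{label}_s{j + 1:02d}"
            samples.append(sid)
            cluster_labels[sid] = label
            members[label].append(sid)

    rows = {s: np.frombuffer(genome.encode(), dtype="S1").copy() for s in samples}
    placer = _EventPlacer(cfg, rng)
    events: list[PlantedEvent] = []
    ctx = genic_context_index(model)

    def other_base(base: bytes) -> bytes:
        choices = [b for b in b"ACGT" if bytes([b]) != base]
        return bytes([choices[int(rng.integers(0, 3))]])

    def plant(category: str, carriers: list[str]) -> None:
        if category == "SNV":
            length = 1
        elif category == "InDel":
            length = _bounded_geometric(rng, *cfg.indel_length)
        elif category == "BlockSub":
            length = _bounded_geometric(rng, cfg.blocksub_length[0],
                                        cfg.blocksub_length[1], minimum=2)
        else:  # Mixed: one substituted column then a gap run
            length = 1 + _bounded_geometric(rng, *cfg.indel_length)
        start = placer.place(length)
        end = start + length
        if category in ("SNV", "BlockSub"):
            for col in range(start, end):
                new = other_base(genome[col].encode())
                for s in carriers:
                    rows[s][col] = new
        elif category == "InDel":
            for s in carriers:
                rows[s][start:end] = b"-"
        else:
            new = other_base(genome[start].encode())
            for s in carriers:
                rows[s][start] = new
                rows[s][start + 1 : end] = b"-"
        events.append(
            PlantedEvent(
                event_id=f"ev{len(events) + 1:04d}",
                category=category,
                columns=(start, end),
                carriers=tuple(carriers),
                region=part.region_of(start),
                context=CONTEXT_NAMES[int(ctx[start])],
            )
        )

    for label in clusters:
        for category in CATEGORY_ORDER:
            for _ in range(cfg.events_per_branch.get(category, 0)):
                plant(category, members[label])
    for label, extra in zip(clusters, cfg.within_cluster_extra_snvs):
        for sample in members[label]:
            for _ in range(extra):
                plant("SNV", [sample])

    records: list[tuple[str, str]] = []
    if cfg.include_reference_row:
        records.append((REFERENCE_ROW_ID, genome))
    records.extend((s, rows[s].tobytes().decode()) for s in samples)
    alignment = AlignmentMatrix.from_sequences(records, ref_index=0)

    newick = (
        "("
        + ",".join(
            "(" + ",".join(members[label]) + ")" + label for label in clusters
        )
        + ")root;"
    )
    truth = SimulationTruth(
        events=events,
        cluster_labels=cluster_labels,
        tree_newick=newick,
        config=cfg,
    )
    return SimulationResult(
        config=cfg,
        ancestor=ancestor,
        partition=part,
        gene_model=model,
        alignment=alignment,
        cluster_labels=cluster_labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# truth checking


def truth_check(
    truth: SimulationTruth,
    observed_events: list[VariantEvent],
    observed_clusters: dict[str, str] | None = None,
) -> dict:
    """Exact-match report of planted vs called events, plus adjusted-Rand
    agreement between true and observed cluster labelings when given."""
    planted = {(ev.columns, ev.category) for ev in truth.events}
    called = {(ev.columns, ev.category) for ev in observed_events}
    planted_spans = {ev.columns: ev.category for ev in truth.events}
    called_spans = {ev.columns: ev.category for ev in observed_events}
    category_mismatches = sorted(
        {
            (span, planted_spans[span], called_spans[span])
            for span in set(planted_spans) & set(called_spans)
            if planted_spans[span] != called_spans[span]
        }
    )
    report = {
        "n_planted": len(truth.events),
        "n_called": len(observed_events),
        "matched": len(planted & called),
        "missing": sorted(planted - called),
        "spurious": sorted(called - planted),
        "category_mismatches": category_mismatches,
        "all_match": planted == called and len(truth.events) == len(observed_events),
    }
    if observed_clusters is not None:
        from sklearn.metrics import adjusted_rand_score

        samples = sorted(truth.cluster_labels)
        true_labels = [truth.cluster_labels[s] for s in samples]
        obs_labels = [observed_clusters[s] for s in samples]
        report["cluster_agreement"] = float(
            adjusted_rand_score(true_labels, obs_labels)
        )
    return report


def tree_cut_labels(tree, k: int) -> dict[str, str]:
    """Cut a tree into k clusters by average-linkage on tip-to-tip distances."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    condensed = squareform(dm.data, checks=False)
    assign = fcluster(linkage(condensed, method="average"), k, criterion="maxclust")
    return {lbl: f"cut{c}" for lbl, c in zip(labels, assign)}
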