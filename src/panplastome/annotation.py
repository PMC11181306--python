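"""Gene annotation loading, unique-gene counting, and genic-context indexing.

Accepts GenBank flat files (via Biopython) or GFF3 (via gffutils). Genes
duplicated across the two inverted repeats share a name and are counted once;
every genome position is assigned exactly one genic context (CDS, intron, or
IGS) with priority CDS > intron > IGS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError
from .structure import QuadripartitePartition

CONTEXT_IGS = 0
CONTEXT_INTRON = 1
CONTEXT_CDS = 2
CONTEXT_RNA_EXON = 3

CONTEXT_NAMES = {CONTEXT_IGS: "IGS", CONTEXT_INTRON: "intron", CONTEXT_CDS: "CDS",
                 CONTEXT_RNA_EXON: "RNA_exon"}

_CATEGORY_BY_FEATURE_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
_SILENT_FEATURE_TYPES = {"gene", "mRNA", "exon", "intron", "source", "region", "misc_feature"}

# joins wider than this are treated as trans-splicing, not introns, in the
# positional context index (plastid introns are < ~3 kb)
DEFAULT_MAX_INTRON = 10_000


@dataclass
class GeneFeature:
    """One annotated gene copy with its exon intervals (0-based half-open)."""

    name: str
    category: str  # PCG | tRNA | rRNA
    strand: str
    exons: list[tuple[int, int]]
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if self.category not in ("PCG", "tRNA", "rRNA"):
            raise AnnotationError(f"{self.name}: unknown category {self.category!r}")
        if not self.exons:
            raise AnnotationError(f"{self.name}: feature has no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.name}: overlapping exons")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GeneModel:
    features: list[GeneFeature]
    genome_length: int
    partition: QuadripartitePartition | None = None


def load_annotation(path: str, genome_length: int,
                    partition: QuadripartitePartition | None = None) -> GeneModel:
    """Load a GenBank flat file or GFF3 into a :class:`GeneModel`.

    Coordinates are converted to 0-based half-open. Unknown feature types are
    skipped with a warning; features extending past ``genome_length`` raise.
    """
    with open(path) as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line
                break
    if head.startswith("LOCUS"):
        features = _load_genbank(path)
    else:
        features = _load_gff3(path)
    for feat in features:
        if feat.span[1] > genome_length or feat.span[0] < 0:
            raise AnnotationError(
                f"{feat.name}: coordinates {feat.span} outside genome "
                f"[0, {genome_length})"
            )
    return GeneModel(features=features, genome_length=genome_length, partition=partition)


def _load_genbank(path: str) -> list[GeneFeature]:
    from Bio import SeqIO

    try:
        record = next(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # noqa: BLE001 - surface as our own error type
        raise AnnotationError(f"unparseable GenBank file {path}: {exc}") from exc
    features: list[GeneFeature] = []
    for feat in record.features:
        category = _CATEGORY_BY_FEATURE_TYPE.get(feat.type)
        if category is None:
            if feat.type not in _SILENT_FEATURE_TYPES:
                warnings.warn(f"skipping unknown feature type {feat.type!r}")
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        exons = [(int(p.start), int(p.end)) for p in feat.location.parts]
        trans = "trans_splicing" in quals or (
            "exception" in quals and "trans-splicing" in quals["exception"]
        )
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, category, strand, exons, trans))
    return features


def _load_gff3(path: str) -> list[GeneFeature]:
    import gffutils

    try:
        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # noqa: BLE001
        raise AnnotationError(f"unparseable GFF3 file {path}: {exc}") from exc
    seen_types = set()
    groups: dict[str, dict] = {}
    for feat in db.all_features():
        category = _CATEGORY_BY_FEATURE_TYPE.get(feat.featuretype)
        if category is None:
            if feat.featuretype not in _SILENT_FEATURE_TYPES and feat.featuretype not in seen_types:
                seen_types.add(feat.featuretype)
                warnings.warn(f"skipping unknown feature type {feat.featuretype!r}")
            continue
        parent = (feat.attributes.get("Parent") or feat.attributes.get("ID") or [feat.id])[0]
        # strip gffutils uniquification suffix so segments regroup
        parent = parent.rsplit("_", 1)[0] if parent.rsplit("_", 1)[-1].isdigit() else parent
        name = (feat.attributes.get("gene") or feat.attributes.get("Name") or [parent])[0]
        entry = groups.setdefault(
            parent,
            {"name": name, "category": category, "strand": feat.strand, "exons": [],
             "trans": False},
        )
        entry["exons"].append((feat.start - 1, feat.end))
        attrs = feat.attributes
        if "exception" in attrs and "trans-splicing" in attrs["exception"]:
            entry["trans"] = True
    return [
        GeneFeature(g["name"], g["category"], g["strand"] or "+", g["exons"], g["trans"])
        for g in groups.values()
    ]


# ---------------------------------------------------------------------------
# counting


def _region_overlap(exons: list[tuple[int, int]], interval: tuple[int, int]) -> int:
    lo, hi = interval
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in exons)


def gene_region(feature_exons: list[tuple[int, int]],
                part: QuadripartitePartition) -> str:
    """Majority-overlap placement of a gene into LSC, SSC, or IR."""
    overlaps = {
        "LSC": _region_overlap(feature_exons, part.lsc),
        "SSC": _region_overlap(feature_exons, part.ssc),
        "IR": _region_overlap(feature_exons, part.irb)
        + _region_overlap(feature_exons, part.ira),
    }
    # deterministic tie-break by fixed region order
    return max(("LSC", "SSC", "IR"), key=lambda r: overlaps[r])


def count_unique_genes(model: GeneModel) -> dict:
    """Gene counts with IR-duplicated copies (same name) counted once.

    Placement per unique gene uses majority exon overlap across all copies.
    Name matching is case-insensitive.
    """
    by_name: dict[str, list[GeneFeature]] = {}
    order: list[str] = []
    for feat in model.features:
        key = feat.name.lower()
        if key not in by_name:
            order.append(key)
        by_name.setdefault(key, []).append(feat)

    counts = {"total": 0, "PCG": 0, "tRNA": 0, "rRNA": 0}
    by_region: dict[str, dict[str, int]] = {
        r: {"total": 0, "PCG": 0, "tRNA": 0, "rRNA": 0} for r in ("LSC", "SSC", "IR")
    }
    placements: dict[str, str | None] = {}
    for key in order:
        copies = by_name[key]
        category = copies[0].category
        counts["total"] += 1
        counts[category] += 1
        region: str | None = None
        if model.partition is not None:
            all_exons = [e for c in copies for e in c.exons]
            region = gene_region(all_exons, model.partition)
            by_region[region]["total"] += 1
            by_region[region][category] += 1
        placements[copies[0].name] = region
    result = dict(counts)
    result["by_region"] = by_region if model.partition is not None else {}
    result["placements"] = placements
    return result


def genic_context_index(
    model: GeneModel,
    rna_exon_separate: bool = False,
    max_intron: int = DEFAULT_MAX_INTRON,
) -> np.ndarray:
    """Context code (CDS/intron/IGS) for every genome position.

    Exons of tRNA/rRNA genes fall in the CDS (exonic) bucket unless
    ``rna_exon_separate`` is set. Inter-exon gaps wider than ``max_intron``
    in trans-spliced genes are not marked as introns.
    """
    ctx = np.zeros(model.genome_length, dtype=np.uint8)
    for feat in model.features:  # introns first, exons overwrite
        for (s0, e0), (s1, _) in zip(feat.exons, feat.exons[1:]):
            if feat.trans_spliced and (s1 - e0) > max_intron:
                continue
            ctx[e0:s1] = np.maximum(ctx[e0:s1], CONTEXT_INTRON)
    for feat in model.features:
        code = CONTEXT_CDS
        if rna_exon_separate and feat.category in ("tRNA", "rRNA"):
            code = CONTEXT_RNA_EXON
        for s, e in feat.exons:
            ctx[s:e] = np.maximum(ctx[s:e], code) if code != CONTEXT_RNA_EXON else CONTEXT_RNA_EXON
    return ctx


def gene_position_index(model: GeneModel,
                        max_intron: int = DEFAULT_MAX_INTRON) -> tuple[np.ndarray, list[str]]:
    """Per-position gene attribution: array of indices into the returned name
    list, -1 where no gene covers the position. Exonic coverage beats intronic
    coverage of another gene; later features do not overwrite earlier exons.
    """
    idx = np.full(model.genome_length, -1, dtype=np.int32)
    exonic = np.zeros(model.genome_length, dtype=bool)
    names: list[str] = []
    for fi, feat in enumerate(model.features):
        names.append(feat.name)
        for (_, e0), (s1, _) in zip(feat.exons, feat.exons[1:]):
            if feat.trans_spliced and (s1 - e0) > max_intron:
                continue
            sub = idx[e0:s1]
            sub[~exonic[e0:s1] & (sub == -1)] = fi
        for s, e in feat.exons:
            sub = idx[s:e]
            sub[~exonic[s:e]] = fi
            exonic[s:e] = True
    return idx, names


def list_intron_genes(model: GeneModel) -> list[dict]:
    """Unique genes with at least one intron, sorted by name.

    Trans-spliced genes are flagged; intron count is (#exons - 1) over all
    segments of one copy (the copy with the most exons wins for duplicates).
    """
    best: dict[str, GeneFeature] = {}
    for feat in model.features:
        key = feat.name.lower()
        if key not in best or feat.n_introns > best[key].n_introns:
            best[key] = feat
    out = []
    for key in sorted(best):
        feat = best[key]
        if feat.n_introns >= 1:
            out.append(
                {"gene": feat.name, "n_introns": feat.n_introns,
                 "trans_spliced": feat.trans_spliced}
            )
    return out
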