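"""Variant-event calling on a plastome multiple alignment.

Maximal runs of contiguous non-invariant columns are merged into single
events and classified with a four-way typology:

* ``SNV`` — a single substituted column;
* ``BlockSub`` — two or more consecutive substituted columns;
* ``InDel`` — a maximal run of gap-containing columns;
* ``Mixed`` — a run containing both substituted and gap columns.

Columns whose only variation involves N or ambiguity codes are invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import (
    CONTEXT_NAMES,
    DEFAULT_MAX_INTRON,
    GeneModel,
    gene_position_index,
    genic_context_index,
)
from .errors import InputError
from .structure import QuadripartitePartition

COL_INVARIANT = 0
COL_SUBSTITUTION = 1
COL_GAP = 2

_BASES = (b"A", b"C", b"G", b"T")

CATEGORIES = ("SNV", "InDel", "BlockSub", "Mixed")


@dataclass
class AlignmentMatrix:
    """A character matrix over {A,C,G,T,N,-,ambiguity} with a coordinate
    reference row.

    ``column_to_ref_pos`` maps each alignment column to a reference genome
    position; columns where the reference holds a gap map to the preceding
    reference position (-1 before the first reference base).
    """

    sample_ids: list[str]
    matrix: np.ndarray  # (n_samples, n_columns), dtype 'S1', uppercase
    ref_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise InputError("alignment matrix must be 2-D")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise InputError("sample_ids length does not match matrix rows")
        if self.matrix.shape[0] < 2:
            raise InputError("alignment needs at least 2 rows")
        self.matrix = np.char.upper(self.matrix)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def column_to_ref_pos(self) -> np.ndarray:
        ref_row = self.matrix[self.ref_index]
        not_gap = ref_row != b"-"
        return np.cumsum(not_gap) - 1

    @property
    def reference_length(self) -> int:
        return int((self.matrix[self.ref_index] != b"-").sum())

    @classmethod
    def from_sequences(cls, records: list[tuple[str, str]], ref_index: int = 0
                       ) -> "AlignmentMatrix":
        if len({len(s) for _, s in records}) > 1:
            raise InputError("alignment rows have unequal lengths")
        ids = [name for name, _ in records]
        mat = np.array([list(s.upper()) for _, s in records], dtype="S1")
        return cls(ids, mat, ref_index)

    @classmethod
    def from_fasta(cls, path: str, ref_id: str | None = None) -> "AlignmentMatrix":
        from Bio import SeqIO

        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
        if not records:
            raise InputError(f"no records in alignment {path}")
        ref_index = 0
        if ref_id is not None:
            ids = [r[0] for r in records]
            if ref_id not in ids:
                raise InputError(f"reference id {ref_id!r} not in alignment")
            ref_index = ids.index(ref_id)
        return cls.from_sequences(records, ref_index)

    def rows(self, sample_ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            take = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise InputError(f"unknown sample {exc.args[0]!r}") from exc
        return self.matrix[take]


@dataclass
class VariantEvent:
    """One merged variant locus (half-open alignment-column interval)."""

    columns: tuple[int, int]
    category: str
    alleles: tuple[str, ...]
    ref_start: int = -1
    ref_end: int = -1
    region: str | None = None
    context: str | None = None
    gene: str | None = None
    spans_boundary: bool = False
    ir_collapsed: bool = False

    @property
    def length(self) -> int:
        return self.columns[1] - self.columns[0]


@dataclass
class VariantSummary:
    total: int
    by_category: dict[str, int]
    by_region: dict[str, int]
    by_context: dict[str, int]
    per_gene: dict[str, dict[str, int]]
    category_shares: dict[str, float]
    region_shares: dict[str, float]
    context_shares: dict[str, float]


def scan_columns(aln: AlignmentMatrix) -> np.ndarray:
    """Per-column state: gap if any row holds '-', substitution if gap-free
    with >= 2 distinct unambiguous states, else invariant."""
    mat = aln.matrix
    gap = (mat == b"-").any(axis=0)
    n_states = np.zeros(aln.n_columns, dtype=np.int8)
    for base in _BASES:
        n_states += (mat == base).any(axis=0)
    states = np.where(gap, COL_GAP, np.where(n_states >= 2, COL_SUBSTITUTION, COL_INVARIANT))
    return states.astype(np.int8)


def call_variant_events(aln: AlignmentMatrix) -> list[VariantEvent]:
    """Merge maximal runs of non-invariant columns into classified events."""
    states = scan_columns(aln)
    variant = states != COL_INVARIANT
    if not variant.any():
        return []
    padded = np.concatenate(([False], variant, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    col_ref = aln.column_to_ref_pos
    events: list[VariantEvent] = []
    for start, end in zip(starts, ends):
        run = states[start:end]
        has_sub = (run == COL_SUBSTITUTION).any()
        has_gap = (run == COL_GAP).any()
        if has_sub and has_gap:
            category = "Mixed"
        elif has_gap:
            category = "InDel"
        elif end - start == 1:
            category = "SNV"
        else:
            category = "BlockSub"
        block = aln.matrix[:, start:end]
        alleles = tuple(sorted({row.tobytes().decode() for row in block}))
        events.append(
            VariantEvent(
                columns=(int(start), int(end)),
                category=category,
                alleles=alleles,
                ref_start=int(col_ref[start]),
                ref_end=int(col_ref[end - 1]) + 1,
            )
        )
    return events


def annotate_events(
    events: list[VariantEvent],
    part: QuadripartitePartition | None = None,
    model: GeneModel | None = None,
    rna_exon_separate: bool = False,
) -> list[VariantEvent]:
    """Attach region / genic context / gene to each event.

    Assignment uses the reference position of the event's first column;
    events whose span crosses a region or context boundary are flagged.
    Reference coordinates are assumed to be on the canonical rotation.
    """
    ctx = gene_idx = gene_names = None
    if model is not None:
        ctx = genic_context_index(model, rna_exon_separate=rna_exon_separate)
        gene_idx, gene_names = gene_position_index(model)
    out: list[VariantEvent] = []
    for ev in events:
        region = context = gene = None
        spans = False
        first = max(ev.ref_start, 0)
        last = max(ev.ref_end - 1, 0)
        if part is not None:
            region = part.region_of(first)
            spans = spans or part.region_of(last) != region
        if ctx is not None:
            context = CONTEXT_NAMES[int(ctx[first])]
            spans = spans or CONTEXT_NAMES[int(ctx[last])] != context
            gi = int(gene_idx[first])
            gene = gene_names[gi] if gi >= 0 else None
        out.append(replace(ev, region=region, context=context, gene=gene,
                           spans_boundary=spans))
    return out


def _mirror_interval(part: QuadripartitePartition, start: int, end: int
                     ) -> tuple[int, int]:
    """Map a reference interval inside IRb to its mirror in IRa (and back)."""
    irb_s, irb_e = part.irb
    ira_s, ira_e = part.ira
    if irb_s <= start and end <= irb_e:
        return (ira_s + (irb_e - end), ira_s + (irb_e - start))
    if ira_s <= start and end <= ira_e:
        return (irb_s + (ira_e - end), irb_s + (ira_e - start))
    raise InputError("interval not contained in a single IR copy")


def collapse_ir_events(events: list[VariantEvent],
                       part: QuadripartitePartition) -> list[VariantEvent]:
    """Merge mirror-position IR event pairs, keeping the IRb-side copy.

    Two events are mirrors when they have the same category and exactly
    mirrored reference intervals in the two IR copies.
    """
    irb_events: dict[tuple[int, int, str], int] = {}
    for i, ev in enumerate(events):
        s, e = ev.ref_start, ev.ref_end
        if part.irb[0] <= s and e <= part.irb[1]:
            irb_events[(s, e, ev.category)] = i
    dropped: set[int] = set()
    collapsed_partners: set[int] = set()
    for i, ev in enumerate(events):
        s, e = ev.ref_start, ev.ref_end
        if part.ira[0] <= s and e <= part.ira[1]:
            mirror = _mirror_interval(part, s, e)
            j = irb_events.get((mirror[0], mirror[1], ev.category))
            if j is not None:
                dropped.add(i)
                collapsed_partners.add(j)
    return [
        replace(ev, ir_collapsed=True) if i in collapsed_partners else ev
        for i, ev in enumerate(events)
        if i not in dropped
    ]


def percentage_shares(counts: dict[str, int], total: int | None = None
                      ) -> dict[str, float]:
    """Each count as a percentage of the grand total, two decimals."""
    grand = sum(counts.values()) if total is None else total
    if grand == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / grand, 2) for k, v in counts.items()}


def summarize_variants(events: list[VariantEvent]) -> VariantSummary:
    """Totals and two-decimal percentage shares per category / region /
    context, plus a per-gene table sorted by descending total."""
    by_category = {c: 0 for c in CATEGORIES}
    by_region: dict[str, int] = {}
    by_context: dict[str, int] = {}
    per_gene: dict[str, dict[str, int]] = {}
    for ev in events:
        by_category[ev.category] += 1
        if ev.region is not None:
            by_region[ev.region] = by_region.get(ev.region, 0) + 1
        if ev.context is not None:
            by_context[ev.context] = by_context.get(ev.context, 0) + 1
        if ev.gene is not None:
            row = per_gene.setdefault(ev.gene, {c: 0 for c in CATEGORIES})
            row[ev.category] += 1
    total = len(events)
    per_gene = dict(
        sorted(per_gene.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    )
    return VariantSummary(
        total=total,
        by_category=by_category,
        by_region=by_region,
        by_context=by_context,
        per_gene=per_gene,
        category_shares=percentage_shares(by_category, total),
        region_shares=percentage_shares(by_region, total),
        context_shares=percentage_shares(by_context, total),
    )


def snv_matrix(aln: AlignmentMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the alignment to substitution (gap-free variable) columns.

    Returns ``(matrix, column_indices)``; warns when no such column exists.
    """
    states = scan_columns(aln)
    cols = np.flatnonzero(states == COL_SUBSTITUTION)
    if cols.size == 0:
        warnings.warn("no SNV columns in alignment")
    return aln.matrix[:, cols], cols
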