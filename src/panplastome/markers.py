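"""Hypervariable-window screening and clade-diagnostic site discovery."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import GeneModel
from .errors import InputError
from .popgen import _mean_pairwise_mismatch, complete_deletion
from .variants import (
    COL_GAP,
    COL_SUBSTITUTION,
    AlignmentMatrix,
    VariantEvent,
    scan_columns,
)

DEFAULT_WINDOW = 600
DEFAULT_STEP = 200

_STATES = (b"A", b"C", b"G", b"T", b"-")


@dataclass
class WindowProfile:
    window_start: int  # reference coordinates, half-open
    window_end: int
    pi: float
    variant_count: int


@dataclass
class DiagnosticSite:
    aln_column: int
    ref_position: int
    site_kind: str  # SNV | InDel
    target_clades: tuple[str, ...]
    allele: str
    locus_label: str | None = None


def sliding_window_diversity(
    aln: AlignmentMatrix,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    events: list[VariantEvent] | None = None,
) -> list[WindowProfile]:
    """Per-window nucleotide diversity (complete deletion inside each
    window) and variant-event counts on reference coordinates.

    A window wider than the reference collapses to a single whole-genome
    window with a warning. Windows with no retained columns report Pi = 0.
    """
    if step < 1 or window < step:
        raise InputError("require window >= step >= 1")
    ref_len = aln.reference_length
    if window > ref_len:
        warnings.warn("window longer than reference; using one whole-genome window")
        window = ref_len
        step = ref_len
    col_ref = aln.column_to_ref_pos
    starts = list(range(0, ref_len, step))
    profiles: list[WindowProfile] = []
    event_starts = np.array([ev.ref_start for ev in events]) if events else None
    for start in starts:
        end = min(start + window, ref_len)
        cols = np.flatnonzero((col_ref >= start) & (col_ref < end))
        pi = 0.0
        if cols.size:
            kept, retained = complete_deletion(aln.matrix[:, cols])
            if retained.size:
                pi = _mean_pairwise_mismatch(kept)
        count = 0
        if event_starts is not None:
            count = int(((event_starts >= start) & (event_starts < end)).sum())
        profiles.append(WindowProfile(start, end, pi, count))
    return profiles


def rank_windows(profiles: list[WindowProfile]) -> list[WindowProfile]:
    """Windows sorted by descending diversity (start position breaks ties)."""
    return sorted(profiles, key=lambda w: (-w.pi, w.window_start))


def locus_label(model: GeneModel, pos: int) -> str:
    """Gene name at ``pos``, or an ``<leftGene>-<rightGene>`` IGS label."""
    spans = sorted((f.span, f.name) for f in model.features)
    left = right = None
    for (s, e), name in spans:
        if s <= pos < e:
            return name
        if e <= pos:
            left = name
        if s > pos and right is None:
            right = name
    return f"{left or 'start'}-{right or 'end'}"


def clade_diagnostic_sites(
    aln: AlignmentMatrix,
    clusters: dict[str, str],
    events: list[VariantEvent] | None = None,
    model: GeneModel | None = None,
) -> list[DiagnosticSite]:
    """Sites where one state is carried by every member of a cluster set and
    by nobody else.

    Every clustered sample must appear in ``clusters`` (sample -> label).
    Sites are sorted so singleton cluster sets come first at each column.
    Columns inside InDel or Mixed events (or holding a gap state) report
    ``site_kind`` InDel.
    """
    members: dict[str, set[str]] = {}
    for sample, label in clusters.items():
        members.setdefault(label, set()).add(sample)
    sample_rows = {s: i for i, s in enumerate(aln.sample_ids)}
    missing = set(clusters) - set(sample_rows)
    if missing:
        raise InputError(f"cluster table names unknown samples: {sorted(missing)}")
    clustered = [s for s in aln.sample_ids if s in clusters]
    all_clades = set(members)

    indel_columns: set[int] = set()
    if events:
        for ev in events:
            if ev.category in ("InDel", "Mixed"):
                indel_columns.update(range(*ev.columns))

    states = scan_columns(aln)
    col_ref = aln.column_to_ref_pos
    sites: list[DiagnosticSite] = []
    for col in np.flatnonzero(states != 0):
        column = aln.matrix[:, col]
        for state in _STATES:
            carriers = {s for s in clustered if column[sample_rows[s]] == state}
            if not carriers:
                continue
            carried_clades = {clusters[s] for s in carriers}
            if carried_clades == all_clades:
                continue
            full = set().union(*(members[c] for c in carried_clades))
            if carriers == full:
                kind = "InDel" if (state == b"-" or int(col) in indel_columns) else "SNV"
                sites.append(
                    DiagnosticSite(
                        aln_column=int(col),
                        ref_position=int(col_ref[col]),
                        site_kind=kind,
                        target_clades=tuple(sorted(carried_clades)),
                        allele=state.decode(),
                        locus_label=(
                            locus_label(model, int(col_ref[col]))
                            if model is not None else None
                        ),
                    )
                )
    sites.sort(key=lambda s: (s.aln_column, len(s.target_clades), s.allele))
    return sites
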