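"""Quadripartite plastome structure: inverted-repeat detection, canonical
orientation, and per-region length/GC metrics.

A typical plastome is a circular molecule tiled, in canonical order, by a
large single-copy region (LSC), one inverted-repeat copy (IRb), a small
single-copy region (SSC), and the second repeat copy (IRa), where IRa is the
reverse complement of IRb. Detection works on the circular sequence via exact
k-mer seeding against the reverse complement, run-merging along
anti-diagonals, and optional mismatch-tolerant extension.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import (
    InputError,
    NoQuadripartiteStructureError,
    StructuralAnomalyError,
    UndefinedGCError,
)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

DEFAULT_MIN_IR_LEN = 1000


def revcomp(seq: str) -> str:
    """Reverse complement with full IUPAC support."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlastomeSequence:
    """A single (usually circular) plastome sequence.

    Residues are stored uppercase and validated against the IUPAC nucleotide
    alphabet.
    """

    sample_id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"{self.sample_id}: empty sequence")
        upper = self.residues.upper()
        bad = set(upper) - IUPAC_NUCLEOTIDES
        if bad:
            raise InputError(
                f"{self.sample_id}: non-IUPAC characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", upper)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical rotation.

    Intervals are 0-based half-open and tile ``[0, total_length)`` in the
    order LSC, IRb, SSC, IRa. ``rotation_offset`` gives the index in the
    *original* sequence of canonical position 0, so the canonical rotation is
    ``seq[rotation_offset:] + seq[:rotation_offset]``.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    rotation_offset: int = 0
    ir_mismatches: int = 0

    @property
    def total_length(self) -> int:
        return self.ira[1]

    @property
    def region_lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc[1] - self.lsc[0],
            "IRb": self.irb[1] - self.irb[0],
            "SSC": self.ssc[1] - self.ssc[0],
            "IRa": self.ira[1] - self.ira[0],
        }

    def region_of(self, pos: int) -> str:
        """Region label ('LSC', 'SSC' or 'IR') of a canonical position."""
        if not 0 <= pos < self.total_length:
            raise InputError(f"position {pos} outside genome [0, {self.total_length})")
        if pos < self.lsc[1]:
            return "LSC"
        if pos < self.irb[1]:
            return "IR"
        if pos < self.ssc[1]:
            return "SSC"
        return "IR"

    def region_of_detailed(self, pos: int) -> str:
        """Like :meth:`region_of` but distinguishes IRb from IRa."""
        if pos < self.lsc[1]:
            return "LSC"
        if pos < self.irb[1]:
            return "IRb"
        if pos < self.ssc[1]:
            return "SSC"
        return "IRa"

    def validate(self, genome_length: int) -> None:
        regions = (self.lsc, self.irb, self.ssc, self.ira)
        if self.lsc[0] != 0 or self.ira[1] != genome_length:
            raise InputError("partition does not span the genome")
        for left, right in zip(regions, regions[1:]):
            if left[1] != right[0]:
                raise InputError("partition intervals do not tile contiguously")


def canonical_rotation(seq: PlastomeSequence, part: QuadripartitePartition) -> str:
    """Residues rotated so that position 0 is the LSC start."""
    r = part.rotation_offset % len(seq)
    s = seq.residues
    return s[r:] + s[:r]


# ---------------------------------------------------------------------------
# inverted-repeat detection


def _circular_interval_positions(start: int, length: int, total: int) -> range | list[int]:
    if start + length <= total:
        return range(start, start + length)
    return list(range(start, total)) + list(range(0, (start + length) % total))


def _circular_disjoint(a0: int, la: int, b0: int, lb: int, total: int) -> bool:
    pos_a = set(p % total for p in range(a0, a0 + la))
    pos_b = set(p % total for p in range(b0, b0 + lb))
    return not (pos_a & pos_b)


def _find_inverted_repeats(s: str, min_len: int, mismatch_rate: float) -> list[tuple[int, int, int, int]]:
    """All maximal inverted-repeat arm pairs of length >= min_len.

    Returns tuples ``(a_start, b_start, length, mismatches)`` on the circle,
    with ``s[a : a+length] == revcomp(s[b : b+length])`` up to the allowed
    mismatch budget. Pairs are deduplicated (arm order is canonicalized).
    """
    total = len(s)
    k = max(4, min(min_len, 21))
    if k > total:
        return []
    doubled = s + s[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(total):
        index.setdefault(doubled[i : i + k], []).append(i)

    # seeds grouped by anti-diagonal D = (a + b + k - 1) mod total
    diagonals: dict[int, set[int]] = {}
    for a in range(total):
        rc_kmer = revcomp(doubled[a : a + k])
        for b in index.get(rc_kmer, ()):
            d = (a + b + k - 1) % total
            diagonals.setdefault(d, set()).add(a)

    candidates: dict[frozenset[int] | tuple[int, int], tuple[int, int, int, int]] = {}
    for d, a_set in diagonals.items():
        a_sorted = sorted(a_set)
        # merge consecutive a-values into runs (with circular wrap)
        runs: list[list[int]] = []
        for a in a_sorted:
            if runs and a == runs[-1][1] + 1:
                runs[-1][1] = a
            else:
                runs.append([a, a])
        if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == total - 1:
            runs[0][0] = runs[-1][0] - total
            runs.pop()
        merged: list[list[int]] = []
        for run in runs:
            if merged and mismatch_rate > 0:
                prev = merged[-1]
                gap_mism = run[0] - (prev[1] + k)  # mismatched pair columns
                combined = run[1] + k - prev[0]
                budget = mismatch_rate * combined
                if 0 < gap_mism and (prev[2] + gap_mism) <= budget:
                    prev[1] = run[1]
                    prev[2] += gap_mism
                    continue
            merged.append([run[0], run[1], 0])
        for a0, a1, mism in merged:
            length = min(a1 + k - a0, total)
            if length < min_len:
                continue
            b0 = (d - (a0 + length - 1)) % total
            a0m = a0 % total
            key = frozenset((a0m, b0)) if a0m != b0 else (a0m, length)
            prev = candidates.get(key)
            if prev is None or length > prev[2]:
                candidates[key] = (a0m, b0, length, mism)
    return list(candidates.values())


def detect_quadripartite(
    seq: PlastomeSequence,
    min_ir_len: int = DEFAULT_MIN_IR_LEN,
    mismatch_rate: float = 0.0,
) -> QuadripartitePartition:
    """Partition a circular plastome into LSC/IRb/SSC/IRa.

    The partition is induced by the longest pair of disjoint inverted repeats
    of length >= ``min_ir_len`` on the circular sequence. Ties between equally
    long pairs are broken by the smallest arm start coordinate. Coordinates
    are reported on the canonical rotation (position 0 = LSC start).

    Raises
    ------
    NoQuadripartiteStructureError
        If no inverted repeat of the required length exists.
    StructuralAnomalyError
        If the best repeat pair overlaps itself or leaves gaps that cannot
        form an LSC > SSC tiling.
    """
    if not seq.circular:
        raise InputError("quadripartite detection requires a circular sequence")
    if min_ir_len < 1:
        raise InputError("min_ir_len must be >= 1")
    if not 0.0 <= mismatch_rate <= 0.001:
        raise InputError("mismatch_rate must be in [0, 0.001]")
    s = seq.residues
    total = len(s)
    repeats = _find_inverted_repeats(s, min_ir_len, mismatch_rate)
    if not repeats:
        raise NoQuadripartiteStructureError(
            f"{seq.sample_id}: no inverted repeat >= {min_ir_len} bp"
        )
    repeats.sort(key=lambda r: (-r[2], min(r[0], r[1]), max(r[0], r[1])))
    a0, b0, length, mism = repeats[0]
    if length * 2 >= total or not _circular_disjoint(a0, length, b0, length, total):
        raise StructuralAnomalyError(
            f"{seq.sample_id}: best repeat pair overlaps itself"
        )
    # the two gaps between the arms are the single-copy regions
    first, second = sorted([a0, b0])
    gap1 = (second - (first + length)) % total  # after arm at `first`
    gap2 = (first - (second + length)) % total  # after arm at `second`
    if gap1 == 0 or gap2 == 0:
        raise StructuralAnomalyError(
            f"{seq.sample_id}: repeat arms are adjacent; no single-copy region"
        )
    if gap1 == gap2:
        raise StructuralAnomalyError(
            f"{seq.sample_id}: single-copy regions have equal length"
        )
    if gap1 > gap2:
        lsc_start = (first + length) % total
        irb_start = second
    else:
        lsc_start = (second + length) % total
        irb_start = first
    lsc_len = max(gap1, gap2)
    ssc_len = min(gap1, gap2)
    assert lsc_len + ssc_len + 2 * length == total
    return QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + length),
        ssc=(lsc_len + length, lsc_len + length + ssc_len),
        ira=(lsc_len + length + ssc_len, total),
        rotation_offset=lsc_start,
        ir_mismatches=mism,
    )


# ---------------------------------------------------------------------------
# metrics


def gc_fraction(segment: str) -> float:
    """GC fraction over unambiguous characters only.

    Raises :class:`UndefinedGCError` when the segment has no A/C/G/T.
    """
    gc = segment.count("G") + segment.count("C")
    at = segment.count("A") + segment.count("T")
    if gc + at == 0:
        raise UndefinedGCError("no unambiguous nucleotides in region")
    return gc / (gc + at)


def region_metrics(
    seq: PlastomeSequence, part: QuadripartitePartition
) -> dict[str, dict[str, float]]:
    """Per-region length and GC content plus whole-genome totals.

    Ambiguity characters count toward region lengths but are excluded from
    both the GC numerator and denominator.
    """
    part.validate(len(seq))
    canon = canonical_rotation(seq, part)
    out: dict[str, dict[str, float]] = {}
    for name, (start, end) in (
        ("LSC", part.lsc),
        ("IRb", part.irb),
        ("SSC", part.ssc),
        ("IRa", part.ira),
    ):
        segment = canon[start:end]
        out[name] = {"length": end - start, "gc": gc_fraction(segment)}
    out["total"] = {"length": len(canon), "gc": gc_fraction(canon)}
    assert sum(int(out[r]["length"]) for r in ("LSC", "IRb", "SSC", "IRa")) == len(canon)
    return out


# ---------------------------------------------------------------------------
# orientation


def _identity_score(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y)


def _flip_segment(canon: str, interval: tuple[int, int]) -> str:
    start, end = interval
    return canon[:start] + revcomp(canon[start:end]) + canon[end:]


def canonicalize_orientation(
    seq: PlastomeSequence,
    reference: PlastomeSequence,
    part: QuadripartitePartition | None = None,
    ref_part: QuadripartitePartition | None = None,
    min_ir_len: int = DEFAULT_MIN_IR_LEN,
    mismatch_rate: float = 0.0,
) -> PlastomeSequence:
    """Choose the quadripartite-preserving isomer of ``seq`` collinear with
    ``reference``.

    The candidate set is {forward, reverse-complement} x {LSC flipped or not}
    x {SSC flipped or not}, each on its canonical rotation. The isomer whose
    LSC and SSC maximize positional identity with the reference's regions
    wins; ties are broken by enumeration order (forward, unflipped first).
    """
    if ref_part is None:
        ref_part = detect_quadripartite(reference, min_ir_len, mismatch_rate)
    ref_canon = canonical_rotation(reference, ref_part)
    ref_lsc = ref_canon[slice(*ref_part.lsc)]
    ref_ssc = ref_canon[slice(*ref_part.ssc)]

    best: tuple[int, int, str] | None = None
    rank = 0
    for strand in ("+", "-"):
        if strand == "+":
            variant = seq
            vpart = part
        else:
            variant = PlastomeSequence(seq.sample_id, revcomp(seq.residues), seq.circular)
            vpart = None
        if vpart is None:
            vpart = detect_quadripartite(variant, min_ir_len, mismatch_rate)
        else:
            vpart.validate(len(variant))
        canon = canonical_rotation(variant, vpart)
        for flip_lsc in (False, True):
            for flip_ssc in (False, True):
                cand = canon
                if flip_lsc:
                    cand = _flip_segment(cand, vpart.lsc)
                if flip_ssc:
                    cand = _flip_segment(cand, vpart.ssc)
                score = _identity_score(
                    cand[slice(*vpart.lsc)], ref_lsc
                ) + _identity_score(cand[slice(*vpart.ssc)], ref_ssc)
                rank -= 1
                if best is None or (score, rank) > (best[0], best[1]):
                    best = (score, rank, cand)
    assert best is not None
    return PlastomeSequence(seq.sample_id, best[2], seq.circular)


def structure_table_row(seq: PlastomeSequence, part: QuadripartitePartition) -> dict[str, object]:
    """One row of the structure report TSV."""
    metrics = region_metrics(seq, part)
    ir_seg_b = canonical_rotation(seq, part)[slice(*part.irb)]
    ir_seg_a = canonical_rotation(seq, part)[slice(*part.ira)]
    asymmetric = revcomp(ir_seg_b) != ir_seg_a
    ir_gc = gc_fraction(ir_seg_b + ir_seg_a)
    return {
        "sample_id": seq.sample_id,
        "total_len": int(metrics["total"]["length"]),
        "lsc_len": int(metrics["LSC"]["length"]),
        "irb_len": int(metrics["IRb"]["length"]),
        "ssc_len": int(metrics["SSC"]["length"]),
        "ira_len": int(metrics["IRa"]["length"]),
        "total_gc": round(metrics["total"]["gc"], 6),
        "lsc_gc": round(metrics["LSC"]["gc"], 6),
        "ssc_gc": round(metrics["SSC"]["gc"], 6),
        "ir_gc": round(ir_gc, 6),
        "ir_asymmetric": asymmetric,
        "ir_mismatches": part.ir_mismatches,
    }
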