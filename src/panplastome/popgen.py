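"""Haplotypes, diversity statistics, substitution-model distances, Fst,
PCA, and neighbor-joining trees.

Conventions follow the common DnaSP/MEGA defaults: complete deletion (drop
any column with a gap or missing state in any retained row) for haplotype
collapsing, Hd and nucleotide diversity; pairwise deletion for model-based
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError, NoInformativeSitesError, SaturationError
from .variants import AlignmentMatrix, snv_matrix

_UNAMBIGUOUS = np.frombuffer(b"ACGT", dtype="S1")


def _valid_mask(rows: np.ndarray) -> np.ndarray:
    """Columns where every row holds an unambiguous nucleotide."""
    ok = np.zeros(rows.shape, dtype=bool)
    for base in _UNAMBIGUOUS:
        ok |= rows == base
    return ok.all(axis=0)


def complete_deletion(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop every column containing any gap/N/ambiguity in any row.

    Returns the retained sub-matrix and the retained column indices.
    """
    keep = np.flatnonzero(_valid_mask(rows))
    return rows[:, keep], keep


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    members: list[str]


@dataclass
class HaplotypeSet:
    haplotypes: list[Haplotype]
    retained_columns: np.ndarray

    @property
    def n_samples(self) -> int:
        return sum(len(h.members) for h in self.haplotypes)

    def membership(self) -> dict[str, str]:
        return {m: h.haplotype_id for h in self.haplotypes for m in h.members}


def collapse_haplotypes(aln: AlignmentMatrix,
                        members: list[str] | None = None) -> HaplotypeSet:
    """Complete-deletion haplotype collapsing.

    Identical sequences over the retained columns merge into one haplotype;
    ids h1, h2, ... are assigned in first-occurrence (row) order.
    """
    ids = members if members is not None else list(aln.sample_ids)
    if len(ids) < 2:
        raise InputError("need at least 2 samples to collapse haplotypes")
    rows = aln.rows(ids)
    kept, cols = complete_deletion(rows)
    if cols.size == 0:
        raise NoInformativeSitesError("complete deletion removed all columns")
    haplotypes: list[Haplotype] = []
    seen: dict[bytes, Haplotype] = {}
    for sample, row in zip(ids, kept):
        key = row.tobytes()
        hap = seen.get(key)
        if hap is None:
            hap = Haplotype(f"h{len(haplotypes) + 1}", key.decode(), [])
            seen[key] = hap
            haplotypes.append(hap)
        hap.members.append(sample)
    return HaplotypeSet(haplotypes=haplotypes, retained_columns=cols)


@dataclass
class DiversityStats:
    n: int
    h: int
    hd: float
    pi: float


def haplotype_diversity(hs: HaplotypeSet) -> float:
    """Hd = n(1 - sum p_i^2) / (n - 1)."""
    n = hs.n_samples
    if n < 2:
        raise InputError("haplotype diversity requires n >= 2")
    freqs = np.array([len(h.members) for h in hs.haplotypes], dtype=float) / n
    return float(n * (1.0 - np.sum(freqs**2)) / (n - 1))


def _mean_pairwise_mismatch(kept: np.ndarray) -> float:
    """Mean per-site pairwise difference over gap-free columns (per site)."""
    k, length = kept.shape
    pairs = k * (k - 1) / 2
    same = np.zeros(length)
    for base in _UNAMBIGUOUS:
        counts = (kept == base).sum(axis=0)
        same += counts * (counts - 1) / 2
    diff_pairs = pairs - same
    return float(diff_pairs.sum() / (length * pairs))


def nucleotide_diversity(aln: AlignmentMatrix,
                         members: list[str] | None = None,
                         columns: np.ndarray | None = None) -> float:
    """Pi: mean over unordered member pairs of per-site differences at the
    retained (complete-deletion) columns.

    ``columns`` overrides the deletion step with a precomputed column set
    (used when one column frame must be shared across clusters).
    """
    ids = members if members is not None else list(aln.sample_ids)
    if len(ids) < 2:
        raise InputError("nucleotide diversity requires >= 2 members")
    rows = aln.rows(ids)
    if columns is not None:
        kept = rows[:, columns]
        n_cols = columns.size
    else:
        kept, cols = complete_deletion(rows)
        n_cols = cols.size
    if n_cols == 0:
        raise NoInformativeSitesError("no retained columns for Pi")
    return _mean_pairwise_mismatch(kept)


def cluster_diversity(aln: AlignmentMatrix,
                      clusters: dict[str, list[str]]) -> dict[str, DiversityStats]:
    """Per-cluster n / haplotype count / Hd / Pi on a shared column frame.

    The complete-deletion column set is computed once over all clustered
    samples so statistics are comparable across clusters.
    """
    all_members = [m for members in clusters.values() for m in members]
    full = collapse_haplotypes(aln, all_members)
    cols = full.retained_columns
    out: dict[str, DiversityStats] = {}
    for label, members in clusters.items():
        if len(members) < 2:
            out[label] = DiversityStats(n=len(members), h=1, hd=0.0, pi=0.0)
            continue
        # collapse on the shared frame so haplotype counts are comparable
        rows = aln.rows(members)[:, cols]
        uniq = {row.tobytes() for row in rows}
        counts: dict[bytes, int] = {}
        for row in rows:
            counts[row.tobytes()] = counts.get(row.tobytes(), 0) + 1
        n = len(members)
        freqs = np.array(list(counts.values()), dtype=float) / n
        hd = float(n * (1.0 - np.sum(freqs**2)) / (n - 1))
        pi = nucleotide_diversity(aln, members, columns=cols)
        out[label] = DiversityStats(n=n, h=len(uniq), hd=hd, pi=pi)
    return out


# ---------------------------------------------------------------------------
# distances


def _pairwise_valid(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok_a = np.zeros(a.shape, dtype=bool)
    ok_b = np.zeros(b.shape, dtype=bool)
    for base in _UNAMBIGUOUS:
        ok_a |= a == base
        ok_b |= b == base
    keep = ok_a & ok_b
    return a[keep], b[keep]


def _as_byte_row(seq) -> np.ndarray:
    if isinstance(seq, str):
        return np.frombuffer(seq.upper().encode(), dtype="S1")
    return np.asarray(seq, dtype="S1")


def p_distance(seq_a, seq_b) -> float:
    """Proportion of differing sites under pairwise deletion."""
    a, b = _pairwise_valid(_as_byte_row(seq_a), _as_byte_row(seq_b))
    if a.size == 0:
        raise InputError("no comparable sites between sequences")
    return float((a != b).mean())


def tn93_distance(seq_a, seq_b) -> float:
    """Tamura-Nei (1993) distance in substitutions/site.

    Base frequencies are estimated from the pooled pair under pairwise
    deletion. P1 is the proportion of sites with purine transitions (A<->G),
    P2 pyrimidine transitions (C<->T), Q transversions:

        d = -k1 ln(1 - P1/k1 - Q/(2 piR))
            -k2 ln(1 - P2/k2 - Q/(2 piY))
            -k3 ln(1 - Q/(2 piR piY))

    with k1 = 2 piA piG / piR, k2 = 2 piT piC / piY and
    k3 = 2 (piR piY - piA piG piY/piR - piT piC piR/piY).

    Raises :class:`SaturationError` when a logarithm argument is <= 0; falls
    back to p-distance (with a warning) when either purine or pyrimidine
    pooled frequency is zero.
    """
    a, b = _pairwise_valid(_as_byte_row(seq_a), _as_byte_row(seq_b))
    n = a.size
    if n == 0:
        raise InputError("no comparable sites between sequences")
    pooled = np.concatenate([a, b])
    freq = {base: float((pooled == base).mean()) for base in _UNAMBIGUOUS}
    pi_a, pi_c, pi_g, pi_t = (freq[b"A"], freq[b"C"], freq[b"G"], freq[b"T"])
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    diff = a != b
    is_ag = diff & (((a == b"A") & (b == b"G")) | ((a == b"G") & (b == b"A")))
    is_ct = diff & (((a == b"C") & (b == b"T")) | ((a == b"T") & (b == b"C")))
    p1 = float(is_ag.mean())
    p2 = float(is_ct.mean())
    q = float(diff.mean()) - p1 - p2
    if pi_r == 0.0 or pi_y == 0.0:
        warnings.warn("zero purine or pyrimidine frequency; falling back to p-distance")
        return float(diff.mean())
    k1 = 2.0 * pi_a * pi_g / pi_r
    k2 = 2.0 * pi_t * pi_c / pi_y
    k3 = 2.0 * (pi_r * pi_y - pi_a * pi_g * pi_y / pi_r - pi_t * pi_c * pi_r / pi_y)
    terms = []
    for coeff, arg in (
        (k1, 1.0 - (p1 / k1 if k1 > 0 else 0.0) - q / (2.0 * pi_r)),
        (k2, 1.0 - (p2 / k2 if k2 > 0 else 0.0) - q / (2.0 * pi_y)),
        (k3, 1.0 - q / (2.0 * pi_r * pi_y)),
    ):
        if coeff == 0.0:
            terms.append(0.0)
            continue
        if arg <= 0.0:
            raise SaturationError("distance undefined (saturation)")
        terms.append(-coeff * np.log(arg))
    return float(sum(terms))


_DISTANCE_FUNCS = {"p": p_distance, "tn93": tn93_distance}


def _model_distance(a, b, model: str) -> float:
    """Model distance with a per-pair p-distance fallback on saturation.

    SNV-only matrices concentrate divergence, so TN93 can saturate for
    strongly differentiated pairs; aggregate statistics (Fst, NJ input)
    substitute the p-distance for those pairs rather than failing outright.
    ``tn93_distance`` itself still raises.
    """
    if model == "tn93":
        try:
            return tn93_distance(a, b)
        except SaturationError:
            warnings.warn("TN93 saturated for one pair; using p-distance")
            return p_distance(a, b)
    return _DISTANCE_FUNCS[model](a, b)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise InputError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise InputError("distances must be nonnegative")


def pairwise_distance_matrix(rows: np.ndarray, labels: list[str],
                             model: str = "tn93") -> DistanceMatrix:
    """All-pairs distances between alignment rows under the given model."""
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _model_distance(rows[i], rows[j], model)
    return DistanceMatrix(labels=labels, matrix=mat, model=model)


# ---------------------------------------------------------------------------
# Fst


def pairwise_fst(aln: AlignmentMatrix, members_a: list[str],
                 members_b: list[str], model: str = "tn93",
                 floor_negative: bool = True) -> float:
    """Hudson-style Fst = 1 - Hw/Hb between two clusters on SNV columns.

    Hw averages the two within-cluster mean pairwise distances; Hb is the
    mean between-cluster pairwise distance. Returns NaN when Hb is zero
    (clusters genetically identical); small negative estimates are floored
    to zero unless ``floor_negative`` is False.
    """
    if len(members_a) < 2 or len(members_b) < 2:
        raise InputError("each cluster needs >= 2 members for Fst")
    sub, cols = snv_matrix(aln)
    if cols.size == 0:
        return float("nan")  # no variation at all: clusters identical
    index = {s: i for i, s in enumerate(aln.sample_ids)}

    def mean_within(members: list[str]) -> float:
        rows = [sub[index[m]] for m in members]
        vals = [_model_distance(rows[i], rows[j], model)
                for i in range(len(rows)) for j in range(i + 1, len(rows))]
        return float(np.mean(vals))

    def mean_between() -> float:
        rows_a = [sub[index[m]] for m in members_a]
        rows_b = [sub[index[m]] for m in members_b]
        vals = [_model_distance(ra, rb, model) for ra in rows_a for rb in rows_b]
        return float(np.mean(vals))

    hw = 0.5 * (mean_within(members_a) + mean_within(members_b))
    hb = mean_between()
    if hb == 0.0:
        return float("nan")
    fst = 1.0 - hw / hb
    if fst < 0.0 and floor_negative:
        return 0.0
    return float(fst)


# ---------------------------------------------------------------------------
# PCA


def pca_coordinates(snv: np.ndarray, n_components: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates of samples from an SNV character
    matrix.

    Each column is expanded into one 0/1 indicator per minor allele (major
    allele = most frequent state, ties broken lexicographically). The
    indicator matrix is column-centered; coordinates come from the leading
    eigenvectors, with each component's sign fixed so its largest-magnitude
    loading is positive. Returns ``(coordinates, explained_variance_ratio)``.
    """
    snv = np.asarray(snv, dtype="S1")
    n, m = snv.shape
    if n < 3:
        raise InputError("PCA requires >= 3 samples")
    if m < 1:
        raise InputError("PCA requires >= 1 SNV column")
    indicators = []
    for j in range(m):
        col = snv[:, j]
        states, counts = np.unique(col, return_counts=True)
        keep = [s for s in states if s in _UNAMBIGUOUS]
        if len(keep) < 2:
            continue
        major = sorted(keep, key=lambda s: (-counts[list(states).index(s)], s))[0]
        for s in keep:
            if s != major:
                indicators.append((col == s).astype(float))
    if not indicators:
        raise InputError("zero-variance SNV matrix")
    X = np.column_stack(indicators)
    X -= X.mean(axis=0)
    if not np.any(X):
        raise InputError("zero-variance SNV matrix")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    evr = s**2 / np.sum(s**2)
    if n_components is not None:
        coords = coords[:, :n_components]
        evr = evr[:n_components]
    return coords, evr


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix):
    """Neighbor-joining tree (unrooted, trifurcating root) as a scikit-bio
    ``TreeNode``.

    Negative branch lengths are floored at zero with the deficit moved to
    the sister edge, so additive matrices are recovered exactly.
    """
    from skbio import TreeNode

    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining requires >= 3 labels")
    nodes = [TreeNode(name=str(lbl)) for lbl in dm.labels]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    def floor_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or qv < best[0] - 1e-12:
                    best = (qv, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (len(active) - 2))
        lj = d[i, j] - li
        li, lj = floor_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new = TreeNode(children=[child_i, child_j])
        nodes.append(new)
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = float(max(length, 0.0))
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])
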