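"""Centromeric satellite detection and subgenome phasing.

Tandem monomer arrays are found by base-offset autocorrelation (the fraction
of positions matching themselves at lag p peaks sharply at multiples of the
monomer period; the smallest near-maximal lag is the period).  A consensus
monomer per chromosome is built by circular register alignment plus
per-column majority vote, pairwise p-distances between consensuses feed a
neighbour-joining tree, and the internal edge maximizing the
between/within-clade distance ratio splits the chromosomes into the two
subgenome clades.  Clade support comes from bootstrap over monomer columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SatelliteArray",
    "PhasingResult",
    "PhasingError",
    "periodicity_profile",
    "best_period",
    "detect_tandem_arrays",
    "circular_align",
    "consensus_monomer",
    "phase_subgenomes",
]

_BASE_ORDER = "ACGT"  # consensus tie-break order


class PhasingError(ValueError):
    """Raised when the two-clade split cannot be resolved."""


@dataclass
class SatelliteArray:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    monomer_period: int
    copy_number: int
    consensus: str
    score: float = 0.0

    def __post_init__(self):
        if self.copy_number < 2:
            raise ValueError("a tandem array needs >= 2 copies")
        if self.monomer_period * self.copy_number > (self.end - self.start) * 1.1:
            raise ValueError("period x copy_number exceeds interval length x 1.1")


@dataclass
class PhasingResult:
    newick: str
    clade_assignments: dict  # chromosome -> "A" | "B"
    support: dict  # "A"/"B" -> bootstrap proportion
    within_distance: float
    between_distance: float
    consistent: bool | None = None  # vs supplied homoeolog pairs; None if not checked
    diagnostics: dict = field(default_factory=dict)


def _as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def periodicity_profile(seq, min_period: int, max_period: int) -> np.ndarray:
    """score[lag] = fraction of positions i with seq[i] == seq[i+lag], for
    lag in [min_period, max_period].  Index 0 of the result is min_period."""
    a = _as_u8(seq) if isinstance(seq, str) else seq
    n = a.size
    max_period = min(max_period, n // 2)
    if max_period < min_period:
        return np.zeros(0)
    scores = np.empty(max_period - min_period + 1)
    for i, lag in enumerate(range(min_period, max_period + 1)):
        scores[i] = float(np.mean(a[:-lag] == a[lag:]))
    return scores


def best_period(seq, min_period: int = 20, max_period: int = 400,
                min_score: float = 0.5, rel_tol: float = 0.02):
    """Smallest lag whose autocorrelation score is within ``rel_tol`` of the
    maximum (multiples of the true period score equally in expectation, so
    the fundamental is the smallest near-maximal lag).  Returns
    (period, score) or None if nothing beats ``min_score``."""
    a = _as_u8(seq) if isinstance(seq, str) else seq
    scores = periodicity_profile(a, min_period, max_period)
    if scores.size == 0 or scores.max() < min_score:
        return None
    cands = np.nonzero(scores >= scores.max() - rel_tol)[0]
    lag = int(cands.min()) + min_period
    return lag, float(scores[lag - min_period])


def _refine_bounds(a: np.ndarray, period: int, lo: int, hi: int,
                   min_match: float = 0.5):
    """Extend/shrink [lo, hi) to the maximal run where the per-position
    lag-``period`` match (smoothed over one period) stays above
    ``min_match``."""
    n = a.size
    if n <= period:
        return lo, hi
    m = (a[:-period] == a[period:]).astype(np.float64)
    c = np.concatenate([[0.0], np.cumsum(m)])
    w = period
    # smoothed[i] = mean match in [i, i+w) over the lag comparison
    upper = m.size - w
    if upper <= 0:
        return lo, hi
    sm = (c[w:] - c[:-w]) / w  # defined for i in [0, m.size - w]
    good = sm >= min_match
    center = min(max((lo + hi) // 2, 0), good.size - 1)
    if not good[center]:
        idx = np.nonzero(good)[0]
        if idx.size == 0:
            return lo, hi
        center = idx[np.argmin(np.abs(idx - center))]
    s = center
    while s > 0 and good[s - 1]:
        s -= 1
    e = center
    while e < good.size - 1 and good[e + 1]:
        e += 1
    return int(s), int(e + 2 * w)  # e indexes start of last good window


def detect_tandem_arrays(sequence: str, min_period: int = 20,
                         max_period: int = 400, min_copies: int = 5,
                         window: int = 3000, step: int = 1500,
                         min_score: float = 0.5) -> list[SatelliteArray]:
    """Scan a sequence for tandem repeat arrays.

    Windows are screened with the autocorrelation profile; runs of windows
    agreeing on a period are merged, boundaries are refined on the
    per-position match profile, and the consensus monomer is the
    column-majority over the chopped copies.  Returns [] when nothing
    periodic is found.
    """
    a = _as_u8(sequence)
    n = a.size
    if n <= 2 * min_period:
        raise ValueError("sequence too short for the requested period range")
    window = min(window, n)
    hits = []  # (win_start, win_end, period)
    for s in range(0, max(1, n - window + 1), step):
        sub = a[s:s + window]
        bp = best_period(sub, min_period, max_period, min_score=min_score)
        if bp is not None:
            hits.append((s, min(s + window, n), bp[0]))
        if s + window >= n:
            break
    arrays: list[SatelliteArray] = []
    if not hits:
        return arrays
    # merge consecutive hits with compatible periods
    runs = []
    cur = list(hits[0])
    for s, e, p in hits[1:]:
        if s <= cur[1] and abs(p - cur[2]) <= 2:
            cur[1] = e
        else:
            runs.append(tuple(cur))
            cur = [s, e, p]
    runs.append(tuple(cur))
    for s, e, p in runs:
        sub = a[s:e]
        bp = best_period(sub, min_period, max_period, min_score=min_score)
        if bp is None:
            continue
        period, score = bp
        lo, hi = _refine_bounds(a, period, s, e)
        lo, hi = max(0, lo), min(n, hi)
        copy_number = (hi - lo) // period
        if copy_number < max(2, min_copies):
            continue
        copies = [sequence[lo + i * period: lo + (i + 1) * period]
                  for i in range(copy_number)]
        cons = consensus_monomer(copies)
        arrays.append(SatelliteArray(chromosome="", start=lo, end=hi,
                                     monomer_period=period,
                                     copy_number=copy_number,
                                     consensus=cons, score=score))
    return arrays


# ---------------------------------------------------------------------------
# consensus and circular register


def circular_align(reference: str, query: str):
    """Rotation of ``query`` minimizing Hamming distance to ``reference``
    (ties -> smallest offset).  Returns (rotated_query, offset, distance).
    Sequences must have equal length."""
    if len(reference) != len(query):
        raise ValueError("circular alignment requires equal lengths")
    r = _as_u8(reference)
    q = _as_u8(query)
    n = r.size
    best = (n + 1, 0)
    for off in range(n):
        d = int(np.count_nonzero(np.roll(q, -off) != r))
        if d < best[0]:
            best = (d, off)
    d, off = best
    return query[off:] + query[:off], off, d


def consensus_monomer(copies: list[str]) -> str:
    """Column-majority consensus of phase-aligned monomer copies; each copy
    is first circularly registered to the first copy.  Ties break by fixed
    base order A<C<G<T."""
    if len(copies) < 2:
        raise ValueError("need >= 2 copies for a consensus")
    lens = [len(c) for c in copies]
    if max(lens) > min(lens) * 1.2:
        raise ValueError("copy lengths differ by more than 20%")
    L = min(lens)
    ref = copies[0][:L]
    mat = np.empty((len(copies), L), dtype=np.uint8)
    mat[0] = _as_u8(ref)
    for i, c in enumerate(copies[1:], start=1):
        rot, _, _ = circular_align(ref, c[:L])
        mat[i] = _as_u8(rot)
    out = []
    base_codes = [ord(b) for b in _BASE_ORDER]
    for col in mat.T:
        counts = [int(np.count_nonzero(col == bc)) for bc in base_codes]
        out.append(_BASE_ORDER[int(np.argmax(counts))])  # argmax: first max wins (A<C<G<T)
    return "".join(out)


# ---------------------------------------------------------------------------
# phasing


def _registered_matrix(consensuses: dict):
    names = sorted(consensuses)
    lens = [len(consensuses[n]) for n in names]
    if max(lens) > min(lens) * 1.2:
        raise PhasingError("consensus lengths differ by more than 20%")
    L = min(lens)
    ref = consensuses[names[0]][:L]
    mat = np.empty((len(names), L), dtype=np.uint8)
    for i, n in enumerate(names):
        rot, _, _ = circular_align(ref, consensuses[n][:L])
        mat[i] = _as_u8(rot)
    return names, mat


def _pdist_matrix(mat: np.ndarray) -> np.ndarray:
    n, L = mat.shape
    dm = np.zeros((n, n))
    for i in range(n):
        diff = np.count_nonzero(mat[i] != mat[i + 1:], axis=1) / L
        dm[i, i + 1:] = diff
        dm[i + 1:, i] = diff
    return dm


def _nj_best_split(dm: np.ndarray, names: list[str]):
    """NJ tree on the distance matrix; return (newick, frozenset of one
    clade, ratio between/within) for the internal edge maximizing the
    between/within mean-distance ratio.  Bipartitions need >= 2 tips per
    side."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk_dm = DistanceMatrix(dm, ids=names)
    tree = nj(sk_dm)
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    best = None
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if not (2 <= len(tips) <= n - 2):
            continue
        side = np.array([idx[t] for t in tips])
        other = np.array([i for i in range(n) if i not in set(side)])
        within_vals = []
        for grp in (side, other):
            sub = dm[np.ix_(grp, grp)]
            within_vals.extend(sub[np.triu_indices(len(grp), 1)])
        within = float(np.mean(within_vals)) if within_vals else 0.0
        between = float(np.mean(dm[np.ix_(side, other)]))
        ratio = between / within if within > 0 else np.inf
        if best is None or ratio > best[2]:
            best = (str(tree).strip(), tips, ratio, within, between)
    if best is None:
        raise PhasingError("no internal bipartition with >= 2 tips per side")
    return best


def phase_subgenomes(consensuses: dict, homoeolog_pairs=None,
                     n_bootstrap: int = 100, seed: int = 0) -> PhasingResult:
    """Partition chromosomes into the two subgenome clades from their
    satellite consensus monomers.

    Pairwise p-distances (after circular register alignment to a common
    reference) feed a neighbour-joining tree; the internal edge maximizing
    the between/within distance ratio defines the clades.  The clade holding
    the lexicographically smallest chromosome id is labelled "A".  Bootstrap
    over monomer columns gives per-clade support.  If ``homoeolog_pairs``
    [(chrom_x, chrom_y), ...] is given, the result is checked for
    one-member-per-pair-per-clade and flagged on ``consistent``.
    """
    if len(consensuses) < 4:
        raise PhasingError("need >= 4 consensus monomers to phase")
    names, mat = _registered_matrix(consensuses)
    dm = _pdist_matrix(mat)
    if not np.any(dm > 0):
        raise PhasingError("all consensus monomers identical: unresolvable phasing")
    newick, cladeset, ratio, within, between = _nj_best_split(dm, names)
    if between <= within:
        raise PhasingError(
            f"between-clade distance ({between:.4g}) <= within-clade ({within:.4g}): "
            "unresolvable phasing")
    a_side = cladeset if min(names) in cladeset else frozenset(names) - cladeset
    assignments = {n: ("A" if n in a_side else "B") for n in names}

    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    hits = 0
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_cols, size=n_cols)
        bdm = _pdist_matrix(mat[:, cols])
        if not np.any(bdm > 0):
            continue
        try:
            _, bset, _, bw, bb = _nj_best_split(bdm, names)
        except PhasingError:
            continue
        if bset == cladeset or bset == frozenset(names) - cladeset:
            hits += 1
    support = hits / n_bootstrap if n_bootstrap else 1.0

    consistent = None
    if homoeolog_pairs is not None:
        consistent = all(
            {assignments.get(x), assignments.get(y)} == {"A", "B"}
            for x, y in homoeolog_pairs)

    return PhasingResult(
        newick=newick, clade_assignments=assignments,
        support={"A": support, "B": support},
        within_distance=within, between_distance=between,
        consistent=consistent,
        diagnostics={"ratio": ratio, "n_chromosomes": len(names),
                     "monomer_length": int(mat.shape[1])})
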