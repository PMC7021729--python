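"""Codon-level molecular evolution: NG86 Ka/Ks, Ks-clock dating, Ks
distribution summaries, and the windowed-Ks scan for homoeologous exchange.

The Nei–Gojobori (1986) counting method is implemented from first
principles: fractional synonymous/nonsynonymous site counts per codon,
pathway-averaged difference counts for codons differing at more than one
position (pathways through stop codons are excluded unless all are blocked),
and Jukes–Cantor correction d = -3/4 ln(1 - 4p/3).  Mutations to stop
codons count as nonsynonymous in site counting; transitions and
transversions are weighted equally (pure NG86, no kappa).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "CodonPairStats",
    "ExchangeScanResult",
    "align_codons",
    "ng86",
    "ks_to_time",
    "ks_distribution",
    "scan_homoeologous_exchange",
]

BASES = "ACGT"
_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _TABLE[codon]


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str):
    """(synonymous, nonsynonymous) site counts of one codon: at each
    position, the fraction of the three single-base changes that preserve
    the amino acid.  Changes to stop codons are nonsynonymous."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    s = 0.0
    ref = _aa(codon)
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == ref:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_diffs(c1: str, c2: str):
    """(synonymous, nonsynonymous) observed differences between two codons,
    averaged over all mutational pathways (orderings of the differing
    positions).  Pathways passing through a stop codon are discarded; if
    every pathway is blocked, all are used."""
    if c1 in _STOPS or c2 in _STOPS:
        raise ValueError("stop codon in pathway counting")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a in _STOPS or b in _STOPS or _aa(a) != _aa(b):
                nd += 1.0
            else:
                sd += 1.0
    k = float(len(usable))
    return sd / k, nd / k


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 0.75: Jukes-Cantor correction undefined (saturated)")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class CodonPairStats:
    """NG86 summary for one aligned codon pair."""

    codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    omega: float | None  # None when Ks == 0 (undefined, not infinity)
    saturated: bool = False


def _codon_columns(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        yield ca, cb


def ng86(aligned_a: str, aligned_b: str, min_codons: int = 30) -> CodonPairStats:
    """Nei–Gojobori Ka/Ks on a codon-aware alignment (gap columns and stop
    codons excluded).  Saturated pairs (ps or pn >= 0.75) are flagged and
    returned with NaN rates."""
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in _codon_columns(aligned_a.upper(), aligned_b.upper()):
        n_codons += 1
        sa, na = syn_site_fraction(ca)
        sb, nb = syn_site_fraction(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    if n_codons < min_codons:
        raise ValueError(f"only {n_codons} ungapped codon columns (< {min_codons})")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return CodonPairStats(n_codons, S, N, Sd, Nd, ps, pn,
                              np.nan, np.nan, None, saturated=True)
    ks = _jc(ps)
    ka = _jc(pn)
    omega = None if ks == 0 else ka / ks
    return CodonPairStats(n_codons, S, N, Sd, Nd, ps, pn, ks, ka, omega)


# ---------------------------------------------------------------------------
# codon-aware alignment


def _translate(cds: str) -> str:
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon")
    return prot


def align_codons(cds_a: str, cds_b: str, max_gap_fraction: float = 0.5):
    """Codon-aware pairwise alignment: global protein alignment (BLOSUM62,
    affine gaps) back-threaded onto the nucleotide sequences.  Returns
    (aligned_a, aligned_b) with '-' gaps in frame."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for s in (cds_a, cds_b):
        if len(s) % 3:
            raise ValueError("CDS length must be a multiple of 3")
    pa, pb = _translate(cds_a), _translate(cds_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(pa, pb)[0]
    out_a, out_b = [], []
    ia = ib = 0
    sa, sb = str(aln[0]), str(aln[1])
    for ca, cb in zip(sa, sb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    aligned_a, aligned_b = "".join(out_a), "".join(out_b)
    gap_frac = max(aligned_a.count("-") / len(aligned_a),
                   aligned_b.count("-") / len(aligned_b))
    if gap_frac > max_gap_fraction:
        raise ValueError(f"alignment is {gap_frac:.0%} gaps; pair skipped")
    return aligned_a, aligned_b


def kaks_pair(cds_a: str, cds_b: str, min_codons: int = 30) -> CodonPairStats:
    """Convenience: codon-aware alignment followed by NG86."""
    aa, ab = align_codons(cds_a, cds_b)
    return ng86(aa, ab, min_codons=min_codons)


# ---------------------------------------------------------------------------
# clocks and distributions


def ks_to_time(ks: float, mu: float = 1.5e-8) -> float:
    """Divergence time T = Ks / (2*mu) in years."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if ks < 0:
        raise ValueError("ks must be >= 0")
    return ks / (2.0 * mu)


def ks_distribution(ks_values, bandwidth: str | float = "silverman",
                    grid_points: int = 512, min_pairs: int = 30,
                    prominence_fraction: float = 0.05) -> dict:
    """Median, kernel-density peak count, and histogram of a Ks sample."""
    from scipy.signal import find_peaks
    from scipy.stats import gaussian_kde

    ks = np.asarray([k for k in ks_values if np.isfinite(k)], dtype=float)
    if ks.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} valid (unsaturated) pairs, got {ks.size}")
    median = float(np.median(ks))
    if np.allclose(ks, ks[0]):
        n_peaks = 1
        grid = np.array([ks[0]])
        density = np.array([1.0])
    else:
        kde = gaussian_kde(ks, bw_method=bandwidth)
        grid = np.linspace(0.0, ks.max() * 1.1 + 1e-9, grid_points)
        density = kde(grid)
        peaks, _ = find_peaks(density, prominence=prominence_fraction * density.max())
        if density[0] > density[1]:  # boundary peak at 0
            peaks = np.concatenate([[0], peaks])
        n_peaks = max(1, len(peaks))
    hist, edges = np.histogram(ks, bins=40)
    return {"median": median, "n_peaks": int(n_peaks), "n_pairs": int(ks.size),
            "hist_counts": hist, "hist_edges": edges, "kde_grid": grid,
            "kde_density": density}


# ---------------------------------------------------------------------------
# homoeologous-exchange scan


@dataclass
class ExchangeScanResult:
    chromosome: str
    start_rank: int
    end_rank: int
    n_pairs: int
    median_ks: float
    genome_median_ks: float
    exchanged: bool


def scan_homoeologous_exchange(pairs: pd.DataFrame, window: int = 50,
                               step: int = 25,
                               threshold_fraction: float = 0.5) -> list[ExchangeScanResult]:
    """Sliding-window scan of homoeolog Ks along each chromosome.  A window
    whose median Ks falls below ``threshold_fraction`` of the genome-wide
    median is flagged as a candidate homoeologous exchange (a recent
    segmental replacement resets divergence to ~0).

    ``pairs`` needs columns chromosome, rank, ks.
    """
    pairs = pairs.dropna(subset=["ks"])
    if pairs.empty:
        return []
    genome_median = float(pairs.ks.median())
    out = []
    for chrom, grp in pairs.groupby("chromosome", sort=True):
        grp = grp.sort_values("rank")
        ks = grp.ks.to_numpy()
        ranks = grp["rank"].to_numpy()
        n = len(grp)
        if n < window:
            warnings.warn(f"{chrom}: only {n} pairs (< window {window}); "
                          "using one whole-chromosome window", stacklevel=2)
            starts = [0]
            w = n
        else:
            starts = list(range(0, n - window + 1, step))
            if starts[-1] != n - window:
                starts.append(n - window)
            w = window
        for s in starts:
            sl = slice(s, s + w)
            med = float(np.median(ks[sl]))
            out.append(ExchangeScanResult(
                chromosome=chrom, start_rank=int(ranks[sl][0]),
                end_rank=int(ranks[sl][-1]), n_pairs=int(w), median_ks=med,
                genome_median_ks=genome_median,
                exchanged=bool(med < threshold_fraction * genome_median)))
    return out
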