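"""Syntenic block chaining, homoeolog pairing, tandem arrays, retention and
fractionation testing.

Homology candidates come from a k-mer-seeded all-vs-all search scored by
global alignment; the C-score filter (hit score over the best score of
either gene) at 0.99 keeps near-reciprocal-best pairs and discards paralogs
from older whole-genome duplications.  Collinear blocks are maximal strictly
monotone anchor chains extracted by gap-penalized dynamic programming over
the dot-plot, mirroring MCScan-style chaining with a minimum block size of
five anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "SyntenyBlock",
    "FractionationTest",
    "find_homology_pairs",
    "chain_blocks",
    "resolve_one_to_one",
    "syntenic_depth",
    "detect_tandem_gene_arrays",
    "classify_retention",
    "test_biased_fractionation",
]


@dataclass
class SyntenyBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    anchors: list  # [(gene_a, gene_b, rank_a, rank_b, score), ...] ordered by rank_a
    orientation: str  # "same" | "inverted"

    @property
    def size(self) -> int:
        return len(self.anchors)


@dataclass
class FractionationTest:
    lost_A: int
    lost_B: int
    binomial_p: float | None
    biased: bool | None
    note: str = ""


def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -4.0
    a.extend_gap_score = -1.0
    return a


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(0, len(seq) - k + 1)}


def find_homology_pairs(cds_a: dict, cds_b: dict, cscore: float = 0.99,
                        k: int = 13, min_shared_kmers: int = 15,
                        max_kmer_hits: int = 100) -> pd.DataFrame:
    """All-vs-all homology with C-score filtering.

    Candidates are gene pairs sharing >= ``min_shared_kmers`` k-mers
    (ubiquitous k-mers hitting > ``max_kmer_hits`` genes are skipped as
    repeats); each candidate is scored by global alignment and
    C(a,b) = score(a,b) / max(best(a), best(b)) must reach ``cscore``.
    When ``cds_a is cds_b`` the search is within-genome and self hits are
    excluded (use a low ``cscore`` there to keep tandem-family hits).

    Returns columns gene_a, gene_b, score, cscore.
    """
    if not cds_a or not cds_b:
        raise ValueError("empty CDS input")
    within = cds_a is cds_b
    index: dict[str, list] = {}
    for gid, seq in cds_b.items():
        for km in _kmer_set(seq, k):
            index.setdefault(km, []).append(gid)
    shared: dict[tuple, int] = {}
    for ga, seq in cds_a.items():
        counts: dict[str, int] = {}
        for km in _kmer_set(seq, k):
            hits = index.get(km)
            if hits is None or len(hits) > max_kmer_hits:
                continue
            for gb in hits:
                counts[gb] = counts.get(gb, 0) + 1
        for gb, c in counts.items():
            if within and gb == ga:
                continue
            if c >= min_shared_kmers:
                shared[(ga, gb)] = c
    aligner = _aligner()
    rows = []
    for (ga, gb), c in shared.items():
        if within and (gb, ga) in shared and gb < ga:
            continue  # score each unordered within-genome pair once
        s = float(aligner.score(cds_a[ga], cds_b[gb]))
        rows.append({"gene_a": ga, "gene_b": gb, "score": s})
    if not rows:
        return pd.DataFrame(columns=["gene_a", "gene_b", "score", "cscore"])
    df = pd.DataFrame(rows)
    if within:
        sym = pd.concat([df, df.rename(columns={"gene_a": "gene_b",
                                                "gene_b": "gene_a"})],
                        ignore_index=True)
        best = {}
        for r in sym.itertuples():
            best[r.gene_a] = max(best.get(r.gene_a, -np.inf), r.score)
        df["cscore"] = [r.score / max(best[r.gene_a], best[r.gene_b])
                        for r in df.itertuples()]
    else:
        best_a = df.groupby("gene_a").score.max()
        best_b = df.groupby("gene_b").score.max()
        df["cscore"] = df.score / np.maximum(best_a[df.gene_a].to_numpy(),
                                             best_b[df.gene_b].to_numpy())
    out = df[df.cscore >= cscore].reset_index(drop=True)
    return df.reset_index(drop=True) if cscore <= 0 else out


# ---------------------------------------------------------------------------
# chaining


def _longest_chain(anchors: np.ndarray, scores: np.ndarray, direction: int,
                   max_gap: int):
    """DP longest chain over anchors (rank_a, rank_b) with strictly
    increasing rank_a and strictly increasing (direction=+1) or decreasing
    (-1) rank_b; consecutive anchors at most ``max_gap`` apart in both
    dimensions.  Returns (indices, length)."""
    n = len(anchors)
    order = np.lexsort((anchors[:, 1] * direction, anchors[:, 0]))
    ra = anchors[order, 0]
    rb = anchors[order, 1] * direction
    L = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            da = ra[i] - ra[j]
            db = rb[i] - rb[j]
            if 0 < da <= max_gap and 0 < db <= max_gap and L[j] + 1 > L[i]:
                L[i] = L[j] + 1
                prev[i] = j
    best = int(np.argmax(L))
    chain = []
    while best != -1:
        chain.append(order[best])
        best = prev[best]
    return chain[::-1], int(L.max())


def chain_blocks(pairs: pd.DataFrame, gene_orders: dict, min_block: int = 5,
                 max_gap: int = 25) -> list[SyntenyBlock]:
    """Extract maximal non-overlapping collinear chains per chromosome pair.

    ``pairs`` needs gene_a/gene_b/score; ``gene_orders`` maps gene id to
    (chromosome, integer rank).  Chains are pulled greedily best-first until
    none of size >= ``min_block`` remains; each anchor is used once.
    """
    rows = []
    for r in pairs.itertuples():
        oa = gene_orders.get(r.gene_a)
        ob = gene_orders.get(r.gene_b)
        if oa is None or ob is None:
            continue
        rows.append((oa[0], ob[0], r.gene_a, r.gene_b, oa[1], ob[1], r.score))
    blocks: list[SyntenyBlock] = []
    bid = 0
    by_pair: dict[tuple, list] = {}
    for row in rows:
        by_pair.setdefault((row[0], row[1]), []).append(row)
    for (ca, cb), group in sorted(by_pair.items()):
        live = list(group)
        while True:
            if len(live) < min_block:
                break
            anchors = np.array([(g[4], g[5]) for g in live])
            scores = np.array([g[6] for g in live])
            cand = []
            for direction in (+1, -1):
                idxs, _ = _longest_chain(anchors, scores, direction, max_gap)
                cand.append((len(idxs), direction, idxs))
            size, direction, idxs = max(cand, key=lambda t: t[0])
            if size < min_block:
                break
            chain = [live[i] for i in idxs]
            bid += 1
            blocks.append(SyntenyBlock(
                block_id=bid, chrom_a=ca, chrom_b=cb,
                anchors=[(g[2], g[3], g[4], g[5], g[6]) for g in chain],
                orientation="same" if direction == 1 else "inverted"))
            used = set(idxs)
            live = [g for i, g in enumerate(live) if i not in used]
    return blocks


def resolve_one_to_one(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """1:1 homoeolog resolution inside blocks: per gene, the highest-scoring
    anchor wins; ties break toward the smaller partner rank."""
    anchors = []
    for b in blocks:
        for ga, gb, ra, rb, s in b.anchors:
            anchors.append({"gene_a": ga, "gene_b": gb, "rank_a": ra,
                            "rank_b": rb, "score": s, "block_id": b.block_id,
                            "chrom_a": b.chrom_a, "chrom_b": b.chrom_b})
    if not anchors:
        return pd.DataFrame(columns=["gene_a", "gene_b", "block_id",
                                     "chrom_a", "chrom_b", "rank_a", "rank_b",
                                     "score"])
    df = pd.DataFrame(anchors).sort_values(
        ["score", "rank_a", "rank_b"], ascending=[False, True, True])
    taken_a: set = set()
    taken_b: set = set()
    keep = []
    for r in df.itertuples():
        if r.gene_a in taken_a or r.gene_b in taken_b:
            continue
        taken_a.add(r.gene_a)
        taken_b.add(r.gene_b)
        keep.append(r.Index)
    return df.loc[keep].sort_values(["chrom_a", "rank_a"]).reset_index(drop=True)


def syntenic_depth(blocks: list[SyntenyBlock], ref_gene_orders: dict,
                   ref_side: str = "a") -> dict:
    """Per-reference-gene coverage depth: the number of block spans (on the
    reference side) covering each gene's rank.  Returns the histogram, the
    modal depth, and per-gene depths."""
    spans: dict[str, list] = {}
    for b in blocks:
        ranks = [a[2] if ref_side == "a" else a[3] for a in b.anchors]
        chrom = b.chrom_a if ref_side == "a" else b.chrom_b
        spans.setdefault(chrom, []).append((min(ranks), max(ranks)))
    depths = {}
    for gid, (chrom, rank) in ref_gene_orders.items():
        d = sum(1 for lo, hi in spans.get(chrom, []) if lo <= rank <= hi)
        depths[gid] = d
    counts = pd.Series(depths).value_counts().sort_index()
    mode = int(counts.idxmax()) if len(counts) else 0
    return {"histogram": counts.to_dict(), "modal_depth": mode,
            "per_gene": depths, "n_genes": len(depths)}


# ---------------------------------------------------------------------------
# tandem arrays, retention, fractionation


def detect_tandem_gene_arrays(within_hits: pd.DataFrame, gene_orders: dict,
                              max_gene_distance: int = 10) -> list[dict]:
    """Tandem gene arrays by single-linkage clustering of within-chromosome
    homology hits whose gene-rank distance is <= ``max_gene_distance``."""
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for r in within_hits.itertuples():
        oa = gene_orders.get(r.gene_a)
        ob = gene_orders.get(r.gene_b)
        if oa is None or ob is None or oa[0] != ob[0]:
            continue
        dist = abs(oa[1] - ob[1])
        if 1 <= dist <= max_gene_distance:
            union(r.gene_a, r.gene_b)
    clusters: dict[str, list] = {}
    for g in parent:
        clusters.setdefault(find(g), []).append(g)
    arrays = []
    for root, members in sorted(clusters.items()):
        if len(members) < 2:
            continue
        chrom = gene_orders[members[0]][0]
        arrays.append({"array_id": root, "chromosome": chrom,
                       "genes": sorted(members, key=lambda g: gene_orders[g][1]),
                       "size": len(members)})
    return arrays


def classify_retention(pairs: pd.DataFrame, all_genes: list,
                       pseudogene_partners: dict | None = None) -> dict:
    """Retention class per gene: ``pair`` (in a 1:1 homoeolog pair),
    ``gene+pseudogene`` (partner survives only as a pseudogene remnant), or
    ``single``.  Summary fraction retained = (paired + pseudogene-partnered)
    / total."""
    pseudogene_partners = pseudogene_partners or {}
    paired = set(pairs.gene_a) | set(pairs.gene_b)
    classes = {}
    for g in all_genes:
        if g in paired:
            if g in pseudogene_partners:
                raise ValueError(f"gene {g} both paired and pseudogene-partnered")
            classes[g] = "pair"
        elif g in pseudogene_partners:
            classes[g] = "gene+pseudogene"
        else:
            classes[g] = "single"
    n = len(classes)
    n_pair = sum(1 for v in classes.values() if v == "pair")
    n_pseudo = sum(1 for v in classes.values() if v == "gene+pseudogene")
    return {"classes": classes, "n_genes": n, "n_pair": n_pair,
            "n_gene_pseudogene": n_pseudo,
            "n_single": n - n_pair - n_pseudo,
            "fraction_retained": (n_pair + n_pseudo) / n if n else np.nan}


def test_biased_fractionation(losses_A: int, losses_B: int) -> FractionationTest:
    """Exact two-sided binomial test of equal loss rates (null p = 0.5)."""
    if losses_A < 0 or losses_B < 0:
        raise ValueError("loss counts must be >= 0")
    total = losses_A + losses_B
    if total == 0:
        return FractionationTest(0, 0, None, None,
                                 note="no losses: test undefined")
    p = float(binomtest(losses_A, total, 0.5).pvalue)
    return FractionationTest(losses_A, losses_B, p, p < 0.05)
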