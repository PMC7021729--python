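"""Synthetic allotetraploid generator with full ground truth.

Emulates the history of an allotetraploid grass: one diploid ancestor whose
two descendant lineages (the future A and B subgenomes) diverge
``t_divergence`` years ago, evolve independently, and merge into a single
tetraploid nucleus ``t_merger`` years ago.  The generator emits chromosome
sequences, gene annotations with homoeolog truth pairing, an LTR
retrotransposon landscape with true insertion ages, centromeric satellite
arrays from two monomer lineages, and a replicated multi-tissue expression
atlas with known per-pair bias states — everything the downstream analysis
stages consume, with truth tables for parameter-recovery testing.

Substitutions follow a Jukes–Cantor-like process (equal exchange rates,
uniform target base).  Coding sequences are composed of fourfold-degenerate
codon families so that third positions are exactly synonymous and first and
second positions (evolving at ``mu_neutral * ka_ks_true``) are exactly
nonsynonymous; the simulator's site bookkeeping therefore matches NG86 site
counting without approximation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "FamilySpec",
    "AtlasSpec",
    "SimConfig",
    "SimulatedPolyploid",
    "default_ltr_families",
    "simulate_progenitors",
    "simulate_ltr_landscape",
    "simulate_satellites",
    "simulate_atlas",
    "simulate_all",
    "write_outputs",
]

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
# Fourfold-degenerate codon families: Ala, Gly, Pro, Thr, Val.
FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT")


def jc_p_diff(mu: float, t: float) -> float:
    """Probability a site differs from its ancestor after time ``t`` under a
    Jukes–Cantor process with substitution rate ``mu`` per site per year."""
    return 0.75 * (1.0 - np.exp(-4.0 * mu * t / 3.0))


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_sequence(seq: str, p_diff: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``p_diff``,
    drawing the new base uniformly from the three alternatives (the JC
    marginal at the corresponding time)."""
    if p_diff <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < p_diff)[0]
    lut = {ord(b): [ord(c) for c in BASES if c != b] for b in BASES}
    choices = rng.integers(0, 3, size=hits.size)
    for i, c in zip(hits, choices):
        arr[i] = lut[arr[i]][c]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class FamilySpec:
    """One LTR-RT family: where it may insert and when it was active.

    ``activity_window`` is (oldest_age, youngest_age) in years before present;
    insertion ages are drawn uniformly inside it.
    """

    name: str
    subgenome_restriction: str  # "A", "B", or "shared"
    activity_window: tuple[float, float]
    copies: int
    ltr_length: int = 500

    def __post_init__(self) -> None:
        start, end = self.activity_window
        if not (start >= end >= 0):
            raise ValueError("activity_window must be (oldest, youngest) with oldest >= youngest >= 0")
        if self.subgenome_restriction not in {"A", "B", "shared"}:
            raise ValueError("subgenome_restriction must be A, B or shared")


@dataclass
class AtlasSpec:
    """Expression-atlas shape and bias structure.

    ``frac_biased`` pairs receive a ±``effect_size_log2`` shift on one
    homoeolog (toward B with probability ``prob_bias_toward_B``);
    ``frac_consistent_across_tissues`` of the biased pairs keep that
    direction in every tissue, the rest flip it in at least one tissue.
    Replicate counts are negative binomial with NB2 ``dispersion`` alpha
    (variance m + alpha*m^2).
    """

    n_tissues: int = 10
    n_reps: int = 3
    dispersion: float = 0.05
    frac_biased: float = 0.30
    prob_bias_toward_B: float = 0.56
    frac_consistent_across_tissues: float = 0.869
    effect_size_log2: float = 1.0
    baseline_log_mean: float = 4.4  # natural-log mean of per-pair baseline (~80 counts)
    baseline_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")


def default_ltr_families(t_merger: float = 1.1e6) -> list[FamilySpec]:
    """The packaged TE landscape: six subgenome-specific families whose
    activity windows all end at the merger (five A-restricted, one
    B-restricted, as in the teff landscape) plus four shared families,
    three of them active after the merger."""
    fams = []
    starts = [2.0e6, 2.5e6, 3.0e6, 3.5e6, 4.0e6, 4.5e6]
    for i, s in enumerate(starts):
        sub = "A" if i < 5 else "B"
        fams.append(FamilySpec(f"RLG_spec{i + 1}", sub, (s, t_merger), copies=40))
    shared_windows = [(1.0e6, 0.0), (2.0e6, 0.0), (0.5e6, 0.0), (3.0e6, 1.5e6)]
    for i, w in enumerate(shared_windows):
        fams.append(FamilySpec(f"RLC_shared{i + 1}", "shared", w, copies=30))
    return fams


@dataclass
class SimConfig:
    """All knobs of the synthetic allotetraploid scenario.

    Defaults encode the published teff-like history: subgenome divergence
    5.0 Mya, merger 1.1 Mya, neutral rate 1.5e-8 /site/yr at synonymous
    sites, LTR rate 1.3e-8 /site/yr, 159 bp satellite monomers, a
    10-tissue x 3-replicate atlas.
    """

    seed: int = 0
    n_chromosome_pairs: int = 10
    genes_per_chromosome: int = 40
    codons_per_gene: int = 300
    t_divergence: float = 5.0e6
    t_merger: float = 1.1e6
    mu_neutral: float = 1.5e-8
    mu_ltr: float = 1.3e-8
    ka_ks_true: float = 0.2
    ltr_families: list[FamilySpec] = field(default_factory=default_ltr_families)
    satellite_monomer_length: int = 159
    satellite_clade_divergence: float = 0.10
    satellite_copy_noise: float = 0.02
    satellite_copy_range: tuple[int, int] = (22, 824)
    fractionation_rate_A: float = 0.02
    fractionation_rate_B: float = 0.02
    pseudogene_fraction: float = 0.5
    tandem_rate: float = 0.02
    tandem_max_copies: int = 15
    inversion_count: int = 2
    intergenic_length: int = 300
    atlas: AtlasSpec = field(default_factory=AtlasSpec)

    def validate(self) -> None:
        if self.n_chromosome_pairs < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome pair and one gene per chromosome")
        if self.codons_per_gene < 100:
            raise ValueError("codons_per_gene must be >= 100")
        if not (0 <= self.t_merger < self.t_divergence or self.t_divergence == 0 == self.t_merger):
            if self.t_merger >= self.t_divergence and self.t_divergence > 0:
                raise ValueError("t_merger must be younger than t_divergence")
        for r in (self.mu_neutral, self.mu_ltr, self.fractionation_rate_A,
                  self.fractionation_rate_B, self.tandem_rate, self.satellite_copy_noise):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.satellite_monomer_length < 20:
            raise ValueError("satellite monomer must be >= 20 bp")
        if not 2 <= self.tandem_max_copies <= 15:
            raise ValueError("tandem_max_copies must be in [2, 15]")


# ---------------------------------------------------------------------------
# result container


@dataclass
class SimulatedPolyploid:
    """Full synthetic truth set produced by the generator stages."""

    config: SimConfig
    chrom_table: pd.DataFrame  # chromosome, subgenome, pair_index
    chrom_segments: dict  # chromosome -> list of sequence segments
    genes: pd.DataFrame  # per-gene truth table
    cds: dict  # gene_id -> CDS (retained + tandem copies + pseudogene remnants)
    ancestor_cds: dict  # ancestral diploid gene_id -> CDS
    ancestor_order: pd.DataFrame  # ancestral gene order (the diploid reference)
    ltr_elements: pd.DataFrame | None = None
    ltr_seqs: dict | None = None  # element_id -> (ltr5, ltr3)
    satellite_arrays: pd.DataFrame | None = None
    satellite_monomers: dict | None = None  # clade -> ancestral monomer
    atlas_counts: pd.DataFrame | None = None
    atlas_samples: pd.DataFrame | None = None
    atlas_truth: pd.DataFrame | None = None
    atlas_pair_truth: pd.DataFrame | None = None

    def chromosome_sequences(self) -> dict:
        return {c: "".join(segs) for c, segs in self.chrom_segments.items()}

    def homoeolog_truth_pairs(self) -> pd.DataFrame:
        """Truth 1:1 pairs where both homoeologs survive as genes."""
        g = self.genes
        ret = g[g.status.isin(["retained"])]
        a = ret[ret.subgenome == "A"][["ancestor", "gene_id", "chromosome"]]
        b = ret[ret.subgenome == "B"][["ancestor", "gene_id", "chromosome"]]
        m = a.merge(b, on="ancestor", suffixes=("_A", "_B"))
        return m.rename(columns={"gene_id_A": "gene_A", "gene_id_B": "gene_B"})


# ---------------------------------------------------------------------------
# stage 1: progenitors, fractionation, tandems, inversions


def _random_cds_body(n_codons: int, rng: np.random.Generator) -> str:
    pref = rng.integers(0, len(FOURFOLD_PREFIXES), size=n_codons)
    third = rng.integers(0, 4, size=n_codons)
    return "".join(FOURFOLD_PREFIXES[p] + BASES[t] for p, t in zip(pref, third))


def _evolve_cds_body(body: str, t: float, mu: float, omega: float,
                     rng: np.random.Generator) -> str:
    """Evolve a CDS body for ``t`` years: third codon positions substitute at
    ``mu`` (synonymous in the fourfold families), first/second at
    ``mu*omega`` (nonsynonymous).  Substitutions creating stop codons are
    redirected to a non-stop alternative."""
    L = len(body)
    if t <= 0 or L == 0:
        return body
    p3 = jc_p_diff(mu, t)
    p12 = jc_p_diff(mu * omega, t)
    pos = np.arange(L)
    p = np.where(pos % 3 == 2, p3, p12)
    hits = np.nonzero(rng.random(L) < p)[0]
    s = list(body)
    for i in hits:
        ci = i - i % 3
        alts = [b for b in BASES if b != s[i]]
        order = rng.permutation(3)
        for j in order:
            cand = s[ci:ci + 3]
            cand[i - ci] = alts[j]
            if "".join(cand) not in STOP_CODONS:
                s[i] = alts[j]
                break
    return "".join(s)


def _pseudogenize(cds: str, rng: np.random.Generator) -> str:
    """Corrupt a CDS into a pseudogene remnant: one frameshift deletion and
    extra substitutions."""
    s = mutate_sequence(cds, 0.03, rng)
    cut = int(rng.integers(3, max(4, len(s) - 3)))
    return s[:cut] + s[cut + 1:]


def simulate_progenitors(config: SimConfig) -> SimulatedPolyploid:
    """Evolve one ancestral diploid gene set along two lineages and merge
    them into an allotetraploid with truth-labelled A/B chromosomes.

    Applies per-gene fractionation (loss, optionally leaving a pseudogene
    remnant), tandem duplication, and whole-segment inversions, then lays
    genes onto chromosome sequences with random intergenic spacers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_chromosome_pairs
    gpc = config.genes_per_chromosome

    chrom_rows = []
    gene_rows = []
    cds: dict[str, str] = {}
    ancestor_cds: dict[str, str] = {}
    anc_rows = []
    chrom_segments: dict[str, list] = {}

    loss_rate = {"A": config.fractionation_rate_A, "B": config.fractionation_rate_B}

    for c in range(1, n_pairs + 1):
        anc_chrom = f"anc{c:02d}"
        bodies = [_random_cds_body(config.codons_per_gene, rng) for _ in range(gpc)]
        for j, body in enumerate(bodies):
            aid = f"{anc_chrom}_g{j + 1:04d}"
            ancestor_cds[aid] = "ATG" + body + "TAA"
            anc_rows.append({"gene_id": aid, "chromosome": anc_chrom, "rank": j})

        for sub in ("A", "B"):
            chrom = f"chr{c}{sub}"
            chrom_rows.append({"chromosome": chrom, "subgenome": sub, "pair_index": c})
            order = []  # list of dicts, in gene order, before inversions
            for j, body in enumerate(bodies):
                aid = f"{anc_chrom}_g{j + 1:04d}"
                gid = f"Eg{c:02d}{sub}_{j + 1:04d}"
                evolved = _evolve_cds_body(body, config.t_divergence,
                                           config.mu_neutral, config.ka_ks_true, rng)
                seq = "ATG" + evolved + "TAA"
                status = "retained"
                if rng.random() < loss_rate[sub]:
                    status = "pseudogene" if rng.random() < config.pseudogene_fraction else "lost"
                if status == "lost":
                    gene_rows.append({"gene_id": gid, "ancestor": aid, "chromosome": chrom,
                                      "subgenome": sub, "status": "lost", "strand": "+",
                                      "tandem_array_id": ""})
                    continue
                if status == "pseudogene":
                    seq = _pseudogenize(seq, rng)
                entry = {"gene_id": gid, "ancestor": aid, "status": status,
                         "seq": seq, "strand": "+", "tandem_array_id": ""}
                order.append(entry)
                if status == "retained" and rng.random() < config.tandem_rate:
                    n_copies = int(rng.integers(2, config.tandem_max_copies + 1))
                    for k in range(2, n_copies + 1):
                        dup = mutate_sequence(seq, 0.01, rng)
                        order.append({"gene_id": f"{gid}_t{k}", "ancestor": aid,
                                      "status": "tandem_copy", "seq": dup, "strand": "+",
                                      "tandem_array_id": gid})
                    entry["tandem_array_id"] = gid

            # inversions: reverse a contiguous run of gene order, flip strands
            for _ in range(config.inversion_count):
                if rng.random() < 1.0 / n_pairs and len(order) >= 6:
                    w = int(rng.integers(3, max(4, len(order) // 3) + 1))
                    s0 = int(rng.integers(0, len(order) - w + 1))
                    seg = order[s0:s0 + w][::-1]
                    for e in seg:
                        e["strand"] = "-" if e["strand"] == "+" else "+"
                    order[s0:s0 + w] = seg

            segments = []
            pos = 0
            for rank, e in enumerate(order):
                spacer = _random_seq(config.intergenic_length, rng)
                segments.append(spacer)
                pos += len(spacer)
                start = pos + 1  # GFF3 1-based
                segments.append(e["seq"])
                pos += len(e["seq"])
                gene_rows.append({"gene_id": e["gene_id"], "ancestor": e["ancestor"],
                                  "chromosome": chrom, "subgenome": sub,
                                  "status": e["status"], "strand": e["strand"],
                                  "rank": rank, "start": start, "end": pos,
                                  "tandem_array_id": e["tandem_array_id"]})
                cds[e["gene_id"]] = e["seq"]
            chrom_segments[chrom] = segments

    genes = pd.DataFrame(gene_rows)
    if "rank" not in genes.columns:
        genes["rank"] = np.nan
    return SimulatedPolyploid(
        config=config,
        chrom_table=pd.DataFrame(chrom_rows),
        chrom_segments=chrom_segments,
        genes=genes,
        cds=cds,
        ancestor_cds=ancestor_cds,
        ancestor_order=pd.DataFrame(anc_rows),
    )


# ---------------------------------------------------------------------------
# stage 2: LTR landscape


def simulate_ltr_landscape(config: SimConfig, genome: SimulatedPolyploid,
                           allow_young_specific: bool = False) -> pd.DataFrame:
    """Place LTR-RT elements with ages drawn uniformly in each family's
    activity window; the two terminal repeats start identical and each
    accumulates substitutions at ``mu_ltr`` for the element's age, so
    E[pairwise divergence] = 2*mu_ltr*age."""
    import warnings

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    seqs: dict[str, tuple] = {}
    chrom_by_sub = {
        s: list(genome.chrom_table[genome.chrom_table.subgenome == s].chromosome)
        for s in ("A", "B")
    }
    for fam in config.ltr_families:
        start, end = fam.activity_window
        if fam.subgenome_restriction != "shared" and end < config.t_merger \
                and not allow_young_specific:
            warnings.warn(
                f"family {fam.name} is subgenome-restricted but its activity window "
                f"extends younger than the merger ({end:.3g} < {config.t_merger:.3g} yr)",
                stacklevel=2)
        for k in range(fam.copies):
            sub = fam.subgenome_restriction
            if sub == "shared":
                sub = "A" if rng.random() < 0.5 else "B"
            chrom = chrom_by_sub[sub][int(rng.integers(0, len(chrom_by_sub[sub])))]
            age = float(rng.uniform(end, start)) if start > end else float(start)
            anc = _random_seq(fam.ltr_length, rng)
            p = jc_p_diff(config.mu_ltr, age)
            ltr5 = mutate_sequence(anc, p, rng)
            ltr3 = mutate_sequence(anc, p, rng)
            eid = f"{fam.name}_{k + 1:03d}"
            internal = _random_seq(300, rng)
            seg = ltr5 + internal + ltr3
            offset = sum(len(s) for s in genome.chrom_segments[chrom])
            genome.chrom_segments[chrom].append(seg)
            rows.append({"element_id": eid, "family": fam.name, "chromosome": chrom,
                         "subgenome": sub, "start": offset + 1, "end": offset + len(seg),
                         "ltr_length": fam.ltr_length, "true_age": age,
                         "family_restriction": fam.subgenome_restriction})
            seqs[eid] = (ltr5, ltr3)
    elements = pd.DataFrame(rows)
    genome.ltr_elements = elements
    genome.ltr_seqs = seqs
    return elements


# ---------------------------------------------------------------------------
# stage 3: centromeric satellites


def simulate_satellites(config: SimConfig, genome: SimulatedPolyploid) -> pd.DataFrame:
    """Append one tandem satellite array per chromosome.  Two monomer
    lineages (clades) are derived from a common random monomer at the
    configured clade divergence; the truth clade of each array is its
    chromosome's subgenome."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    base = _random_seq(config.satellite_monomer_length, rng)
    d = config.satellite_clade_divergence
    mon = {"A": mutate_sequence(base, d / 2.0, rng),
           "B": mutate_sequence(base, d / 2.0, rng)}
    unresolvable = d <= 0
    lo, hi = config.satellite_copy_range
    rows = []
    for _, ch in genome.chrom_table.iterrows():
        chrom = ch.chromosome
        clade = "A" if unresolvable else ch.subgenome
        n_copies = int(rng.integers(lo, hi + 1))
        copies = [mutate_sequence(mon[clade], config.satellite_copy_noise, rng)
                  for _ in range(n_copies)]
        arr = "".join(copies)
        offset = sum(len(s) for s in genome.chrom_segments[chrom])
        genome.chrom_segments[chrom].append(arr)
        rows.append({"chromosome": chrom, "start": offset, "end": offset + len(arr),
                     "true_clade": clade, "copy_number": n_copies,
                     "monomer_length": config.satellite_monomer_length,
                     "unresolvable": unresolvable})
    arrays = pd.DataFrame(rows)
    genome.satellite_arrays = arrays
    genome.satellite_monomers = mon
    return arrays


# ---------------------------------------------------------------------------
# stage 4: expression atlas


def simulate_atlas(config: SimConfig, genome: SimulatedPolyploid) -> pd.DataFrame:
    """Negative-binomial expression atlas over the truth homoeolog pairs.

    Returns the counts matrix (genes x tissue_rep); truth tables land on the
    genome object (``atlas_truth`` per pair per tissue, ``atlas_pair_truth``
    per pair).
    """
    spec = config.atlas
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    pairs = genome.homoeolog_truth_pairs()
    if pairs.empty:
        raise ValueError("no surviving homoeolog pairs to build an atlas over")
    n = len(pairs)
    tissues = [f"tissue{t + 1:02d}" for t in range(spec.n_tissues)]

    baseline = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n))
    biased = rng.random(n) < spec.frac_biased
    toward_b = rng.random(n) < spec.prob_bias_toward_B
    consistent = rng.random(n) < spec.frac_consistent_across_tissues
    # direction per pair per tissue: +1 = A-dominant, -1 = B-dominant, 0 = none
    direction = np.zeros((n, spec.n_tissues), dtype=int)
    for i in range(n):
        if not biased[i]:
            continue
        d = -1 if toward_b[i] else 1
        direction[i, :] = d
        if not consistent[i]:
            n_flip = int(rng.integers(1, max(2, spec.n_tissues // 2 + 1)))
            flip = rng.choice(spec.n_tissues, size=n_flip, replace=False)
            direction[i, flip] = -d

    tissue_factor = np.exp(rng.normal(0.0, 0.2, size=(n, spec.n_tissues)))
    shift = 2.0 ** (spec.effect_size_log2 * direction)
    mean_A = baseline[:, None] * tissue_factor * np.where(direction > 0, shift, 1.0)
    mean_B = baseline[:, None] * tissue_factor * np.where(direction < 0, 2.0 ** (
        spec.effect_size_log2 * -direction), 1.0)

    inv_disp = 1.0 / spec.dispersion
    cols = {}
    lib = rng.uniform(0.7, 1.3, size=(spec.n_tissues, spec.n_reps))
    for t in range(spec.n_tissues):
        for r in range(spec.n_reps):
            mA = mean_A[:, t] * lib[t, r]
            mB = mean_B[:, t] * lib[t, r]
            lamA = rng.gamma(inv_disp, mA * spec.dispersion)
            lamB = rng.gamma(inv_disp, mB * spec.dispersion)
            col = f"{tissues[t]}_r{r + 1}"
            cols[col] = (rng.poisson(lamA), rng.poisson(lamB))

    index = list(pairs.gene_A) + list(pairs.gene_B)
    data = {c: np.concatenate([a, b]) for c, (a, b) in cols.items()}
    counts = pd.DataFrame(data, index=index)
    counts.index.name = "gene_id"

    samples = pd.DataFrame(
        [{"sample": f"{t}_r{r + 1}", "tissue": t, "replicate": r + 1}
         for t in tissues for r in range(spec.n_reps)])

    truth_rows = []
    pair_ids = [f"pair{i + 1:05d}" for i in range(n)]
    for i in range(n):
        for t, tis in enumerate(tissues):
            truth_rows.append({"pair_id": pair_ids[i], "gene_A": pairs.gene_A.iloc[i],
                               "gene_B": pairs.gene_B.iloc[i], "tissue": tis,
                               "true_direction": {1: "A", -1: "B", 0: "none"}[direction[i, t]]})
    truth = pd.DataFrame(truth_rows)
    pair_truth = pd.DataFrame({
        "pair_id": pair_ids,
        "gene_A": pairs.gene_A.values, "gene_B": pairs.gene_B.values,
        "chromosome_A": pairs.chromosome_A.values,
        "chromosome_B": pairs.chromosome_B.values,
        "true_biased": biased,
        "true_direction": np.where(biased, np.where(toward_b, "B", "A"), "none"),
        "true_consistent": np.where(biased, consistent, False),
    })
    genome.atlas_counts = counts
    genome.atlas_samples = samples
    genome.atlas_truth = truth
    genome.atlas_pair_truth = pair_truth
    return counts


def simulate_all(config: SimConfig) -> SimulatedPolyploid:
    """Run all four generator stages in order."""
    genome = simulate_progenitors(config)
    simulate_ltr_landscape(config, genome)
    simulate_satellites(config, genome)
    simulate_atlas(config, genome)
    return genome


# ---------------------------------------------------------------------------
# writers


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["ltr_families"] = [asdict(f) for f in config.ltr_families]
    return d


def config_hash(config: SimConfig) -> str:
    import yaml

    return hashlib.sha256(
        yaml.safe_dump(config_to_dict(config), sort_keys=True).encode()).hexdigest()


def write_outputs(genome: SimulatedPolyploid, outdir) -> dict:
    """Write the standard file bundle (FASTA/GFF3/BED/TSV/YAML).  Returns
    {name: path}.  Truth labels travel as ``truth_*`` GFF3 attributes and
    dedicated truth TSVs."""
    import os

    import yaml

    from . import gffio

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    gffio.write_fasta(genome.chromosome_sequences(), p("genome.fasta"))
    gffio.write_fasta(genome.cds, p("cds.fasta"))
    gffio.write_fasta(genome.ancestor_cds, p("ancestor_cds.fasta"))

    g = genome.genes
    placed = g[g.status != "lost"]
    feats = [{"seqid": r.chromosome, "source": "polysub_sim", "type": "gene",
              "start": int(r.start), "end": int(r.end), "score": ".",
              "strand": r.strand, "phase": ".",
              "attributes": {"ID": r.gene_id, "truth_ancestor": r.ancestor,
                             "truth_status": r.status,
                             "truth_subgenome": r.subgenome}}
             for r in placed.itertuples()]
    gffio.write_gff3(feats, p("genes.gff3"))
    g.to_csv(p("truth_genes.tsv"), sep="\t", index=False)

    if genome.ltr_elements is not None:
        feats = [{"seqid": r.chromosome, "source": "polysub_sim",
                  "type": "LTR_retrotransposon", "start": int(r.start),
                  "end": int(r.end), "score": ".", "strand": "+", "phase": ".",
                  "attributes": {"ID": r.element_id, "family": r.family,
                                 "ltr_length": str(r.ltr_length),
                                 "truth_age": f"{r.true_age:.1f}",
                                 "truth_subgenome": r.subgenome}}
                 for r in genome.ltr_elements.itertuples()]
        gffio.write_gff3(feats, p("ltr.gff3"))
        ltr_fa = {}
        for eid, (l5, l3) in genome.ltr_seqs.items():
            ltr_fa[f"{eid}_5p"] = l5
            ltr_fa[f"{eid}_3p"] = l3
        gffio.write_fasta(ltr_fa, p("ltr_ltrs.fasta"))
        genome.ltr_elements.to_csv(p("truth_ltr.tsv"), sep="\t", index=False)

    if genome.satellite_arrays is not None:
        gffio.write_bed(
            [(r.chromosome, int(r.start), int(r.end), f"sat_{r.chromosome}")
             for r in genome.satellite_arrays.itertuples()], p("satellites.bed"))
        genome.satellite_arrays.to_csv(p("truth_satellites.tsv"), sep="\t", index=False)

    if genome.atlas_counts is not None:
        genome.atlas_counts.to_csv(p("counts.tsv"), sep="\t")
        genome.atlas_samples.to_csv(p("samples.tsv"), sep="\t", index=False)
        genome.atlas_truth.to_csv(p("truth_atlas.tsv"), sep="\t", index=False)
        genome.atlas_pair_truth.to_csv(p("truth_pairs.tsv"), sep="\t", index=False)

    with open(p("config.yaml"), "w") as fh:
        yaml.safe_dump(config_to_dict(genome.config), fh, sort_keys=True)
    return paths
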