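"""End-to-end pipeline, input validation, and the consolidated report.

``run_pipeline`` chains simulation (or user inputs), satellite phasing, LTR
dating, synteny/homoeolog pairing, Ka/Ks, the homoeologous-exchange scan and
expression-bias analysis, and emits a JSON report whose summary block holds
the headline quantities: subgenome divergence time, polyploidy bracket,
retention fraction, fractionation p, repeat-content excess, bias shares and
cross-tissue consistency.
"""

from __future__ import annotations

import hashlib
import json
import os
import time

import numpy as np
import pandas as pd

from . import expression, ltr, molevol, satellites, simulate, synteny

__version__ = "0.1.0"


def percent_excess(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent: 100*(a-b)/b."""
    if b <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (a - b) / b


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(paths: dict) -> list[dict]:
    """Diagnose FASTA/GFF3/BED/TSV bundles without mutating anything.

    ``paths`` may hold keys genome_fasta, cds_fasta, genes_gff3, bed,
    counts_tsv, samples_tsv.  Returns a machine-readable issue list (empty
    when clean)."""
    from . import gffio

    issues = []

    def issue(path, what):
        issues.append({"path": path, "issue": what})

    for key in ("genome_fasta", "cds_fasta"):
        p = paths.get(key)
        if p is None:
            continue
        if not os.path.exists(p):
            issue(p, "missing file")
            continue
        seqs = gffio.read_fasta(p)
        if not seqs:
            issue(p, "no FASTA records")
        for name, s in seqs.items():
            if set(s) - set("ACGTN"):
                issue(p, f"record {name} has non-ACGTN characters")
                break
    gff_ids = set()
    p = paths.get("genes_gff3")
    if p is not None:
        if not os.path.exists(p):
            issue(p, "missing file")
        else:
            try:
                gff = gffio.read_gff3(p)
            except ValueError as e:
                gff = None
                issue(p, str(e))
            if gff is not None and len(gff):
                bad = gff[gff.end < gff.start]
                for r in bad.itertuples():
                    issue(p, f"feature end < start at {r.seqid}:{r.start}-{r.end}")
                if (gff.start < 1).any():
                    issue(p, "GFF3 coordinates must be 1-based (start >= 1)")
                if "attr_ID" in gff.columns:
                    gff_ids = set(gff.attr_ID.dropna())
    p = paths.get("bed")
    if p is not None:
        if not os.path.exists(p):
            issue(p, "missing file")
        else:
            bed = gffio.read_bed(p)
            if len(bed) and (bed.end <= bed.start).any():
                issue(p, "BED interval with end <= start (0-based half-open expected)")
    p = paths.get("counts_tsv")
    samples = None
    if p is not None:
        if not os.path.exists(p):
            issue(p, "missing file")
        else:
            counts = pd.read_csv(p, sep="\t", index_col=0)
            if (counts.to_numpy() < 0).any():
                issue(p, "negative counts")
            sp = paths.get("samples_tsv")
            if sp is not None and os.path.exists(sp):
                samples = pd.read_csv(sp, sep="\t")
                missing = set(samples["sample"]) - set(counts.columns)
                for m in sorted(missing):
                    issue(sp, f"sample sheet column {m} missing from counts matrix")
            elif sp is not None:
                issue(sp, "missing file")
            if gff_ids:
                unknown = set(counts.index) - gff_ids
                if unknown:
                    issue(p, f"{len(unknown)} count rows not present in the gene GFF3")
    return issues


def run_pipeline(config: simulate.SimConfig, outdir: str,
                 write_files: bool = True) -> dict:
    """Run all stages on a simulated scenario and return the report dict.

    Stage order mirrors the analysis narrative: simulate, phase satellites,
    date LTRs (subgenome labels taken from the phasing), pair homoeologs in
    syntenic blocks, Ka/Ks and divergence time, homoeologous-exchange scan,
    expression bias.  Partial outputs are written as stages complete.
    """
    t0 = time.time()
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"stages": {}, "summary": {}}
    manifest = {"seed": config.seed, "config_hash": simulate.config_hash(config),
                "software_version": __version__,
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": []}

    def stage_done(name, outputs=()):
        manifest["stages"].append({
            "stage": name, "elapsed_s": round(time.time() - t0, 2),
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs
                        if os.path.exists(p)}})

    # --- simulate -----------------------------------------------------
    genome = simulate.simulate_all(config)
    paths = simulate.write_outputs(genome, outdir) if write_files else {}
    report["stages"]["simulate"] = {
        "n_chromosomes": int(len(genome.chrom_table)),
        "n_genes": int((genome.genes.status != "lost").sum()),
        "n_ltr_elements": int(len(genome.ltr_elements)),
        "n_satellite_arrays": int(len(genome.satellite_arrays)),
        "n_atlas_pairs": int(len(genome.atlas_pair_truth)),
    }
    stage_done("simulate", paths.values())

    # --- satellite phasing -------------------------------------------
    consensuses = {}
    detected_periods = {}
    chrom_seqs = genome.chromosome_sequences()
    sat = genome.satellite_arrays.set_index("chromosome")
    for chrom, seq in chrom_seqs.items():
        region = seq[sat.loc[chrom, "start"]:sat.loc[chrom, "end"]]
        arrays = satellites.detect_tandem_arrays(region, min_copies=5)
        if arrays:
            best = max(arrays, key=lambda a: a.copy_number)
            consensuses[chrom] = best.consensus
            detected_periods[chrom] = best.monomer_period
    pairs_of_chroms = [(f"chr{c}A", f"chr{c}B")
                       for c in range(1, config.n_chromosome_pairs + 1)]
    phasing = satellites.phase_subgenomes(consensuses,
                                          homoeolog_pairs=pairs_of_chroms,
                                          seed=config.seed)
    truth_lab = dict(zip(genome.chrom_table.chromosome, genome.chrom_table.subgenome))
    agree = np.mean([phasing.clade_assignments[c] == truth_lab[c]
                     for c in phasing.clade_assignments])
    phasing_accuracy = float(max(agree, 1 - agree))  # label swap is arbitrary
    report["stages"]["satellite_phasing"] = {
        "detected_periods": detected_periods,
        "clade_assignments": phasing.clade_assignments,
        "bootstrap_support": phasing.support["A"],
        "one_member_per_pair": phasing.consistent,
        "phasing_accuracy_vs_truth": phasing_accuracy,
    }
    if write_files:
        with open(os.path.join(outdir, "phasing.newick"), "w") as fh:
            fh.write(phasing.newick + "\n")
        pd.DataFrame({"chromosome": list(phasing.clade_assignments),
                      "subgenome": list(phasing.clade_assignments.values())}) \
            .to_csv(os.path.join(outdir, "subgenome_assignments.tsv"),
                    sep="\t", index=False)
    # use phased labels downstream, remapped onto truth letters if swapped
    labels = phasing.clade_assignments
    if agree < 0.5:
        labels = {c: ("A" if v == "B" else "B") for c, v in labels.items()}
    stage_done("satellite_phasing",
               [os.path.join(outdir, "phasing.newick"),
                os.path.join(outdir, "subgenome_assignments.tsv")])

    # --- LTR dating ---------------------------------------------------
    elements = ltr.elements_from_simulation(genome, subgenome_labels=labels)
    ltr.annotate_elements(elements, mu=config.mu_ltr)
    fam_reports = ltr.classify_family_specificity(elements, min_copies=5)
    bracket = ltr.bracket_polyploidy(fam_reports)
    report["stages"]["ltr_dating"] = {
        "n_families_reported": len(fam_reports),
        "n_specific_families": sum(
            1 for r in fam_reports if r.specificity.endswith("-specific")),
        "bracket": {k: v for k, v in bracket.items() if k != "evidence"},
        "polyploidy_estimate_myr": (None if bracket["estimate"] is None
                                    else bracket["estimate"] / 1e6),
    }
    if write_files:
        ltr.elements_to_frame(elements).to_csv(
            os.path.join(outdir, "ltr_elements.tsv"), sep="\t", index=False)
    stage_done("ltr_dating", [os.path.join(outdir, "ltr_elements.tsv")])

    # --- synteny and homoeolog pairing -------------------------------
    genes = genome.genes
    placed = genes[genes.status.isin(["retained", "tandem_copy", "pseudogene"])]
    cds_a = {r.gene_id: genome.cds[r.gene_id]
             for r in placed.itertuples() if r.subgenome == "A" and r.status != "pseudogene"}
    cds_b = {r.gene_id: genome.cds[r.gene_id]
             for r in placed.itertuples() if r.subgenome == "B" and r.status != "pseudogene"}
    gene_orders = {r.gene_id: (r.chromosome, int(r.rank))
                   for r in placed.itertuples() if pd.notna(r.rank)}
    hits = synteny.find_homology_pairs(cds_a, cds_b, cscore=0.99)
    blocks = synteny.chain_blocks(hits, gene_orders, min_block=5)
    pairs11 = synteny.resolve_one_to_one(blocks)

    within_a = synteny.find_homology_pairs(cds_a, cds_a, cscore=0.0)
    tandem_arrays = synteny.detect_tandem_gene_arrays(within_a, gene_orders,
                                                      max_gene_distance=10)

    # retention + fractionation from the A-side perspective using truth
    # pseudogene partners (a caller with real data supplies GFF3 tags)
    pseudo = genes[genes.status == "pseudogene"]
    pseudo_by_anc = {}
    for r in pseudo.itertuples():
        pseudo_by_anc.setdefault(r.ancestor, r.subgenome)
    retained_main = genes[genes.status == "retained"]
    pg_partner = {}
    for r in retained_main.itertuples():
        other = pseudo_by_anc.get(r.ancestor)
        if other is not None and other != r.subgenome:
            pg_partner[r.gene_id] = f"pseudo:{r.ancestor}"
    main_a = [g for g in cds_a if gene_orders.get(g) and not g.endswith(tuple(
        f"_t{i}" for i in range(2, 16)))]
    main_b = [g for g in cds_b if not any(g.endswith(f"_t{i}") for i in range(2, 16))]
    paired_genes = set(pairs11.gene_a) | set(pairs11.gene_b)
    pg_partner = {g: v for g, v in pg_partner.items() if g not in paired_genes}
    retention = synteny.classify_retention(
        pairs11.rename(columns={"gene_a": "gene_a", "gene_b": "gene_b"}),
        main_a + main_b, pg_partner)
    losses = genes[genes.status.isin(["lost", "pseudogene"])]
    lost_a = int((losses.subgenome == "A").sum())
    lost_b = int((losses.subgenome == "B").sum())
    frac_test = synteny.test_biased_fractionation(lost_a, lost_b)
    report["stages"]["synteny"] = {
        "n_candidate_hits": int(len(hits)),
        "n_blocks": len(blocks),
        "n_homoeolog_pairs": int(len(pairs11)),
        "n_tandem_arrays": len(tandem_arrays),
        "fraction_retained": retention["fraction_retained"],
        "fractionation": {"lost_A": lost_a, "lost_B": lost_b,
                          "binomial_p": frac_test.binomial_p,
                          "biased": frac_test.biased},
    }
    if write_files:
        pairs11.to_csv(os.path.join(outdir, "homoeolog_pairs.tsv"),
                       sep="\t", index=False)
    stage_done("synteny", [os.path.join(outdir, "homoeolog_pairs.tsv")])

    # --- Ka/Ks and divergence time ------------------------------------
    kaks_rows = []
    cds_all = genome.cds
    for r in pairs11.itertuples():
        try:
            st = molevol.kaks_pair(cds_all[r.gene_a], cds_all[r.gene_b])
        except ValueError:
            continue
        kaks_rows.append({"gene_a": r.gene_a, "gene_b": r.gene_b,
                          "chromosome": r.chrom_a, "rank": r.rank_a,
                          "ka": st.Ka, "ks": st.Ks, "omega": st.omega})
    kaks = pd.DataFrame(kaks_rows)
    dist = molevol.ks_distribution(kaks.ks)
    div_time = molevol.ks_to_time(dist["median"], mu=config.mu_neutral)
    report["stages"]["kaks"] = {
        "n_pairs": int(len(kaks)), "median_ks": dist["median"],
        "median_ka": float(kaks.ka.median()),
        "n_ks_peaks": dist["n_peaks"],
        "divergence_time_myr": div_time / 1e6,
    }
    if write_files:
        kaks.to_csv(os.path.join(outdir, "kaks.tsv"), sep="\t", index=False)
    stage_done("kaks", [os.path.join(outdir, "kaks.tsv")])

    # --- homoeologous-exchange scan -----------------------------------
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        scan = molevol.scan_homoeologous_exchange(kaks)
    n_flagged = sum(1 for w in scan if w.exchanged)
    report["stages"]["exchange_scan"] = {
        "n_windows": len(scan), "n_flagged": n_flagged,
    }
    stage_done("exchange_scan")

    # --- expression bias ----------------------------------------------
    pair_truth = genome.atlas_pair_truth
    records = expression.heb_table(genome.atlas_counts,
                                   pair_truth[["pair_id", "gene_A", "gene_B"]],
                                   genome.atlas_samples)
    chrom_pairs = pair_truth.assign(
        chromosome_pair=pair_truth.chromosome_A.str.rstrip("A"))[
        ["pair_id", "chromosome_pair"]]
    summary = expression.dominance_consistency(records, chrom_pairs)
    report["stages"]["expression_bias"] = {
        "n_pairs": int(pair_truth.shape[0]),
        "n_significant_comparisons": summary.extras["n_significant_comparisons"],
        "b_share_significant_pct": 100.0 * summary.b_share_significant,
        "consistent_share_pct": 100.0 * summary.consistent_share,
        "n_consistent": summary.n_consistent,
        "n_reversing": summary.n_reversing,
        "n_never_biased": summary.n_never_biased,
    }
    if write_files:
        records.to_csv(os.path.join(outdir, "heb_records.tsv"), sep="\t",
                       index=False)
    stage_done("expression_bias", [os.path.join(outdir, "heb_records.tsv")])

    # --- repeat content ----------------------------------------------
    te = genome.ltr_elements.assign(length=lambda d: d.end - d.start + 1)
    te["label"] = te.chromosome.map(labels)
    rep = te.groupby("label").length.sum() / 1e6
    rep_a, rep_b = float(rep.get("A", 0)), float(rep.get("B", 0))
    excess = percent_excess(max(rep_a, rep_b), min(rep_a, rep_b)) \
        if min(rep_a, rep_b) > 0 else None
    report["stages"]["repeat_content"] = {
        "repeat_mb_A": rep_a, "repeat_mb_B": rep_b,
        "percent_excess_larger_subgenome": excess,
    }

    report["summary"] = {
        "subgenome_divergence_myr": div_time / 1e6,
        "polyploidy_bracket_myr": report["stages"]["ltr_dating"]["polyploidy_estimate_myr"],
        "fraction_retained": retention["fraction_retained"],
        "fractionation_binomial_p": frac_test.binomial_p,
        "repeat_excess_pct": excess,
        "b_share_significant_pct": report["stages"]["expression_bias"]["b_share_significant_pct"],
        "consistent_share_pct": report["stages"]["expression_bias"]["consistent_share_pct"],
        "exchange_windows_flagged": n_flagged,
    }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    report["manifest"] = manifest
    if write_files:
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def format_report(report: dict) -> str:
    """Human-readable one-screen summary of a pipeline report."""
    s = report["summary"]
    lines = [
        "polysub pipeline summary",
        "------------------------",
        f"subgenome divergence:      {s['subgenome_divergence_myr']:.2f} Myr",
        f"polyploidy bracket:        {s['polyploidy_bracket_myr']:.2f} Myr"
        if s["polyploidy_bracket_myr"] is not None else
        "polyploidy bracket:        undetermined",
        f"gene retention fraction:   {s['fraction_retained']:.3f}",
        f"fractionation p (binomial):{s['fractionation_binomial_p']:.3f}",
        f"repeat excess (A vs B):    "
        + (f"{s['repeat_excess_pct']:.1f}%" if s["repeat_excess_pct"] is not None else "n/a"),
        f"HE windows flagged:        {s['exchange_windows_flagged']}",
        f"B-ward share (signif.):    {s['b_share_significant_pct']:.1f}%",
        f"consistent dominance:      {s['consistent_share_pct']:.1f}%",
    ]
    return "\n".join(lines)
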