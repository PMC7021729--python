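"""Expression-bias tests: HEB identities, NB Wald behavior vs a
likelihood-ratio oracle, type-I control, dominance and Ka/Ks strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from polysub import expression as ex
from polysub import simulate as sim


# ---------------------------------------------------------------------------
# heb identities


def test_heb_basic_values():
    assert ex.heb(10.0, 10.0) == 0.0
    assert ex.heb(300.0, 100.0) == pytest.approx(np.log2(3), abs=0.02)
    with pytest.raises(ValueError):
        ex.heb(-1.0, 5.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(a=st.floats(0, 1e5), b=st.floats(0, 1e5))
def test_heb_antisymmetry(a, b):
    assert ex.heb(a, b) == pytest.approx(-ex.heb(b, a), abs=1e-9)


# ---------------------------------------------------------------------------
# NB Wald test


def _nb_loglik(x, m, alpha):
    r = 1.0 / alpha
    p = r / (r + m)
    return float(np.sum(gammaln(x + r) - gammaln(r) - gammaln(x + 1)
                        + r * np.log(p) + x * np.log1p(-p)))


def lr_oracle(a, b, alpha):
    """Likelihood-ratio test on the same NB model with fixed dispersion.
    With known alpha the NB MLE of a group mean is the sample mean."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ll_sep = _nb_loglik(a, max(a.mean(), 1e-9), alpha) + \
        _nb_loglik(b, max(b.mean(), 1e-9), alpha)
    pooled = np.concatenate([a, b])
    ll_com = _nb_loglik(pooled, max(pooled.mean(), 1e-9), alpha)
    lr = 2 * (ll_sep - ll_com)
    return stats.chi2.sf(max(lr, 0), 1)


def test_pair_tissue_identical_replicates():
    z, p, fc = ex.test_pair_tissue([100, 110, 90], [100, 110, 90])
    assert fc == 0.0
    assert p > 0.9


def test_pair_tissue_clear_difference_agrees_with_lr_oracle():
    a, b = [200, 220, 180], [100, 110, 90]
    z, p, fc = ex.test_pair_tissue(a, b, dispersion=0.01)
    assert fc == pytest.approx(1.0, abs=0.1)
    assert p < 0.05
    assert lr_oracle(a, b, 0.01) < 0.05
    # a hopeless case is insignificant for both routes
    z2, p2, _ = ex.test_pair_tissue([100, 140, 80], [95, 135, 100],
                                    dispersion=0.05)
    assert p2 > 0.05 and lr_oracle([100, 140, 80], [95, 135, 100], 0.05) > 0.05


def test_pair_tissue_not_expressed_and_validation():
    z, p, fc = ex.test_pair_tissue([0, 0, 0], [0, 0, 0])
    assert np.isnan(p) and np.isnan(fc)
    with pytest.raises(ValueError, match="replicates"):
        ex.test_pair_tissue([1], [2, 3])


@pytest.mark.parametrize("trial", range(10))
def test_wald_and_lr_oracle_significance_calls_agree(trial):
    """On random NB draws with a known dispersion, the Wald p and the LR
    oracle p agree on the call at alpha 0.05 away from the boundary."""
    rng = np.random.default_rng(trial)
    disp, m = 0.05, 150
    shift = 2.0 if trial % 2 else 1.0
    a = rng.poisson(rng.gamma(1 / disp, m * disp * shift, 4))
    b = rng.poisson(rng.gamma(1 / disp, m * disp, 4))
    _, p_wald, _ = ex.test_pair_tissue(a, b, dispersion=disp)
    p_lr = lr_oracle(a, b, disp)
    if min(p_wald, p_lr) < 0.01 or max(p_wald, p_lr) > 0.2:
        assert (p_wald < 0.05) == (p_lr < 0.05)


def _null_matrix(seed, disp, n_pairs, n_tissues=2):
    cfg = sim.SimConfig(seed=seed, n_chromosome_pairs=1,
                        genes_per_chromosome=n_pairs, codons_per_gene=100,
                        t_divergence=0, t_merger=0, fractionation_rate_A=0,
                        fractionation_rate_B=0, tandem_rate=0,
                        inversion_count=0, intergenic_length=10)
    cfg.atlas.frac_biased = 0.0
    cfg.atlas.dispersion = disp
    cfg.atlas.n_tissues = n_tissues
    g = sim.simulate_progenitors(cfg)
    sim.simulate_atlas(cfg, g)
    return g


@pytest.mark.parametrize("disp", [0.01, 0.2, 1.0])
def test_type_one_error_controlled_across_dispersions(disp):
    """Under the NB null the raw rejection rate stays at or below nominal
    (within Monte-Carlo error) and BH-adjusted discoveries are rare."""
    g = _null_matrix(900 + int(disp * 100), disp, 1500)
    rec = ex.heb_table(g.atlas_counts,
                       g.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]],
                       g.atlas_samples)
    ok = rec.p.notna()
    n = int(ok.sum())
    raw_rate = float((rec.p[ok] < 0.05).mean())
    mc_margin = 2 * np.sqrt(0.05 * 0.95 / n)
    assert raw_rate <= 0.05 + mc_margin
    assert (rec.padj[ok] < 0.05).mean() <= 0.05


def test_classify_bias_thresholds():
    rec = pd.DataFrame({
        "pair_id": ["p1", "p2", "p3", "p4"],
        "tissue": "t1",
        "heb": [0.8, -0.8, 0.5, 0.1],
        "p": [0.001, 0.001, 0.2, np.nan],
        "padj": [0.01, 0.01, 0.2, np.nan],
    })
    cls = ex.classify_bias(rec, alpha=0.05)
    assert list(cls) == ["A", "B", "balanced", "not_expressed"]


def test_relabeling_subgenomes_negates_heb_and_swaps_classes(atlas_genome):
    cfg, g = atlas_genome
    pairs = g.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]].head(300)
    swapped = pairs.rename(columns={"gene_A": "gene_B", "gene_B": "gene_A"})
    r1 = ex.heb_table(g.atlas_counts, pairs, g.atlas_samples)
    r2 = ex.heb_table(g.atlas_counts, swapped, g.atlas_samples)
    assert np.allclose(r1.heb, -r2.heb)
    swap = {"A": "B", "B": "A", "balanced": "balanced",
            "not_expressed": "not_expressed"}
    assert list(r2.bias_class) == [swap[c] for c in r1.bias_class]


def test_bias_class_counts_partition_tested_pairs(atlas_genome):
    cfg, g = atlas_genome
    rec = ex.heb_table(g.atlas_counts,
                       g.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]],
                       g.atlas_samples)
    summ = ex.dominance_consistency(rec)
    n_pairs = g.atlas_pair_truth.shape[0]
    for r in summ.per_tissue.itertuples():
        assert r.n_A + r.n_B + r.n_balanced + r.n_not_expressed == n_pairs
    assert summ.n_consistent + summ.n_reversing + summ.n_never_biased == n_pairs


def test_dominance_labels_toy_cases():
    rows = []
    for t in range(10):
        # pair1: A-biased in 3 tissues, balanced elsewhere
        rows.append(("pair1", f"t{t}", 0.9 if t < 3 else 0.01,
                     0.01 if t < 3 else 0.5))
        # pair2: A in one tissue, B in another
        heb = 0.9 if t == 0 else (-0.9 if t == 1 else 0.0)
        rows.append(("pair2", f"t{t}", heb, 0.01 if t < 2 else 0.5))
        # pair3: never significant
        rows.append(("pair3", f"t{t}", 0.2, 0.3))
    rec = pd.DataFrame(rows, columns=["pair_id", "tissue", "heb", "padj"])
    rec["p"] = rec.padj
    rec["bias_class"] = ex.classify_bias(rec)
    summ = ex.dominance_consistency(rec)
    labels = summ.per_pair.set_index("pair_id").label
    assert labels["pair1"] == "consistent_A"
    assert labels["pair2"] == "reversing"
    assert labels["pair3"] == "never_biased"


def test_consistency_share_recovers_generator_parameter(atlas_genome):
    """High-power atlas: the recovered consistent share sits near the
    generator's 0.869 (detection misses inflate it slightly)."""
    cfg, g = atlas_genome
    rec = ex.heb_table(g.atlas_counts,
                       g.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]],
                       g.atlas_samples)
    summ = ex.dominance_consistency(rec)
    assert summ.consistent_share == pytest.approx(
        cfg.atlas.frac_consistent_across_tissues, abs=0.04)


def test_b_share_among_significant_matches_direction_truth(atlas_genome):
    """The B-ward share among significant comparisons recovers the realized
    truth share of the generated atlas (which itself sits within binomial
    error of the direction parameter)."""
    cfg, g = atlas_genome
    rec = ex.heb_table(g.atlas_counts,
                       g.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]],
                       g.atlas_samples)
    summ = ex.dominance_consistency(rec)
    assert summ.extras["n_significant_comparisons"] > 500
    truth = g.atlas_truth
    truth_share = (truth[truth.true_direction != "none"].true_direction == "B").mean()
    n_biased_pairs = int(g.atlas_pair_truth.true_biased.sum())
    p = cfg.atlas.prob_bias_toward_B
    assert abs(truth_share - p) < 4 * np.sqrt(p * (1 - p) / n_biased_pairs)
    assert summ.b_share_significant == pytest.approx(truth_share, abs=0.02)


def _records_with_strata(rng, n_none=300, n_all=300, omega_none=0.17,
                         omega_all=0.28, spread=0.05):
    stats_rows = []
    for i in range(n_none):
        stats_rows.append({"pair_id": f"n{i}", "n_biased_tissues": 0,
                           "omega": max(rng.normal(omega_none, spread), 0.01),
                           "ks": max(rng.normal(0.15, 0.03), 0.01)})
    for i in range(n_all):
        stats_rows.append({"pair_id": f"a{i}", "n_biased_tissues": 10,
                           "omega": max(rng.normal(omega_all, spread), 0.01),
                           "ks": max(rng.normal(0.15, 0.03), 0.01)})
    return pd.DataFrame(stats_rows)


def _dummy_summary():
    per_pair = pd.DataFrame({"pair_id": ["x"], "label": ["never_biased"]})
    per_tissue = pd.DataFrame({"tissue": [f"t{i}" for i in range(10)]})
    return ex.DominanceSummary(per_pair=per_pair, per_tissue=per_tissue,
                               per_chromosome=None, n_consistent=0,
                               n_reversing=0, n_never_biased=1,
                               consistent_share=np.nan,
                               b_share_significant=np.nan)


def test_kaks_by_heb_separated_strata(rng):
    df = _records_with_strata(rng)
    out = ex.kaks_by_heb(df, _dummy_summary())
    assert out["median_omega"]["none"] == pytest.approx(0.17, abs=0.02)
    assert out["median_omega"]["all"] == pytest.approx(0.28, abs=0.02)
    assert out["mannwhitney_p_omega"] < 0.01
    assert out["mannwhitney_p_ks"] > 0.01  # no divergence difference built in


def test_kaks_by_heb_null_is_nonsignificant(rng):
    hits = 0
    for rep in range(10):
        df = _records_with_strata(np.random.default_rng(rep),
                                  omega_none=0.2, omega_all=0.2)
        out = ex.kaks_by_heb(df, _dummy_summary())
        hits += out["mannwhitney_p_omega"] < 0.01
    assert hits <= 1  # alpha 0.01: >=95% of replicate runs stay null


def test_kaks_by_heb_skips_small_strata(rng):
    df = _records_with_strata(rng, n_none=5, n_all=5)
    with pytest.warns(UserWarning, match="minimum size"):
        out = ex.kaks_by_heb(df, _dummy_summary())
    assert out["mannwhitney_p_omega"] is None


def test_size_factors_recover_library_scaling(rng):
    true = np.array([0.5, 1.0, 2.0, 1.0])
    base = rng.poisson(np.outer(rng.lognormal(4, 0.5, 400), true))
    counts = pd.DataFrame(base, columns=list("abcd"))
    sf = ex.size_factors(counts)
    ratio = sf.to_numpy() / true
    assert np.allclose(ratio, ratio[0], rtol=0.05)
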