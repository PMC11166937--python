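"""Core-set construction and reversal metrics (sign flips, correlation, GSEA)."""

import numpy as np
import pandas as pd
import pytest

from gravisig.io import DEGTable, GeneSet
from gravisig.reversal import (
    CoreSet,
    build_core_set,
    gsea_es,
    lfc_correlation,
    reversal_fraction,
    reversal_report,
)
from gravisig.signatures import GeneSignature, build_signature
from gravisig.simulate import simulate_deg_pair


def _deg(rows, **kw):
    return DEGTable(pd.DataFrame(rows, columns=["gene", "log2fc", "p", "adj_p"]), **kw)


def _sig(lfcs: dict[str, float]) -> GeneSignature:
    entries = pd.DataFrame(
        {
            "direction": np.sign(list(lfcs.values())).astype(int),
            "log2fc": list(lfcs.values()),
            "adj_p": [0.01] * len(lfcs),
        },
        index=pd.Index(list(lfcs), name="gene"),
    )
    return GeneSignature("sc", entries)


def _core(lfcs: dict[str, float]) -> CoreSet:
    df = pd.DataFrame(
        {"log2fc_ref": list(lfcs.values()),
         "direction": np.sign(list(lfcs.values())).astype(int)},
        index=pd.Index(list(lfcs), name="gene"),
    )
    return CoreSet(df)


# ---------------------------------------------------------------------------
# build_core_set
# ---------------------------------------------------------------------------

def test_core_set_requires_concordance():
    sig = _sig({"A": 0.4, "B": -0.4})
    bulk = _deg([("A", 0.3, 0.01, np.nan), ("B", 0.3, 0.01, np.nan)])
    core = build_core_set(sig, bulk)
    assert core.genes == {"A"}
    assert core.up_set.genes == {"A"}


def test_core_set_bulk_p_threshold():
    sig = _sig({"A": 0.4})
    bulk = _deg([("A", 0.3, 0.06, np.nan)])
    with pytest.raises(ValueError, match="empty core"):
        build_core_set(sig, bulk)


def test_core_set_matches_independent_recomputation():
    """Core equals a direct pandas recomputation on a simulated table pair."""
    a, b, truth = simulate_deg_pair(n_genes=800, sig_size=80,
                                    concordant_fraction=0.4, seed=5)
    sig = build_signature(a)
    core = build_core_set(sig, b)

    sig_df = a.df[(a.df["adj_p"] < 0.05) & (a.df["log2fc"].abs() > 0.1)]
    merged = sig_df.merge(b.df, on="gene", suffixes=("_sc", "_bulk"))
    expected = set(
        merged.loc[
            (merged["p_bulk"] < 0.05)
            & (np.sign(merged["log2fc_sc"]) == np.sign(merged["log2fc_bulk"]))
            & (merged["log2fc_bulk"] != 0),
            "gene",
        ]
    )
    assert core.genes == expected
    assert truth.planted_concordant_genes <= core.genes


def test_core_set_partition_is_disjoint_cover():
    core = _core({"A": 0.5, "B": -0.2, "C": 1.0})
    assert core.up_set.genes | core.down_set.genes == core.genes
    assert not (core.up_set.genes & core.down_set.genes)


# ---------------------------------------------------------------------------
# reversal_fraction
# ---------------------------------------------------------------------------

def test_reversal_headline_seventy_percent():
    """74 sign flips among 106 core genes print as 70%."""
    genes = [f"g{i:03d}" for i in range(106)]
    ref = {g: 0.5 if i % 2 else -0.5 for i, g in enumerate(genes)}
    core = _core(ref)
    treated_lfc = {g: (-v if i < 74 else v) for i, (g, v) in enumerate(ref.items())}
    treated = _deg([(g, v, 0.01, np.nan) for g, v in treated_lfc.items()])
    n_rev, frac, pct = reversal_fraction(core, treated)
    assert n_rev == 74
    assert frac == pytest.approx(74 / 106)
    assert pct == 70


def test_reversal_identity_and_negation():
    core = _core({"A": 0.5, "B": -0.3, "C": 1.2})
    same = _deg([("A", 0.5, 0.01, np.nan), ("B", -0.3, 0.01, np.nan), ("C", 1.2, 0.01, np.nan)])
    flipped = _deg([("A", -0.5, 0.01, np.nan), ("B", 0.3, 0.01, np.nan), ("C", -1.2, 0.01, np.nan)])
    assert reversal_fraction(core, same) == (0, 0.0, 0)
    assert reversal_fraction(core, flipped) == (3, 1.0, 100)


def test_reversal_zero_treated_lfc_not_reversed():
    core = _core({"A": 0.5})
    treated = _deg([("A", 0.0, 0.01, np.nan)])
    assert reversal_fraction(core, treated)[0] == 0


def test_reversal_missing_core_genes_errors():
    core = _core({"A": 0.5})
    with pytest.raises(ValueError, match="no core gene"):
        reversal_fraction(core, _deg([("X", 0.1, 0.5, np.nan)]))


# ---------------------------------------------------------------------------
# lfc_correlation
# ---------------------------------------------------------------------------

def test_correlation_extremes():
    core = _core({"A": 0.5, "B": -0.3, "C": 1.2})
    same = _deg([("A", 0.5, 0.01, np.nan), ("B", -0.3, 0.01, np.nan), ("C", 1.2, 0.01, np.nan)])
    flipped = _deg([("A", -0.5, 0.01, np.nan), ("B", 0.3, 0.01, np.nan), ("C", -1.2, 0.01, np.nan)])
    assert lfc_correlation(core, same)[0] == pytest.approx(1.0)
    assert lfc_correlation(core, flipped)[0] == pytest.approx(-1.0)


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(14)
    ref = rng.normal(0, 1, 10)
    trt = -0.5 * ref + rng.normal(0, 0.4, 10)
    genes = [f"g{i}" for i in range(10)]
    core = _core(dict(zip(genes, ref)))
    treated = _deg([(g, float(v), 0.01, np.nan) for g, v in zip(genes, trt)])
    r, _ = lfc_correlation(core, treated)
    x, y = ref, trt
    expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(expected, rel=1e-12)


def test_correlation_zero_variance_errors():
    core = _core({"A": 0.5, "B": 0.5, "C": 0.5})
    treated = _deg([("A", 0.1, 0.5, np.nan), ("B", 0.2, 0.5, np.nan), ("C", 0.3, 0.5, np.nan)])
    with pytest.raises(ValueError, match="variance"):
        lfc_correlation(core, treated)


# ---------------------------------------------------------------------------
# gsea_es
# ---------------------------------------------------------------------------

def brute_force_es(stats: np.ndarray, hits: np.ndarray, w: float) -> float:
    """Oracle: explicit prefix-sum loop, signed value at maximal |deviation|."""
    n_hit = int(hits.sum())
    denom = float(np.sum(np.abs(stats[hits]) ** w))
    running, best = 0.0, 0.0
    for s, h in zip(stats, hits):
        running += (abs(s) ** w) / denom if h else -1.0 / (len(stats) - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def test_gsea_single_gene_first_is_one():
    ranking = pd.Series([5.0, 4.0, 3.0, 2.0], index=["a", "b", "c", "d"])
    es, _ = gsea_es(ranking, GeneSet("s", frozenset({"a"})), weight_exp=0.0, n_perm=0)
    assert es == pytest.approx(1.0)


def test_gsea_single_gene_last_matches_prefix_minimum():
    ranking = pd.Series([5.0, 4.0, 3.0, 2.0], index=["a", "b", "c", "d"])
    es, _ = gsea_es(ranking, GeneSet("s", frozenset({"d"})), weight_exp=0.0, n_perm=0)
    stats = np.array([5.0, 4.0, 3.0, 2.0])
    hits = np.array([False, False, False, True])
    assert es == pytest.approx(brute_force_es(stats, hits, 0.0))
    assert es == pytest.approx(-1.0)  # all three misses walk to -(N-1)/(N-1)


def test_gsea_weighted_matches_prefix_sum():
    rng = np.random.default_rng(6)
    stats = np.sort(rng.normal(0, 2, 8))[::-1]
    genes = [f"g{i}" for i in range(8)]
    hits = np.zeros(8, dtype=bool)
    hits[[1, 4, 6]] = True
    ranking = pd.Series(stats, index=genes)
    es, _ = gsea_es(ranking, GeneSet("s", frozenset(np.array(genes)[hits])),
                    weight_exp=1.0, n_perm=0)
    assert es == pytest.approx(brute_force_es(stats, hits, 1.0))


def test_gsea_antisymmetric_under_negation():
    rng = np.random.default_rng(7)
    stats = rng.normal(0, 1, 12)
    genes = [f"g{i:02d}" for i in range(12)]
    s = GeneSet("s", frozenset({"g02", "g05", "g09"}))
    up = pd.Series(stats, index=genes)
    es_pos, _ = gsea_es(up, s, weight_exp=0.0, n_perm=0)
    es_neg, _ = gsea_es(-up, s, weight_exp=0.0, n_perm=0)
    assert es_neg == pytest.approx(-es_pos)


def test_gsea_permutation_p_reproducible():
    rng = np.random.default_rng(8)
    ranking = pd.Series(rng.normal(0, 1, 30), index=[f"g{i:02d}" for i in range(30)])
    s = GeneSet("s", frozenset({"g00", "g01", "g02", "g03"}))
    es1, p1 = gsea_es(ranking, s, n_perm=200, seed=42)
    es2, p2 = gsea_es(ranking, s, n_perm=200, seed=42)
    assert (es1, p1) == (es2, p2)
    assert 0 < p1 <= 1


def test_gsea_degenerate_sets_error():
    ranking = pd.Series([2.0, 1.0], index=["a", "b"])
    with pytest.raises(ValueError):
        gsea_es(ranking, GeneSet("s", frozenset({"a", "b"})), n_perm=0)
    with pytest.raises(ValueError):
        gsea_es(ranking, GeneSet("s", frozenset({"zzz"})), n_perm=0)


# ---------------------------------------------------------------------------
# reversal_report
# ---------------------------------------------------------------------------

def _mixed_core(n=40, seed=2):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n)]
    lfc = np.concatenate([rng.uniform(0.2, 1.5, n // 2), rng.uniform(-1.5, -0.2, n - n // 2)])
    return _core(dict(zip(genes, lfc)))


def test_report_identity_treatment():
    core = _mixed_core()
    treated = _deg([(g, float(v), 0.01, np.nan)
                    for g, v in core.df["log2fc_ref"].items()])
    rep = reversal_report(core, treated, seed=1, n_perm=50)
    assert rep.percent_reversed == 0
    assert rep.pearson_r == pytest.approx(1.0)
    assert rep.es_up_treated == pytest.approx(rep.es_up_ref)
    assert rep.es_up_ref > 0  # up-set genes sit atop the reference ranking


def test_report_full_reversal_flips_es():
    core = _mixed_core()
    treated = _deg([(g, float(-v), 0.01, np.nan)
                    for g, v in core.df["log2fc_ref"].items()])
    rep = reversal_report(core, treated, seed=1, n_perm=50, weight_exp=0.0)
    assert rep.percent_reversed == 100
    assert rep.pearson_r == pytest.approx(-1.0)
    assert rep.es_up_treated == pytest.approx(-rep.es_up_ref)


def test_report_planted_partial_reversal():
    """A treatment flipping ~70% of core genes reports ~70% and negative r."""
    rng = np.random.default_rng(7)
    core = _mixed_core(n=106, seed=7)
    ref = core.df["log2fc_ref"]
    flip = np.zeros(len(ref), dtype=bool)
    flip[rng.choice(len(ref), size=74, replace=False)] = True
    treated_vals = np.where(flip, -ref.to_numpy(), ref.to_numpy())
    treated = _deg([(g, float(v), 0.01, np.nan) for g, v in zip(ref.index, treated_vals)])
    rep = reversal_report(core, treated, seed=7, n_perm=50)
    assert rep.n_reversed == 74
    assert rep.percent_reversed == 70
    assert rep.pearson_r < 0
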