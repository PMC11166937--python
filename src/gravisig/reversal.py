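"""Countermeasure assessment: does a treatment reverse a microgravity signature?

The reference object is a :class:`CoreSet` — genes significant and
sign-concordant between the single-cell signature and an independent bulk
contrast of the same comparison, partitioned into up- and down-regulated
halves.  Against a treated-condition DE table, reversal is quantified three
ways:

* sign-flip fraction (headline percent, nearest-integer as conventionally
  printed: 74/106 reported as 70%);
* Pearson correlation of reference vs treated log2 fold changes (negative r
  = systematic reversal);
* classic GSEA running-sum enrichment scores of the up- and down-sets on the
  reference and treated fold-change rankings — sign inversion of the ES
  under treatment is the enrichment-level evidence of reversal.

The ES convention is the signed running-sum value at the point of maximal
absolute deviation (not the maximum positive excursion), so inversion is
representable as a sign change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import DEGTable, GeneSet
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "CoreSet",
    "ReversalReport",
    "build_core_set",
    "reversal_fraction",
    "lfc_correlation",
    "gsea_es",
    "reversal_report",
]


@dataclass
class CoreSet:
    """Cross-platform concordant genes with their reference fold changes.

    ``df`` is indexed by gene with columns log2fc_ref and direction; the up
    and down partitions are disjoint and together cover every gene.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        d = np.sign(self.df["log2fc_ref"].to_numpy())
        if not np.array_equal(d, self.df["direction"].to_numpy()):
            raise ValueError("CoreSet: direction must equal sign(log2fc_ref)")
        if (d == 0).any():
            raise ValueError("CoreSet: zero reference fold change is directionless")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.df.index)

    @property
    def up_set(self) -> GeneSet:
        return GeneSet("core_up", frozenset(self.df.index[self.df["direction"] > 0]))

    @property
    def down_set(self) -> GeneSet:
        return GeneSet("core_down", frozenset(self.df.index[self.df["direction"] < 0]))


@dataclass
class ReversalReport:
    """Bundle of reversal evidence for one treatment."""

    n_core: int
    n_reversed: int
    fraction_reversed: float
    percent_reversed: int  # nearest-integer headline
    pearson_r: float
    pearson_p: float
    es_up_ref: float
    es_up_treated: float
    es_down_ref: float
    es_down_treated: float
    es_p_up_ref: float
    es_p_up_treated: float
    es_p_down_ref: float
    es_p_down_treated: float
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_core_set(
    sc_sig: GeneSignature, bulk: DEGTable, bulk_p_max: float = 0.05
) -> CoreSet:
    """Core set = signature genes significant and sign-concordant in bulk.

    A gene qualifies when its bulk raw p is strictly below ``bulk_p_max``
    and its bulk fold change has the same sign as the signature direction.
    The reference fold change stored is the signature's (single-cell) one.
    """
    bulk_sig = bulk.df[(bulk.df["p"] < bulk_p_max) & (bulk.df["log2fc"] != 0)]
    bulk_dirs = dict(zip(bulk_sig["gene"], np.sign(bulk_sig["log2fc"]).astype(int)))
    rows = []
    n_discordant = 0
    for gene, row in sc_sig.entries.iterrows():
        d = bulk_dirs.get(gene)
        if d is None:
            continue
        if d == int(row["direction"]):
            rows.append((gene, float(row["log2fc"]), int(row["direction"])))
        else:
            n_discordant += 1
    if not rows:
        raise ValueError(
            "build_core_set: empty core "
            f"(signature {len(sc_sig)}, bulk significant {len(bulk_dirs)}, "
            f"shared-but-discordant {n_discordant})"
        )
    df = pd.DataFrame(rows, columns=["gene", "log2fc_ref", "direction"]).set_index("gene")
    return CoreSet(df.sort_index())


def _treated_lfc(core: CoreSet, treated: DEGTable) -> pd.Series:
    t = treated.df.set_index("gene")["log2fc"]
    shared = core.df.index.intersection(t.index)
    missing = core.df.index.difference(t.index)
    if len(shared) == 0:
        raise ValueError("no core gene present in the treated table")
    if len(missing):
        logger.info("%d core genes absent from the treated table: %s",
                    len(missing), sorted(missing)[:10])
    return t[shared]


def reversal_fraction(core: CoreSet, treated: DEGTable) -> tuple[int, float, int]:
    """(n_reversed, raw fraction, nearest-integer percent) of sign flips.

    A gene counts as reversed iff its treated fold change has the opposite
    sign to the reference; exact zero under treatment is not a reversal.
    Core genes missing from the treated table are excluded (and logged).
    """
    t = _treated_lfc(core, treated)
    ref_dir = core.df.loc[t.index, "direction"].to_numpy()
    t_sign = np.sign(t.to_numpy())
    reversed_mask = (t_sign != 0) & (t_sign != ref_dir)
    n_rev = int(reversed_mask.sum())
    frac = n_rev / len(t)
    return n_rev, frac, int(np.floor(100.0 * frac + 0.5))


def lfc_correlation(core: CoreSet, treated: DEGTable) -> tuple[float, float]:
    """Pearson r (and two-tailed p) of reference vs treated log2 fold changes."""
    t = _treated_lfc(core, treated)
    if len(t) < 3:
        raise ValueError("lfc_correlation: need at least 3 shared genes")
    ref = core.df.loc[t.index, "log2fc_ref"].to_numpy()
    trt = t.to_numpy()
    if np.ptp(ref) == 0 or np.ptp(trt) == 0:
        raise ValueError("lfc_correlation: zero variance in a fold-change vector")
    r, p = pearsonr(ref, trt)
    return float(r), float(p)


def _running_es(stats_sorted: np.ndarray, hit_sorted: np.ndarray,
                weight_exp: float) -> float:
    """Signed ES at the maximal |deviation| of the classic running sum."""
    n = len(stats_sorted)
    n_hit = int(hit_sorted.sum())
    n_miss = n - n_hit
    inc = np.abs(stats_sorted) ** weight_exp
    denom = inc[hit_sorted].sum()
    steps = np.where(
        hit_sorted,
        inc / denom if denom > 0 else (1.0 / n_hit if n_hit else 0.0),
        -1.0 / n_miss,
    )
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_es(
    ranking: "pd.Series | dict[str, float]",
    s: GeneSet,
    weight_exp: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Classic GSEA running-sum enrichment score with a permutation p-value.

    Genes are ordered by decreasing statistic (ties broken lexicographically
    by symbol).  Hits step up by |stat|^weight_exp normalized over the set's
    hits; misses step down by 1/(N - Nh).  The ES is the running-sum value at
    maximal absolute deviation, signed.  The two-sided p permutes gene labels
    (equivalently, the set's positions) with the seeded generator; ranked
    statistics, not expression replicates, are what is available here, so
    sample-label permutation is not an option.
    """
    if isinstance(ranking, dict):
        ranking = pd.Series(ranking, dtype=float)
    ranking = ranking.sort_index()
    genes = ranking.index.to_numpy()
    hit = np.isin(genes, list(s.genes))
    if not hit.any():
        raise ValueError("gsea_es: set disjoint from ranking")
    if hit.all():
        raise ValueError("gsea_es: set covers every ranked gene")
    order = np.lexsort((genes, -ranking.to_numpy()))
    stats_sorted = ranking.to_numpy()[order]
    hit_sorted = hit[order]

    es = _running_es(stats_sorted, hit_sorted, weight_exp)
    if n_perm <= 0:
        return es, float("nan")
    rng = np.random.default_rng(seed)
    n, n_hit = len(genes), int(hit.sum())
    count = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=n_hit, replace=False)] = True
        if abs(_running_es(stats_sorted, perm_hit, weight_exp)) >= abs(es) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return es, float(p)


def reversal_report(core: CoreSet, treated: DEGTable, seed: int = 0,
                    weight_exp: float = 1.0, n_perm: int = 1000) -> ReversalReport:
    """Full reversal assessment of one treatment against a core set.

    GSEA scores are computed for the up- and down-partitions on two rankings
    built over the core genes shared with the treated table: the reference
    fold changes and the treated fold changes.  Reversal manifests as the
    up-set ES flipping sign (and the down-set ES rising) between the two.
    """
    n_rev, frac, pct = reversal_fraction(core, treated)
    r, rp = lfc_correlation(core, treated)

    t = _treated_lfc(core, treated)
    ref_ranking = core.df.loc[t.index, "log2fc_ref"]
    up = GeneSet("core_up", frozenset(g for g in core.up_set.genes if g in t.index))
    down = GeneSet("core_down", frozenset(g for g in core.down_set.genes if g in t.index))

    es_u_ref, p_u_ref = gsea_es(ref_ranking, up, weight_exp, n_perm, seed)
    es_u_trt, p_u_trt = gsea_es(t, up, weight_exp, n_perm, seed + 1)
    es_d_ref, p_d_ref = gsea_es(ref_ranking, down, weight_exp, n_perm, seed + 2)
    es_d_trt, p_d_trt = gsea_es(t, down, weight_exp, n_perm, seed + 3)

    return ReversalReport(
        n_core=len(t), n_reversed=n_rev, fraction_reversed=frac, percent_reversed=pct,
        pearson_r=r, pearson_p=rp,
        es_up_ref=es_u_ref, es_up_treated=es_u_trt,
        es_down_ref=es_d_ref, es_down_treated=es_d_trt,
        es_p_up_ref=p_u_ref, es_p_up_treated=p_u_trt,
        es_p_down_ref=p_d_ref, es_p_down_treated=p_d_trt,
        seed=seed,
    )
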