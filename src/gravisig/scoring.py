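"""Per-cell / per-sample gene-set scores and group-difference statistics.

Three scoring flavours, matching how inflammatory-aging and senescence gene
sets are applied to expression data:

* :func:`iage_index` — a weighted-sum clock: the dot product of the
  normalized layer with published per-gene coefficients.
* :func:`module_score` — mean expression of a gene set minus the mean of
  expression-matched control genes drawn from bins of average expression
  (the single-cell module-score construction).
* :func:`ssgsea_score` — single-sample enrichment: a rank-weighted ECDF
  difference over one sample's profile (used for bulk samples).

Group comparisons use the two-tailed Mann–Whitney test, exact by permutation
enumeration for small combined n and tie-corrected normal otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, WeightedGeneSet
from .signatures import _mwu_asymptotic

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "GroupComparison",
    "iage_index",
    "module_score",
    "ssgsea_score",
    "relative_abundance",
    "compare_groups",
]


@dataclass
class ScoreVector:
    """One finite score per sample, with condition labels carried along."""

    samples: list[str]
    score: np.ndarray
    score_name: str
    condition: list[str]

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.samples) != len(self.score) or len(self.condition) != len(self.score):
            raise ValueError("ScoreVector: mismatched lengths")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("ScoreVector: non-finite scores")

    def __len__(self) -> int:
        return len(self.score)

    def values_for(self, label: str) -> np.ndarray:
        return self.score[[c == label for c in self.condition]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "score": self.score, "condition": self.condition}
        )


@dataclass
class GroupComparison:
    """Mann–Whitney comparison of one score between two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")
        if not (0.0 <= self.u_statistic <= self.n_a * self.n_b):
            raise ValueError("U outside [0, n_a * n_b]")


def _require_normalized(m: ExpressionMatrix) -> np.ndarray:
    if m.normalized is None:
        raise ValueError("normalized layer missing (call gravisig.signatures.normalize)")
    return m.normalized


def iage_index(m: ExpressionMatrix, w: WeightedGeneSet) -> ScoreVector:
    """Weighted-sum clock score per sample.

    score(sample) = sum over weighted genes present in the matrix of
    coefficient x normalized expression.  Genes absent from the matrix
    contribute 0 and are logged; if none are present that is an error, since
    the clock would be vacuous.
    """
    layer = _require_normalized(m)
    gene_idx = {g: i for i, g in enumerate(m.genes)}
    present = [(gene_idx[g], coef) for g, coef in w.weights.items() if g in gene_idx]
    absent = sorted(g for g in w.weights if g not in gene_idx)
    if not present:
        raise ValueError(f"iage_index: no gene of {w.name!r} present in the matrix")
    if absent:
        logger.info("iage_index: %d weighted genes absent: %s", len(absent), absent[:10])
    rows = np.array([i for i, _ in present])
    coefs = np.array([c for _, c in present])
    scores = coefs @ layer[rows, :]
    return ScoreVector(
        samples=list(m.samples), score=scores,
        score_name=f"iage:{w.name}", condition=list(m.condition),
    )


def module_score(
    m: ExpressionMatrix,
    s: GeneSet,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> ScoreVector:
    """Binned-control module score per sample.

    All genes are binned into ``nbin`` equal-frequency bins of average
    normalized expression.  For each set gene, ``nctrl`` control genes are
    drawn from its bin (without replacement when the bin is large enough,
    with replacement otherwise).  score(sample) = mean expression of the set
    genes minus mean expression of the pooled controls, so a constant matrix
    scores exactly 0 everywhere.
    """
    layer = _require_normalized(m)
    if nbin < 1:
        raise ValueError("module_score: nbin must be >= 1")
    gene_idx = {g: i for i, g in enumerate(m.genes)}
    set_idx = sorted(gene_idx[g] for g in s.genes if g in gene_idx)
    dropped = sorted(g for g in s.genes if g not in gene_idx)
    if dropped:
        logger.warning("module_score: dropping %d absent genes: %s", len(dropped), dropped[:10])
    if not set_idx:
        raise ValueError(f"module_score: no gene of {s.name!r} present in the matrix")

    avg = layer.mean(axis=1)
    # equal-frequency bins via average-expression ranks (ties share a bin order
    # determined by gene position, which the seed-fixed draw makes reproducible)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum((np.arange(len(avg)) * nbin) // len(avg), nbin - 1)

    rng = np.random.default_rng(seed)
    control_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero(bin_of == bin_of[gi])
        if len(pool) >= nctrl:
            control_idx.append(rng.choice(pool, size=nctrl, replace=False))
        else:
            control_idx.append(rng.choice(pool, size=nctrl, replace=True))
    controls = np.concatenate(control_idx)
    scores = layer[set_idx, :].mean(axis=0) - layer[controls, :].mean(axis=0)
    return ScoreVector(
        samples=list(m.samples), score=scores,
        score_name=f"module:{s.name}", condition=list(m.condition),
    )


def ssgsea_score(sample_profile: "pd.Series | dict[str, float]", s: GeneSet,
                 alpha: float = 0.25) -> float:
    """Single-sample enrichment score for one profile.

    Genes are ordered by decreasing value (ties broken lexicographically by
    symbol).  With position i = 1..N in that order, in-set genes at position
    i carry weight (N - i + 1)^alpha; the score is the summed difference
    between the weighted in-set ECDF and the uniform out-of-set ECDF.  At
    alpha = 0 the score depends on ranks only, hence is invariant to
    strictly monotone transforms of the profile.  Unnormalized.
    """
    if isinstance(sample_profile, dict):
        sample_profile = pd.Series(sample_profile, dtype=float)
    if len(s) == 0:
        raise ValueError("ssgsea_score: empty gene set")
    profile = sample_profile.sort_index()
    n = len(profile)
    in_set = profile.index.isin(s.genes)
    n_in = int(in_set.sum())
    if n_in == n:
        raise ValueError("ssgsea_score: set covers every profiled gene")
    if n < len(s) + 1:
        raise ValueError("ssgsea_score: profile must exceed the set size")

    order = np.lexsort((profile.index.to_numpy(), -profile.to_numpy()))
    hit = in_set.astype(bool)[order]
    weights = (n - np.arange(n)).astype(float) ** alpha
    w_in = np.where(hit, weights, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~hit) / float(n - n_in)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_matrix(
    m: ExpressionMatrix, s: GeneSet, alpha: float = 0.25, minmax: bool = False
) -> ScoreVector:
    """ssGSEA over every sample of a matrix.

    ``minmax=True`` rescales the batch of scores to [0, 1] (an optional
    across-sample normalization; raw scores are the default and are what
    single-score comparisons should use).
    """
    layer = _require_normalized(m)
    scores = np.array([
        ssgsea_score(pd.Series(layer[:, j], index=m.genes), s, alpha=alpha)
        for j in range(layer.shape[1])
    ])
    if minmax:
        span = scores.max() - scores.min()
        scores = (scores - scores.min()) / span if span > 0 else np.zeros_like(scores)
    return ScoreVector(
        samples=list(m.samples), score=scores,
        score_name=f"ssgsea:{s.name}", condition=list(m.condition),
    )


def relative_abundance(
    taxon_counts: pd.Series, total_counts: pd.Series
) -> pd.Series:
    """Taxon read frequency per sample: taxon reads / total (host + non-host) reads."""
    taxon = pd.Series(taxon_counts, dtype=float)
    total = pd.Series(total_counts, dtype=float).reindex(taxon.index)
    if total.isna().any():
        raise ValueError("relative_abundance: totals missing for some samples")
    if (taxon > total).any():
        bad = taxon.index[taxon > total].tolist()
        raise ValueError(f"relative_abundance: taxon exceeds total for samples {bad}")
    zero = total == 0
    if zero.any():
        logger.warning("relative_abundance: %d samples with zero total reads", int(zero.sum()))
    out = taxon.divide(total.where(~zero, other=1.0))
    out[zero] = 0.0
    return out


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-tailed Mann–Whitney by enumerating all group assignments.

    Mid-ranks handle ties; two-tailed p = min(1, 2 * min(P(U <= u), P(U >= u)))
    over the permutation distribution, which is symmetric under exchanging
    the group labels.
    """
    from scipy.stats import rankdata

    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array([
        ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1)
    ])
    eps = 1e-9
    lower = np.mean(us <= u_obs + eps)
    upper = np.mean(us >= u_obs - eps)
    return float(u_obs), float(min(1.0, 2.0 * min(lower, upper)))


def compare_groups(
    v: ScoreVector, group_a: str, group_b: str, exact_max_n: int = 20
) -> GroupComparison:
    """Two-tailed Mann–Whitney comparison of a score between two conditions.

    Exact permutation enumeration (mid-ranks) when the combined sample count
    is at most ``exact_max_n``; tie-corrected normal approximation beyond
    that.  The boundary is configurable; exactness is used where cheap.
    """
    a, b = v.values_for(group_a), v.values_for(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("compare_groups: both groups must be non-empty")
    if len(a) + len(b) <= exact_max_n:
        u, p = _exact_mwu_p(a, b)
        method = "exact"
    else:
        u_arr, p_arr = _mwu_asymptotic(a[None, :], b[None, :])
        u, p = float(u_arr[0]), float(p_arr[0])
        method = "normal"
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        u_statistic=u, p=p, method=method,
    )
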