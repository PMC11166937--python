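"""Directional gene signatures from DE tables, plus cell QC and a DE stand-in.

The core object is a :class:`GeneSignature`: the set of genes passing an
adjusted-p and absolute log2 fold-change threshold in one contrast, each
carrying the sign of its fold change.  Signatures are the query side of every
cross-dataset comparison (see :mod:`gravisig.overlap`).

Thresholds use strict inequalities (adj_p < cutoff, |log2fc| > cutoff): a
gene sitting exactly on a cutoff is excluded.  Cell QC likewise removes
cells with a mitochondrial fraction strictly above the cutoff, or with 250
or fewer detected genes (keep-if detected >= 251).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io import DEGTable, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "SensitivityTable",
    "normalize",
    "qc_filter",
    "build_signature",
    "sensitivity_differential",
    "rank_conserved",
    "ranksum_de",
]


@dataclass
class GeneSignature:
    """Directional gene set: gene -> {direction, log2fc, adj_p} + provenance.

    Invariants: every stored direction equals sign(log2fc); every gene passed
    the thresholds recorded in ``provenance``.
    """

    name: str
    entries: pd.DataFrame  # index: gene; columns: direction, log2fc, adj_p
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = self.entries
        if len(e):
            if not np.array_equal(np.sign(e["log2fc"]), e["direction"]):
                raise ValueError("direction inconsistent with sign(log2fc)")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries.index)

    def directions(self) -> dict[str, int]:
        return {g: int(d) for g, d in self.entries["direction"].items()}

    def to_frame(self) -> pd.DataFrame:
        out = self.entries.reset_index(names="gene")
        return out[["gene", "direction", "log2fc", "adj_p"]]


@dataclass
class SensitivityTable:
    """Per-gene stimulation-induction differential, uG minus 1G.

    ``delta_log2fc`` is exactly ``log2fc_uG - log2fc_1G``; a negative value
    means blunted induction under simulated microgravity.  Genes requested
    but absent from either input table are listed in ``missing``.
    """

    df: pd.DataFrame  # columns: gene, log2fc_uG, log2fc_1G, delta_log2fc
    missing: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


def normalize(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Attach the normalized layer: per-sample scaling to ``target_sum`` then log1p.

    This monotone, deterministic transform is the package's declared
    normalization for all downstream scoring; variance-stabilising model fits
    are out of scope.  Zero-total samples stay all-zero.
    """
    totals = m.counts.sum(axis=0).astype(float)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    m.normalized = np.log1p(m.counts * scale[None, :])
    return m


def qc_filter(
    m: ExpressionMatrix,
    max_mito_frac: float = 0.10,
    min_genes_detected: int = 251,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Remove low-quality cells.

    A cell is removed when its mitochondrial count fraction is strictly
    greater than ``max_mito_frac`` (a cell at exactly 10.0% is retained) or
    when it detects fewer than ``min_genes_detected`` genes.  Cell order is
    preserved.  If no gene matches ``mito_prefix`` the mitochondrial
    criterion is inert (fraction 0 for all cells) and a warning is logged.
    """
    mito_rows = np.array([g.startswith(mito_prefix) for g in m.genes])
    totals = m.counts.sum(axis=0).astype(float)
    if mito_rows.any():
        mito = m.counts[mito_rows].sum(axis=0).astype(float)
        frac = np.divide(mito, totals, out=np.zeros_like(totals), where=totals > 0)
    else:
        logger.warning("qc_filter: no genes match prefix %r; mito criterion inert", mito_prefix)
        frac = np.zeros_like(totals)
    detected = (m.counts > 0).sum(axis=0)
    keep = (frac <= max_mito_frac) & (detected >= min_genes_detected)
    n_removed = int((~keep).sum())
    logger.info("qc_filter: removed %d of %d cells", n_removed, len(keep))
    return m.subset_samples(keep)


def build_signature(
    t: DEGTable,
    adj_p_max: float = 0.05,
    min_abs_lfc: float = 0.1,
    use_raw_p: bool = False,
    name: str | None = None,
) -> GeneSignature:
    """Threshold a DE table into a directional signature.

    Keeps exactly the genes with adj_p < ``adj_p_max`` and
    |log2fc| > ``min_abs_lfc`` (strict on both sides); directions are
    sign(log2fc).  ``use_raw_p=True`` substitutes the raw p column for tables
    that carry no adjusted values.  A gene passing the p filter with log2fc
    exactly 0 is directionless and excluded with a warning.
    """
    df = t.df
    pcol = "p" if use_raw_p else "adj_p"
    if df[pcol].isna().any() and len(df):
        raise ValueError(
            f"build_signature: {pcol!r} missing for some rows "
            "(pass use_raw_p=True for unadjusted tables)"
        )
    passing = df[(df[pcol] < adj_p_max) & (df["log2fc"].abs() > min_abs_lfc)]
    zero = passing[passing["log2fc"] == 0]
    if len(zero):
        logger.warning("build_signature: dropping %d directionless genes (log2fc == 0)", len(zero))
        passing = passing[passing["log2fc"] != 0]
    entries = pd.DataFrame(
        {
            "direction": np.sign(passing["log2fc"].to_numpy()).astype(int),
            "log2fc": passing["log2fc"].to_numpy(),
            "adj_p": passing[pcol].to_numpy(),
        },
        index=pd.Index(passing["gene"], name="gene"),
    ).sort_index()
    return GeneSignature(
        name=name or f"{t.dataset_id}:{t.contrast}",
        entries=entries,
        provenance={
            "adj_p_max": adj_p_max,
            "min_abs_lfc": min_abs_lfc,
            "dataset_id": t.dataset_id,
            "contrast": t.contrast,
            "p_column": pcol,
        },
    )


def sensitivity_differential(
    uG_induction: DEGTable, oneG_induction: DEGTable, gene_list: GeneSet
) -> SensitivityTable:
    """Subtract 1G induction from uG induction over a chosen gene list.

    Both tables must be stimulated-vs-unstimulated contrasts; ``gene_list``
    is typically the top-50 genes most induced by stimulation at 1G.  One row
    per requested gene present in both tables; the rest are reported in
    ``missing`` per source.
    """
    if len(gene_list) == 0:
        raise ValueError("sensitivity_differential: empty gene list")
    ug = uG_induction.df.set_index("gene")["log2fc"]
    og = oneG_induction.df.set_index("gene")["log2fc"]
    wanted = sorted(gene_list.genes)
    rows, miss_ug, miss_1g = [], [], []
    for g in wanted:
        in_ug, in_1g = g in ug.index, g in og.index
        if in_ug and in_1g:
            rows.append((g, float(ug[g]), float(og[g]), float(ug[g]) - float(og[g])))
        else:
            if not in_ug:
                miss_ug.append(g)
            if not in_1g:
                miss_1g.append(g)
    df = pd.DataFrame(rows, columns=["gene", "log2fc_uG", "log2fc_1G", "delta_log2fc"])
    return SensitivityTable(df=df, missing={"uG": miss_ug, "1G": miss_1g})


def rank_conserved(
    unstim: DEGTable, stim: DEGTable, top_n: int = 50
) -> tuple[list[str], list[str]]:
    """Rank genes conserved across the unstimulated and stimulated contrasts.

    A gene qualifies when present in both tables with the same fold-change
    sign; its score is the sum of the two log2fc values.  Returns the top_n
    largest positive sums and the top_n largest-magnitude negative sums, each
    sorted by |sum| descending with lexicographic tie-break on the symbol.
    """
    a = unstim.df.set_index("gene")["log2fc"]
    b = stim.df.set_index("gene")["log2fc"]
    shared = a.index.intersection(b.index)
    concordant = shared[np.sign(a[shared]) == np.sign(b[shared])]
    concordant = concordant[np.sign(a[concordant]) != 0]
    sums = (a[concordant] + b[concordant]).sort_index()
    pos = sums[sums > 0].reset_index()
    neg = sums[sums < 0].reset_index()
    pos = pos.sort_values(["log2fc", "gene"], ascending=[False, True])
    neg = neg.assign(absv=neg["log2fc"].abs()).sort_values(
        ["absv", "gene"], ascending=[False, True]
    )
    if len(pos) < top_n or len(neg) < top_n:
        logger.warning(
            "rank_conserved: only %d positive / %d negative concordant genes for top_n=%d",
            len(pos), len(neg), top_n,
        )
    return pos["gene"].head(top_n).tolist(), neg["gene"].head(top_n).tolist()


def _mwu_asymptotic(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-tailed Mann–Whitney with mid-ranks and tie correction.

    ``a``, ``b`` are (n_rows, n1) and (n_rows, n2).  Returns (U of group a,
    two-tailed p).  No continuity correction, so identical groups give z = 0
    and p = 1 exactly.
    """
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    pooled = np.hstack([a, b])
    ranks = rankdata(pooled, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    z = np.where(sd > 0, (u - n1 * n2 / 2.0) / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return u, np.minimum(p, 1.0)


def ranksum_de(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1e-9,
    dataset_id: str = "ranksum",
) -> DEGTable:
    """Per-gene Wilcoxon rank-sum DE on the normalized layer, BH-adjusted.

    A desk-scale stand-in for full single-cell or count-model DE fits: the
    two-sided rank-sum p per gene is BH-adjusted across genes, and
    log2fc = log2(mean_a + pc) - log2(mean_b + pc) with a pseudocount scaled
    to the layer's units.  Positive log2fc means higher in ``group_a``.
    """
    if m.normalized is None:
        raise ValueError("ranksum_de: normalized layer missing (call normalize first)")
    mask_a, mask_b = m.sample_mask(group_a), m.sample_mask(group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("ranksum_de: both groups need at least 2 samples")
    layer = m.normalized
    a, b = layer[:, mask_a], layer[:, mask_b]
    scale = float(np.abs(layer).mean())
    pc = pseudocount * (scale if scale > 0 else 1.0)
    lfc = np.log2(a.mean(axis=1) + pc) - np.log2(b.mean(axis=1) + pc)
    _, p = _mwu_asymptotic(a, b)
    adj = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({"gene": m.genes, "log2fc": lfc, "p": p, "adj_p": adj})
    return DEGTable(df, dataset_id=dataset_id, contrast=f"{group_a}_vs_{group_b}")
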