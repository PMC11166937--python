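"""Gene Compound Enrichment Analysis (GCEA).

For each compound in an interaction table, test whether differentially
expressed genes are over-represented among the compound's interacting genes,
relative to the class's universal gene set (every gene interacting with at
least one compound of that class).  The test is the right-tailed Fisher's
exact test on the 2x2 table (k, K-k, n-k, N-K-n+k); p-values are
Bonferroni-adjusted over the number of compounds tested in the class.

Each class (drug / food / lincs) is tested against its own universe —
the interaction corpora come from different sources and their raw tables are
not comparable.  Confidence scores never weight the test; they only populate
the report matrix for the top compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import GeneSet, InteractionTable
from .overlap import fisher_overlap_p
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "build_universe",
    "compound_enrichment",
    "top_compound_matrix",
]


@dataclass
class EnrichmentRecord:
    """One compound's enrichment result.

    k = DEGs interacting with the compound, K = the compound's genes within
    the universe, n = DEGs within the universe, N = universe size.
    adj_p = min(1, p * m) with m the number of compounds tested in the class.
    """

    compound_id: str
    compound_class: str
    k: int
    K: int
    n: int
    N: int
    p: float
    adj_p: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("EnrichmentRecord: k exceeds min(K, n)")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.adj_p <= 1.0):
            raise ValueError("EnrichmentRecord: p outside [0, 1]")


def build_universe(t: InteractionTable, compound_class: str) -> GeneSet:
    """Universal gene set of a class: all genes interacting with >= 1 compound."""
    sub = t.of_class(compound_class)
    if len(sub) == 0:
        raise ValueError(f"build_universe: no records of class {compound_class!r}")
    return GeneSet(name=f"universe:{compound_class}", genes=frozenset(sub["gene"]))


def _deg_genes(degs: "GeneSignature | GeneSet | list[str] | set[str]") -> set[str]:
    if isinstance(degs, GeneSignature):
        return set(degs.genes)
    if isinstance(degs, GeneSet):
        return set(degs.genes)
    return {str(g).strip() for g in degs}


def compound_enrichment(
    t: InteractionTable,
    degs: "GeneSignature | GeneSet | list[str] | set[str]",
    compound_class: str,
    adjust: str = "bonferroni",
) -> list[EnrichmentRecord]:
    """Per-compound Fisher enrichment of DEGs, sorted by (p, compound_id).

    DEGs outside the class universe are excluded from n (the 2x2 table must
    live inside one finite universe); their count is logged.  A compound
    interacting with no DEG has p = 1 by construction.  ``adjust`` is
    "bonferroni" (the stated default) or "bh" for exploratory use.
    """
    sub = t.of_class(compound_class)
    if len(sub) == 0:
        raise ValueError(f"compound_enrichment: no records of class {compound_class!r}")
    universe = set(sub["gene"])
    big_n = len(universe)
    deg_all = _deg_genes(degs)
    deg_in = deg_all & universe
    n_out = len(deg_all) - len(deg_in)
    if n_out:
        logger.info("compound_enrichment: %d DEGs outside the %s universe excluded",
                    n_out, compound_class)
    if not deg_in:
        logger.warning("compound_enrichment: no DEG inside the %s universe; all p = 1",
                       compound_class)
    n = len(deg_in)

    genes_by_compound = sub.groupby("compound_id")["gene"].apply(set)
    m = len(genes_by_compound)
    records = []
    for cid, genes in genes_by_compound.items():
        big_k = len(genes)
        k = len(genes & deg_in)
        p = fisher_overlap_p(k, big_k, n, big_n) if n else 1.0
        records.append((cid, k, big_k, p))

    if adjust == "bonferroni":
        adj = {cid: min(1.0, p * m) for cid, _, _, p in records}
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        adj_vals = multipletests([p for *_, p in records], method="fdr_bh")[1]
        adj = {cid: float(ap) for (cid, *_), ap in zip(records, adj_vals)}
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = [
        EnrichmentRecord(
            compound_id=cid, compound_class=compound_class,
            k=k, K=big_k, n=n, N=big_n, p=p, adj_p=adj[cid],
        )
        for cid, k, big_k, p in records
    ]
    out.sort(key=lambda r: (r.p, r.compound_id))
    return out


def top_compound_matrix(
    records: list[EnrichmentRecord],
    t: InteractionTable,
    degs: "GeneSignature | GeneSet | list[str] | set[str]",
    top_k: int = 50,
) -> pd.DataFrame:
    """Confidence-score matrix (top compounds x their interacting DEGs).

    Rows are the ``top_k`` smallest-p compounds (input order is preserved,
    i.e. records must already be sorted); columns are the union of the DEGs
    those compounds interact with; entries are the interaction confidence
    score, 0 where no interaction exists.
    """
    if top_k < 1:
        raise ValueError("top_compound_matrix: top_k must be >= 1")
    if len(records) < top_k:
        logger.warning("top_compound_matrix: only %d compounds available for top_k=%d",
                       len(records), top_k)
    top = records[:top_k]
    deg_set = _deg_genes(degs)
    ids = [r.compound_id for r in top]
    sub = t.df[t.df["compound_id"].isin(ids) & t.df["gene"].isin(deg_set)]
    cols = sorted(set(sub["gene"]))
    mat = pd.DataFrame(0.0, index=ids, columns=cols)
    for _, row in sub.iterrows():
        mat.loc[row["compound_id"], row["gene"]] = row["score"]
    mat.index.name = "compound_id"
    return mat


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id, "compound_class": r.compound_class,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p, "adj_p": r.adj_p,
            }
            for r in records
        ]
    )
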