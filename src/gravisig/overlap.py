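"""Cross-dataset directional signature overlap with exact Fisher testing.

Given a directional signature (query) and another dataset's DE table
(comparison), count the genes significant in both, split by whether the fold
changes agree in sign, and score the overlap with a right-tailed Fisher's
exact test over a declared gene universe.  Three matching modes:

* ``same``     — overlap requires the same log2FC sign (the default rule);
* ``either``   — any sign counts (used for return-to-gravity comparisons,
                 where sign flips on landing are themselves informative);
* ``opposite`` — only sign flips count.

The universe is explicit: by default the intersection of the two datasets'
tested gene lists, overridable with a fixed genome size.  The exact
hypergeometric tail P(X >= k) is computed by summation, never by a normal
approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .io import DEGTable, OrthologMap
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "translate_orthologs",
    "fisher_overlap_p",
    "decide_universe",
    "directional_overlap",
    "overlap_percentage",
]


@dataclass
class OverlapResult:
    """Counts, gene lists and the right-tailed Fisher p for one comparison.

    ``n_sig`` is the full signature size (the paper-style denominator);
    ``n_sig_tested`` restricts to signature genes actually tested in the
    comparison dataset and inside the universe — this is the count entering
    the Fisher table, since absent genes cannot overlap by construction.
    """

    k_same: int
    k_opposite: int
    k_total: int
    n_sig: int
    n_sig_tested: int
    n_other: int
    universe_n: int
    p_right: float
    mode: str
    genes_same: list[str] = field(default_factory=list)
    genes_opposite: list[str] = field(default_factory=list)
    sig_genes_untested: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_same": self.k_same,
            "k_opposite": self.k_opposite,
            "k_total": self.k_total,
            "n_sig": self.n_sig,
            "n_sig_tested": self.n_sig_tested,
            "n_other": self.n_other,
            "universe_n": self.universe_n,
            "p_right": self.p_right,
            "mode": self.mode,
            "genes_same": self.genes_same,
            "genes_opposite": self.genes_opposite,
            "sig_genes_untested": self.sig_genes_untested,
        }


def translate_orthologs(sig: GeneSignature, map: OrthologMap) -> GeneSignature:
    """Carry a signature across species via a symbol map.

    One-to-many sources expand to every target with the source's direction
    and fold change; unmapped genes are dropped and counted.  When two
    sources with conflicting directions land on one target, that target is
    dropped (its direction is undefined) and the conflict logged.
    """
    if len(map) == 0:
        raise ValueError("translate_orthologs: empty ortholog map")
    targets_of: dict[str, list[str]] = {}
    for a, b in map.pairs:
        targets_of.setdefault(a, []).append(b)

    rows: dict[str, tuple[int, float, float]] = {}
    conflicts: set[str] = set()
    n_unmapped = 0
    for gene, row in sig.entries.iterrows():
        targets = targets_of.get(gene)
        if not targets:
            n_unmapped += 1
            continue
        for t in targets:
            d = int(row["direction"])
            if t in rows and rows[t][0] != d:
                conflicts.add(t)
            elif t not in rows:
                rows[t] = (d, float(row["log2fc"]), float(row["adj_p"]))
    for t in conflicts:
        rows.pop(t, None)
        logger.warning("translate_orthologs: conflicting directions onto %r; dropped", t)
    if n_unmapped:
        logger.info("translate_orthologs: %d signature genes unmapped", n_unmapped)

    import pandas as pd

    entries = pd.DataFrame(
        [(t, d, lfc, ap) for t, (d, lfc, ap) in rows.items()],
        columns=["gene", "direction", "log2fc", "adj_p"],
    ).set_index("gene").sort_index()
    prov = dict(sig.provenance, translated=True, n_unmapped=n_unmapped,
                n_conflicts=len(conflicts))
    return GeneSignature(name=sig.name + "|orthologs", entries=entries, provenance=prov)


def fisher_overlap_p(k: int, n_a: int, n_b: int, universe_n: int) -> float:
    """Right-tailed exact overlap p: P(X >= k), X ~ Hypergeom(N, n_a, n_b).

    The probability that two sets of sizes ``n_a`` and ``n_b`` drawn from a
    universe of ``universe_n`` genes share at least ``k`` members — identical
    to the one-sided Fisher's exact test on the 2x2 overlap table.
    """
    if not (0 <= n_a <= universe_n and 0 <= n_b <= universe_n):
        raise ValueError("fisher_overlap_p: set sizes must lie within the universe")
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"fisher_overlap_p: k={k} outside [0, min(n_a, n_b)]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, universe_n, n_a, n_b))


def decide_universe(
    sig_source: DEGTable, other_source: DEGTable, override: int | None = None
) -> int:
    """Universe size = |intersection of the tested gene lists|, unless overridden."""
    if override is not None:
        return int(override)
    common = set(sig_source.genes) & set(other_source.genes)
    if not common:
        raise ValueError("decide_universe: tested gene lists do not intersect")
    return len(common)


def directional_overlap(
    sig: GeneSignature,
    other: DEGTable,
    mode: str = "same",
    sig_p_max: float = 0.05,
    use_adj: bool = False,
    universe_n: int | None = None,
    universe_genes: set[str] | None = None,
) -> OverlapResult:
    """Count and test the directional overlap of a signature with a DE table.

    Comparison rows are filtered to p (or adj_p with ``use_adj=True``,
    the single-cell-style convention) strictly below ``sig_p_max``.  Matched
    genes are split into same-sign and opposite-sign; ``k_total`` follows
    ``mode``.  ``universe_genes`` (or a precomputed ``universe_n``) defines
    the Fisher background; by default the comparison table's full tested
    list is used.
    """
    if mode not in ("same", "either", "opposite"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    pcol = "adj_p" if use_adj else "p"
    df = other.df
    if universe_genes is None:
        universe_genes = set(df["gene"])
    if universe_n is None:
        universe_n = len(universe_genes)

    tested = set(df["gene"]) & universe_genes
    sig_dirs = sig.directions()
    sig_tested = {g: d for g, d in sig_dirs.items() if g in tested}
    untested = sorted(set(sig_dirs) - set(sig_tested))

    sig_rows = df[df["gene"].isin(tested)]
    significant = sig_rows[(sig_rows[pcol] < sig_p_max) & (sig_rows["log2fc"] != 0)]
    other_dirs = dict(zip(significant["gene"], np.sign(significant["log2fc"]).astype(int)))

    genes_same = sorted(g for g, d in sig_tested.items()
                        if g in other_dirs and other_dirs[g] == d)
    genes_opposite = sorted(g for g, d in sig_tested.items()
                            if g in other_dirs and other_dirs[g] != d)
    k_same, k_opp = len(genes_same), len(genes_opposite)
    k_total = {"same": k_same, "opposite": k_opp, "either": k_same + k_opp}[mode]

    n_a, n_b = len(sig_tested), len(other_dirs)
    if len(sig_dirs) == 0 or n_a == 0:
        p_right = 1.0
    else:
        p_right = fisher_overlap_p(k_total, n_a, n_b, universe_n)
    return OverlapResult(
        k_same=k_same,
        k_opposite=k_opp,
        k_total=k_total,
        n_sig=len(sig_dirs),
        n_sig_tested=n_a,
        n_other=n_b,
        universe_n=universe_n,
        p_right=p_right,
        mode=mode,
        genes_same=genes_same,
        genes_opposite=genes_opposite,
        sig_genes_untested=untested,
    )


def overlap_percentage(
    r: "OverlapResult | tuple[int, int]", decimals: int = 1
) -> float:
    """Overlap as a percentage of the signature, rounded half away from zero.

    Accepts an :class:`OverlapResult` or a bare ``(k_total, n_sig)`` pair;
    uses the full signature size as denominator (the convention in which
    106/375 prints as 28.3%).
    """
    if isinstance(r, OverlapResult):
        k, n = r.k_total, r.n_sig
    else:
        k, n = r
    if n <= 0:
        raise ValueError("overlap_percentage: empty signature")
    pct = 100.0 * k / n
    factor = 10 ** decimals
    return float(np.floor(abs(pct) * factor + 0.5) / factor * np.sign(pct))
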