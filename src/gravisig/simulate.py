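"""Synthetic inputs with recorded ground truth.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes — negative-binomial counts with planted DE
genes, DE-table pairs sharing a planted concordant fraction, compound–gene
networks with planted enriched compounds, and weighted gene sets — so every
stage is testable with no external download.  Each generator is a pure
function of its parameters and seed, and emits a :class:`SimTruth` recording
what was planted.

Count model
-----------
Counts are negative-binomial with variance = mean + dispersion * mean^2
(dispersion 0 degenerates to Poisson); the default dispersion of 0.5 is a
typical single-cell overdispersion scale.  Baseline per-gene means are
log-normal with log-mean ln(5) and log-sd 1.0 — counts of roughly 0.5–50 per
cell, i.e. the expressed-gene stratum on which DE calling operates.  Planted
DE genes have one condition's mean scaled by 2^(+-lfc_magnitude).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DEGTable, ExpressionMatrix, GeneSet, InteractionTable, WeightedGeneSet

__all__ = [
    "SimTruth",
    "simulate_expression",
    "simulate_deg_pair",
    "simulate_interactions",
    "simulate_weighted_gene_set",
]

#: baseline-mean distribution of simulate_expression (log-normal parameters)
BASELINE_LOG_MEAN = float(np.log(5.0))
BASELINE_LOG_SD = 1.0


@dataclass
class SimTruth:
    """Ground truth of one simulation: what was planted, and all parameters."""

    planted_de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed lfc
    planted_concordant_genes: set[str] = field(default_factory=set)
    planted_compounds: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_de_genes": self.planted_de_genes,
                "planted_concordant_genes": sorted(self.planted_concordant_genes),
                "planted_compounds": sorted(self.planted_compounds),
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(
    n_genes: int = 500,
    n_per_condition: int = 100,
    de_fraction: float = 0.1,
    lfc_magnitude: float = 1.0,
    nb_dispersion: float = 0.5,
    seed: int = 0,
    conditions: tuple[str, str] = ("uG", "1G"),
) -> tuple[ExpressionMatrix, SimTruth]:
    """Two-condition negative-binomial count matrix with planted DE genes.

    A ``de_fraction`` of genes is planted differentially expressed: the
    first condition's mean is scaled by 2^(+-lfc_magnitude), sign drawn at
    random and recorded in the truth (positive = higher in the first
    condition).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    if n_genes < 1 or lfc_magnitude < 0 or nb_dispersion < 0:
        raise ValueError("invalid simulate_expression parameters")

    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base = rng.lognormal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)

    mean_a = np.tile(base[:, None], (1, n_per_condition))
    mean_b = mean_a.copy()
    mean_a[de_idx] *= (2.0 ** (signs * lfc_magnitude))[:, None]
    counts = np.hstack(
        [_nb_sample(rng, mean_a, nb_dispersion), _nb_sample(rng, mean_b, nb_dispersion)]
    )
    cond_a, cond_b = conditions
    samples = [f"{cond_a}_{i + 1}" for i in range(n_per_condition)] + [
        f"{cond_b}_{i + 1}" for i in range(n_per_condition)
    ]
    condition = [cond_a] * n_per_condition + [cond_b] * n_per_condition
    m = ExpressionMatrix(genes=genes, samples=samples, counts=counts, condition=condition)
    truth = SimTruth(
        planted_de_genes={genes[i]: float(s * lfc_magnitude) for i, s in zip(de_idx, signs)},
        params={
            "n_genes": n_genes, "n_per_condition": n_per_condition,
            "de_fraction": de_fraction, "lfc_magnitude": lfc_magnitude,
            "nb_dispersion": nb_dispersion, "seed": seed,
            "baseline_log_mean": BASELINE_LOG_MEAN, "baseline_log_sd": BASELINE_LOG_SD,
            "conditions": list(conditions),
        },
    )
    return m, truth


def simulate_deg_pair(
    n_genes: int = 4000,
    sig_size: int = 375,
    concordant_fraction: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[DEGTable, DEGTable, SimTruth]:
    """A pair of DE tables sharing a planted fraction of concordant genes.

    Table A carries ``sig_size`` significant genes (adj_p < 0.05,
    |log2fc| > 0.1, random signs).  A ``concordant_fraction`` of them is
    planted significant in table B with the same sign; every other B entry
    is null: p ~ Uniform(0, 1), log2fc ~ Normal(0, noise_sd).  Null
    p-values are drawn uniform rather than simulated from tests so that
    overlap-calibration checks are exact in expectation.  A uses adjusted
    p-values (single-cell style), B raw p-values (bulk style).
    """
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must be in [0, 1]")
    if sig_size > n_genes:
        raise ValueError("sig_size exceeds n_genes")

    rng = np.random.default_rng(seed)
    genes = np.array(_gene_names(n_genes))
    sig_idx = rng.choice(n_genes, size=sig_size, replace=False)
    sig_mask = np.zeros(n_genes, dtype=bool)
    sig_mask[sig_idx] = True
    signs = rng.choice([-1.0, 1.0], size=sig_size)

    # table A: planted signature + null background (adj_p-based)
    lfc_a = rng.normal(0.0, noise_sd * 0.2, n_genes)
    adj_a = rng.uniform(0.05, 1.0, n_genes)
    lfc_a[sig_idx] = signs * (0.1 + np.abs(rng.normal(0.4, 0.2, sig_size)))
    adj_a[sig_idx] = rng.uniform(1e-8, 0.05, sig_size)
    table_a = DEGTable(
        pd.DataFrame({"gene": genes, "log2fc": lfc_a,
                      "p": adj_a / 2.0, "adj_p": adj_a}),
        dataset_id="simA", contrast="uG_vs_1G",
    )

    # table B: concordant subset planted significant, rest null (p-based)
    n_conc = int(round(concordant_fraction * sig_size))
    conc_idx = rng.choice(sig_idx, size=n_conc, replace=False)
    lfc_b = rng.normal(0.0, noise_sd, n_genes)
    p_b = rng.uniform(0.0, 1.0, n_genes)
    conc_pos = {int(i): s for i, s in zip(sig_idx, signs)}
    for i in conc_idx:
        s = conc_pos[int(i)]
        lfc_b[i] = s * (0.1 + abs(rng.normal(0.4, 0.2)))
        p_b[i] = rng.uniform(1e-8, 0.05)
    table_b = DEGTable(
        pd.DataFrame({"gene": genes, "log2fc": lfc_b, "p": p_b, "adj_p": np.nan}),
        dataset_id="simB", contrast="uG_vs_1G",
    )

    truth = SimTruth(
        planted_de_genes={genes[i]: float(lfc_a[i]) for i in sig_idx},
        planted_concordant_genes={genes[i] for i in conc_idx},
        params={
            "n_genes": n_genes, "sig_size": sig_size,
            "concordant_fraction": concordant_fraction,
            "noise_sd": noise_sd, "seed": seed,
        },
    )
    return table_a, table_b, truth


def simulate_interactions(
    n_compounds: int = 200,
    genes: GeneSet | None = None,
    degs: "list[str] | set[str] | None" = None,
    n_planted: int = 0,
    planted_deg_fraction: float = 0.6,
    background_deg_fraction: float | None = None,
    genes_per_compound: int = 30,
    degree_sigma: float = 0.0,
    compound_class: str = "drug",
    seed: int = 0,
) -> tuple[InteractionTable, SimTruth]:
    """Bipartite compound–gene network with optionally planted enriched compounds.

    Planted compounds draw ``planted_deg_fraction`` of their genes from the
    DEG list, the rest uniformly from the remaining pool.  Background
    compounds draw ``background_deg_fraction`` from the DEG list, or — when
    that is None — sample uniformly from the whole pool (the no-structure
    null).  ``degree_sigma`` > 0 draws each compound's degree from a
    log-normal around ``genes_per_compound``: real compound–gene networks
    are heavy-tailed in degree.  Confidence scores are Uniform(150, 1000).
    """
    if genes is None:
        genes = GeneSet("simulated_pool", frozenset(_gene_names(2000)))
    pool = np.array(sorted(genes.genes))
    deg_list = np.array(sorted({str(g).strip() for g in (degs or [])}))
    if n_planted > n_compounds:
        raise ValueError("n_planted exceeds n_compounds")
    for f in (planted_deg_fraction,) + (
        (background_deg_fraction,) if background_deg_fraction is not None else ()
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError("deg fractions must be in [0, 1]")
    if (n_planted > 0 or background_deg_fraction is not None) and len(deg_list) == 0:
        raise ValueError("a DEG list is required for stratified sampling")
    if len(deg_list) and not set(deg_list) & set(pool):
        raise ValueError("DEG list disjoint from the gene pool")
    deg_list = deg_list[np.isin(deg_list, pool)]
    non_deg = pool[~np.isin(pool, deg_list)]

    rng = np.random.default_rng(seed)
    width = len(str(n_compounds))
    ids = [f"CPD{i:0{width}d}" for i in range(1, n_compounds + 1)]
    planted = {str(c) for c in rng.choice(ids, size=n_planted, replace=False)} if n_planted else set()

    rows = []
    for cid in ids:
        if degree_sigma > 0:
            degree = int(np.clip(
                round(rng.lognormal(np.log(genes_per_compound), degree_sigma)),
                2, len(pool),
            ))
        else:
            degree = min(genes_per_compound, len(pool))
        if cid in planted or background_deg_fraction is not None:
            frac = planted_deg_fraction if cid in planted else background_deg_fraction
            n_from_deg = min(int(round(frac * degree)), len(deg_list))
            n_from_bg = min(degree - n_from_deg, len(non_deg))
            chosen = np.concatenate([
                rng.choice(deg_list, size=n_from_deg, replace=False),
                rng.choice(non_deg, size=n_from_bg, replace=False),
            ])
        else:
            chosen = rng.choice(pool, size=degree, replace=False)
        scores = rng.uniform(150.0, 1000.0, size=len(chosen))
        rows.extend(
            {"compound_id": cid, "compound_class": compound_class, "gene": g, "score": s}
            for g, s in zip(chosen, scores)
        )
    table = InteractionTable(pd.DataFrame(rows))
    truth = SimTruth(
        planted_compounds=planted,
        params={
            "n_compounds": n_compounds, "n_planted": n_planted,
            "planted_deg_fraction": planted_deg_fraction,
            "background_deg_fraction": background_deg_fraction,
            "genes_per_compound": genes_per_compound,
            "degree_sigma": degree_sigma, "compound_class": compound_class,
            "n_genes_pool": len(pool), "n_degs": len(deg_list), "seed": seed,
        },
    )
    return table, truth


def simulate_weighted_gene_set(
    n_genes_in_set: int = 50,
    coefficient_sd: float = 1.0,
    seed: int = 0,
    genes: "list[str] | None" = None,
    name: str = "simulated_weights",
) -> WeightedGeneSet:
    """Weighted gene set with Normal(0, coefficient_sd) coefficients."""
    if n_genes_in_set < 1:
        raise ValueError("n_genes_in_set must be >= 1")
    if coefficient_sd < 0:
        raise ValueError("coefficient_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = _gene_names(n_genes_in_set, prefix="W")
    elif len(genes) != n_genes_in_set:
        raise ValueError("genes list length must equal n_genes_in_set")
    coefs = rng.normal(0.0, coefficient_sd, n_genes_in_set)
    if coefficient_sd == 0:
        import logging

        logging.getLogger(__name__).warning(
            "simulate_weighted_gene_set: all-zero coefficients (degenerate for scoring)"
        )
    return WeightedGeneSet(name=name, weights=dict(zip(genes, coefs)))
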