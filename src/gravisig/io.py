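"""Readers, writers and validated in-memory containers.

Every external representation the pipeline touches — differential-expression
(DE) tables, count matrices (MatrixMarket triplet or dense TSV), GMT and
weighted gene sets, compound–gene interaction tables and ortholog maps — is
parsed here into a small set of domain types.  All other modules operate on
these types only, so format quirks (column-name dialects, 1-based MTX
indices, CSV vs TSV) never leak downstream.

Conventions
-----------
* Gene symbols are compared case-sensitively after stripping whitespace; pass
  ``uppercase=True`` to a reader to normalise, since human symbol conventions
  vary between sources.
* A missing adjusted p-value is ``NaN``, never 1.0: downstream thresholding
  must be able to distinguish "not adjusted" from "adjusted, non-significant".
* MatrixMarket files are 1-based on disk (per the standard); everything in
  memory is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "DEGTable",
    "ExpressionMatrix",
    "GeneSet",
    "WeightedGeneSet",
    "InteractionTable",
    "OrthologMap",
    "FormatError",
    "ValidationError",
    "read_deg_table",
    "write_deg_table",
    "read_expression",
    "write_expression",
    "read_gene_set",
    "write_gene_set",
    "read_interactions",
    "write_interactions",
    "read_ortholog_map",
    "write_ortholog_map",
]


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


class ValidationError(ValueError):
    """Parsed content violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

#: canonical DE-table column names; dialects map on to these
DEG_COLUMNS = ("gene", "log2fc", "p", "adj_p", "cell_type")

#: ready-made column dialects for common upstream tools
DEG_DIALECTS = {
    "canonical": {},
    "seurat": {"gene": "gene", "log2fc": "avg_log2FC", "p": "p_val", "adj_p": "p_val_adj"},
    "deseq2": {"gene": "gene", "log2fc": "log2FoldChange", "p": "pvalue", "adj_p": "padj"},
}


@dataclass
class DEGTable:
    """Per-gene differential-expression records for one contrast.

    ``df`` has columns gene, log2fc, p, adj_p, cell_type.  ``p``/``adj_p`` are
    in [0, 1] (adj_p may be NaN), log2fc is finite, and gene symbols are
    unique within (dataset_id, contrast, cell_type).
    """

    df: pd.DataFrame
    dataset_id: str = "dataset"
    contrast: str = "uG_vs_1G"

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in DEG_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "cell_type" else pd.NA
        df = df[list(DEG_COLUMNS)]
        df["gene"] = df["gene"].astype(str).str.strip()
        df["cell_type"] = df["cell_type"].astype(object).where(df["cell_type"].notna(), np.nan)
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if (df["gene"] == "").any():
            raise ValidationError("empty gene symbols present")
        dup = df.loc[df.duplicated(subset=["gene", "cell_type"], keep=False), "gene"]
        if len(dup):
            raise ValidationError(
                f"duplicate genes within contrast {self.contrast!r}: "
                f"{sorted(dup.unique())[:10]}"
            )
        lfc = df["log2fc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lfc)):
            bad = df.index[~np.isfinite(lfc)].tolist()
            raise ValidationError(f"non-finite log2fc at rows {bad[:10]}")
        for col in ("p", "adj_p"):
            v = df[col].to_numpy(dtype=float)
            ok = np.isnan(v) | ((v >= 0.0) & (v <= 1.0))
            if not ok.all():
                bad = df.index[~ok].tolist()
                raise ValidationError(f"{col} outside [0, 1] at rows {bad[:10]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> list[str]:
        return self.df["gene"].tolist()


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with per-sample condition labels.

    ``normalized``, when present, is a real matrix of the same shape (the
    library-size-scaled log layer produced by
    :func:`gravisig.signatures.normalize`).
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    condition: list[str]
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.genes = [str(g).strip() for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.condition = [str(c) for c in self.condition]
        self.validate()

    def validate(self) -> None:
        n_g, n_s = self.counts.shape
        if len(self.genes) != n_g or len(self.samples) != n_s:
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.condition) != n_s:
            raise ValidationError("condition must be defined for every sample")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError("normalized layer shape differs from counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the boolean/index mask ``keep``."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx],
            condition=[self.condition[i] for i in idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def sample_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.condition])


@dataclass
class GeneSet:
    """An unweighted, non-empty set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(str(g).strip() for g in self.genes)
        if not self.genes or "" in self.genes:
            raise ValidationError(f"gene set {self.name!r} empty or has blank symbols")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class WeightedGeneSet:
    """Gene -> signed real coefficient, e.g. an inflammatory-aging clock."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        self.weights = {str(g).strip(): float(w) for g, w in self.weights.items()}
        if "" in self.weights:
            raise ValidationError("blank gene symbol in weighted set")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.weights)


@dataclass
class InteractionTable:
    """Compound -> (gene, confidence) bipartite store, STITCH-style.

    Scores are combined confidence values on the [0, 1000] scale; a
    (compound_id, gene) pair appears at most once.
    """

    df: pd.DataFrame  # columns: compound_id, compound_class, gene, score

    def __post_init__(self) -> None:
        df = self.df.copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["compound_class"] = df["compound_class"].astype(str)
        df["gene"] = df["gene"].astype(str).str.strip()
        df["score"] = df["score"].astype(float)
        self.df = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        bad_class = set(df["compound_class"]) - {"drug", "food", "lincs"}
        if bad_class:
            raise ValidationError(f"unknown compound classes: {sorted(bad_class)}")
        if ((df["score"] < 0) | (df["score"] > 1000)).any():
            raise ValidationError("interaction scores outside [0, 1000]")
        dup = df.loc[df.duplicated(subset=["compound_id", "gene"], keep=False)]
        if len(dup):
            pairs = sorted(set(zip(dup["compound_id"], dup["gene"])))
            raise ValidationError(f"duplicated (compound, gene) pairs: {pairs[:10]}")

    def __len__(self) -> int:
        return len(self.df)

    def of_class(self, compound_class: str) -> pd.DataFrame:
        return self.df[self.df["compound_class"] == compound_class]

    def compound_genes(self, compound_id: str) -> frozenset[str]:
        return frozenset(self.df.loc[self.df["compound_id"] == compound_id, "gene"])


@dataclass
class OrthologMap:
    """Source-species -> target-species symbol pairs; one-to-many allowed."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        pairs = [(str(a).strip(), str(b).strip()) for a, b in self.pairs]
        if any(a == "" or b == "" for a, b in pairs):
            raise ValidationError("empty symbol in ortholog map")
        self.pairs = pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def targets(self, source_gene: str) -> list[str]:
        return [b for a, b in self.pairs if a == source_gene]


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_deg_table(
    path: str | Path,
    dialect: str | dict[str, str] | None = None,
    dataset_id: str = "dataset",
    contrast: str = "uG_vs_1G",
    uppercase: bool = False,
) -> DEGTable:
    """Read a DE table in TSV or CSV form.

    ``dialect`` maps canonical column names (gene, log2fc, p, adj_p,
    cell_type) to the file's headers; it may also name a built-in dialect
    ("seurat", "deseq2").  The file must provide gene and log2fc plus at
    least one of p / adj_p.  Rows with unparseable numerics are rejected
    with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(dialect, str):
        dialect = DEG_DIALECTS[dialect]
    dialect = dict(dialect or {})

    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    for col in ("gene", "log2fc"):
        if col not in raw.columns:
            raise FormatError(f"{path.name}: missing mandatory column {col!r}")
    if "p" not in raw.columns and "adj_p" not in raw.columns:
        raise FormatError(f"{path.name}: neither 'p' nor 'adj_p' column present")

    df = pd.DataFrame({"gene": raw["gene"].astype(str).str.strip()})
    if uppercase:
        df["gene"] = df["gene"].str.upper()
    for col in ("log2fc", "p", "adj_p"):
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            missing_in = raw[col].isna() | (raw[col].astype(str).str.strip() == "")
            bad = vals.isna() & ~missing_in
            # inf parses numerically but violates the finiteness invariant
            bad |= ~np.isfinite(vals.fillna(0.0)) if col == "log2fc" else False
            if bad.any():
                rows = (df.index[bad] + 2).tolist()  # 1-based incl. header
                raise FormatError(
                    f"{path.name}: unparseable or non-finite {col!r} at file rows {rows[:10]}"
                )
            df[col] = vals
        else:
            df[col] = np.nan
    if "log2fc" in df and df["log2fc"].isna().any():
        rows = (df.index[df["log2fc"].isna()] + 2).tolist()
        raise FormatError(f"{path.name}: missing log2fc at file rows {rows[:10]}")
    df["cell_type"] = raw["cell_type"] if "cell_type" in raw.columns else pd.NA
    return DEGTable(df, dataset_id=dataset_id, contrast=contrast)


def write_deg_table(t: DEGTable, path: str | Path) -> None:
    path = Path(path)
    t.df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_lines(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip() != ""]


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    conditions_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load counts from MatrixMarket triplet (+ sidecar name files) or dense TSV.

    For a dense TSV the first column holds gene names and the header holds
    sample ids; a conditions file (one label per line) is required either way.
    Gene and sample order is preserved exactly as given.
    """
    matrix_path = Path(matrix_path)
    if conditions_path is None:
        raise FormatError("a conditions file (one label per sample line) is required")
    conditions = _read_lines(Path(conditions_path))

    if matrix_path.suffix == ".mtx":
        if genes_path is None or samples_path is None:
            raise FormatError("MTX input requires gene and sample name files")
        genes = _read_lines(Path(genes_path))
        samples = _read_lines(Path(samples_path))
        m = scipy.io.mmread(matrix_path)
        counts = np.asarray(m.todense() if scipy.sparse.issparse(m) else m)
        if counts.shape != (len(genes), len(samples)):
            raise FormatError(
                f"MTX header declares {counts.shape}, name files give "
                f"({len(genes)}, {len(samples)})"
            )
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        genes = [str(g) for g in dense.index]
        samples = [str(s) for s in dense.columns]
        counts = dense.to_numpy()
    if len(conditions) != len(samples):
        raise FormatError(
            f"{len(conditions)} condition labels for {len(samples)} samples"
        )
    return ExpressionMatrix(genes=genes, samples=samples, counts=counts, condition=conditions)


def write_expression(m: ExpressionMatrix, out_dir: str | Path, stem: str = "matrix") -> dict[str, Path]:
    """Write counts as .mtx plus sidecar genes/samples/conditions files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{stem}.mtx",
        "genes": out_dir / f"{stem}.genes.txt",
        "samples": out_dir / f"{stem}.samples.txt",
        "conditions": out_dir / f"{stem}.conditions.txt",
    }
    scipy.io.mmwrite(paths["matrix"], scipy.sparse.coo_matrix(m.counts))
    paths["genes"].write_text("\n".join(m.genes) + "\n")
    paths["samples"].write_text("\n".join(m.samples) + "\n")
    paths["conditions"].write_text("\n".join(m.condition) + "\n")
    return paths


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_set(
    path: str | Path, format: str = "gmt", uppercase: bool = False
) -> GeneSet | WeightedGeneSet | list[GeneSet]:
    """Read a GMT gene set or a two-column gene/coefficient weighted set.

    GMT: one set per line, ``name<TAB>description<TAB>gene...``; a single-set
    file returns that :class:`GeneSet`, a multi-set file returns a list.
    two_column: ``gene<TAB>coefficient`` -> :class:`WeightedGeneSet`.
    """
    path = Path(path)
    if format == "gmt":
        sets = []
        for i, line in enumerate(_read_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path.name}:{i}: GMT line needs name, description, genes")
            name, _desc, *genes = parts
            genes = [g.strip().upper() if uppercase else g.strip() for g in genes if g.strip()]
            if len(genes) != len(set(genes)):
                dups = sorted({g for g in genes if genes.count(g) > 1})
                raise ValidationError(f"{path.name}:{i}: duplicate genes {dups}")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
        if not sets:
            raise FormatError(f"{path.name}: no gene sets found")
        return sets[0] if len(sets) == 1 else sets
    if format == "two_column":
        weights: dict[str, float] = {}
        for i, line in enumerate(_read_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{i}: expected 'gene<TAB>coefficient'")
            gene, coef = parts[0].strip(), parts[1].strip()
            if uppercase:
                gene = gene.upper()
            try:
                value = float(coef)
            except ValueError:
                raise FormatError(f"{path.name}:{i}: unparseable coefficient {coef!r}") from None
            if gene in weights:
                raise ValidationError(f"{path.name}:{i}: duplicate gene {gene!r}")
            weights[gene] = value
        if not weights:
            raise FormatError(f"{path.name}: empty weighted gene set")
        return WeightedGeneSet(name=path.stem, weights=weights)
    raise ValueError(f"unknown gene-set format {format!r}")


def write_gene_set(s: GeneSet | WeightedGeneSet, path: str | Path) -> None:
    path = Path(path)
    if isinstance(s, WeightedGeneSet):
        lines = [f"{g}\t{w:.17g}" for g, w in sorted(s.weights.items())]
    else:
        lines = [s.name + "\tna\t" + "\t".join(sorted(s.genes))]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# interactions and orthologs
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path, min_score: float = 0.0) -> InteractionTable:
    """Read a compound–gene interaction TSV, dropping records below min_score.

    The default min_score of 0 keeps everything: whether a confidence cutoff
    should be applied before enrichment is a user choice, exposed here.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"compound_id", "compound_class", "gene", "score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    table = InteractionTable(df)
    if min_score > 0:
        kept = table.df[table.df["score"] >= min_score]
        n_excluded = len(table.df) - len(kept)
        if n_excluded:
            logger.info("read_interactions: excluded %d records below score %g",
                        n_excluded, min_score)
        table = InteractionTable(kept)
    return table


def write_interactions(t: InteractionTable, path: str | Path) -> None:
    t.df.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column source->target symbol TSV; one-to-many retained."""
    path = Path(path)
    pairs = []
    for i, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise FormatError(f"{path.name}:{i}: expected two non-empty columns")
        pairs.append((parts[0].strip(), parts[1].strip()))
    return OrthologMap(pairs)


def write_ortholog_map(m: OrthologMap, path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{a}\t{b}" for a, b in m.pairs) + "\n")
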