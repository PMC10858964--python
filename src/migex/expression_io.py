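"""Tabular I/O for expression matrices, gene sets, interaction edges and
gene-evidence tables.

All gene identifiers are uppercase HGNC-style symbols; matching across tables
is case-insensitive exact string match, implemented by upper-casing symbols at
the boundary (readers and constructors). Expression values live on an additive
log-like scale throughout.

Formats
-------
* Expression: tab-delimited, genes in rows, first column ``gene``, header row of
  sample IDs; a sidecar metadata TSV maps ``sample`` -> ``group``, ``batch``.
* Gene sets: GMT (set name, description, members, tab-separated).
* Edges: 3-column TSV ``gene_a  gene_b  weight`` (undirected; duplicates merged
  by max weight; self-loops rejected).
* Evidence: 2-column TSV ``gene  value`` (report counts or DisGeNET scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = {"control", "STEMI", "NSTEMI", "day7", "day30", "MI"}


class FormatError(ValueError):
    """A file did not conform to the expected tabular dialect."""


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of log-scale expression values with per-sample
    group and batch labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = uppercase symbols), samples in columns.
    groups : pandas.Series
        Sample -> group label (``control``, ``STEMI``, ``NSTEMI``, ``day7``,
        ``day30`` or ``MI``), indexed like ``values.columns``.
    batches : pandas.Series
        Sample -> batch label, indexed like ``values.columns``.
    """

    values: pd.DataFrame
    groups: pd.Series
    batches: pd.Series
    name: str = "dataset"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.upper()
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        for lab, series in (("groups", self.groups), ("batches", self.batches)):
            missing = set(self.values.columns) - set(series.index)
            if missing:
                raise ValueError(f"{lab} missing for samples {sorted(missing)}")
        self.groups = self.groups.reindex(self.values.columns)
        self.batches = self.batches.reindex(self.values.columns)
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = [g.upper() for g in genes]
        return ExpressionDataset(
            self.values.loc[genes].copy(), self.groups.copy(),
            self.batches.copy(), name=self.name, attrs=dict(self.attrs),
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(), self.groups.copy(), self.batches.copy(),
            name=self.name, attrs=dict(self.attrs),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (uppercase symbols) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = members
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class EdgeList:
    """Undirected weighted interaction edges.

    Self-loops are rejected; duplicate edges (either orientation) are merged
    keeping the maximum weight.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b, weight

    def __post_init__(self) -> None:
        df = self.edges.copy()
        df["gene_a"] = df["gene_a"].astype(str).str.upper()
        df["gene_b"] = df["gene_b"].astype(str).str.upper()
        df["weight"] = df["weight"].astype(float)
        if (df["weight"] < 0).any():
            raise ValueError("edge weights must be non-negative")
        loops = df["gene_a"] == df["gene_b"]
        if loops.any():
            g = df.loc[loops, "gene_a"].iloc[0]
            raise ValueError(f"self-loop on gene {g!r}")
        lo = df[["gene_a", "gene_b"]].min(axis=1)
        hi = df[["gene_a", "gene_b"]].max(axis=1)
        df["gene_a"], df["gene_b"] = lo, hi
        df = (
            df.groupby(["gene_a", "gene_b"], as_index=False)["weight"]
            .max()
            .sort_values(["gene_a", "gene_b"])
            .reset_index(drop=True)
        )
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str, float]]:
        return list(self.edges.itertuples(index=False, name=None))


def read_expression_tsv(path, metadata_path) -> ExpressionDataset:
    """Read an expression TSV plus its sample metadata sidecar.

    Raises on non-numeric cells (naming the offending gene and sample),
    duplicate sample IDs, and metadata rows for unknown samples.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {raw.columns[0]!r}")
    if raw.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ID in header")
    raw = raw.set_index("gene")
    values = pd.DataFrame(index=raw.index.str.upper(), columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed)
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value for gene {gene!r}, sample {col!r}"
            )
        values[col] = parsed.to_numpy()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample", "group", "batch"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{metadata_path}: needs columns {sorted(required)}")
    unknown = set(meta["sample"]) - set(values.columns)
    if unknown:
        raise FormatError(f"{metadata_path}: unknown sample(s) {sorted(unknown)}")
    meta = meta.set_index("sample")
    return ExpressionDataset(
        values,
        groups=meta["group"].astype(str),
        batches=meta["batch"].astype(str),
        name=path.stem,
    )


def write_expression_tsv(dataset: ExpressionDataset, path, metadata_path) -> None:
    out = dataset.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {"sample": dataset.samples, "group": dataset.groups.to_numpy(),
         "batch": dataset.batches.astype(str).to_numpy()}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def collapse_probes(
    dataset: ExpressionDataset,
    probe_to_gene: Mapping[str, str],
    method: str = "mean",
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene symbol.

    ``method='mean'`` averages all probes mapping to a symbol;
    ``method='max-variance'`` keeps verbatim the row of the most variable probe.
    Unmapped probes are dropped; the drop count is logged and stored in
    ``attrs['dropped_probes']``.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if method not in ("mean", "max-variance"):
        raise ValueError(f"unknown collapse method {method!r}")
    mapping = {str(k).upper(): str(v).upper() for k, v in probe_to_gene.items()}
    keep = [p for p in dataset.genes if p in mapping]
    dropped = len(dataset.genes) - len(keep)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", dropped)
    sub = dataset.values.loc[keep]
    symbols = pd.Series([mapping[p] for p in keep], index=sub.index)
    if method == "mean":
        collapsed = sub.groupby(symbols.to_numpy()).mean()
    else:
        variances = sub.var(axis=1, ddof=1)
        best = variances.groupby(symbols.to_numpy()).idxmax()
        collapsed = sub.loc[best.to_numpy()]
        collapsed.index = best.index
    collapsed = collapsed.sort_index()
    ds = ExpressionDataset(
        collapsed, dataset.groups.copy(), dataset.batches.copy(),
        name=dataset.name, attrs=dict(dataset.attrs),
    )
    ds.attrs["dropped_probes"] = dropped
    return ds


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name = parts[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(p.upper() for p in parts[2:] if p)
        desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name in sorted(collection.sets):
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{collection.descriptions.get(name, '')}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_tsv(path) -> EdgeList:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        if lineno == 1 and parts == ["gene_a", "gene_b", "weight"]:
            continue
        try:
            w = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from exc
        rows.append((parts[0], parts[1], w))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    try:
        return EdgeList(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_edge_tsv(edges: EdgeList, path) -> None:
    edges.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_evidence_tsv(path) -> pd.Series:
    """Read a 2-column ``gene  value`` table into a Series indexed by symbol.

    Values must be non-negative; duplicate symbols are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns")
    genes = df.iloc[:, 0].astype(str).str.upper()
    if genes.duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbol {genes[genes.duplicated()].iloc[0]!r}")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        lineno = int(values.isna().to_numpy().nonzero()[0][0]) + 2
        raise FormatError(f"{path}:{lineno}: non-numeric value")
    if (values < 0).any():
        raise FormatError(f"{path}: negative evidence value")
    out = pd.Series(values.to_numpy(dtype=float), index=pd.Index(genes, name="gene"))
    out.name = df.columns[1]
    return out


def write_evidence_tsv(evidence: pd.Series, path, value_name: str = "value") -> None:
    df = pd.DataFrame({"gene": evidence.index, value_name: evidence.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
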