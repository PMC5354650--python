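"""Input/output for expression matrices, annotations, target maps, gene sets
and network serialization.

Expression preprocessing follows the study design for bulk RNA-seq cohorts:
transcripts with expression 0 in every sample are removed, then values are
log2 transformed (``log2(value + pseudocount)``, pseudocount 1 by default so
zeros stay at 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")

__all__ = [
    "RNA_CLASSES",
    "ExpressionMatrix",
    "SampleAnnotation",
    "TargetMap",
    "GeneSetCollection",
    "read_expression",
    "read_annotation",
    "read_target_map",
    "read_gmt",
    "read_gene_list",
    "write_network",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression for one RNA class.

    ``data`` has gene ids as index and sample ids as columns; values are
    log2-transformed and finite.
    """

    rna_class: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}; expected one of {RNA_CLASSES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = [s for s in samples if s in self.data.columns]
        return ExpressionMatrix(self.rna_class, self.data.loc[:, samples])


@dataclass
class SampleAnnotation:
    """Mapping of sample id to group label (a subtype name or ``"normal"``)."""

    groups: Mapping[str, str]
    normal_label: str = "normal"

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def subtypes(self) -> list[str]:
        return [g for g in self.group_names if g != self.normal_label]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without annotation: {missing[:5]}")
        counts: dict[str, int] = {}
        for s in expr.sample_ids:
            g = self.groups[s]
            counts[g] = counts.get(g, 0) + 1
        small = [g for g, c in counts.items() if c < 2]
        if small:
            raise ValueError(f"groups with fewer than 2 samples: {small}")


@dataclass
class TargetMap:
    """Unique (miRNA, target, target class) triples from sequence prediction."""

    triples: frozenset  # of (mirna, target, target_class)

    def __post_init__(self) -> None:
        self.triples = frozenset(self.triples)
        for m, t, c in self.triples:
            if m == t:
                raise ValueError(f"self pair in target map: {m}")
            if c not in ("mRNA", "lncRNA", None):
                raise ValueError(f"bad target class {c!r} for pair ({m}, {t})")

    def __len__(self) -> int:
        return len(self.triples)

    def pairs(self) -> set[tuple[str, str]]:
        return {(m, t) for m, t, _ in self.triples}

    def targets_of(self, mirna: str) -> set[str]:
        return {t for m, t, _ in self.triples if m == mirna}

    def regulators_of(self, target: str) -> set[str]:
        return {m for m, t, _ in self.triples if t == target}

    def target_class(self, target: str) -> str | None:
        for _, t, c in self.triples:
            if t == target:
                return c
        return None


@dataclass
class GeneSetCollection:
    """Named gene sets grouped by category (HALLMARK, GO_BP, KEGG, CGP, ...)."""

    sets: dict[str, dict[str, frozenset]] = field(default_factory=dict)

    def add(self, category: str, name: str, members: Iterable[str]) -> None:
        members = frozenset(members)
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        cat = self.sets.setdefault(category, {})
        if name in cat:
            raise ValueError(f"duplicate gene set name {name!r} in category {category!r}")
        cat[name] = members

    def categories(self) -> list[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return sum(len(c) for c in self.sets.values())


def read_expression(path: str | Path, rna_class: str, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Read a genes x samples TSV of raw non-negative expression values.

    Genes that are zero in every sample are dropped, then values are
    transformed to ``log2(value + pseudocount)``.  Row and column order is
    otherwise preserved.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from None
    if values.isna().to_numpy().any():
        raise ValueError(f"missing values in expression table {path}")
    if raw.index.has_duplicates or raw.columns.has_duplicates:
        raise ValueError(f"duplicate gene or sample ids in {path}")
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative raw expression values in {path}")
    nonzero = values.to_numpy().sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("dropped %d all-zero genes from %s", dropped, path)
    values = values.loc[nonzero]
    data = np.log2(values.to_numpy() + pseudocount)
    return ExpressionMatrix(rna_class, pd.DataFrame(data, index=values.index, columns=values.columns))


def read_annotation(path: str | Path, normal_label: str = "normal") -> SampleAnnotation:
    """Read a two-column TSV (sample id, group label)."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if table["sample"].duplicated().any():
        raise ValueError(f"duplicate sample ids in annotation {path}")
    return SampleAnnotation(dict(zip(table["sample"], table["group"])), normal_label)


def read_target_map(path: str | Path, gene_classes: Mapping[str, str] | None = None) -> TargetMap:
    """Read miRNA-target pairs from a two- or three-column TSV.

    Column three, when present, is the target class (mRNA/lncRNA); when
    absent the class is inferred from ``gene_classes`` (target id -> class),
    typically built from the expression matrices.  Targets never seen in any
    expression matrix are kept with a warning.
    """
    triples = set()
    unseen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                mirna, target = fields
                cls = None
            elif len(fields) == 3:
                mirna, target, cls = fields
                if cls not in ("mRNA", "lncRNA"):
                    raise ValueError(f"{path}:{lineno}: bad target class {cls!r}")
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}")
            if not mirna or not target:
                raise ValueError(f"{path}:{lineno}: empty miRNA or target id")
            if cls is None and gene_classes is not None:
                if target in gene_classes:
                    cls = gene_classes[target]
                else:
                    unseen += 1
            triples.add((mirna, target, cls))
    if unseen:
        warnings.warn(f"{unseen} target-map entries reference targets absent from the gene universe")
    if not triples:
        warnings.warn(f"target map {path} is empty")
    return TargetMap(frozenset(triples))


def read_gmt(path: str | Path, category: str = "GENESET") -> GeneSetCollection:
    """Read a GMT file (set name, description, members; tab-separated)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields (name, description, members)")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            collection.add(category, name, members)
    return collection


def read_gene_list(path: str | Path) -> frozenset:
    """Read one gene id per line (mutated-gene lists)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_network(network, path: str | Path, format: str = "edge-TSV") -> None:
    """Serialize a dys-regulatory or ceRNA network deterministically.

    ``edge-TSV`` writes one row per edge with attribute columns; ``SIF``
    writes the Cytoscape simple-interaction format.  Undirected edges are
    canonicalized (lexicographically smaller endpoint first) and rows are
    sorted, so rewriting the same network is byte-identical.
    """
    table = network.to_edge_table()
    path = Path(path)
    if format == "edge-TSV":
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "SIF":
        rel = getattr(network, "sif_relation", "interacts")
        with open(path, "w") as fh:
            for _, row in table.iterrows():
                fh.write(f"{row.iloc[0]}\t{rel}\t{row.iloc[1]}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")
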