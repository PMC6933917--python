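"""Readers, writers and validated in-memory containers for all on-disk formats.

Everything is plain TSV (tab-separated, UTF-8, "." decimal, no quoting)
except gene-set catalogs, which use the standard GMT layout. Gene and
sample identifiers are opaque, case-sensitive strings: no case folding ever
happens here — mapping between mouse and human namespaces is solely the
ortholog map's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SCALE_TAGS = ("counts", "tpm", "log2tpm")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix with a scale tag.

    ``data`` is indexed by gene (rows) and sample (columns); ``scale_tag``
    is one of ``counts`` (nonnegative integers), ``tpm`` (nonnegative
    reals) or ``log2tpm`` (reals).
    """

    data: pd.DataFrame
    scale_tag: str

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        dup_g = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene identifiers: {dup_g}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample identifiers: {dup_s}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(values.astype(float)).any():
            bad = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValueError(
                f"missing value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale_tag in ("counts", "tpm") and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative {self.scale_tag} value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )
        if self.scale_tag == "counts":
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.data = self.data.round().astype(np.int64)

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample strain and batch labels with a designated control strain."""

    table: pd.DataFrame  # indexed by sample id; columns: strain, batch
    control: str = "B6"

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dup}")
        for col in ("strain", "batch"):
            if col not in self.table.columns:
                raise ValueError(f"metadata is missing the {col!r} column")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.samples if s not in self.table.index]
        if missing:
            raise ValueError(f"expression samples missing from metadata: {missing}")
        n_control = int((self.table["strain"] == self.control).sum())
        if n_control < 2:
            raise ValueError(
                f"control strain {self.control!r} needs >= 2 samples, found {n_control}"
            )

    def strains(self) -> list[str]:
        return self.table["strain"].unique().tolist()

    def samples_of(self, strain: str) -> list[str]:
        return self.table.index[self.table["strain"] == strain].tolist()


@dataclass
class GeneSetCatalog:
    """Named gene sets, optionally carrying a grouping label per set."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class OrthologMap:
    """Mouse-to-human gene pairs; may contain one-to-many rows."""

    table: pd.DataFrame  # columns: mouse, human[, confidence]

    def __post_init__(self) -> None:
        for col in ("mouse", "human"):
            if col not in self.table.columns:
                raise ValueError(f"ortholog map is missing the {col!r} column")
            col_vals = self.table[col].astype(str)
            if (col_vals.str.len() == 0).any() or col_vals.isin(["nan"]).any():
                raise ValueError(f"empty identifiers in ortholog column {col!r}")
        ndup = int(self.table.duplicated(subset=["mouse", "human"]).sum())
        if ndup:
            log.warning("ortholog map: dropping %d exactly duplicated rows", ndup)
            self.table = self.table.drop_duplicates(subset=["mouse", "human"]).reset_index(
                drop=True
            )

    def human_partners(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m, h in zip(self.table["mouse"], self.table["human"]):
            out.setdefault(m, []).append(h)
        return out


@dataclass
class HumanLFCTable:
    """Per-gene human log2 fold change (AD vs control), one column per region."""

    table: pd.DataFrame  # indexed by human gene; columns = region labels

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers in LFC table: {dup}")
        values = self.table.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("LFC table contains missing or non-finite values")

    @property
    def regions(self) -> list[str]:
        return self.table.columns.tolist()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                       keep_default_na=False, na_values=[])


def read_expression(path, scale_tag: str) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    raw = _read_tsv(path)
    try:
        data = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(raw.columns):
            conv = pd.to_numeric(raw[col], errors="coerce")
            if conv.isna().any():
                i = int(np.argmax(conv.isna().to_numpy()))
                raise ValueError(
                    f"non-numeric cell {raw.iloc[i, j]!r} at gene "
                    f"{raw.index[i]!r}, sample {col!r}"
                ) from None
        raise
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    return ExpressionMatrix(data, scale_tag)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path, control: str = "B6") -> SampleMetadata:
    """Read sample metadata; a missing batch column defaults to one batch."""
    raw = _read_tsv(path)
    raw.index = raw.index.astype(str)
    if "strain" not in raw.columns:
        raise ValueError("metadata must have a 'strain' column")
    if "batch" not in raw.columns:
        log.warning("metadata has no 'batch' column; assuming a single batch 'batch1'")
        raw = raw.assign(batch="batch1")
    return SampleMetadata(raw[["strain", "batch"]].astype(str), control=control)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path) -> GeneSetCatalog:
    """Read a GMT catalog: name, description, then member genes per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                log.info("GMT set %s: collapsed %d duplicate genes",
                         name, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCatalog(sets, descriptions)


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in catalog.sets.items():
            desc = catalog.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_ortholog_map(path) -> OrthologMap:
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str,
                      keep_default_na=False, na_values=[])
    cols = list(raw.columns)
    if len(cols) < 2:
        raise ValueError("ortholog map needs at least 2 columns (mouse, human)")
    rename = {cols[0]: "mouse", cols[1]: "human"}
    if len(cols) >= 3:
        rename[cols[2]] = "confidence"
    return OrthologMap(raw.rename(columns=rename))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    omap.table.to_csv(path, sep="\t", index=False)


def read_lfc_table(path) -> HumanLFCTable:
    raw = _read_tsv(path)
    raw.index = raw.index.astype(str)
    bad = raw.isin(["NA", "NaN", "nan", ""]).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"missing value in LFC table at gene {raw.index[i]!r}, "
            f"region {raw.columns[j]!r}"
        )
    return HumanLFCTable(raw.apply(pd.to_numeric))


def write_lfc_table(lfc: HumanLFCTable, path) -> None:
    lfc.table.to_csv(path, sep="\t", index_label="gene")


def read_module_assignment(path) -> dict[str, str]:
    """Read a two-column (gene, module) TSV into a gene -> label map."""
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return dict(zip(raw.iloc[:, 0], raw.iloc[:, 1]))


def write_module_assignment(assignment: dict[str, str], path) -> None:
    pd.DataFrame(
        {"gene": list(assignment), "module": list(assignment.values())}
    ).to_csv(path, sep="\t", index=False)
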