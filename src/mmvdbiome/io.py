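"""Readers and writers for the on-disk cohort formats.

All feature tables are samples-in-columns on disk (the common amplicon
convention) and samples-in-rows in memory.  Readers validate and reject
malformed values rather than coercing them; writers emit a canonical
tab-separated dialect that round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

STAGES = ("A", "B1", "B2", "CD")

QPCR_TARGETS = (
    "total_bacteria",
    "faecalibacterium",
    "turicibacter",
    "streptococcus",
    "e_coli",
    "blautia",
    "fusobacterium",
    "c_hiranonis",
)

BILE_ACIDS = ("ca", "cdca", "dca", "lca", "udca")
PRIMARY_BAS = ("ca", "cdca")
SECONDARY_BAS = ("dca", "lca", "udca")

SCFAS = ("acetate", "propionate", "butyrate", "valerate", "isobutyrate", "isovalerate")

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ConsistencyError(ValueError):
    """Cross-table identifiers do not line up."""


@dataclass
class OtuTable:
    """Integer OTU counts with 7-rank taxonomy lineages.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples in rows, OTUs in columns, non-negative integers.
    lineage : pandas.Series
        Semicolon-delimited taxonomy string per OTU, up to 7 ranks
        (kingdom through species); empty ranks allowed.
    """

    counts: pd.DataFrame
    lineage: pd.Series = field(default=None)

    def __post_init__(self):
        if self.lineage is None:
            self.lineage = pd.Series("", index=self.counts.columns)
        self.lineage = self.lineage.reindex(self.counts.columns)
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in OTU table")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate OTU identifiers in OTU table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise FormatError("OTU counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        if self.lineage.isna().any():
            self.lineage = self.lineage.fillna("")
        bad = self.lineage[self.lineage.str.count(";") > 6]
        if len(bad):
            raise FormatError(f"lineage with more than 7 ranks for OTU {bad.index[0]!r}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)


def read_otu_table(path) -> OtuTable:
    """Read a tab-separated OTU table (first column OTU id, last column taxonomy)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[-1] != "taxonomy":
        raise FormatError(f"{path}: last column must be 'taxonomy', got {df.columns[-1]!r}")
    otu_ids = df.iloc[:, 0]
    if otu_ids.duplicated().any():
        dup = otu_ids[otu_ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate OTU id {dup!r}")
    sample_cols = list(df.columns[1:-1])
    counts = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count {raw!r} at OTU {otu_ids.iloc[i]!r}, sample {col!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count {raw!r} at OTU {otu_ids.iloc[i]!r}, sample {col!r}"
                )
            counts[i, j] = val
    counts_df = pd.DataFrame(counts.T, index=pd.Index(sample_cols, name="sample_id"),
                             columns=list(otu_ids))
    lineage = pd.Series(list(df["taxonomy"]), index=list(otu_ids))
    return OtuTable(counts_df, lineage)


def write_otu_table(table: OtuTable, path) -> None:
    """Write the canonical tab-separated dialect (features in rows)."""
    out = table.counts.T.copy()
    out.insert(len(out.columns), "taxonomy", table.lineage)
    out.index.name = "#OTU_ID"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError(f"{path}: duplicate tip labels")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (stage, age, body_weight, bcs, sex).

    Stages C and D are analyzed pooled; a raw "C" or "D" label is rejected
    with a hint to relabel as "CD".
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"stage", "age", "body_weight", "bcs", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        hint = " (stages C and D are pooled: use 'CD')" if bad & {"C", "D"} else ""
        raise FormatError(f"{path}: unknown stage label(s) {sorted(bad)}{hint}")
    if (df["age"] <= 0).any():
        raise FormatError(f"{path}: non-positive age")
    if ((df["bcs"] < 1) | (df["bcs"] > 9)).any():
        raise FormatError(f"{path}: BCS outside 1-9")
    if not set(df["sex"]) <= {"M", "F"}:
        raise FormatError(f"{path}: sex must be M or F")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_numeric_table(path, columns=None) -> pd.DataFrame:
    """Read a tab-separated numeric table indexed by sample id.

    Parameters
    ----------
    columns : sequence of str, optional
        Required column names; extra columns are kept.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate sample ids")
    if columns is not None:
        missing = set(columns) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{path}: non-numeric column {col!r}")
        if not np.all(np.isfinite(df[col])):
            raise FormatError(f"{path}: non-finite value in column {col!r}")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate column names")
    return df


def write_numeric_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_qpcr(path) -> pd.DataFrame:
    return read_numeric_table(path, columns=QPCR_TARGETS)


def read_bile_acids(path) -> pd.DataFrame:
    df = read_numeric_table(path, columns=BILE_ACIDS)
    if (df[list(BILE_ACIDS)] < 0).to_numpy().any():
        raise FormatError(f"{path}: negative bile-acid concentration")
    return df


def check_cohort(otu_table: OtuTable = None, tree: TreeNode = None, **tables) -> None:
    """Assert shared sample ids across tables and tree tips covering all OTUs.

    Raises
    ------
    ConsistencyError
        Listing the offending identifiers.
    """
    sample_sets = {}
    if otu_table is not None:
        sample_sets["otu_table"] = set(otu_table.sample_ids)
    for name, tab in tables.items():
        if tab is not None:
            sample_sets[name] = set(tab.index)
    if sample_sets:
        names = sorted(sample_sets)
        ref = sample_sets[names[0]]
        for name in names[1:]:
            if sample_sets[name] != ref:
                diff = sorted(ref ^ sample_sets[name])
                raise ConsistencyError(
                    f"sample ids differ between {names[0]} and {name}: {diff[:10]}"
                )
    if tree is not None and otu_table is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(otu_table.otu_ids) - tips)
        if missing:
            raise ConsistencyError(f"tree is missing OTU tip(s): {missing[:10]}")


def write_truth(truth: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(truth, indent=2, default=_default) + "\n")
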