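"""Readers and writers for the pipeline's tab-separated formats.

Everything on disk is TSV: taxon-by-sample feature tables with a metadata
sidecar, taxon-by-KO gene content, PICRUSt2-layout predicted-metagenome
tables ("pred_metagenome_unstrat": rows are function ids, first column header
``function``; legacy "contrib": one row per sample/function/taxon), KO ->
subpathway maps, dye series, and KO annotations.  Every writer has a reader
that round-trips it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community_metrics import FeatureTable
from .function_link import GenomeContent, PathwayMap

__all__ = [
    "load_feature_table", "write_feature_table",
    "load_genome_content", "write_genome_content",
    "load_ko_table", "write_ko_table",
    "load_contrib_table", "write_contrib_table",
    "load_pathway_map", "write_pathway_map",
    "load_dye_series", "write_dye_series",
    "load_annotations", "write_annotations",
]

CONTRIB_LEGACY_COLUMNS = [
    "sample", "function", "taxon", "taxon_abun", "taxon_rel_abun",
    "genome_function_count", "taxon_function_abun", "taxon_rel_function_abun",
]


def _read_tsv_matrix(path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(index_name)
    df.columns = df.columns.astype(str)
    return df


def load_feature_table(counts_path, meta_path) -> FeatureTable:
    """Load a taxon x sample count TSV plus its sample-metadata sidecar.

    Non-integer or negative counts, duplicate ids, and samples missing from
    the metadata are rejected with the offending row/column named.
    """
    counts = _read_tsv_matrix(counts_path, "taxon_id")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = counts.columns[[not np.issubdtype(counts[c].dtype, np.number)
                              for c in counts.columns]].tolist()
        raise ValueError(f"non-numeric counts in column(s) {bad}")
    if not np.allclose(vals, np.round(vals)):
        r, c = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise ValueError(
            f"non-integer count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}")
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str).rename("sample_id")
    return FeatureTable(counts=counts.astype(np.int64), sample_meta=meta)


def write_feature_table(table: FeatureTable, counts_path, meta_path) -> None:
    table.counts.rename_axis("taxon_id").to_csv(counts_path, sep="\t")
    table.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def load_genome_content(path) -> GenomeContent:
    return GenomeContent(copies=_read_tsv_matrix(path, "taxon_id"))


def write_genome_content(genome: GenomeContent, path) -> None:
    genome.copies.rename_axis("taxon_id").to_csv(path, sep="\t")


def load_ko_table(path) -> pd.DataFrame:
    """Read a pred_metagenome_unstrat-layout TSV (first column ``function``)."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first not in ("function", "#OTU ID", "ko_id"):
        raise ValueError(f"unexpected first column {first!r} for a KO table")
    return df.set_index(first).rename_axis("function")


def write_ko_table(kt: pd.DataFrame, path) -> None:
    kt.rename_axis("function").to_csv(path, sep="\t")


def write_contrib_table(contrib: pd.DataFrame, path) -> None:
    """Write a stratified contribution table in the legacy contrib layout."""
    out = pd.DataFrame({
        "sample": contrib["sample_id"],
        "function": contrib["ko_id"],
        "taxon": contrib["taxon_id"],
        "taxon_abun": contrib["taxon_abundance"],
        "taxon_rel_abun": contrib["taxon_abundance"],
        "genome_function_count": contrib["copy_number"],
        "taxon_function_abun": contrib["contributed_count"],
        "taxon_rel_function_abun": contrib["contributed_count"],
    })
    out.to_csv(path, sep="\t", index=False)


def load_contrib_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CONTRIB_LEGACY_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"contrib table lacks column(s) {missing}")
    return pd.DataFrame({
        "sample_id": df["sample"].astype(str),
        "ko_id": df["function"].astype(str),
        "taxon_id": df["taxon"].astype(str),
        "taxon_abundance": df["taxon_abun"].astype(float),
        "copy_number": df["genome_function_count"].astype(float),
        "contributed_count": df["taxon_function_abun"].astype(float),
    })


def load_pathway_map(path) -> PathwayMap:
    """KO -> subpathway map TSV with columns ko_id, subpathway
    (one row per membership) and optional super_pathway/category columns."""
    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, set[str]] = {}
    info: dict[str, dict] = {}
    for row in df.itertuples():
        mapping.setdefault(str(row.ko_id), set()).add(str(row.subpathway))
        meta = {}
        if hasattr(row, "super_pathway"):
            meta["super_pathway"] = row.super_pathway
        if hasattr(row, "category"):
            meta["category"] = row.category
        if meta:
            info.setdefault(str(row.subpathway), meta)
    return PathwayMap(ko_to_subpathways=mapping, subpathway_info=info)


def write_pathway_map(pmap: PathwayMap, path) -> None:
    rows = []
    for ko, subs in sorted(pmap.ko_to_subpathways.items()):
        for s in sorted(subs):
            meta = pmap.subpathway_info.get(s, {})
            rows.append({"ko_id": ko, "subpathway": s,
                         "super_pathway": meta.get("super_pathway", ""),
                         "category": meta.get("category", "")})
    pd.DataFrame(rows, columns=["ko_id", "subpathway", "super_pathway", "category"]).to_csv(
        path, sep="\t", index=False)


def load_dye_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename("sample_id")
    return df


def write_dye_series(dye: pd.DataFrame, path) -> None:
    dye.rename_axis("sample_id").to_csv(path, sep="\t")


def load_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename("ko_id")
    if "nadp_dependent" in df.columns:
        df["nadp_dependent"] = df["nadp_dependent"].astype(bool)
    return df


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.rename_axis("ko_id").to_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
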