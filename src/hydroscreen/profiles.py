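"""ASV count tables: reading, depth filtering, diversity, aggregation.

Consumes denoised amplicon (ASV) count tables with per-sample metadata
(reactor, day, replicate) and a 7-rank taxonomy, as produced by standard
amplicon workflows. Provides the sample-depth filter, relative-abundance
closure, bias-corrected Chao1 richness, Shannon diversity (natural log),
and taxon-level aggregation used for reporting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _alpha

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "Unclassified"


class TableError(ValueError):
    pass


@dataclass
class AsvCountTable:
    """Samples × ASVs integer counts with per-sample metadata.

    ``counts`` is indexed by sample id with ASV ids as columns;
    ``metadata`` is indexed by sample id and must carry at least
    ``reactor``, ``day`` and ``replicate`` for every sample.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise TableError("counts: negative values")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise TableError(f"metadata: missing samples {list(missing)[:5]}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, mask: pd.Series) -> "AsvCountTable":
        return AsvCountTable(self.counts.loc[mask], self.metadata.loc[mask])

    def for_reactor(self, reactor: str, replicate: str | None = None) -> "AsvCountTable":
        m = self.metadata["reactor"] == reactor
        if replicate is not None:
            m &= self.metadata["replicate"] == replicate
        return self.subset(m)


@dataclass
class TaxonomyTable:
    """ASV id → 7-rank lineage; missing entries resolve to "Unclassified"."""

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        self.lineages = self.lineages.reindex(columns=list(RANKS)).fillna("")

    def label(self, asv_id: str, rank: str = "genus") -> str:
        """Deepest classified label at or above ``rank`` for one ASV."""
        if asv_id not in self.lineages.index:
            return UNCLASSIFIED
        upto = list(RANKS)[: RANKS.index(rank) + 1]
        row = self.lineages.loc[asv_id, upto]
        named = [v for v in row if isinstance(v, str) and v.strip()]
        if not named:
            return UNCLASSIFIED
        if len(named) < len(upto):
            return f"{named[-1]} (unclassified {rank})"
        return named[-1]


def filter_samples(table: AsvCountTable, min_reads: int = 10_000) -> AsvCountTable:
    """Remove samples with fewer than ``min_reads`` total reads.

    Samples with totals strictly below the threshold are dropped (the
    standard rarefaction-informed depth cut); removed sample ids are
    logged. An all-below-threshold table yields an empty table with a
    warning, not an error.
    """
    keep = table.totals >= min_reads
    removed = table.counts.index[~keep]
    if len(removed):
        logger.info("filter_samples: removed %d samples below %d reads: %s",
                    len(removed), min_reads, list(removed))
    if not keep.any():
        warnings.warn(f"all samples below {min_reads} reads; empty table", stacklevel=2)
    return table.subset(keep)


def to_relative(table: AsvCountTable) -> pd.DataFrame:
    """Close each sample's counts to relative abundances summing to 1."""
    totals = table.totals
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise TableError(f"zero-total samples (filter first): {bad[:5]}")
    return table.counts.div(totals, axis=0)


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1−1) / (2(f2+1))."""
    c = np.asarray(counts)
    return float(_alpha.chao1(c, bias_corrected=True))


def shannon(counts: Sequence[int]) -> float:
    """Shannon diversity −Σ p ln p in nats over non-zero taxa."""
    c = np.asarray(counts)
    return float(_alpha.shannon(c, base=np.e))


def alpha_diversity_table(table: AsvCountTable) -> pd.DataFrame:
    """Per-sample observed richness, Chao1 and Shannon with metadata."""
    rows = {
        s: {
            "observed": int((table.counts.loc[s] > 0).sum()),
            "chao1": chao1(table.counts.loc[s].to_numpy()),
            "shannon": shannon(table.counts.loc[s].to_numpy()),
        }
        for s in table.sample_ids
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    return table.metadata.join(out)


def aggregate_taxon(
    table: AsvCountTable, taxonomy: TaxonomyTable, rank: str = "genus"
) -> pd.DataFrame:
    """Sum counts of ASVs sharing a lineage at ``rank`` (samples × taxa).

    ASVs unresolved at ``rank`` are pooled under their nearest classified
    parent label; ``rank="asv"`` is the identity. Sample totals are
    conserved.
    """
    if rank == "asv":
        return table.counts.copy()
    if rank not in RANKS:
        raise TableError(f"rank: {rank!r} not in {RANKS} or 'asv'")
    labels = {asv: taxonomy.label(asv, rank) for asv in table.asv_ids}
    return table.counts.T.groupby(labels.get).sum().T


# ---------------------------------------------------------------------------
# Readers / writers

_ASV_HEADER_HINTS = {"asv", "asv_id", "#otu id", "otu", "otu_id", "feature id", "feature_id"}


def read_counts_tsv(path, metadata: pd.DataFrame | None = None, sep: str = "\t") -> AsvCountTable:
    """Read a delimited ASV table; orientation auto-detected from the header.

    If the first header cell names the ASV/OTU/feature axis, rows are
    taken as ASVs and the table is transposed to samples × ASVs.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if str(df.index.name).strip().lower() in _ASV_HEADER_HINTS:
        df = df.T
    df = df.astype(np.int64)
    if metadata is None:
        metadata = pd.DataFrame(index=df.index)
    return AsvCountTable(counts=df, metadata=metadata)


def read_biom_json(path, metadata: pd.DataFrame | None = None) -> AsvCountTable:
    """Read a BIOM-format v1.0 JSON table (sparse or dense, ASVs as rows)."""
    with open(path) as fh:
        doc = json.load(fh)
    asvs = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(asvs), len(samples)), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(v)
    df = pd.DataFrame(mat.T, index=samples, columns=asvs)
    if metadata is None:
        metadata = pd.DataFrame(index=df.index)
    return AsvCountTable(counts=df, metadata=metadata)


def read_taxonomy_tsv(path, sep: str = "\t") -> TaxonomyTable:
    """Read ASV → semicolon-delimited lineage (column 2) as a taxonomy."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    lineage_col = df.columns[0]
    rows = {}
    for asv, lineage in df[lineage_col].items():
        parts = [p.strip() for p in str(lineage).split(";")] if pd.notna(lineage) else []
        parts = (parts + [""] * len(RANKS))[: len(RANKS)]
        rows[asv] = parts
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def read_metadata_tsv(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    missing = [c for c in ("reactor", "day", "replicate") if c not in df.columns]
    if missing:
        raise TableError(f"metadata: missing columns {missing}")
    return df


def write_counts_tsv(table: AsvCountTable, path, sep: str = "\t") -> None:
    out = table.counts.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=sep)


def write_taxonomy_tsv(taxonomy: TaxonomyTable, path, sep: str = "\t") -> None:
    lineage = taxonomy.lineages.apply(lambda r: ";".join(r), axis=1)
    pd.DataFrame({"lineage": lineage}).rename_axis("asv_id").to_csv(path, sep=sep)
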