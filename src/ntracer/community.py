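"""Genus-level community tables: ingestion, subsetting, diversity, dissimilarity.

Consumes feature tables produced by an upstream amplicon pipeline (taxa x
samples, counts or relative abundances) with 7-level semicolon taxonomy
strings (``d__Bacteria; p__Cyanobacteria; ...; g__Microcystis``, rank
prefixes optional). Provides the composition quantities reported for plankton
fractions: clade-restricted relative frequencies, Shannon diversity (nats),
Pielou evenness, and Bray-Curtis dissimilarity feeding the permutation
statistics in :mod:`ntracer.stats`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RANKS",
    "CommunityTable",
    "DiversityRecord",
    "parse_lineage",
    "load_table",
    "subset_relative_frequency",
    "diversity",
    "bray_curtis",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_lineage(taxonomy: str) -> tuple[str, ...]:
    """Parse a semicolon taxonomy string into up to 7 ranks, stripping prefixes."""
    levels = []
    for part in str(taxonomy).split(";"):
        name = part.strip()
        for p in _PREFIXES:
            if name.lower().startswith(p):
                name = name[len(p):]
                break
        if name:
            levels.append(name)
    return tuple(levels[: len(RANKS)])


@dataclass
class CommunityTable:
    """Samples x taxa relative abundances with lineage and sample metadata.

    ``abundance`` is taxa x samples; columns sum to 1 after normalization.
    ``lineage`` maps taxon id -> parsed rank tuple. ``metadata`` (optional)
    is indexed by sample id with e.g. lake / date / fraction columns.
    """

    abundance: pd.DataFrame
    lineage: dict[str, tuple[str, ...]] = field(default_factory=dict)
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.abundance.index.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.abundance.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.abundance.values < 0).any():
            raise ValueError("negative abundances")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.index)

    def normalized(self) -> "CommunityTable":
        """Per-sample proportions; empty samples are dropped with a warning."""
        totals = self.abundance.sum(axis=0)
        empty = totals[totals <= 0].index
        if len(empty):
            warnings.warn(f"dropping empty sample(s): {list(empty)}")
        keep = self.abundance.drop(columns=empty)
        norm = keep / keep.sum(axis=0)
        meta = self.metadata.drop(index=empty, errors="ignore") if self.metadata is not None else None
        return CommunityTable(norm, dict(self.lineage), meta)

    def is_proportional(self, tol: float = 1e-6) -> bool:
        totals = self.abundance.sum(axis=0)
        return bool(np.allclose(totals[totals > 0], 1.0, atol=tol))


def _parse_taxonomy_map(path: Path) -> dict[str, tuple[str, ...]]:
    tax = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if tax.shape[1] < 2:
        raise ValueError("taxonomy map needs two columns: taxon id, lineage string")
    out = {}
    for _, row in tax.iterrows():
        lin = parse_lineage(row.iloc[1])
        if not lin:
            warnings.warn(f"malformed taxonomy for {row.iloc[0]!r}; kept unclassified")
        out[str(row.iloc[0])] = lin
    return out


def load_table(
    path: str | Path,
    format: str = "tsv",
    taxonomy: str | Path | None = None,
    metadata: str | Path | None = None,
    *,
    as_counts: Optional[bool] = None,
) -> CommunityTable:
    """Load a feature table from TSV (taxa x samples) or BIOM 1.0 JSON.

    Counts vs proportions are auto-detected (column sums ~ 1 -> proportions);
    either way the returned table is normalized to per-sample proportions.
    ``taxonomy`` is a 2-column TSV (taxon id, semicolon lineage); BIOM files
    may instead carry lineage in row metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lineage: dict[str, tuple[str, ...]] = {}
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if "taxonomy" in df.columns:
            lineage = {str(t): parse_lineage(s) for t, s in df["taxonomy"].items()}
            df = df.drop(columns="taxonomy")
        df = df.astype(float)
    elif format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [str(r["id"]) for r in doc["rows"]]
        samples = [str(c["id"]) for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(mat, index=taxa, columns=samples)
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy")
            if tax is not None:
                s = "; ".join(tax) if isinstance(tax, (list, tuple)) else str(tax)
                lineage[str(r["id"])] = parse_lineage(s)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")

    if taxonomy is not None:
        lineage.update(_parse_taxonomy_map(Path(taxonomy)))
    meta = None
    if metadata is not None:
        meta = pd.read_csv(metadata).set_index("sample_id")
    table = CommunityTable(df, lineage, meta)
    if as_counts is False and not table.is_proportional():
        raise ValueError("table declared proportional but columns do not sum to 1")
    return table.normalized()


def _collapse(table: CommunityTable, rank: str) -> CommunityTable:
    depth = RANKS.index(rank)
    labels = []
    for t in table.taxa:
        lin = table.lineage.get(t, ())
        labels.append(lin[depth] if len(lin) > depth else f"unclassified_{t}")
    grouped = table.abundance.groupby(labels).sum()
    return CommunityTable(grouped, {}, table.metadata)


def subset_relative_frequency(
    table: CommunityTable,
    clade: Sequence[str] | str,
    collapse: Optional[str] = "genus",
) -> CommunityTable:
    """Restrict to a clade (lineage prefix), re-normalize within it, collapse to a rank.

    Samples with no clade members are dropped (reported missing, never
    zero-divided). E.g. ``clade=("Bacteria", "Cyanobacteria")`` with
    ``collapse="genus"`` yields each sample's cyanobacterial genera as
    fractions of its cyanobacterial reads.
    """
    prefix = tuple(parse_lineage(clade)) if isinstance(clade, str) else tuple(clade)
    keep = [
        t
        for t in table.taxa
        if table.lineage.get(t, ())[: len(prefix)] == prefix
    ]
    if not keep:
        raise ValueError(f"clade {prefix} matches no taxon")
    sub = CommunityTable(table.abundance.loc[keep], {t: table.lineage[t] for t in keep},
                         table.metadata)
    sub = sub.normalized()
    if collapse is not None:
        sub = _collapse(sub, collapse)
    return sub


@dataclass(frozen=True)
class DiversityRecord:
    sample: str
    richness: int
    shannon: float  # nats
    pielou: Optional[float]  # undefined for richness <= 1


def diversity(table: CommunityTable) -> pd.DataFrame:
    """Richness, Shannon diversity (nats) and Pielou evenness per sample."""
    table = table if table.is_proportional() else table.normalized()
    rows = []
    for s in table.samples:
        p = table.abundance[s].to_numpy()
        p = p[p > 0]
        richness = int(p.size)
        shannon = float(-(p * np.log(p)).sum()) if richness else 0.0
        pielou = shannon / np.log(richness) if richness >= 2 else np.nan
        rows.append({"sample": s, "richness": richness, "shannon": shannon, "pielou": pielou})
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    ab = table.abundance if isinstance(table, CommunityTable) else table
    totals = ab.sum(axis=0)
    zero = totals[totals <= 0].index
    if len(zero):
        warnings.warn(f"excluding zero-total sample(s) from distances: {list(zero)}")
        ab = ab.drop(columns=zero)
    if ab.shape[1] < 2:
        raise ValueError("need at least two non-empty samples")
    d = squareform(pdist(ab.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=ab.columns, columns=ab.columns)
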