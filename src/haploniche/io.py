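"""Readers and writers for the external formats of the pipeline.

CSV for haplotype count tables, cpSSR genotypes, population metadata and
occurrence records; FASTA (via Biopython) for aligned haplotype
sequences; ESRI ASCII grids for rasters (see .raster); GraphML for
haplotype networks; JSON for reports. Every reader validates its input
and raises with a diagnostic naming the offending row or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from Bio import SeqIO

from .config import PopulationMeta
from .haplostats import HaplotypeTable
from .haplonet import SequenceSet
from .niche import OccurrenceSet, GEO_COLUMNS
from .raster import EnvRaster, read_raster, write_raster  # noqa: F401  (re-export)


def read_haplotype_table(path: str | Path, genome: str = "mt") -> HaplotypeTable:
    """Read a populations x haplotypes count CSV.

    First column: population id. Optional column 'N': declared sample
    size, validated against the row sum. Remaining columns: integer
    haplotype counts, labels preserved in input order.
    """
    df = pd.read_csv(path)
    pop_col = df.columns[0]
    pops = df[pop_col].astype(str).tolist()
    if len(set(pops)) != len(pops):
        dupes = sorted({p for p in pops if pops.count(p) > 1})
        raise ValueError(f"{path}: duplicate population ids {dupes}")
    declared = None
    if "N" in df.columns:
        declared = df["N"].to_numpy()
        df = df.drop(columns=["N"])
    hap_cols = [c for c in df.columns if c != pop_col]
    counts = df[hap_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: non-numeric haplotype counts")
    if np.any(counts != np.floor(counts)) or np.any(counts < 0):
        bad = [pops[i] for i in np.flatnonzero(
            np.any((counts != np.floor(counts)) | (counts < 0), axis=1))]
        raise ValueError(f"{path}: non-integer or negative counts in rows {bad}")
    counts = counts.astype(np.int64)
    if declared is not None:
        mism = np.flatnonzero(counts.sum(axis=1) != declared)
        if mism.size:
            raise ValueError(
                f"{path}: row sums differ from declared N for populations "
                f"{[pops[i] for i in mism]}")
    keep = counts.sum(axis=0) > 0
    return HaplotypeTable(counts[:, keep], pops,
                          [h for h, k in zip(hap_cols, keep) if k], genome=genome)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, columns=table.haplotype_ids)
    df.insert(0, "population", table.population_ids)
    df.insert(1, "N", table.sample_sizes)
    df.to_csv(path, index=False)


def read_fasta_alignment(path: str | Path,
                         indel_blocks: list[tuple[int, int]] | None = None,
                         ) -> SequenceSet:
    """Read an aligned FASTA into a SequenceSet (equal lengths enforced)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}; "
                         "input must be aligned")
    return SequenceSet(names=[r.id for r in records],
                       sequences=[str(r.seq) for r in records],
                       indel_blocks=indel_blocks or [])


def write_fasta_alignment(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(seqs.names, seqs.sequences):
            fh.write(f">{name}\n{seq}\n")


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    """Population coordinate/altitude CSV -> list of PopulationMeta."""
    df = pd.read_csv(path)
    required = {"population_id", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(PopulationMeta(
            population_id=str(row["population_id"]),
            name=str(row.get("name", row["population_id"])),
            longitude=float(row["longitude"]),
            latitude=float(row["latitude"]),
            altitude=float(row.get("altitude", 0.0)),
            sample_size_mt=int(row.get("sample_size_mt", 1)),
            sample_size_cp=int(row.get("sample_size_cp", 1))))
    return out


def read_genotypes(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """cpSSR genotype CSV (first column haplotype/individual id, remaining
    columns allele sizes per locus) -> (sizes matrix, ids)."""
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    sizes = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(sizes)):
        bad = [ids[i] for i in np.flatnonzero(~np.isfinite(sizes).all(axis=1))]
        raise ValueError(f"{path}: missing allele sizes for {bad}")
    return sizes, ids


def read_occurrences(path: str | Path, raster: EnvRaster | None = None,
                     ) -> OccurrenceSet:
    """Occurrence CSV (longitude, latitude, altitude + environmental
    columns). When a raster is supplied, points are deduplicated to one
    per grid cell (the first record in each cell is kept)."""
    df = pd.read_csv(path)
    missing = set(GEO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no occurrence rows")
    env_cols = [c for c in df.columns if c not in GEO_COLUMNS and c != "ecotype"]
    na_rows = df.index[df[env_cols].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"{path}: missing environmental values in rows {na_rows}")
    if raster is not None:
        row, col = raster.cell_index(df["longitude"].to_numpy(),
                                     df["latitude"].to_numpy())
        cell = pd.Series(list(zip(row, col)), index=df.index)
        df = df[~cell.duplicated()].reset_index(drop=True)
    return OccurrenceSet(df)


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Export a haplotype network as GraphML (node frequency / observed /
    outgroup attributes, edge step counts)."""
    nx.write_graphml(net, str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_report(results: dict, path: str | Path) -> None:
    """Deterministic JSON report (sorted keys, numpy types coerced)."""

    def coerce(obj):
        if isinstance(obj, dict):
            return {str(k): coerce(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [coerce(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return coerce(obj.tolist())
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        json.dump(coerce(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
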