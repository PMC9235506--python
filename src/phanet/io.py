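"""Readers and writers for the standard on-disk formats.

FASTA (gzip-transparent) for genomes and contigs, TSV tables for association
pairs / cluster maps / host taxa / scores, YAML for configs and JSON for run
manifests.  All tabular outputs carry header rows and use locale-independent
number formatting.
"""

from __future__ import annotations

import gzip
import json
import sys
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import pandas as pd
from Bio import SeqIO

from .encoding import ContigRecord, Role

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pair_table",
    "write_pair_table",
    "read_cluster_map",
    "read_taxon_map",
    "write_manifest",
]


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path], role: Union[Role, str] = Role.PHAGE,
               source_id: Optional[str] = None) -> List[ContigRecord]:
    """Read a (possibly gzipped) multi-FASTA file into contig records.

    Record ids are the first whitespace-delimited header token; record order
    is preserved.  A record with an empty sequence is rejected with its
    position in the file.
    """
    role = Role(role)
    records: List[ContigRecord] = []
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            seq = str(rec.seq)
            if not seq:
                raise ValueError(
                    f"{path}: record {i + 1} ({rec.id!r}) has a blank sequence")
            records.append(ContigRecord(id=rec.id, sequence=seq, role=role,
                                        source_id=source_id or rec.id))
    return records


def write_fasta(records: Iterable[ContigRecord], path: Union[str, Path],
                width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


def read_pair_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV of (phage_id, host_id[, label]); missing labels default to 1."""
    df = pd.read_csv(path, sep="\t", dtype={"phage_id": str, "host_id": str})
    required = {"phage_id", "host_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pair table needs columns {sorted(required)}")
    if "label" not in df.columns:
        df["label"] = 1
    df["label"] = df["label"].astype(int)
    return df[["phage_id", "host_id", "label"]]


def write_pair_table(pairs, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [(p.phage_id, p.host_id, p.label) for p in pairs],
        columns=["phage_id", "host_id", "label"])
    df.to_csv(path, sep="\t", index=False)


def _read_two_column(path: Union[str, Path], key: str, value: str) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {key, value}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {key!r} and {value!r}")
    return dict(zip(df[key], df[value]))


def read_cluster_map(path: Union[str, Path]) -> Dict[str, str]:
    """TSV (contig_id, cluster_id) from an external clustering run."""
    return _read_two_column(path, "contig_id", "cluster_id")


def read_taxon_map(path: Union[str, Path]) -> Dict[str, str]:
    """TSV (host_id, taxon) mapping hosts to the rank used for split hygiene."""
    return _read_two_column(path, "host_id", "taxon")


def write_manifest(path: Union[str, Path], config: dict, seed: int) -> None:
    """Record the run's configuration, seed and library versions as JSON."""
    import numpy

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
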