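"""Readers and writers for the pipeline's plain-text formats.

TSV for matrices/tables, GMT for gene sets, FASTA for regions and
miRNAs, YAML for configs and manifests.  All writers emit canonical,
byte-reproducible output (fixed column order, ``%.10g`` floats, LF
line endings).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from dualrepress.expression import ExpressionMatrix
from dualrepress.enrichment import RegulatoryNetwork

FLOAT_FMT = "%.10g"


def read_expression(
    expr_path: str | Path,
    detect_path: str | Path,
    condition: Mapping[str, str],
) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    detected = pd.read_csv(detect_path, sep="\t", index_col=0).astype(bool)
    return ExpressionMatrix(
        values=values, detected=detected, condition=dict(condition)
    )


def write_expression(
    matrix: ExpressionMatrix, expr_path: str | Path, detect_path: str | Path
) -> None:
    matrix.values.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    matrix.detected.astype(int).to_csv(detect_path, sep="\t")


def read_network(path: str | Path) -> RegulatoryNetwork:
    edges = pd.read_csv(
        path, sep="\t", dtype={"regulator": str, "gene": str, "score": float}
    )
    return RegulatoryNetwork(edges=edges)


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then members, tab-separated."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = []
    for name in sorted(sets):
        members = sorted(sets[name])
        lines.append("\t".join([name, f"{len(members)} members"] + members))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if current is not None:
                records[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if current is not None:
        records[current] = "".join(chunks)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records.items():
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True, default_flow_style=False)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
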