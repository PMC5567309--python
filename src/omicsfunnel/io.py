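"""Readers and writers for the plain-text interchange formats used by the pipeline.

All tables are tab-separated with a header row; gene-set collections use the
GMT convention (set name, description, then one member symbol per column).
The GMT description column is load-bearing here — concept gene sets carry
their tier/direction metadata in it — so it is always preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

STUDY_COLUMNS = ["study_id", "gene", "direction", "fold_change", "p_value"]


def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """Read a GMT file into ``(name, description, members)`` triples.

    Blank lines are skipped; a line must have at least one member.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name, description, members = parts[0], parts[1], [m for m in parts[2:] if m]
        out.append((name, description, members))
    return out


def write_gmt(path, sets: list[tuple[str, str, list[str]]]) -> None:
    lines = ["\t".join([name, desc, *members]) for name, desc, members in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_hierarchy(path) -> dict[str, str]:
    """Read a two-column child→parent TSV (no header)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent'")
        mapping[parts[0]] = parts[1]
    return mapping


def write_hierarchy(path, mapping: dict[str, str]) -> None:
    lines = [f"{child}\t{parent}" for child, parent in sorted(mapping.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_study_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "gene": str, "direction": str})
    missing = [c for c in ("study_id", "gene", "direction") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: study table missing columns {missing}")
    return df


def write_study_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_list(path) -> set[str]:
    """One symbol per line; blank lines and ``#`` comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def write_gene_list(path, genes) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def read_ppi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in ("gene_a", "gene_b", "score") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: PPI table missing columns {missing}")
    return df


def read_expression_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str})
    missing = [c for c in ("gene", "tissue", "detected") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: expression table missing columns {missing}")
    return df


def read_annotation_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("gene", "text") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table missing columns {missing}")
    return dict(zip(df["gene"], df["text"]))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
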