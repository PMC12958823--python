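"""Readers and writers for the pipeline's plain-text formats.

Dialects: pedigree CSV (id, sire, dam, group; empty string = unknown
parent), genotype TSV (trees in rows, NA = missing), a minimal VCF
(GT-only, unphased, "./." missing), trait CSV with a JSON provenance
sidecar, relationship-matrix TSV with id headers, DAG edge-list CSV and
DOT, and YAML simulation configs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bn import AveragedNetwork, DagStructure
from .kinship import GenotypeMatrix, RelationshipMatrix
from .pedigree import Pedigree
from .preprocess import TraitTable


class IoError(ValueError):
    pass


# --- pedigree ---------------------------------------------------------------

def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    try:
        return Pedigree(table)
    except ValueError as exc:
        raise IoError(f"{path}: {exc}") from exc


# --- genotypes --------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(genotypes.dosages, index=genotypes.ids,
                         columns=genotypes.snp_ids)
    frame.to_csv(path, sep="\t", na_rep="NA", index_label="id")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    return GenotypeMatrix(
        [str(i) for i in frame.index], list(frame.columns),
        frame.to_numpy(dtype=float),
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
_GT_PARSE = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal unphased GT-only VCF; non-integer (imputed) dosages are not
    representable and raise."""
    dosages = genotypes.dosages
    observed = dosages[~np.isnan(dosages)]
    if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
        raise IoError("VCF output requires integer dosage codes 0/1/2")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.ids) + "\n")
        for k, snp in enumerate(genotypes.snp_ids):
            calls = [
                "./." if np.isnan(v) else _GT_CODE[v] for v in dosages[:, k]
            ]
            fh.write(f"1\t{k + 1}\t{snp}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    ids: list[str] = []
    snp_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                ids = fields[9:]
                continue
            if len(fields) < 10:
                raise IoError(f"{path}:{line_no}: truncated VCF record")
            snp_ids.append(fields[2])
            gt_index = fields[8].split(":").index("GT")
            try:
                rows.append([
                    _GT_PARSE[cell.split(":")[gt_index].replace("|", "/")]
                    for cell in fields[9:]
                ])
            except KeyError as exc:
                raise IoError(
                    f"{path}:{line_no}: unrecognized genotype {exc}"
                ) from exc
    if not ids:
        raise IoError(f"{path}: no #CHROM header line")
    return GenotypeMatrix(ids, snp_ids, np.array(rows, dtype=float).T)


# --- traits -----------------------------------------------------------------

def write_traits(table: TraitTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump({
            "trait_names": table.trait_names,
            "design_cols": table.design_cols,
            "provenance": table.provenance,
        }, fh, indent=1)


def read_traits(path: str | Path) -> TraitTable:
    path = Path(path)
    data = pd.read_csv(path)
    if "group" in data.columns:
        data["group"] = data["group"].astype(str)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return TraitTable(data, meta["trait_names"], meta["design_cols"],
                          meta["provenance"])
    traits = [c for c in data.columns if c not in ("id", "group", "rep", "set")]
    return TraitTable(data, traits)


# --- matrices ---------------------------------------------------------------

def write_matrix(matrix: RelationshipMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label=f"kind={matrix.kind}")


def read_matrix(path: str | Path, kind: str | None = None) -> RelationshipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    label = str(frame.index.name or "")
    inferred = label.split("=", 1)[1] if label.startswith("kind=") else "A"
    return RelationshipMatrix(
        [str(i) for i in frame.index], frame.to_numpy(dtype=float),
        kind or inferred,
    )


# --- networks ---------------------------------------------------------------

def write_dag(dag: DagStructure, path: str | Path) -> None:
    pd.DataFrame(sorted(dag.edges), columns=["from", "to"]).to_csv(path, index=False)


def read_dag(path: str | Path, nodes: tuple[str, ...] | None = None) -> DagStructure:
    frame = pd.read_csv(path)
    edges = frozenset(zip(frame["from"].astype(str), frame["to"].astype(str)))
    if nodes is None:
        nodes = tuple(sorted({v for e in edges for v in e}))
    return DagStructure(tuple(nodes), edges)


def write_dot(dag: DagStructure, path: str | Path,
              averaged: AveragedNetwork | None = None) -> None:
    lines = ["digraph traits {"]
    for node in dag.nodes:
        lines.append(f'  "{node}";')
    for p, c in sorted(dag.edges):
        label = ""
        if averaged is not None:
            arc = averaged.arcs[(averaged.arcs["from"] == p)
                                & (averaged.arcs["to"] == c)]
            if len(arc):
                s = arc["strength"].iloc[0]
                dconf = arc["direction"].iloc[0]
                label = f' [label="{s:.2f} ({dconf:.2f})"]'
        lines.append(f'  "{p}" -> "{c}"{label};')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_averaged_network(avg: AveragedNetwork, path: str | Path) -> None:
    avg.arcs.to_csv(path, index=False)


# --- configs ----------------------------------------------------------------

def write_config(config, path: str | Path) -> None:
    """YAML dump of a (nested) dataclass config; arrays become lists."""

    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if dataclasses.is_dataclass(v):
            return clean(dataclasses.asdict(v))
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(path, "w") as fh:
        yaml.safe_dump(clean(dataclasses.asdict(config)), fh, sort_keys=False)


def read_config(path: str | Path, cls):
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - fields
    if unknown:
        raise IoError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("maf_range", "design", "trait_names"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    opf = raw.get("offspring_per_family")
    if (isinstance(opf, list) and len(opf) == 2
            and raw.get("n_families", 0) != 2):
        raw["offspring_per_family"] = tuple(opf)  # a (low, high) range
    return cls(**raw)
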