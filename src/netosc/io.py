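"""File formats: TSV matrices, budding curves, GMT gene sets, flat YAML config.

All writers are deterministic: stable orders, floats at 6 significant digits
in result tables and 12 in expression matrices (so round-trips hold to 1e-9
relative).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .enrichment import GeneSetAnnotation
from .errors import FormatError
from .periodicity import PeriodPhaseEstimate
from .synthgen import BuddingCurve, TimeSeriesMatrix

logger = logging.getLogger(__name__)

_MATRIX_FMT = "%.12g"
_TABLE_FMT = "%.6g"


def fmt(x: float) -> str:
    """Result-table float formatting (6 significant digits)."""
    return _TABLE_FMT % x


def write_matrix(matrix: TimeSeriesMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join("%g" % t for t in matrix.times) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(_MATRIX_FMT % v for v in row) + "\n")


def read_matrix(path, condition: str = "WT", replicate: int = 1) -> TimeSeriesMatrix:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty file", line=1)
    header = lines[0].split("\t")
    if header[0] != "gene_id":
        raise FormatError("header must start with 'gene_id'", line=1)
    try:
        times = np.array([float(x) for x in header[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric time in header: {exc}", line=1) from None
    n_cols = len(times)
    gene_ids: list[str] = []
    seen: dict[str, int] = {}
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols + 1:
            raise FormatError(
                f"expected {n_cols + 1} fields, got {len(fields)}", line=ln)
        gid = fields[0]
        if gid in seen:
            raise FormatError(
                f"duplicate gene id {gid!r} (first seen on line {seen[gid]})", line=ln)
        seen[gid] = ln
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"non-numeric cell: {exc}", line=ln) from None
        gene_ids.append(gid)
    return TimeSeriesMatrix(gene_ids=gene_ids, times=times,
                            values=np.array(rows).reshape(len(gene_ids), n_cols),
                            condition=condition, replicate=replicate)


def write_budding_curve(curve: BuddingCurve, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("time\tfraction_budded\n")
        for t, f in zip(curve.times, curve.fraction_budded):
            fh.write("%g\t%s\n" % (t, _MATRIX_FMT % f))


def read_budding_curve(path) -> BuddingCurve:
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["time", "fraction_budded"]:
        raise FormatError("expected header 'time\\tfraction_budded'", line=1)
    ts, fs = [], []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError("expected 2 fields", line=ln)
        try:
            ts.append(float(fields[0]))
            fs.append(float(fields[1]))
        except ValueError as exc:
            raise FormatError(f"non-numeric cell: {exc}", line=ln) from None
    return BuddingCurve(times=np.array(ts), fraction_budded=np.array(fs))


def read_gene_sets(path) -> list[GeneSetAnnotation]:
    """GMT convention: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    path = Path(path)
    annotations = []
    names: dict[str, int] = {}
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"gene set {fields[0]!r} needs a description and >= 1 gene",
                    line=ln)
            name = fields[0]
            if name in names:
                raise FormatError(
                    f"duplicate gene-set name {name!r} (first on line {names[name]})",
                    line=ln)
            names[name] = ln
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"gene set {name!r} is empty", line=ln)
            annotations.append(GeneSetAnnotation(tf_name=name, targets=genes))
    return annotations


def write_gene_sets(annotations: list[GeneSetAnnotation], path,
                    description: str = "netosc") -> None:
    with Path(path).open("w") as fh:
        for ann in annotations:
            fh.write("\t".join([ann.tf_name, description] + sorted(ann.targets)) + "\n")


def order_by_peak_time(gene_ids: list[str],
                       estimates: list[PeriodPhaseEstimate]) -> list[str]:
    """Heat-map row order: peak time ascending, ties lexicographic by id.

    Genes without an estimate go to a trailing block (sorted by id) and are
    logged; the same ordering is meant to be reused for every condition.
    """
    peak = {e.gene_id: e.peak_time for e in estimates}
    called = sorted((g for g in gene_ids if g in peak), key=lambda g: (peak[g], g))
    uncalled = sorted(g for g in gene_ids if g not in peak)
    if uncalled:
        logger.info("order_by_peak_time: %d genes lack estimates; placed last",
                    len(uncalled))
    return called + uncalled


# ---------------------------------------------------------------------------
# flat YAML config
# ---------------------------------------------------------------------------

def load_flat_config(path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError("config must be a flat key: value mapping", line=1)
    return data


def save_flat_config(config: dict, path) -> None:
    with Path(path).open("w") as fh:
        for key in sorted(config):
            yaml.safe_dump({key: config[key]}, fh, default_flow_style=False)
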