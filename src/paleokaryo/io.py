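"""Readers and writers for the workbench's file formats.

Native tabular dialect: TSV with a header line and ``#`` comment lines,
tab-separated, no quoting.  Hit tables use the 12-column tabular (BLAST
outfmt-6) dialect without a header.  BED intervals are 0-based half-open;
GFF3 features are 1-based closed and converted at the boundary.  All
writers emit files their own readers parse back to equal in-memory
values.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import Gene, GenomeMap
from .simulate import HIT_COLUMNS

__all__ = [
    "ParseError",
    "read_gene_map",
    "write_gene_map",
    "read_hit_table",
    "write_hit_table",
    "read_trees",
    "write_trees",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_expression",
    "write_expression",
    "write_json_summary",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = str(path), line_no


# ---------------------------------------------------------------------------
# gene maps
# ---------------------------------------------------------------------------

_GENE_MAP_COLUMNS = ["species", "chromosome", "gene_id", "family_id"]


def write_gene_map(g: GenomeMap, path, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("\t".join(_GENE_MAP_COLUMNS) + "\n")
        for gene in g:
            fh.write(
                f"{gene.species}\t{gene.chromosome}\t{gene.gene_id}\t{gene.family_id}\n"
            )


def read_gene_map(path, format: str = "tsv") -> GenomeMap:
    """Read a gene map from 4-column TSV or from GFF3 gene features.

    TSV requires the header ``species chromosome gene_id family_id``; GFF3
    gene features need ``ID`` attributes (``family_id`` attribute optional,
    defaulting to the ID), and genes are ordered by start coordinate.
    """
    if format == "tsv":
        return _read_gene_map_tsv(path)
    if format == "gff3":
        return _read_gene_map_gff3(path)
    raise ValueError(f"unknown gene-map format {format!r}")


def _read_gene_map_tsv(path) -> GenomeMap:
    species = None
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    header_seen = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _GENE_MAP_COLUMNS:
                    raise ParseError(
                        path, line_no,
                        f"expected header {_GENE_MAP_COLUMNS}, got {fields}",
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, got {len(fields)}")
            sp, chrom, gid, fam = fields
            if species is None:
                species = sp
            elif sp != species:
                raise ParseError(path, line_no, f"mixed species {species!r}/{sp!r}")
            if gid in seen:
                raise ParseError(path, line_no, f"duplicate gene_id {gid!r}")
            seen.add(gid)
            records.append((chrom, gid, fam))
    if species is None:
        raise ParseError(path, 0, "no data rows")
    return GenomeMap.from_records(species, records)


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


def _read_gene_map_gff3(path) -> GenomeMap:
    rows = []
    seen = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, line_no, f"expected 9 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, line_no, "non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(path, line_no, f"bad interval {start}..{end}")
            a = _parse_gff3_attributes(attrs)
            gid = a.get("ID")
            if gid is None:
                raise ParseError(path, line_no, "gene feature without ID attribute")
            if gid in seen:
                raise ParseError(path, line_no, f"duplicate gene_id {gid!r}")
            seen.add(gid)
            rows.append((seqid, start_i - 1, gid, a.get("family_id", gid)))
    if not rows:
        raise ParseError(path, 0, "no gene features")
    rows.sort(key=lambda r: (r[0], r[1]))
    species = os.path.splitext(os.path.basename(str(path)))[0]
    return GenomeMap.from_records(species, [(c, g, f) for c, _s, g, f in rows])


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_hit_table(path) -> pd.DataFrame:
    """Parse a 12-column tabular hit file, keeping the best row per pair."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    path, line_no, f"expected 12 columns, got {len(fields)}"
                )
            try:
                rows.append(
                    (
                        fields[0], fields[1], float(fields[2]), int(fields[3]),
                        int(fields[4]), int(fields[5]), int(fields[6]),
                        int(fields[7]), int(fields[8]), int(fields[9]),
                        float(fields[10]), float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, line_no, f"bad numeric field: {exc}") from None
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    n_raw = len(df)
    df = (
        df.sort_values(
            ["qseqid", "sseqid", "bitscore", "evalue"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop_duplicates(["qseqid", "sseqid"], keep="first")
        .reset_index(drop=True)
    )
    logger.info("%s: %d rows, %d after per-pair dedup", path, n_raw, len(df))
    return df


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_trees(trees: dict[str, str], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, newick in trees.items():
        (directory / f"{name}.nwk").write_text(newick + "\n")


def read_trees(directory) -> tuple[dict[str, str], dict[str, str]]:
    """Read all ``*.nwk``/``*.newick``/``*.tre`` files in a directory.

    Returns (trees, errors): unparseable files are collected into the
    error report rather than aborting the run.
    """
    import dendropy

    directory = Path(directory)
    trees: dict[str, str] = {}
    errors: dict[str, str] = {}
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix in (".nwk", ".newick", ".tre")
    )
    if not paths:
        logger.warning("%s: no tree files found", directory)
    for p in paths:
        text = p.read_text().strip()
        try:
            dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        except Exception as exc:  # noqa: BLE001 - error report, not crash
            errors[p.stem] = str(exc)
            continue
        trees[p.stem] = text
    return trees, errors


# ---------------------------------------------------------------------------
# intervals and gene models
# ---------------------------------------------------------------------------


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, line_no, "non-integer coordinates") from None
            if start < 0 or end <= start:
                raise ParseError(path, line_no, f"bad interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"feature{line_no}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_gff3_genes(gene_models: pd.DataFrame, path) -> None:
    """Write tidy gene models (0-based half-open) as GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in gene_models.itertuples(index=False):
            attrs = (
                f"ID={row.gene_id}"
                if row.feature == "gene"
                else f"Parent={row.gene_id}"
            )
            fh.write(
                f"{row.chrom}\tpaleokaryo\t{row.feature}\t{row.start + 1}\t"
                f"{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene/exon features from GFF3 into the tidy 0-based frame."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, line_no, f"expected 9 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "exon"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, line_no, "non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(path, line_no, f"bad interval {start}..{end}")
            a = _parse_gff3_attributes(attrs)
            gid = a.get("ID") or a.get("Parent")
            if gid is None:
                raise ParseError(path, line_no, "feature without ID/Parent")
            rows.append((gid, seqid, start_i - 1, end_i, strand, ftype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"]
    )


# ---------------------------------------------------------------------------
# expression and summaries
# ---------------------------------------------------------------------------


def write_expression(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
    if (m.values < 0).any():
        raise ValueError(f"{path}: negative TPM values")
    return m


def write_json_summary(summary: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
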