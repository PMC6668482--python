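"""Readers and writers for the plain-text genomics formats the pipeline uses.

All internal coordinates are 0-based half-open.  BED and bedGraph are read
natively; GFF3 (1-based, closed) is converted on read and write.  Writers
emit sorted, tab-separated, newline-terminated records, optionally preceded
by ``#`` provenance comment lines.  Malformed input lines are rejected with
their line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

from .enrichment import AnnotationSet, SignalTrack
from .simulate import ZygositySample

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_list",
    "load_annotation",
    "write_report",
    "load_config",
]


class FormatError(ValueError):
    """A malformed record in an input file (carries the line number)."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path, extra_names: Sequence[str] = ()) -> pd.DataFrame:
    """Read a BED(+) file into a frame: chrom, start, end [, name, score,
    strand, *extra_names]."""
    base = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    width = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise FormatError(f"{path}:{lineno}: inconsistent column count")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not (0 <= start < end):
            raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
        rows.append([fields[0], start, end, *fields[3:]])
    if width is None:
        width = 3 + len(extra_names)
    names = base[: min(width, 6)] + list(extra_names)
    if len(names) != width:
        raise FormatError(
            f"{path}: {width} columns but names for {len(names)} "
            f"(pass extra_names for BED+ columns)"
        )
    df = pd.DataFrame(rows, columns=names)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(frame: pd.DataFrame, path, provenance: Iterable[str] = ()) -> None:
    frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


_PART_TYPES = {
    "five_prime_UTR": "five_prime_utr",
    "three_prime_UTR": "three_prime_utr",
    "exon": "exon",
    "intron": "intron",
}


def read_gff3(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse gene models from GFF3 (via gffutils, in-memory).

    Returns (genes, gene_parts) with 0-based half-open coordinates.
    Parts (five_prime_UTR / exon / intron / three_prime_UTR) are attached
    to their gene through the Parent chain.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    genes, parts = [], []
    for gene in db.features_of_type("gene"):
        genes.append((gene.id, gene.seqid, gene.start - 1, gene.end, gene.strand))
        for child in db.children(gene.id):
            part = _PART_TYPES.get(child.featuretype)
            if part is None:
                continue
            parts.append((gene.id, part, child.seqid, child.start - 1, child.end))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    if gene_df["gene_id"].duplicated().any():
        dup = gene_df.loc[gene_df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    part_df = pd.DataFrame(parts, columns=["gene_id", "part", "chrom", "start", "end"])
    return gene_df, part_df


_PART_TYPES_OUT = {v: k for k, v in _PART_TYPES.items()}


def write_gff3(genes: pd.DataFrame, gene_parts: pd.DataFrame, path,
               source: str = "tedrift", provenance: Iterable[str] = ()) -> None:
    """Write gene models as GFF3 (converting to 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in provenance:
            fh.write(f"# {line}\n")
        for gene in genes.sort_values(["chrom", "start"]).itertuples(index=False):
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            parts = gene_parts[gene_parts["gene_id"] == gene.gene_id]
            for i, part in enumerate(parts.sort_values("start").itertuples(index=False), 1):
                ptype = _PART_TYPES_OUT[part.part]
                fh.write(
                    f"{part.chrom}\t{source}\t{ptype}\t{part.start + 1}\t{part.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.{ptype}.{i};Parent={gene.gene_id}\n"
                )


def read_bedgraph(path) -> SignalTrack:
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed bedGraph record") from exc
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return SignalTrack(frame)


def write_bedgraph(track: SignalTrack, path, provenance: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        for row in track.intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_counts_tsv(path) -> ZygositySample:
    """Read a per-line zygosity sample: line_id <TAB> n_hom <TAB> n_het."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"line_id", "n_hom", "n_het"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return ZygositySample(
        df["n_hom"].to_numpy(np.int64),
        df["n_het"].to_numpy(np.int64),
        tuple(df["line_id"].astype(str)),
    )


def write_counts_tsv(sample: ZygositySample, path, provenance: Iterable[str] = ()) -> None:
    ids = sample.line_ids or tuple(f"line{i + 1}" for i in range(len(sample)))
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("line_id\tn_hom\tn_het\n")
        for lid, h, t in zip(ids, sample.n_hom, sample.n_het):
            fh.write(f"{lid}\t{h}\t{t}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: chrom sizes need 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_gene_list(path) -> set[str]:
    return {line for _, line in _data_lines(path)}


def load_annotation(
    gff3_path,
    chrom_sizes_path,
    states_bed=None,
    dyads_bed=None,
    mask_bed=None,
    essential_genes=None,
) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from its on-disk pieces."""
    genes, parts = read_gff3(gff3_path)
    sizes = read_chrom_sizes(chrom_sizes_path)
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    states = read_bed(states_bed) if states_bed else empty.assign(state=[])
    if states_bed:
        if "name" not in states.columns:
            raise FormatError(f"{states_bed}: state BED needs a name column (state 1-9)")
        states = states.rename(columns={"name": "state"})
        states["state"] = states["state"].astype(int)
        states = states[["chrom", "start", "end", "state"]]
    if dyads_bed:
        dy = read_bed(dyads_bed)
        dyads = pd.DataFrame({"chrom": dy["chrom"], "pos": (dy["start"] + dy["end"]) // 2})
    else:
        dyads = pd.DataFrame(columns=["chrom", "pos"])
    mask = read_bed(mask_bed)[["chrom", "start", "end"]] if mask_bed else empty
    genes = genes.copy()
    essential = read_gene_list(essential_genes) if essential_genes else set()
    genes["essential"] = genes["gene_id"].isin(essential)
    return AnnotationSet(
        chrom_sizes=sizes, genes=genes, gene_parts=parts,
        states=states, dyads=dyads, mask=mask,
    )


def write_report(frame: pd.DataFrame, path, provenance: Iterable[str] = ()) -> None:
    """Write an analysis report as TSV with ``#`` provenance header lines."""
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
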