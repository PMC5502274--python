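"""Readers and writers for every on-disk format the pipeline touches.

One tabular dialect only: tab-separated values with '.' decimals.
Readers validate at the boundary and reject rather than repair; error
messages carry file coordinates where possible.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from berrynet.datatypes import (
    CoResponseNetwork,
    DETable,
    ExpressionMatrix,
    MetaboliteTable,
    MotifSet,
    PromoterSet,
    ValidationError,
)


def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no features (empty file)") from None
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no features")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no samples")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"{path}: non-numeric {what} value at row {df.index[i]!r} "
                f"(line {i + 2}), column {col!r} (column {j + 2})"
            )
        out[col] = converted
    out.index.name = None
    out.columns.name = None
    return out


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValidationError(f"{path}: sample metadata must have a sample_id column")
    meta = meta.set_index("sample_id")
    for col in ("stage_daa", "replicate"):
        if col in meta.columns:
            try:
                meta[col] = meta[col].astype(int)
            except ValueError as exc:
                raise ValidationError(f"{path}: non-integer {col}: {exc}") from None
    return meta


def read_expression(
    path: str | Path, meta_path: str | Path, mode: str = "vst"
) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids) plus its sample-metadata TSV."""
    values = _read_tsv_matrix(path, "expression")
    meta = read_sample_meta(meta_path)
    if mode == "counts":
        arr = values.to_numpy()
        off = np.argwhere((arr < 0) | (arr != np.round(arr)))
        if off.size:
            r, c = off[0]
            raise ValidationError(
                f"{path}: counts mode requires nonnegative integers; cell at row "
                f"{values.index[r]!r} (line {r + 2}), column {values.columns[c]!r}"
            )
        values = values.astype(int)
    return ExpressionMatrix(values, meta, mode=mode)


def write_expression(
    x: ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    x.values.to_csv(path, sep="\t", index_label="feature_id")
    if meta_path is not None:
        x.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_metabolites(
    path: str | Path,
    meta_path: str | Path,
    classes_path: str | Path | None = None,
) -> MetaboliteTable:
    values = _read_tsv_matrix(path, "concentration")
    meta = read_sample_meta(meta_path)
    classes = None
    if classes_path is not None:
        cdf = pd.read_csv(classes_path, sep="\t", dtype=str)
        if not {"metabolite_id", "class"} <= set(cdf.columns):
            raise ValidationError(
                f"{classes_path}: expected columns metabolite_id and class"
            )
        classes = cdf.set_index("metabolite_id")["class"]
    return MetaboliteTable(values, meta, classes=classes)


def write_metabolites(
    m: MetaboliteTable,
    path: str | Path,
    meta_path: str | Path | None = None,
    classes_path: str | Path | None = None,
) -> None:
    m.values.to_csv(path, sep="\t", index_label="metabolite_id")
    if meta_path is not None:
        m.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    if classes_path is not None:
        m.classes.rename("class").to_csv(classes_path, sep="\t",
                                         index_label="metabolite_id")


def read_de_table(path: str | Path) -> DETable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "stage_daa", "log2fc", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: DE table lacks columns {missing}")
    if "direction" not in df.columns:
        df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    return DETable(df)


def write_de_table(de: DETable, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", index=False)


def read_promoters(path: str | Path, nominal_length: int = 1000) -> PromoterSet:
    """Read promoters from FASTA; record id = first whitespace token."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValidationError(f"{path}: no FASTA records")
    return PromoterSet(seqs, nominal_length=nominal_length)


def write_promoters(p: PromoterSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="")
        for gid, seq in p.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_motifs(path: str | Path) -> MotifSet:
    """One motif per line; optional tab-separated label; '#' comments."""
    path = Path(path)
    motifs: list[str] = []
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                motif = parts[0]
                motifs.append(motif)
                if len(parts) > 1 and parts[1].strip():
                    labels[motif] = parts[1].strip()
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    try:
        return MotifSet(motifs, labels)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_motifs(m: MotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for motif in m:
            label = m.label(motif)
            fh.write(f"{motif}\t{label}\n" if label else f"{motif}\n")


def write_network(
    net: CoResponseNetwork, fmt: str, path: str | Path
) -> list[Path]:
    """Export a network as SIF (+ node/edge attribute sidecars) or GraphML.

    SIF lines are ``source<TAB>edge_kind<TAB>target``; attributes go to
    ``<stem>.nodes.tsv`` and ``<stem>.edges.tsv`` next to the SIF file.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for _, row in net.edge_table().iterrows():
                fh.write(f"{row['source']}\t{row['edge_kind']}\t{row['target']}\n")
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        net.node_table().to_csv(nodes_path, sep="\t", index=False)
        net.edge_table().to_csv(edges_path, sep="\t", index=False)
        return [path, nodes_path, edges_path]
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
        return [path]
    raise ValidationError(f"unknown network format {fmt!r}")


def read_network_graphml(path: str | Path) -> CoResponseNetwork:
    g = nx.read_graphml(str(path))
    net = CoResponseNetwork()
    for n, attrs in g.nodes(data=True):
        net.add_node(str(n), attrs.get("kind", "structural_gene"),
                     attrs.get("module_id", ""), attrs.get("annotation", ""))
    for a, b, attrs in g.edges(data=True):
        net.add_edge(str(a), str(b), float(attrs["pcc"]), float(attrs["p_emp"]),
                     attrs["edge_kind"])
    return net
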