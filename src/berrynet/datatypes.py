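"""Core data model shared by the whole pipeline.

All tabular containers wrap pandas objects; validation happens at
construction so downstream code can assume well-formed inputs. Readers
and writers for these types live in :mod:`berrynet.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

TREATMENTS = ("CT", "WD")

#: IUPAC nucleotide codes mapped to the set of concrete bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (uppercase)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Malformed input rejected at a package boundary."""


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} id: {dup!r}")


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate per-sample metadata (stage_daa, treatment, replicate).

    The index must hold unique sample ids; treatment values must be CT/WD.
    """
    required = {"stage_daa", "treatment", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"sample metadata lacks columns: {sorted(missing)}")
    _check_unique(meta.index, "sample")
    bad = set(meta["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatment label(s): {sorted(bad)}")
    meta = meta.copy()
    meta["stage_daa"] = meta["stage_daa"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta


@dataclass
class ExpressionMatrix:
    """A features x samples numeric table with sample metadata.

    ``values`` rows are features, columns are samples (matching the
    on-disk TSV layout). ``mode`` is "counts" (nonnegative integers) or
    "vst" (any finite reals).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    mode: str = "vst"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "vst"):
            raise ValidationError(f"unknown expression mode {self.mode!r}")
        self.values = self.values.rename_axis(index=None, columns=None)
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        self.sample_meta = validate_sample_meta(self.sample_meta)
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(
                f"samples present in data but absent from metadata: {missing}"
            )
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.mode == "counts":
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere((arr < 0) | (arr != np.round(arr)))[0]
                raise ValidationError(
                    f"counts mode requires nonnegative integers; offending cell at "
                    f"feature {self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[int]:
        """Sorted unique stages (DAA)."""
        return sorted(self.sample_meta["stage_daa"].unique())

    def samples_for(self, stage: int, treatment: str) -> list[str]:
        m = self.sample_meta
        sel = m[(m["stage_daa"] == stage) & (m["treatment"] == treatment)]
        return list(sel.index)


@dataclass
class MetaboliteTable:
    """Per-sample metabolite concentrations with optional class labels."""

    values: pd.DataFrame  # metabolites x samples
    sample_meta: pd.DataFrame
    classes: pd.Series | None = None  # metabolite id -> class label

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index=None, columns=None)
        _check_unique(self.values.index, "metabolite")
        _check_unique(self.values.columns, "sample")
        self.sample_meta = validate_sample_meta(self.sample_meta)
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(
                f"samples present in data but absent from metadata: {missing}"
            )
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValidationError("metabolite concentrations must be finite and >= 0")
        if self.classes is None:
            self.classes = pd.Series("unclassified", index=self.values.index)
        else:
            self.classes = self.classes.reindex(self.values.index).fillna("unclassified")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[int]:
        return sorted(self.sample_meta["stage_daa"].unique())

    def samples_for(self, stage: int, treatment: str) -> list[str]:
        m = self.sample_meta
        sel = m[(m["stage_daa"] == stage) & (m["treatment"] == treatment)]
        return list(sel.index)


@dataclass
class DETable:
    """Differential-expression calls consumed (never computed) by the pipeline."""

    table: pd.DataFrame  # columns: gene_id, stage_daa, log2fc, padj, direction

    def __post_init__(self) -> None:
        required = ["gene_id", "stage_daa", "log2fc", "padj", "direction"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"DE table lacks columns: {missing}")
        t = self.table
        if t.duplicated(["gene_id", "stage_daa"]).any():
            dup = t[t.duplicated(["gene_id", "stage_daa"])].iloc[0]
            raise ValidationError(
                f"duplicate (gene, stage) row: ({dup['gene_id']!r}, {dup['stage_daa']})"
            )
        if ((t["padj"] < 0) | (t["padj"] > 1)).any():
            bad = t[(t["padj"] < 0) | (t["padj"] > 1)].iloc[0]
            raise ValidationError(
                f"padj outside [0, 1] for gene {bad['gene_id']!r} at stage {bad['stage_daa']}"
            )
        expected = np.where(t["log2fc"] >= 0, "up", "down")
        mismatch = (t["direction"] != expected) & (t["log2fc"] != 0)
        if mismatch.any():
            bad = t[mismatch].iloc[0]
            raise ValidationError(
                f"direction {bad['direction']!r} inconsistent with log2fc "
                f"{bad['log2fc']} for gene {bad['gene_id']!r}"
            )

    def genes_at(self, stage: int, direction: str | None = None) -> set[str]:
        t = self.table[self.table["stage_daa"] == stage]
        if direction is not None:
            t = t[t["direction"] == direction]
        return set(t["gene_id"])

    @property
    def stages(self) -> list[int]:
        return sorted(self.table["stage_daa"].unique())

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])


@dataclass
class PromoterSet:
    """gene id -> uppercase promoter sequence over {A,C,G,T,N}."""

    sequences: dict[str, str]
    nominal_length: int = 1000

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for gid, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty promoter sequence for gene {gid!r}")
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise ValidationError(
                    f"invalid character {sorted(bad)[0]!r} in promoter of gene {gid!r}"
                )
            self.sequences[gid] = seq
        short = [g for g, s in self.sequences.items() if len(s) < self.nominal_length]
        if short:
            warnings.warn(
                f"{len(short)} promoter(s) shorter than the nominal "
                f"{self.nominal_length} bp (e.g. {short[0]!r}); accepted as-is",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


def validate_iupac(motif: str) -> str:
    """Uppercase and validate an IUPAC 6-8-mer; returns the cleaned motif."""
    motif = motif.strip().upper()
    for ch in motif:
        if ch not in IUPAC_CODES:
            raise ValidationError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
    if not 6 <= len(motif) <= 8:
        raise ValidationError(
            f"motif {motif!r} has length {len(motif)}; expected 6-8"
        )
    return motif


@dataclass
class MotifSet:
    """Catalog of degenerate promoter elements (IUPAC 6-8-mers)."""

    motifs: list[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = [validate_iupac(m) for m in self.motifs]
        _check_unique(cleaned, "motif")
        self.motifs = cleaned
        self.labels = {validate_iupac(k): v for k, v in self.labels.items()}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def label(self, motif: str) -> str:
        return self.labels.get(motif, "")


NODE_KINDS = ("structural_gene", "TF", "metabolite")
EDGE_KINDS = ("gene-gene", "gene-metabolite")


@dataclass
class CoResponseNetwork:
    """Undirected gene/TF/metabolite association network.

    Backed by :class:`networkx.Graph`; node attributes ``kind``,
    ``module_id``, ``annotation``; edge attributes ``pcc``, ``p_emp``,
    ``edge_kind``. Edges are stored once with canonical (sorted) node
    order; self-edges are rejected.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id: str, kind: str, module_id: str = "",
                 annotation: str = "") -> None:
        if kind not in NODE_KINDS:
            raise ValidationError(f"unknown node kind {kind!r}")
        self.graph.add_node(node_id, kind=kind, module_id=module_id,
                            annotation=annotation)

    def add_edge(self, a: str, b: str, pcc: float, p_emp: float,
                 edge_kind: str) -> None:
        if a == b:
            raise ValidationError(f"self-edge on node {a!r}")
        for n in (a, b):
            if n not in self.graph:
                raise ValidationError(f"edge references unknown node {n!r}")
        if edge_kind not in EDGE_KINDS:
            raise ValidationError(f"unknown edge kind {edge_kind!r}")
        if not -1.0 <= pcc <= 1.0:
            raise ValidationError(f"pcc {pcc} outside [-1, 1]")
        if not 0.0 < p_emp <= 1.0:
            raise ValidationError(f"p_emp {p_emp} outside (0, 1]")
        a, b = sorted((a, b))
        self.graph.add_edge(a, b, pcc=float(pcc), p_emp=float(p_emp),
                            edge_kind=edge_kind)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"id": n, **attrs}
            for n, attrs in sorted(self.graph.nodes(data=True))
        ]
        cols = ["id", "kind", "module_id", "annotation"]
        return pd.DataFrame(rows, columns=cols)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b, **attrs}
            for a, b, attrs in sorted(self.graph.edges(data=True))
        ]
        cols = ["source", "target", "edge_kind", "pcc", "p_emp"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class ResponseProfiles:
    """Per-feature log2(WD/CT) vectors across stages, plus significance.

    ``log2fc`` is features x stages; ``significance`` (optional) holds
    per-(feature, stage) p-values or adjusted-p flags on the same axes.
    """

    log2fc: pd.DataFrame
    significance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.log2fc.index, "feature")
        if not np.isfinite(self.log2fc.to_numpy(dtype=float)).all():
            raise ValidationError("log2fc profiles must be finite")
        if self.significance is not None:
            if list(self.significance.index) != list(self.log2fc.index) or list(
                self.significance.columns
            ) != list(self.log2fc.columns):
                raise ValidationError("significance axes must match log2fc axes")

    @property
    def stages(self) -> list[int]:
        return [int(c) for c in self.log2fc.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.log2fc.index)


@dataclass
class NetworkParams:
    """WGCNA-style network construction parameters."""

    power: float = 6.0
    network_type: str = "unsigned"
    min_module_size: int = 20
    cut_height: float | str = 0.99
    merge_cut: float = 0.25
    pam_stage: bool = True

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ConfigurationError("power must be positive")
        if self.network_type not in ("unsigned", "signed"):
            raise ConfigurationError(f"unknown network type {self.network_type!r}")
        if self.min_module_size < 1:
            raise ConfigurationError("min_module_size must be >= 1")
        if isinstance(self.cut_height, str):
            if self.cut_height != "dynamic":
                raise ConfigurationError(
                    f"cut_height must be a real in (0, 1] or 'dynamic', "
                    f"got {self.cut_height!r}"
                )
        elif not 0 < self.cut_height <= 1:
            raise ConfigurationError("cut_height must lie in (0, 1]")
        if not 0 <= self.merge_cut <= 1:
            raise ConfigurationError("merge_cut must lie in [0, 1]")


@dataclass
class ModuleAssignment:
    """feature -> module label, with per-module eigengenes.

    ``labels`` maps every feature to a module id or "unassigned".
    ``eigengenes`` is modules x observation axis (samples or stages);
    ``var_explained`` maps module id -> fraction of variance captured
    by the eigengene.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    var_explained: pd.Series

    UNASSIGNED = "unassigned"

    def __post_init__(self) -> None:
        mods = set(self.labels.unique()) - {self.UNASSIGNED}
        missing = mods - set(self.eigengenes.index)
        if missing:
            raise ValidationError(f"modules without eigengene: {sorted(missing)}")
        bad = self.var_explained[(self.var_explained < 0) | (self.var_explained > 1)]
        if len(bad):
            raise ValidationError(
                f"var_explained outside [0, 1] for module {bad.index[0]!r}"
            )

    @property
    def module_ids(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, module_id: str) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != self.UNASSIGNED].value_counts()


@dataclass
class ThresholdPolicy:
    """Edge-screening thresholds for co-response networks.

    Defaults follow the convention of requiring a strong correlation
    (PCC > 0.8) supported by a permutation p-value below 0.01 from
    1,000 label permutations.
    """

    pcc_min: float = 0.8
    p_emp_max: float = 0.01
    n_perm: int = 1000
    use_abs_for_edges: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.pcc_min < 1:
            raise ConfigurationError("pcc_min must lie in (0, 1)")
        if not 0 < self.p_emp_max <= 1:
            raise ConfigurationError("p_emp_max must lie in (0, 1]")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")

    def passes(self, pcc: float, p_emp: float) -> bool:
        stat = abs(pcc) if self.use_abs_for_edges else pcc
        return stat > self.pcc_min and p_emp < self.p_emp_max
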