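"""Synthetic input stack with planted ground truth.

Emulates the statistical structure of a two-treatment (well-watered CT
vs water-deficit WD) fruit-development study: negative-binomial RNA-seq
counts over stages x treatments x replicates with planted co-response
modules, metabolite concentration profiles correlated with chosen
modules, and promoter sequences with degenerate motifs inserted at
elevated frequency in chosen modules. Every output is a deterministic
function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from berrynet.datatypes import (
    ConfigurationError,
    DETable,
    ExpressionMatrix,
    IUPAC_CODES,
    MetaboliteTable,
    MotifSet,
    PromoterSet,
    validate_iupac,
)

#: Default 5-stage log2(WD/CT) response shapes. Under an unsigned
#: co-expression network only profile shape up to sign is identifiable,
#: so the defaults are three weakly collinear shapes: induction through
#: ripening, a transient peak at the onset of ripening, and a
#: harvest-specific spike. Values within each pattern are deliberately
#: all distinct: exactly tied stage means would give the profiles a
#: permutation symmetry that no real measurement has, putting an
#: artificial floor under downstream permutation p-values.
DEFAULT_PATTERNS = {
    "late_up": (-0.4, 0.2, 1.0, 1.7, 2.3),
    "veraison_peak": (-0.5, 1.3, 2.2, 0.8, 0.1),
    "harvest_spike": (0.6, -0.2, 0.2, -0.6, 2.0),
}

#: Sampling stages in days after anthesis for the default 5-stage design.
DEFAULT_STAGES = (26, 53, 67, 81, 106)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-response module."""

    module_id: str
    size: int
    response_pattern: tuple[float, ...]
    within_module_noise_sd: float = 0.25


@dataclass(frozen=True)
class MetaboliteLink:
    """A planted metabolite-module co-response."""

    metabolite_id: str
    module_id: str
    link_strength: float
    metabolite_class: str = "unclassified"


@dataclass(frozen=True)
class MotifPlant:
    """A motif inserted preferentially into one module's promoters."""

    motif: str
    module_id: str
    carrier_fraction: float
    background_fraction: float


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset.

    The default design mirrors a two-treatment field experiment sampled
    at five developmental stages with three biological replicates per
    treatment and stage.
    """

    n_genes: int = 1000
    n_metabolites: int = 30
    n_stages: int = 5
    n_reps: int = 3
    module_spec: list[ModuleSpec] = field(default_factory=list)
    metabolite_links: list[MetaboliteLink] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    extra_motifs: list[str] = field(default_factory=list)
    promoter_length: int = 1000
    gc_content: float = 0.35
    nb_dispersion: float = 0.1
    baseline_log_mean_range: tuple[float, float] = (3.0, 10.0)
    stages_daa: tuple[int, ...] | None = None
    metabolite_rep_noise_sd: float = 0.15
    metabolite_profile_noise_sd: float = 1.0
    de_lfc_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_metabolites < 0:
            raise ConfigurationError("n_genes must be >= 1 and n_metabolites >= 0")
        if self.n_stages < 1 or self.n_reps < 1:
            raise ConfigurationError("n_stages and n_reps must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0 < self.gc_content < 1:
            raise ConfigurationError("gc_content must lie in (0, 1)")
        if self.promoter_length < 1:
            raise ConfigurationError("promoter_length must be positive")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log_mean_range must be ordered")
        total = sum(m.size for m in self.module_spec)
        if total > self.n_genes:
            raise ConfigurationError(
                f"sum of module sizes ({total}) exceeds n_genes ({self.n_genes})"
            )
        seen: set[str] = set()
        for m in self.module_spec:
            if m.module_id in seen:
                raise ConfigurationError(f"duplicate module id {m.module_id!r}")
            seen.add(m.module_id)
            if m.size < 1:
                raise ConfigurationError(f"module {m.module_id!r} has size < 1")
            if len(m.response_pattern) != self.n_stages:
                raise ConfigurationError(
                    f"response_pattern of module {m.module_id!r} has length "
                    f"{len(m.response_pattern)}; expected n_stages={self.n_stages}"
                )
            if m.within_module_noise_sd < 0:
                raise ConfigurationError(
                    f"within_module_noise_sd of module {m.module_id!r} is negative"
                )
        for link in self.metabolite_links:
            if link.module_id not in seen:
                raise ConfigurationError(
                    f"metabolite link references unknown module {link.module_id!r}"
                )
            if not 0 <= link.link_strength <= 1:
                raise ConfigurationError(
                    f"link_strength for {link.metabolite_id!r} outside [0, 1]"
                )
        for plant in self.motif_plants:
            motif = validate_iupac(plant.motif)
            if plant.module_id not in seen:
                raise ConfigurationError(
                    f"motif plant references unknown module {plant.module_id!r}"
                )
            if not 0 <= plant.background_fraction <= plant.carrier_fraction <= 1:
                raise ConfigurationError(
                    f"motif {motif!r}: carrier_fraction must be >= "
                    "background_fraction and both in [0, 1]"
                )
            if len(motif) > self.promoter_length:
                raise ConfigurationError(
                    f"motif {motif!r} (length {len(motif)}) does not fit in a "
                    f"{self.promoter_length} bp promoter"
                )
        if self.stages_daa is not None and len(self.stages_daa) != self.n_stages:
            raise ConfigurationError("stages_daa must list n_stages values")

    @property
    def stage_values(self) -> tuple[int, ...]:
        if self.stages_daa is not None:
            return tuple(self.stages_daa)
        if self.n_stages == len(DEFAULT_STAGES):
            return DEFAULT_STAGES
        return tuple(range(1, self.n_stages + 1))

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"gene{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met{i:03d}" for i in range(1, self.n_metabolites + 1)]


@dataclass
class GroundTruth:
    """Planted structure behind one simulated dataset."""

    gene_module: pd.Series  # gene -> module id or "none"
    metabolite_module: pd.Series  # metabolite -> module id or "none"
    motif_module: pd.Series  # motif -> module id
    planted_log2fc: pd.DataFrame  # genes x stages, pattern means
    realized_log2fc: pd.DataFrame  # genes x stages, pattern + gene noise

    NONE = "none"

    def module_members(self, module_id: str) -> list[str]:
        return list(self.gene_module.index[self.gene_module == module_id])

    def module_response_profiles(self) -> pd.DataFrame:
        """Mean planted log2FC profile per module (modules x stages)."""
        mask = self.gene_module != self.NONE
        grouped = self.planted_log2fc[mask].groupby(self.gene_module[mask])
        return grouped.mean()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_module.rename("module_id").to_csv(
            outdir / "gene_module.tsv", sep="\t", index_label="gene_id"
        )
        self.metabolite_module.rename("module_id").to_csv(
            outdir / "metabolite_module.tsv", sep="\t", index_label="metabolite_id"
        )
        self.motif_module.rename("module_id").to_csv(
            outdir / "motif_module.tsv", sep="\t", index_label="motif"
        )
        self.planted_log2fc.to_csv(
            outdir / "planted_log2fc.tsv", sep="\t", index_label="gene_id"
        )
        self.realized_log2fc.to_csv(
            outdir / "realized_log2fc.tsv", sep="\t", index_label="gene_id"
        )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The bundled demo scenario: three planted modules of 100 genes in a
    1,000-gene universe, three linked metabolites per module, and one
    planted drought-signalling motif per module."""
    patterns = list(DEFAULT_PATTERNS.items())
    module_spec = [
        ModuleSpec(f"M{i + 1}", 100, tuple(p), 0.25)
        for i, (_, p) in enumerate(patterns)
    ]
    links = []
    classes = ["anthocyanin", "amino_acid", "volatile"]
    for i, mod in enumerate(module_spec):
        for j in range(3):
            links.append(
                MetaboliteLink(f"met{3 * i + j + 1:03d}", mod.module_id, 0.9,
                               classes[i])
            )
    plants = [
        MotifPlant("ACGTGKC", "M1", 0.6, 0.05),
        MotifPlant("RCCGACA", "M2", 0.6, 0.05),
        MotifPlant("CATGTG", "M3", 0.6, 0.05),
    ]
    cfg = dict(
        module_spec=module_spec,
        metabolite_links=links,
        motif_plants=plants,
        extra_motifs=["CACGTG", "TGTCGG"],
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _sample_meta(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for stage in cfg.stage_values:
        for trt in ("CT", "WD"):
            for rep in range(1, cfg.n_reps + 1):
                rows.append(
                    {
                        "sample_id": f"{trt}_{stage}_r{rep}",
                        "stage_daa": stage,
                        "treatment": trt,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stream]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mu + alpha * mu^2."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes with any zero count excluded
    from the geometric-mean reference)."""
    arr = counts.to_numpy(dtype=float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ConfigurationError("size factors undefined: every gene has a zero count")
    ref = np.exp(np.log(arr[nonzero]).mean(axis=1))
    sf = np.median(arr[nonzero] / ref[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate the counts table, its log2-normalized companion, and truth.

    CT means are constant across stages; WD means are CT means scaled by
    2 ** (pattern + gene-level N(0, noise_sd)) for module genes and equal
    to CT means for null genes. Counts are negative binomial with global
    dispersion alpha (variance mu + alpha mu^2). The variance-stabilized
    stand-in is log2(count / size_factor + 1) with median-of-ratios size
    factors.
    """
    genes = cfg.gene_ids
    stages = list(cfg.stage_values)
    meta = _sample_meta(cfg)

    # module membership: first genes in config order, remainder null
    labels = pd.Series(GroundTruth.NONE, index=genes, name="module_id")
    pos = 0
    for m in cfg.module_spec:
        labels.iloc[pos : pos + m.size] = m.module_id
        pos += m.size

    planted = pd.DataFrame(0.0, index=genes, columns=stages)
    for m in cfg.module_spec:
        planted.loc[labels == m.module_id, :] = np.asarray(m.response_pattern)

    rng = _rng(cfg, stream=1)
    lo, hi = cfg.baseline_log_mean_range
    base_log2 = rng.uniform(lo, hi, size=cfg.n_genes)
    ct_mean = 2.0 ** base_log2

    realized = planted.copy()
    for m in cfg.module_spec:
        idx = labels == m.module_id
        if m.within_module_noise_sd > 0:
            noise = rng.normal(0.0, m.within_module_noise_sd, size=(idx.sum(), len(stages)))
            realized.loc[idx, :] += noise

    counts = pd.DataFrame(0, index=genes, columns=meta.index, dtype=int)
    for s_i, stage in enumerate(stages):
        wd_mean = ct_mean * 2.0 ** realized.iloc[:, s_i].to_numpy()
        for trt, mu in (("CT", ct_mean), ("WD", wd_mean)):
            for rep in range(1, cfg.n_reps + 1):
                col = f"{trt}_{stage}_r{rep}"
                counts[col] = _nb_draw(rng, mu, cfg.nb_dispersion)

    sf = size_factors(counts)
    vst_like = np.log2(counts / sf + 1.0)

    truth = GroundTruth(
        gene_module=labels,
        metabolite_module=pd.Series(dtype=object, name="module_id"),
        motif_module=pd.Series(
            {validate_iupac(p.motif): p.module_id for p in cfg.motif_plants},
            dtype=object,
            name="module_id",
        ),
        planted_log2fc=planted,
        realized_log2fc=realized,
    )
    counts_em = ExpressionMatrix(counts, meta, mode="counts")
    vst_em = ExpressionMatrix(vst_like, meta, mode="vst")
    return counts_em, vst_em, truth


def simulate_metabolites(
    cfg: SimulationConfig,
    truth: GroundTruth,
    module_profiles: pd.DataFrame | None = None,
) -> MetaboliteTable:
    """Simulate replicate-level metabolite concentrations.

    A linked metabolite's log2(WD/CT) profile is
    link_strength * (module mean response) + (1 - link_strength) * noise;
    unlinked metabolites are pure noise. Replicate concentrations are a
    per-metabolite lognormal baseline scaled by the treatment effect and
    multiplicative replicate noise, hence strictly positive.
    """
    if module_profiles is None:
        module_profiles = truth.module_response_profiles()
    for link in cfg.metabolite_links:
        if link.module_id not in module_profiles.index:
            raise ConfigurationError(
                f"metabolite link references unknown module {link.module_id!r}"
            )
    stages = list(cfg.stage_values)
    meta = _sample_meta(cfg)
    rng = _rng(cfg, stream=2)

    links = {l.metabolite_id: l for l in cfg.metabolite_links}
    met_ids = cfg.metabolite_ids
    met_module = pd.Series(GroundTruth.NONE, index=met_ids, name="module_id")
    classes = pd.Series("unclassified", index=met_ids)

    base = 10.0 ** rng.uniform(0.0, 3.0, size=len(met_ids))  # mg/kg scale
    values = pd.DataFrame(0.0, index=met_ids, columns=meta.index)
    for i, mid in enumerate(met_ids):
        noise = rng.normal(0.0, cfg.metabolite_profile_noise_sd, size=len(stages))
        link = links.get(mid)
        if link is not None:
            met_module[mid] = link.module_id
            classes[mid] = link.metabolite_class
            profile = (
                link.link_strength * module_profiles.loc[link.module_id].to_numpy()
                + (1.0 - link.link_strength) * noise
            )
        else:
            profile = noise
        for s_i, stage in enumerate(stages):
            for trt, lfc in (("CT", 0.0), ("WD", profile[s_i])):
                for rep in range(1, cfg.n_reps + 1):
                    eps = (
                        rng.normal(0.0, cfg.metabolite_rep_noise_sd)
                        if cfg.metabolite_rep_noise_sd > 0
                        else 0.0
                    )
                    values.loc[mid, f"{trt}_{stage}_r{rep}"] = (
                        base[i] * 2.0 ** (lfc + eps)
                    )
    truth.metabolite_module = met_module
    return MetaboliteTable(values, meta, classes=classes)


def _random_promoters(
    rng: np.random.Generator, n: int, length: int, gc: float
) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    draws = rng.choice(4, size=(n, length), p=probs)
    return ["".join(row) for row in bases[draws]]


def expand_motif_instance(rng: np.random.Generator, motif: str) -> str:
    """One uniformly sampled concrete expansion of an IUPAC motif."""
    return "".join(rng.choice(sorted(IUPAC_CODES[ch])) for ch in motif)


def simulate_promoters(
    cfg: SimulationConfig, truth: GroundTruth
) -> tuple[PromoterSet, MotifSet]:
    """Random promoters with motifs planted at elevated module frequency.

    Each insertion overwrites a random window with one concrete
    expansion of the motif, forward strand only; detecting the reverse
    strand is the scanner's job.
    """
    rng = _rng(cfg, stream=3)
    genes = cfg.gene_ids
    seqs = dict(zip(genes, _random_promoters(rng, len(genes), cfg.promoter_length,
                                             cfg.gc_content)))
    for plant in cfg.motif_plants:
        motif = validate_iupac(plant.motif)
        member = truth.gene_module == plant.module_id
        for gid in genes:
            frac = plant.carrier_fraction if member[gid] else plant.background_fraction
            if rng.random() >= frac:
                continue
            inst = expand_motif_instance(rng, motif)
            start = int(rng.integers(0, cfg.promoter_length - len(inst) + 1))
            s = seqs[gid]
            seqs[gid] = s[:start] + inst + s[start + len(inst):]

    motifs = list(dict.fromkeys(
        [validate_iupac(p.motif) for p in cfg.motif_plants]
        + [validate_iupac(m) for m in cfg.extra_motifs]
    ))
    return (
        PromoterSet(seqs, nominal_length=cfg.promoter_length),
        MotifSet(motifs),
    )


def synthetic_de_table(cfg: SimulationConfig, truth: GroundTruth) -> DETable:
    """Differential-expression calls derived from the planted truth.

    A (gene, stage) pair is called DE when the realized planted log2FC
    magnitude exceeds ``cfg.de_lfc_threshold``; the table emulates the
    filtered output of an upstream count-based DE test, which this
    package consumes but never computes.
    """
    rng = _rng(cfg, stream=4)
    rows = []
    realized = truth.realized_log2fc
    for gid in realized.index:
        for stage in realized.columns:
            lfc = float(realized.loc[gid, stage])
            if abs(lfc) < cfg.de_lfc_threshold:
                continue
            rows.append(
                {
                    "gene_id": gid,
                    "stage_daa": int(stage),
                    "log2fc": lfc,
                    "padj": float(rng.uniform(1e-6, 0.04)),
                    "direction": "up" if lfc >= 0 else "down",
                }
            )
    cols = ["gene_id", "stage_daa", "log2fc", "padj", "direction"]
    return DETable(pd.DataFrame(rows, columns=cols))


@dataclass
class SimulatedStudy:
    """The complete generated input stack for one configuration."""

    config: SimulationConfig
    counts: ExpressionMatrix
    vst: ExpressionMatrix
    metabolites: MetaboliteTable
    promoters: PromoterSet
    motifs: MotifSet
    de_table: DETable
    truth: GroundTruth


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage in order and bundle the results."""
    counts, vst, truth = simulate_expression(cfg)
    metabolites = simulate_metabolites(cfg, truth)
    promoters, motifs = simulate_promoters(cfg, truth)
    de_table = synthetic_de_table(cfg, truth)
    return SimulatedStudy(cfg, counts, vst, metabolites, promoters, motifs,
                          de_table, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the full input stack to ``outdir`` in the pipeline's formats."""
    from berrynet import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "vst": outdir / "vst.tsv",
        "samples": outdir / "samples.tsv",
        "metabolites": outdir / "metabolites.tsv",
        "metabolite_classes": outdir / "metabolite_classes.tsv",
        "promoters": outdir / "promoters.fasta",
        "motifs": outdir / "motifs.txt",
        "de_table": outdir / "de_table.tsv",
    }
    io.write_expression(study.counts, paths["counts"], paths["samples"])
    io.write_expression(study.vst, paths["vst"])
    io.write_metabolites(study.metabolites, paths["metabolites"],
                         classes_path=paths["metabolite_classes"])
    io.write_promoters(study.promoters, paths["promoters"])
    io.write_motifs(study.motifs, paths["motifs"])
    io.write_de_table(study.de_table, paths["de_table"])
    study.truth.write(outdir / "truth")
    return paths
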