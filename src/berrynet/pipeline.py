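"""Module-metabolite co-response screening, subnetwork assembly, and the
end-to-end orchestrated pipeline run."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from berrynet import __version__, io
from berrynet.datatypes import (
    ConfigurationError,
    CoResponseNetwork,
    ModuleAssignment,
    NetworkParams,
    ResponseProfiles,
    ThresholdPolicy,
    ValidationError,
)
from berrynet.cre import enrichment_table, module_cre_enrichment, scan_promoters
from berrynet.netmodules import find_modules
from berrynet.response import (
    cluster_response_profiles,
    de_overlap,
    log2_fold_change,
    pca_scores,
    stagewise_anova,
)
from berrynet.simulate import (
    MetaboliteLink,
    ModuleSpec,
    MotifPlant,
    SimulationConfig,
    default_config,
    simulate_study,
    write_study,
)
from berrynet.stats import empirical_pcc_pvalue, pair_seed

logger = logging.getLogger("berrynet")


def module_metabolite_coresponse(
    module_profiles: pd.DataFrame,
    metabolite_profiles: ResponseProfiles,
    policy: ThresholdPolicy | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every (module representative, metabolite) pair.

    ``module_profiles`` holds one representative response vector per
    module (eigengene or mean member log2FC) over the same stage axis as
    the metabolite profiles. Returns a table with pcc, permutation
    p-value and the policy verdict for every pair; zero-variance
    metabolite profiles are excluded with a warning (their correlation
    is undefined).
    """
    policy = policy or ThresholdPolicy()
    if list(module_profiles.columns) != list(metabolite_profiles.log2fc.columns):
        raise ValidationError(
            "module and metabolite profiles are on different stage axes: "
            f"{list(module_profiles.columns)} vs "
            f"{list(metabolite_profiles.log2fc.columns)}"
        )
    met = metabolite_profiles.log2fc
    var = met.var(axis=1, ddof=0)
    flat = list(met.index[var == 0.0])
    if flat:
        warnings.warn(
            f"{len(flat)} zero-variance metabolite profile(s) skipped",
            stacklevel=2,
        )
        met = met.drop(index=flat)
    rows = []
    for mod in module_profiles.index:
        mp = module_profiles.loc[mod].to_numpy(dtype=float)
        for mid in met.index:
            res = empirical_pcc_pvalue(
                mp,
                met.loc[mid].to_numpy(dtype=float),
                n_perm=policy.n_perm,
                seed=pair_seed(seed, str(mod), str(mid)),
                id_a=str(mod),
                id_b=str(mid),
            )
            rows.append(
                {
                    "module": mod,
                    "metabolite": mid,
                    "pcc": res.pcc,
                    "p_emp": res.p_emp,
                    "passes": policy.passes(res.pcc, res.p_emp),
                }
            )
    return pd.DataFrame(rows, columns=["module", "metabolite", "pcc", "p_emp",
                                       "passes"])


def build_subnetwork(
    gene_kinds: dict[str, str],
    metabolites: set[str],
    profiles: ResponseProfiles,
    policy: ThresholdPolicy | None = None,
    modules: ModuleAssignment | None = None,
    seed: int = 0,
) -> CoResponseNetwork:
    """Gene-gene and gene-metabolite association network under a policy.

    Every gene pair and every (gene, metabolite) pair with PCC above the
    threshold and permutation p below it becomes an edge;
    metabolite-metabolite pairs are never tested. Node attributes carry
    the kind (structural_gene / TF / metabolite) and module id.
    """
    policy = policy or ThresholdPolicy()
    wanted = set(gene_kinds) | set(metabolites)
    missing = sorted(wanted - set(profiles.feature_ids))
    if missing:
        raise ValidationError(f"no response profile for: {missing[:10]}")
    lf = profiles.log2fc
    net = CoResponseNetwork()
    genes = sorted(gene_kinds)
    mets = sorted(metabolites)
    for g in genes:
        mod = modules.labels.get(g, "") if modules is not None else ""
        net.add_node(g, gene_kinds[g], module_id=str(mod))
    for m in mets:
        net.add_node(m, "metabolite")

    def maybe_edge(a: str, b: str, kind: str) -> None:
        xa = lf.loc[a].to_numpy(dtype=float)
        xb = lf.loc[b].to_numpy(dtype=float)
        if xa.var() == 0 or xb.var() == 0:
            return
        res = empirical_pcc_pvalue(
            xa, xb, n_perm=policy.n_perm, seed=pair_seed(seed, a, b),
            id_a=a, id_b=b,
        )
        if policy.passes(res.pcc, res.p_emp):
            net.add_edge(a, b, res.pcc, res.p_emp, kind)

    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            maybe_edge(a, b, "gene-gene")
    for g in genes:
        for m in mets:
            maybe_edge(g, m, "gene-metabolite")
    return net


# --------------------------------------------------------------------------
# end-to-end pipeline

_TOP_KEYS = {"seed", "outdir", "simulate", "inputs", "respond", "modules",
             "cre", "coresponse", "network"}
_SECTION_KEYS = {
    "simulate": {
        "n_genes", "n_metabolites", "n_stages", "n_reps", "modules",
        "metabolite_links", "motif_plants", "extra_motifs", "promoter_length",
        "gc_content", "nb_dispersion", "baseline_log_mean_range", "stages_daa",
        "metabolite_rep_noise_sd", "metabolite_profile_noise_sd",
        "de_lfc_threshold", "default_scenario",
    },
    "inputs": {"counts", "vst", "samples", "metabolites", "metabolite_classes",
               "de_table", "promoters", "motifs", "gene_kinds"},
    "respond": {"pseudocount", "metabolite_pseudocount"},
    "modules": {"network_type", "min_module_size_coresponse",
                "min_module_size_development", "cut_height", "merge_cut",
                "target_r2", "candidate_powers"},
    "cre": {"strands", "fdr"},
    "coresponse": {"representative", "pcc_min", "p_emp_max", "n_perm",
                   "use_abs_for_edges"},
    "network": {"max_genes_per_module", "pcc_min", "p_emp_max", "n_perm",
                "use_abs_for_edges"},
}


def _check_config(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for section, keys in _SECTION_KEYS.items():
        sub = cfg.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigurationError(f"config section {section!r} must be a mapping")
        bad = set(sub) - keys
        if bad:
            raise ConfigurationError(
                f"unknown key(s) in config section {section!r}: {sorted(bad)}"
            )
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config needs a 'simulate' or 'inputs' section")


def _simulation_config(sim: dict, seed: int) -> SimulationConfig:
    sim = dict(sim)
    if sim.pop("default_scenario", False) and not sim:
        return default_config(seed)
    kwargs: dict = {"seed": seed}
    if "modules" in sim:
        kwargs["module_spec"] = [
            ModuleSpec(m["module_id"], int(m["size"]),
                       tuple(float(v) for v in m["response_pattern"]),
                       float(m.get("within_module_noise_sd", 0.25)))
            for m in sim.pop("modules")
        ]
    if "metabolite_links" in sim:
        kwargs["metabolite_links"] = [
            MetaboliteLink(l["metabolite_id"], l["module_id"],
                           float(l["link_strength"]),
                           l.get("metabolite_class", "unclassified"))
            for l in sim.pop("metabolite_links")
        ]
    if "motif_plants" in sim:
        kwargs["motif_plants"] = [
            MotifPlant(p["motif"], p["module_id"], float(p["carrier_fraction"]),
                       float(p["background_fraction"]))
            for p in sim.pop("motif_plants")
        ]
    for key in ("baseline_log_mean_range", "stages_daa"):
        if key in sim and sim[key] is not None:
            sim[key] = tuple(sim[key])
    kwargs.update(sim)
    return SimulationConfig(**kwargs)


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute simulate -> respond -> modules -> cre-enrich -> coresponse
    -> subnetwork -> export from one configuration.

    Re-running with the same config and seed reproduces every numeric
    output. Returns the artifact directory; a ``manifest.json`` records
    inputs, parameters, seed and package version.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _check_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "berrynet_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config, "stages": []}

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        # ------------------------------------------------ inputs
        if "simulate" in config:
            stage("simulate")
            sim_cfg = _simulation_config(config["simulate"] or
                                         {"default_scenario": True}, seed)
            study = simulate_study(sim_cfg)
            write_study(study, outdir / "inputs")
            counts, vst = study.counts, study.vst
            metabolites, promoters = study.metabolites, study.promoters
            motifs, det = study.motifs, study.de_table
            gene_kinds_path = None
        else:
            stage("load")
            paths = config["inputs"]
            counts = io.read_expression(paths["counts"], paths["samples"],
                                        mode="counts")
            vst = io.read_expression(paths["vst"], paths["samples"], mode="vst")
            metabolites = io.read_metabolites(
                paths["metabolites"], paths["samples"],
                classes_path=paths.get("metabolite_classes"))
            promoters = io.read_promoters(paths["promoters"])
            motifs = io.read_motifs(paths["motifs"])
            det = io.read_de_table(paths["de_table"])
            gene_kinds_path = paths.get("gene_kinds")

        # ------------------------------------------------ respond
        stage("respond")
        rcfg = config.get("respond") or {}
        gene_lfc = log2_fold_change(counts, rcfg.get("pseudocount"))
        met_lfc = log2_fold_change(metabolites,
                                   rcfg.get("metabolite_pseudocount"))
        anova = stagewise_anova(metabolites)
        order = cluster_response_profiles(met_lfc)
        pca = pca_scores(vst.values.T, center=True, scale=False)
        overlap = de_overlap(det)

        gene_lfc.log2fc.to_csv(outdir / "log2fc_genes.tsv", sep="\t",
                               index_label="gene_id")
        met_lfc.log2fc.to_csv(outdir / "log2fc_metabolites.tsv", sep="\t",
                              index_label="metabolite_id")
        anova.to_csv(outdir / "anova.tsv", sep="\t", index_label="metabolite_id")
        pd.Series(order.leaf_order, name="metabolite_id").to_csv(
            outdir / "cluster_order.tsv", sep="\t", index_label="rank")
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t",
                          index_label="sample_id")
        overlap.per_stage.to_csv(outdir / "de_per_stage.tsv", sep="\t")
        manifest["pca_variance_explained_pct"] = [
            round(float(v), 3) for v in pca.variance_explained_pct[:5]
        ]

        # ------------------------------------------------ modules
        stage("modules")
        mcfg = config.get("modules") or {}
        de_genes = sorted(det.genes & set(counts.feature_ids))
        if len(de_genes) < 2:
            raise ValidationError("fewer than 2 DE genes; cannot build modules")
        candidate_powers = tuple(mcfg.get("candidate_powers",
                                          tuple(range(1, 21))))
        common = dict(
            network_type=mcfg.get("network_type", "unsigned"),
            cut_height=mcfg.get("cut_height", 0.99),
            merge_cut=float(mcfg.get("merge_cut", 0.25)),
        )
        params_wd = NetworkParams(
            min_module_size=int(mcfg.get("min_module_size_coresponse", 20)),
            **common)
        params_dev = NetworkParams(
            min_module_size=int(mcfg.get("min_module_size_development", 30)),
            **common)
        target_r2 = float(mcfg.get("target_r2", 0.8))
        wd = find_modules(gene_lfc.log2fc.loc[de_genes], params_wd, prefix="WD",
                          candidate_powers=candidate_powers, target_r2=target_r2)
        dev = find_modules(vst.values.loc[de_genes], params_dev, prefix="DEV",
                           candidate_powers=candidate_powers, target_r2=target_r2)
        for name, res in (("coresponse", wd), ("development", dev)):
            res.assignment.labels.rename("module_id").to_csv(
                outdir / f"assignment_{name}.tsv", sep="\t",
                index_label="gene_id")
            res.assignment.eigengenes.to_csv(
                outdir / f"eigengenes_{name}.tsv", sep="\t",
                index_label="module_id")
        manifest["soft_power"] = {"coresponse": wd.power, "development": dev.power}
        manifest["n_modules"] = {
            "coresponse": len(wd.assignment.module_ids),
            "development": len(dev.assignment.module_ids),
        }

        # ------------------------------------------------ cre-enrich
        stage("cre-enrich")
        ccfg = config.get("cre") or {}
        strands = ccfg.get("strands", "both")
        fdr = float(ccfg.get("fdr", 0.01))
        de_prom = {g: promoters.sequences[g] for g in de_genes
                   if g in promoters.sequences}
        missing_prom = sorted(set(de_genes) - set(de_prom))
        if missing_prom:
            raise ValidationError(
                f"DE gene(s) without promoter sequence: {missing_prom[:5]}")
        match = scan_promoters(
            type(promoters)(de_prom, nominal_length=promoters.nominal_length),
            motifs, strands=strands)
        records = module_cre_enrichment(match, wd.assignment,
                                        background=set(de_prom),
                                        fdr_threshold=fdr)
        enr = enrichment_table(records, motifs)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        manifest["cre"] = {"strands": strands, "fdr_threshold": fdr,
                           "n_enriched": int(enr["enriched"].sum())}

        # ------------------------------------------------ coresponse
        stage("coresponse")
        pcfg = config.get("coresponse") or {}
        policy = ThresholdPolicy(
            pcc_min=float(pcfg.get("pcc_min", 0.8)),
            p_emp_max=float(pcfg.get("p_emp_max", 0.01)),
            n_perm=int(pcfg.get("n_perm", 1000)),
            use_abs_for_edges=bool(pcfg.get("use_abs_for_edges", False)),
        )
        representative = pcfg.get("representative", "eigengene")
        if representative == "eigengene":
            stage_eg = {}
            for mod in wd.assignment.module_ids:
                members = wd.assignment.members(mod)
                from berrynet.netmodules import module_eigengene
                stage_eg[mod], _ = module_eigengene(gene_lfc.log2fc.loc[members])
            reps = pd.DataFrame(stage_eg).T
        elif representative == "mean":
            reps = pd.concat(
                {mod: gene_lfc.log2fc.loc[wd.assignment.members(mod)].mean()
                 for mod in wd.assignment.module_ids}, axis=1).T
        else:
            raise ConfigurationError(
                f"unknown coresponse representative {representative!r}")
        reps.columns = met_lfc.log2fc.columns
        cores = module_metabolite_coresponse(reps, met_lfc, policy, seed=seed)
        cores.to_csv(outdir / "coresponse.tsv", sep="\t", index=False)

        # ------------------------------------------------ network
        stage("network")
        ncfg = config.get("network") or {}
        npolicy = ThresholdPolicy(
            pcc_min=float(ncfg.get("pcc_min", policy.pcc_min)),
            p_emp_max=float(ncfg.get("p_emp_max", policy.p_emp_max)),
            n_perm=int(ncfg.get("n_perm", policy.n_perm)),
            use_abs_for_edges=bool(ncfg.get("use_abs_for_edges",
                                            policy.use_abs_for_edges)),
        )
        cap = int(ncfg.get("max_genes_per_module", 15))
        passing = cores[cores["passes"]]
        sel_modules = sorted(set(passing["module"]))
        sel_mets = sorted(set(passing["metabolite"]))
        kinds: dict[str, str] = {}
        if gene_kinds_path := (gene_kinds_path if "inputs" in config else None):
            kt = pd.read_csv(gene_kinds_path, sep="\t")
            kinds_map = dict(zip(kt["gene_id"], kt["kind"]))
        else:
            kinds_map = {}
        for mod in sel_modules:
            members = wd.assignment.members(mod)[:cap]
            for g in members:
                kinds[g] = kinds_map.get(g, "structural_gene")
        combined = pd.concat([gene_lfc.log2fc, met_lfc.log2fc])
        profiles = ResponseProfiles(combined.loc[sorted(set(kinds) | set(sel_mets))])
        net = build_subnetwork(kinds, set(sel_mets), profiles, npolicy,
                               modules=wd.assignment, seed=seed)
        stage("export")
        io.write_network(net, "sif", outdir / "network.sif")
        io.write_network(net, "graphml", outdir / "network.graphml")
        manifest["network"] = {"n_nodes": net.n_nodes, "n_edges": net.n_edges}
        manifest["policy"] = asdict(npolicy)
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise type(exc)(
            f"pipeline stage {manifest['failed_stage']!r} failed: {exc}"
        ) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
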