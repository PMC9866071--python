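"""One-shot pipeline: run the full reproductive-mode signature battery on a
simulated fixture or a user-supplied VCF bundle, writing per-stage TSV tables
and a machine-readable JSON summary.

Stages run in dependency order (io -> diversity / structure / linkage ->
coding / sexsignal).  A single top-level seed fans out to one named
substream per stage, so toggling one stage never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import yaml

from . import coding, diversity, genio, linkage, sexsignal, structure, synthpop

log = logging.getLogger(__name__)

_STAGE_STREAM = {"simulate": 0, "diversity": 1, "structure": 2, "linkage": 3,
                 "coding": 4, "sexsignal": 5}

DEFAULT_PARAMS = {
    "n_perm_amova": 99,
    "n_perm_outlier": 200,
    "n_perm_mantel": 999,
    "n_perm_phi": 200,
    "phi_window": 100,
    "epsilon": 0.03,
    "ld_max_dist": 300_000,
    "ld_bin_width": 5_000,
    "q_threshold": 0.01,
    "rf_threshold": 0.1,
    "sfs_subset": None,          # list of sample ids, or null for all
}

_TOP_KEYS = {"seed", "output_dir", "simulate", "input", "stages", "params",
             "log_level"}
_INPUT_KEYS = {"vcf", "gff", "fasta", "pops", "coords", "go"}
_STAGE_KEYS = {"diversity", "structure", "linkage", "coding", "sexsignal"}


class ConfigError(ValueError):
    pass


def validate_config(path_or_dict) -> dict:
    """Normalize a pipeline config: reject unknown keys, fill defaults."""
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    errors = []
    for k in cfg:
        if k not in _TOP_KEYS:
            errors.append(f"unknown key: {k}")
    has_sim = "simulate" in cfg and cfg["simulate"] is not None
    has_inp = "input" in cfg and cfg["input"] is not None
    if has_sim == has_inp:
        errors.append("exactly one of 'simulate' or 'input' must be present")
    if has_inp:
        inp = cfg["input"]
        for k in inp:
            if k not in _INPUT_KEYS:
                errors.append(f"unknown key: input.{k}")
        for req in ("vcf", "pops"):
            if req not in inp:
                errors.append(f"missing key: input.{req}")
    if has_sim:
        valid = {f.name for f in dataclasses.fields(synthpop.SimConfig)}
        for k in cfg["simulate"] or {}:
            if k not in valid:
                errors.append(f"unknown key: simulate.{k}")
    stages = dict.fromkeys(_STAGE_KEYS, True)
    for k, v in (cfg.get("stages") or {}).items():
        if k not in _STAGE_KEYS:
            errors.append(f"unknown key: stages.{k}")
        else:
            stages[k] = bool(v)
    params = dict(DEFAULT_PARAMS)
    for k, v in (cfg.get("params") or {}).items():
        if k not in DEFAULT_PARAMS:
            errors.append(f"unknown key: params.{k}")
        else:
            params[k] = v
    if errors:
        raise ConfigError("; ".join(errors))
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "clonalsig_out")
    cfg["stages"] = stages
    cfg["params"] = params
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(seed), _STAGE_STREAM[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config) -> dict:
    """Run all enabled stages; returns (and writes) the summary dict."""
    cfg = validate_config(config)
    out = cfg["output_dir"]
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "effective_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh)
    seed = int(cfg["seed"])
    P = cfg["params"]
    summary = {"seed": seed}

    # --- io -----------------------------------------------------------------
    hap = genome = go_table = None
    if cfg.get("simulate") is not None:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
        sc = synthpop.SimConfig(**{k: (tuple(v) if k == "pops_per_group" else v)
                                   for k, v in sim_kwargs.items()})
        g, hap, genome, hierarchy, truth = synthpop.simulate(sc)
        synthpop.write_fixture(os.path.join(out, "fixture"), g, hap, genome,
                               hierarchy, truth)
        summary["io"] = {"source": "simulate", "n_samples": g.n_samples,
                         "n_sites": g.n_sites}
    else:
        inp = cfg["input"]
        g = genio.read_vcf(inp["vcf"])
        summary["io"] = {"source": inp["vcf"], "n_samples": g.n_samples,
                         "n_sites_raw": g.n_sites,
                         "excluded": getattr(g, "excluded", {})}
        hierarchy = genio.read_tables(inp["pops"], inp.get("coords"),
                                      samples=g.samples)
        if bool(g.phased.all()) and not g.missing_mask().any():
            hap = genio.read_phased_haplotypes(inp["vcf"])
        if inp.get("fasta") and inp.get("gff"):
            genome = genio.read_gff_cds(inp["gff"], genio.read_fasta(inp["fasta"]))
        if inp.get("go"):
            import pandas as pd
            go_table = pd.read_csv(inp["go"], sep="\t")
    res = genio.filter_sites(g)
    g = res.matrix
    summary["filter"] = {"n_input": res.n_input,
                         "removed_missing": res.n_removed_missing,
                         "removed_monomorphic": res.n_removed_monomorphic,
                         "n_retained": res.n_retained}
    if hap is not None:
        keep = g.sites.merge(hap.sites.assign(_i=np.arange(hap.n_sites)),
                             on=["contig", "pos", "ref", "alt"])["_i"].to_numpy()
        hap = hap.take_sites(keep)

    stages = cfg["stages"]
    try:
        if stages["diversity"]:
            fis = diversity.individual_fis(g)
            fis.to_csv(os.path.join(out, "fis.tsv"), sep="\t", index=False)
            pi = diversity.nucleotide_diversity(g, hierarchy, by="group")
            pi.to_csv(os.path.join(out, "pi_groups.tsv"), sep="\t", index=False)
            sfs = diversity.het_sharing_sfs(g, P["sfs_subset"])
            sfs.to_csv(os.path.join(out, "sfs.tsv"), sep="\t", index=False)
            all_het = sfs.iloc[-1]
            summary["diversity"] = {
                "mean_fis": float(fis["fis"].mean()),
                "pi_by_group": dict(zip(pi.iloc[:, 0], pi["pi"])),
                "all_het_excess": float(all_het["excess"]),
            }
        groups_df = None
        if stages["structure"]:
            st = {}
            fst_groups = structure.pairwise_fst(g, hierarchy, level="groups")
            fst_groups.to_csv(os.path.join(out, "fst_groups.tsv"), sep="\t")
            st["fst_group_pairs"] = {
                f"{a}~{b}": float(fst_groups.loc[a, b])
                for i, a in enumerate(fst_groups.index)
                for b in fst_groups.index[i + 1:]}
            fst_pops = structure.pairwise_fst(g, hierarchy, level="populations")
            fst_pops.to_csv(os.path.join(out, "fst_populations.tsv"), sep="\t")
            if hap is not None and len(hierarchy.groups()) >= 2:
                am = structure.amova(hap, hierarchy, n_perm=P["n_perm_amova"],
                                     seed=_stage_seed(seed, "structure"))
                am.to_csv(os.path.join(out, "amova.tsv"), sep="\t", index=False)
                st["amova_percent"] = dict(zip(am["source"], am["percentage"]))
            if hierarchy.coords:
                r, p = structure.mantel_ibd(fst_pops, hierarchy.coords,
                                            n_perm=P["n_perm_mantel"],
                                            seed=_stage_seed(seed, "structure"))
                st["mantel"] = {"r": r, "p": p}
            groups_df = structure.mds_genotypic_groups(g, hierarchy,
                                                       epsilon=P["epsilon"])
            groups_df.to_csv(os.path.join(out, "genotypic_groups.tsv"),
                             sep="\t", index=False)
            st["n_genotypic_groups"] = int(groups_df.attrs["n_groups"])
            scan = structure.fst_outlier_scan(
                g, hierarchy, n_perm=P["n_perm_outlier"],
                q_threshold=P["q_threshold"],
                seed=_stage_seed(seed, "structure"))
            scan.to_csv(os.path.join(out, "outlier_scan.tsv"), sep="\t",
                        index=False)
            st["n_outliers"] = int(scan["outlier"].sum())
            summary["structure"] = st
        if stages["linkage"]:
            decay = linkage.ld_decay(g, max_dist=P["ld_max_dist"],
                                     bin_width=P["ld_bin_width"])
            decay.to_csv(os.path.join(out, "ld_decay.tsv"), sep="\t", index=False)
            summary["linkage"] = linkage.summarize_ld(decay)
        if stages["coding"] and genome is not None and len(genome.cds):
            cod = {}
            deg = coding.classify_degeneracy(genome)
            deg.table.to_csv(os.path.join(out, "degeneracy.tsv"), sep="\t",
                             index=False)
            if groups_df is not None:
                reps = sorted(groups_df.loc[groups_df["representative"],
                                            "individual"])
            else:
                reps = sorted(g.samples)
            if len(reps) >= 2:
                cod.update(coding.pi0_pi4(g, reps, deg))
            if stages["structure"]:
                genes = coding.map_outliers_to_genes(scan, genome)
                genes.to_csv(os.path.join(out, "outlier_genes.tsv"), sep="\t",
                             index=False)
                cod["n_outlier_genes"] = int(
                    (genes["gene_id"] != "(unassigned)").sum())
                if go_table is not None and cod.get("n_outlier_genes"):
                    study = [x for x in genes["gene_id"] if x != "(unassigned)"]
                    enr = coding.enrichment(study, go_table)
                    enr.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t",
                               index=False)
                    cod["n_enriched_terms"] = int((enr["p"] < 0.05).sum())
            if hap is not None:
                stops = coding.premature_stop_screen(hap, genome)
                stops.to_csv(os.path.join(out, "stop_screen.tsv"), sep="\t",
                             index=False)
                cod["n_premature_stops"] = int(
                    (stops["kind"] == "premature_stop").sum())
            summary["coding"] = cod
        if stages["sexsignal"] and hap is not None:
            sx = {}
            split = sexsignal.split_haplotypes(hap)
            split.table.to_csv(os.path.join(out, "haplotype_split.tsv"),
                               sep="\t", index=False)
            if len(split.samples) >= 4:
                pair = sexsignal.meselson_test(split,
                                               rf_threshold=P["rf_threshold"])
                sexsignal.write_newick(pair.tree_a,
                                       os.path.join(out, "tree_hapA.nwk"))
                sexsignal.write_newick(pair.tree_b,
                                       os.path.join(out, "tree_hapB.nwk"))
                sx["rf_normalized"] = pair.rf_normalized
                sx["mirrored"] = bool(pair.mirrored)
            phi = sexsignal.phi_test(hap, window=P["phi_window"],
                                     n_perm=P["n_perm_phi"],
                                     seed=_stage_seed(seed, "sexsignal"))
            sx["phi"] = {"phi": phi.phi, "p_permutation": phi.p_permutation,
                         "p_normal": phi.p_normal,
                         "n_informative": phi.n_informative,
                         "status": phi.status}
            summary["sexsignal"] = sx
    except Exception as exc:
        log.error("pipeline halted: %s", exc)
        summary["error"] = str(exc)
        genio.write_json(summary, os.path.join(out, "summary.json"))
        raise
    genio.write_json(summary, os.path.join(out, "summary.json"))
    return summary
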