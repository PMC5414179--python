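"""End-to-end demo pipeline tying the stages together.

``run_pipeline`` executes, with a single seed governing every stochastic
stage: genotype/phenotype simulation (or loading, when the config points at
files), the unconditional and conditional association scans, correlated-set
extraction, label-swap binder calling, the qPCR analyses and telomere
quantification.  Each stage writes a TSV and contributes to a JSON summary;
a log records parameters and input digests so a rerun with the same config
is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd

from . import binders as bnd
from . import finemap as fm
from . import io as aio
from . import qpcr as qp
from . import simulate as sim
from . import telomere as tel
from .config import RunConfig

__all__ = ["run_pipeline"]


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def _demo_region(seed: int):
    """One causal SNP plus three proxies, retrospective 500+500 study."""
    ids = ["rs_causal", "rs_proxy1", "rs_proxy2", "rs_proxy3"]
    spec = sim.HaplotypeSpec(
        variant_ids=ids,
        allele_freqs=[0.19, 0.20, 0.22, 0.24],
        ld_targets=[("rs_causal", p, 0.7) for p in ids[1:]],
        seed=seed,
    )
    pool = sim.make_haplotype_pool(spec)
    cc = sim.CaseControlSpec(
        odds_ratios={"rs_causal": 1.5},
        mode="retrospective", n_cases=500, n_controls=500, seed=seed,
    )
    return pool, sim.simulate_case_control_study(pool, cc, cohort_multiplier=4)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    os.makedirs(config.out_dir, exist_ok=True)
    rng_seed = config.seed
    summary: dict = {"seed": rng_seed, "params": config.params.model_dump()}
    log: dict = {"package_version": _pkg_version("allelics"),
                 "config": config.model_dump(), "inputs": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # -- genotypes & association ------------------------------------------
    def geno_stage():
        if config.genotypes:
            G = aio.read_genotypes(config.genotypes, config.variants)
            log["inputs"]["genotypes"] = _digest(config.genotypes)
            pheno = aio.read_phenotypes(config.phenotypes)
            y = pheno["phenotype"].to_numpy(float)
        else:
            _, data = _demo_region(rng_seed)
            G, y = data.genotypes, data.phenotype
            aio.write_genotypes_vcf(G, os.path.join(config.out_dir, "genotypes.vcf"))
            aio.write_phenotypes(G.sample_ids, y,
                                 os.path.join(config.out_dir, "phenotypes.tsv"))
        return G, y

    G, y = stage("genotypes")(geno_stage)

    def assoc_stage():
        kept, dropped = fm.variant_qc_filter(
            G.variants, config.params.maf_min, config.params.info_min
        )
        scan = fm.association_scan(G, y)
        scan.to_csv(os.path.join(config.out_dir, "association.tsv"), sep="\t", index=False)
        condition_on = config.condition_on or [scan.loc[scan["p_value"].idxmin(), "id"]]
        cond = fm.association_scan(G, y, condition_on=condition_on)
        cond["conditioned_on"] = [",".join(c) for c in cond["conditioned_on"]]
        cond.to_csv(os.path.join(config.out_dir, "association_conditional.tsv"),
                    sep="\t", index=False)
        index = condition_on[0]
        proxies = fm.correlated_set(G, index, config.params.r2_threshold)
        return {
            "n_variants_qc_pass": int(len(kept)),
            "n_variants_qc_dropped": int(len(dropped)),
            "top_variant": str(scan.loc[scan["p_value"].idxmin(), "id"]),
            "min_p": float(scan["p_value"].min()),
            "conditioned_on": condition_on,
            "max_conditional_p_on_others": float(cond["p_value"].max()),
            "correlated_set": proxies,
        }

    summary["association"] = stage("association")(assoc_stage)

    # -- binder calling ----------------------------------------------------
    def binder_stage():
        if config.pulldown_forward and config.pulldown_reverse:
            fwd = aio.read_pulldown_run(config.pulldown_forward)
            rev = aio.read_pulldown_run(config.pulldown_reverse)
            log["inputs"]["pulldown_forward"] = _digest(config.pulldown_forward)
            truth = None
        else:
            fwd, rev, truth = sim.simulate_pulldown(
                sim.PulldownSimSpec(n_proteins=400, n_c_binders=3, seed=rng_seed + 1)
            )
            aio.write_pulldown_run(fwd, os.path.join(config.out_dir, "pulldown_fwd.tsv"))
            aio.write_pulldown_run(rev, os.path.join(config.out_dir, "pulldown_rev.tsv"))
        calls = bnd.call_binders(fwd, rev, k=config.params.iqr_k)
        calls.to_csv(os.path.join(config.out_dir, "binder_calls.tsv"), sep="\t", index=False)
        counts = calls["classification"].value_counts().to_dict()
        out = {"class_counts": {k: int(v) for k, v in counts.items()}}
        if truth is not None:
            called = set(calls.loc[calls["classification"] == "C-preferential", "protein_id"])
            planted = set(truth.loc[truth["truth"] == "C-binder", "protein_id"])
            out["c_binder_recall"] = (len(called & planted) / len(planted)) if planted else None
        return out

    summary["binders"] = stage("binders")(binder_stage)

    # -- qPCR --------------------------------------------------------------
    def qpcr_stage():
        if config.ct_table:
            ct = aio.read_ct_table(config.ct_table)
            log["inputs"]["ct_table"] = _digest(config.ct_table)
        else:
            spec = sim.QpcrSimSpec.for_expression(
                {("cellA", "scrambled"): 1.0, ("cellA", "siRNA3"): 0.4},
                ct_noise_sd=0.1, seed=rng_seed + 2,
            )
            ct = sim.simulate_qpcr(spec)
            aio.write_ct_table(ct, os.path.join(config.out_dir, "ct_table.tsv"))
        rel = qp.ddct_expression(ct, "TERT", "GAPDH", "scrambled")
        rel.to_csv(os.path.join(config.out_dir, "ddct.tsv"), sep="\t", index=False)
        treated = rel.loc[rel["condition"] != "scrambled", "fold"]
        return {"fold_by_condition": dict(zip(rel["condition"], rel["fold"])),
                "min_treated_fold": float(treated.min()) if len(treated) else None}

    summary["qpcr"] = stage("qpcr")(qpcr_stage)

    # -- telomere ----------------------------------------------------------
    def telomere_stage():
        spec = sim.QpcrSimSpec.for_telomere(
            {("cellA", "scrambled"): 1.0, ("cellA", "siZNF148"): 0.7},
            ct_noise_sd=0.1, seed=rng_seed + 3,
        )
        ct = sim.simulate_qpcr(spec)
        res = tel.ts_ratio(ct, "scrambled")
        res.to_csv(os.path.join(config.out_dir, "telomere.tsv"), sep="\t", index=False)
        return {"relative_length": dict(zip(res["condition"], res["relative_length"]))}

    summary["telomere"] = stage("telomere")(telomere_stage)

    with open(os.path.join(config.out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(os.path.join(config.out_dir, "run_log.json"), "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    return summary
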