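"""End-to-end pipeline driver: simulate -> smoothness -> fit -> coherence.

Each stage logs its parameters, seed and record counts; outputs carry a
provenance stamp (config hash + seed).  A stage failure aborts the run
with the stage name while keeping whatever earlier stages wrote.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import (ModelSpec, SamplerConfig, SmoothnessMixedLM,
                    compare_models, fit_pre_difference, psis_loo)
from .config import PipelineConfig
from .io import make_provenance, write_records
from .neurophys import cluster_permutation, epoch, preprocess, wpli
from .simulate import gen_clinical_table, gen_ephys
from .simulate.cohort import cohort_records

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("moveson.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages on simulated data; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # hash the science, not the destination
    prov = make_provenance(cfg_dict, config.seed)
    manifest: dict = {"provenance": prov, "stages": {}}
    stage = "setup"
    try:
        # ---------------- smoothness cohort ---------------------------
        stage = "cohort"
        log.info("cohort: design=%s", config.cohort)
        records, truth = cohort_records(
            config.cohort, standardize_outcome=config.standardize_outcome)
        write_records(records, out / "records.csv", provenance=prov)
        truth.to_csv(out / "cohort_truth.csv", index=False)
        manifest["stages"]["cohort"] = {
            "n_records": int(len(records)),
            "n_patients": int(records["IDanon"].nunique())}

        # ---------------- model ladder + comparison -------------------
        stage = "fit"
        scfg = SamplerConfig(n_steps=config.sampler_steps)
        loos = {}
        fit_rows = []
        for number in config.models:
            spec = ModelSpec.ladder(number)
            res = SmoothnessMixedLM(records, spec).fit(
                seed=config.seed + number, sampler=scfg)
            summ = res.summary()
            summ.insert(0, "model", number)
            summ.to_csv(out / f"fit_model{number}.csv", index=False)
            fit_rows.append(summ)
            loos[f"#{number}"] = psis_loo(res, label=f"#{number}")
            log.info("fit #%d: converged=%s", number, res.converged)
        pd.concat(fit_rows).to_csv(out / "fits.csv", index=False)
        fit_stage = {"models": [f"#{n}" for n in config.models]}
        if len(loos) >= 2:
            comparison = compare_models(loos)
            comparison.to_csv(out / "model_comparison.csv")
            fit_stage["best"] = comparison.index[0]
        manifest["stages"]["fit"] = fit_stage

        # ---------------- clinical pre-differences --------------------
        stage = "clinical"
        table = gen_clinical_table(config.clinical_n_per_group,
                                   seed=config.seed)
        table.to_csv(out / "clinical.csv", index=False)
        rows = []
        for scale in config.clinical_scales:
            r = fit_pre_difference(table, scale, seed=config.seed)
            rows.append(r.summary())
        pre = pd.concat(rows)
        pre.to_csv(out / "pre_differences.csv", index=False)
        manifest["stages"]["clinical"] = {"scales": list(config.clinical_scales)}

        # ---------------- coherence -----------------------------------
        stage = "coherence"
        rec_pre = preprocess(gen_ephys(config.ephys))
        post_design = config.ephys_post or config.ephys
        rec_post = preprocess(gen_ephys(post_design))
        tr_pre = epoch(rec_pre)
        tr_post = epoch(rec_post)
        map_pre = wpli(tr_pre)
        map_post = wpli(tr_post)
        pd.DataFrame({"channel": map_pre.channels,
                      "wpli_pre": map_pre.wpli,
                      "wpli_post": map_post.wpli,
                      "sig_pre": map_pre.significant,
                      "sig_post": map_post.significant,
                      }).to_csv(out / "wpli.csv", index=False)
        cres = cluster_permutation(tr_pre, tr_post,
                                   n_perm=max(config.n_permutations, 200),
                                   seed=config.seed)
        pd.DataFrame([{"channels": "+".join(c.channels), "sign": c.sign,
                       "statistic": c.statistic, "p_value": c.p_value}
                      for c in cres.clusters]).to_csv(out / "clusters.csv",
                                                      index=False)
        manifest["stages"]["coherence"] = {
            "n_trials_pre": tr_pre.n_trials,
            "n_trials_post": tr_post.n_trials,
            "n_clusters": len(cres.clusters),
            "n_significant": len(cres.significant())}
    except Exception as e:  # noqa: BLE001 - report stage then re-raise
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=_jsonable))
        raise PipelineError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=_jsonable))
    log.info("pipeline complete: %s", out)
    return out


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
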