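"""End-to-end orchestration: discovery -> modules -> meta-genes ->
association screens -> classifier -> external validation -> sparsification
-> enrichment, with a reproducibility manifest.

Module discovery runs only on the discovery cohort; validation cohorts
receive the module gene lists and recompute their own meta-genes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from . import association, classify, enrichment, metagene, network, sparsify
from .io import AnalysisConfig, ExpressionMatrix, GeneSetLibrary, \
    PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with context
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_pipeline(discovery: tuple,
                 validations: Sequence[tuple] = (),
                 config: Optional[AnalysisConfig] = None,
                 library: Optional[GeneSetLibrary] = None) -> dict:
    """Run the whole analysis; returns a JSON-serializable report dict.

    ``discovery`` and each entry of ``validations`` are
    (ExpressionMatrix, PhenotypeTable) pairs.  Deterministic given the
    config seed.
    """
    cfg = config or AnalysisConfig()
    x_d, ph_d = discovery
    ph_d = ph_d.aligned_to(x_d)
    report: dict = {"stages": {}}

    # ---- module discovery (discovery cohort only) ----------------------
    class _Holder:
        pass

    holder = _Holder()

    @_stage("network")
    def _discover():
        return network.fit_modules(
            x_d, power="auto", sign_mode=cfg.sign_mode,
            min_module_size=cfg.min_module_size, deep_split=cfg.deep_split,
            max_height=cfg.max_height, pam_stage=cfg.pam_stage,
            power_candidates=cfg.power_candidates,
            target_r2=cfg.scale_free_r2_target, _store=holder)

    partition = _discover()
    modules = partition.modules()
    if not modules:
        raise StageError("network", ValidationError("no modules detected"))
    report["stages"]["network"] = {
        "power": int(getattr(holder, "power_", 0)),
        "scale_free_target_met": bool(getattr(
            holder, "scale_free_target_met_", False)),
        "module_sizes": {m: len(g) for m, g in modules.items()},
        "n_unassigned": int((partition.labels == network.UNASSIGNED).sum()),
    }

    # ---- meta-genes and association screens -----------------------------
    @_stage("metagene")
    def _metagenes():
        return metagene.compute_metagenes(x_d, modules)

    mg_d = _metagenes()

    @_stage("association")
    def _associate():
        out = {}
        for m in modules:
            scores = mg_d.series(m)
            tt = association.recurrence_ttest(scores, ph_d, unit=m)
            av = association.grade_anova(scores, ph_d, unit=m)
            entry = {
                "ttest_p": tt.p_value, "ttest_t": tt.statistic,
                "direction": tt.direction,
                "anova_p": av.p_value, "anova_F": av.statistic,
            }
            try:
                rho = association.ttr_correlation(scores, ph_d, unit=m)
                entry["ttr_rho"] = rho.statistic
                entry["ttr_p"] = rho.p_value
            except ValidationError:
                pass
            out[m] = entry
        return out

    assoc = _associate()
    report["stages"]["association"] = assoc
    significant = [m for m in modules
                   if assoc[m]["ttest_p"] < cfg.module_ttest_alpha]
    report["significant_modules"] = significant
    if not significant:
        logger.warning("no module passes the recurrence t-test screen; "
                       "using the lowest-p module")
        significant = [min(modules, key=lambda m: assoc[m]["ttest_p"])]
    predictive = min(significant, key=lambda m: assoc[m]["ttest_p"])
    report["predictive_module"] = predictive
    pred_modules = {predictive: modules[predictive]}

    # ---- discovery cross-validation -------------------------------------
    @_stage("classifier")
    def _cv():
        return classify.cross_validate(x_d, ph_d, pred_modules,
                                       k=cfg.cv_folds, seed=cfg.seed)

    cv = _cv()
    report["stages"]["cv"] = {"auc": cv.auc, "se": cv.se,
                              "folds": cfg.cv_folds}

    # ---- multivariate model on discovery --------------------------------
    @_stage("classifier")
    def _mv(x, ph, covs):
        model = classify.multivariate_model(x, ph, pred_modules, predictive,
                                            covariates=covs)
        row = model.odds_ratios.loc[predictive]
        return {"OR": row["OR"], "ci_low": row["ci_low"],
                "ci_high": row["ci_high"], "p": row["p"],
                "separation": model.separation, "n": model.n_obs}

    report["stages"]["multivariate"] = {
        "discovery": _mv(x_d, ph_d, ("who_grade",))}

    # ---- external validation --------------------------------------------
    report["stages"]["external"] = {}
    for i, (x_v, ph_v) in enumerate(validations, start=1):
        name = f"validation{i}"

        @_stage("classifier")
        def _ext():
            roc, _ = classify.evaluate_external(
                (x_d, ph_d), (x_v, ph_v), pred_modules)
            return roc

        roc = _ext()
        entry = {"auc": roc.auc, "se": roc.se}
        entry["multivariate"] = _mv(x_v, ph_v.aligned_to(x_v), ("who_grade",))
        ph_al = ph_v.aligned_to(x_v)
        if ph_al.data["simpson_grade"].notna().sum() >= 0.5 * len(ph_al.data):
            entry["multivariate_simpson"] = _mv(
                x_v, ph_al, ("who_grade", "simpson_grade"))
        entry["by_grade"] = {}
        for g in (1, 2, 3):
            try:
                r = classify.stratified_by_grade(x_v, ph_v, pred_modules, g)
                entry["by_grade"][str(g)] = {"auc": r.auc, "se": r.se}
            except ValidationError as e:
                entry["by_grade"][str(g)] = {"error": str(e)}
        report["stages"]["external"][name] = entry

    # ---- sparsification on validation cohorts ---------------------------
    if validations:
        @_stage("sparsify")
        def _sparse():
            traces = {}
            for i, (x_v, ph_v) in enumerate(validations, start=1):
                traces[f"validation{i}"] = sparsify.sparsify_module(
                    x_v, modules[predictive], ph_v,
                    threshold=cfg.sparsify_retention, cap=cfg.sparsify_cap)
            return traces

        traces = _sparse()
        report["stages"]["sparsify"] = {
            name: {"sparse_set_size": len(t.sparse_set),
                   "termination": t.termination,
                   "full_auc": t.full_auc}
            for name, t in traces.items()}
        if len(validations) >= 2:
            cohorts = {f"validation{i}": v
                       for i, v in enumerate(validations, start=1)}
            cross = sparsify.evaluate_sparse_cross_cohort(
                {n: t.sparse_set for n, t in traces.items()},
                cohorts, modules[predictive])
            report["stages"]["sparsify"]["cross_cohort"] = {
                "overlaps": cross["overlaps"],
                "evaluations": cross["evaluations"],
            }

    # ---- enrichment ------------------------------------------------------
    if library is not None:
        @_stage("enrichment")
        def _enrich():
            out = {}
            for m in modules:
                res = enrichment.overrepresentation_test(
                    modules[m], library, universe=x_d.gene_ids)
                out[m] = res
            return out

        enr = _enrich()
        report["stages"]["enrichment"] = {
            m: df.drop(columns="overlap_genes").head(10).to_dict("records")
            for m, df in enr.items()}
        if validations:
            @_stage("association")
            def _tf():
                cohorts = [(x_v, ph_v.aligned_to(x_v))
                           for x_v, ph_v in validations]
                return association.tf_marker_screen(
                    enr[predictive], cohorts,
                    q_alpha=cfg.enrichment_q_alpha,
                    p_alpha=cfg.module_ttest_alpha)

            tf = _tf()
            report["stages"]["tf_markers"] = tf.to_dict("records")

    # ---- manifest --------------------------------------------------------
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    report["manifest"] = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "n_cohorts": 1 + len(validations),
    }
    report["module_genes"] = {m: list(g) for m, g in modules.items()}
    return report
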