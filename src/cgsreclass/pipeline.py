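"""End-to-end orchestration: simulate -> QC -> score -> associate ->
predict -> reclassify -> report.

Each stage reads and writes only documented TSV/JSON artifacts in the run
directory, so every report number can be re-derived from the emitted
intermediate files.  A fixed config and seed produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cgsreclass import association as assoc
from cgsreclass import prediction as pred
from cgsreclass import score as scoring
from cgsreclass import simulate as sim
from cgsreclass.genotypes import (
    read_genotypes,
    read_panel,
    summarize_snps,
    write_genotypes,
    write_panel,
)

__all__ = ["RunConfig", "run_pipeline", "Stage"]

log = logging.getLogger("cgsreclass")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run.

    Defaults mirror the emulated study's settings: prevalence 0.10, risk
    category bounds 5/10/15/20%, 10,000 permutations, QC thresholds call
    rate > 0.95 and control HWE exact P > 0.01.
    """

    out_dir: str = "cgs_run"
    seed: int = 0
    # simulation (used when no genotype/phenotype paths are given)
    n_case: int = sim.STUDY_N_CASE
    n_control: int = sim.STUDY_N_CONTROL
    missing_rate: float = 0.027
    include_adolescents: bool = True
    # input paths (optional; override simulation)
    genotypes: str | None = None
    phenotypes: str | None = None
    panel: str | None = None
    # QC
    call_rate_min: float = 0.95
    hwe_p_min: float = 0.01
    # association
    n_perm: int = 10000
    assoc_covariates: tuple[str, ...] = ("sex", "age", "bmi")
    significance_p: float = 0.05
    # prediction
    prevalence: float = 0.10
    risk_bounds: tuple[float, ...] = pred.DEFAULT_RISK_BOUNDS
    ci_method: str = "asymptotic"  # or "bootstrap"
    n_boot: int = 2000
    clinical_covariates: tuple[str, ...] = ("sex", "age", "bmi")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("genotypes", "phenotypes", "panel"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {key} path does not exist: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT, index=index)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


class Stage:
    """Names of the pipeline stages, in execution order."""

    SIMULATE = "simulate"
    QC = "qc"
    SCORE = "score"
    ASSOCIATE = "associate"
    PREDICT = "predict"
    RECLASSIFY = "reclassify"
    REPORT = "report"
    ALL = (SIMULATE, QC, SCORE, ASSOCIATE, PREDICT, RECLASSIFY, REPORT)


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    """Write phenotypes.tsv, dosages.tsv, panel.tsv and truth.json.

    When input paths are configured, the files are copied into the run
    directory via read/write round-trips instead of simulated.
    """
    if cfg.genotypes is not None:
        panel = read_panel(cfg.panel) if cfg.panel else None
        dosages = read_genotypes(cfg.genotypes, panel=panel)
        phen = pd.read_csv(
            cfg.phenotypes, sep="\t", index_col="subject_id",
            na_values=["NA"], keep_default_na=False,
        )
        if panel is not None:
            write_panel(panel, out / "panel.tsv")
    else:
        config = sim.SimulationConfig(
            n_case=cfg.n_case,
            n_control=cfg.n_control,
            prevalence=cfg.prevalence,
            missing_rate=cfg.missing_rate,
            include_adolescents=cfg.include_adolescents,
            seed=cfg.seed,
        )
        cohort, truth = sim.simulate_cohort(config)
        dosages, phen = cohort.dosages, cohort.phenotypes
        truth.to_json(out / "truth.json")
        write_panel(config.panel(), out / "panel.tsv")
    write_genotypes(dosages, out / "dosages.tsv")
    _write_tsv(phen, out / "phenotypes.tsv")
    log.info("simulate: %d subjects x %d SNPs", len(phen), dosages.shape[1])


def _load(out: Path):
    dosages = read_genotypes(out / "dosages.tsv")
    phen = pd.read_csv(
        out / "phenotypes.tsv", sep="\t", index_col="subject_id",
        na_values=["NA"], keep_default_na=False,
    )
    if not dosages.index.equals(phen.index):
        raise ValueError("dosage and phenotype subject ids do not align")
    return dosages, phen


def stage_qc(cfg: RunConfig, out: Path) -> None:
    """Per-SNP QC summary (call rate, frequencies, exact HWE in controls)."""
    dosages, phen = _load(out)
    panel = read_panel(out / "panel.tsv") if (out / "panel.tsv").exists() else None
    summary = summarize_snps(
        dosages,
        phen["status"],
        panel=panel,
        call_rate_min=cfg.call_rate_min,
        hwe_p_min=cfg.hwe_p_min,
    )
    _write_tsv(summary, out / "qc_summary.tsv")
    n_fail = int((~summary["qc_pass"]).sum())
    log.info("qc: %d/%d SNPs flagged", n_fail, len(summary))


def stage_associate(cfg: RunConfig, out: Path) -> None:
    """Per-SNP additive-model association table with permutation p-values."""
    dosages, phen = _load(out)
    y = phen["status"].to_numpy(dtype=float)
    cov = phen[list(cfg.assoc_covariates)].astype(float)
    rows = []
    imputed = scoring.impute_mean_dosage(dosages)

    def stat_fn(labels):
        z = np.empty(dosages.shape[1])
        for j, snp in enumerate(imputed.columns):
            try:
                r = assoc.fit_logistic_additive(labels, imputed[snp], cov)
                z[j] = abs(r.beta / r.se)
            except (assoc.FitError, ValueError):
                z[j] = 0.0
        return z

    observed = stat_fn(y)
    if cfg.n_perm > 0:
        p_perm = assoc.permutation_adjust(
            stat_fn, y, cfg.n_perm, seed=cfg.seed, observed=observed
        )
    else:
        p_perm = np.full(dosages.shape[1], np.nan)

    for j, snp in enumerate(imputed.columns):
        r = assoc.fit_logistic_additive(y, imputed[snp], cov)
        rows.append(
            {
                "id": snp,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "p_permutation": p_perm[j],
                "significant": r.p < cfg.significance_p and r.beta > 0,
            }
        )
    table = pd.DataFrame(rows).set_index("id")
    _write_tsv(table, out / "association.tsv")
    log.info(
        "associate: %d/%d SNPs significant at P<%g",
        int(table["significant"].sum()), len(table), cfg.significance_p,
    )


def stage_score(cfg: RunConfig, out: Path) -> None:
    """Unweighted and weighted CGS over the significant risk SNPs."""
    dosages, phen = _load(out)
    assoc_table = pd.read_csv(out / "association.tsv", sep="\t", index_col="id")
    selected = assoc_table.index[assoc_table["significant"]].tolist()
    if len(selected) == 0:
        raise RuntimeError("no SNP passed the significance filter; cannot score")
    X = dosages[selected]
    betas = assoc_table.loc[selected, "beta"]

    for kind in ("unweighted", "weighted"):
        est = scoring.GeneticScoreTransformer(
            weighting=kind, betas=None if kind == "unweighted" else betas
        ).fit(X)
        scores = est.score_set(X)
        _write_tsv(scores, out / f"scores_{kind}.tsv")
        if kind == "weighted":
            _write_tsv(
                pd.DataFrame({"id": selected, "weight": est.weights_}),
                out / "weights.tsv",
                index=False,
            )
    log.info("score: CGS over %d SNPs", len(selected))


def stage_predict(cfg: RunConfig, out: Path) -> None:
    """Fit the three prevalence-adjusted models per score kind; write AUCs,
    per-subject risks and ROC curves."""
    _, phen = _load(out)
    cov = phen[list(cfg.clinical_covariates)].astype(float)
    complete = cov.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    y = phen.loc[complete, "status"].to_numpy(dtype=float)
    summary = {"n_excluded_incomplete_covariates": n_excluded}
    for kind in ("unweighted", "weighted"):
        scores = pd.read_csv(out / f"scores_{kind}.tsv", sep="\t", index_col="subject_id")
        s = scores.loc[complete, "rounded_score"].to_numpy(dtype=float)
        fits = pred.fit_risk_models(
            cov[complete], s, y, prevalence=cfg.prevalence
        )
        risks = pd.DataFrame({"status": y}, index=cov.index[complete])
        for model_id, fit in fits.items():
            risks[f"risk_{model_id}"] = fit.risks
            summary[f"{kind}_{model_id}"] = {
                "auc": fit.auc,
                "auc_ci": list(fit.auc_ci),
                "llf": fit.llf,
                "coef": dict(
                    zip(
                        ["const"] + fit.columns,
                        np.concatenate([fit.model.intercept_, fit.model.coef_[0]]),
                    )
                ),
                "intercept_adjustment": fit.model.intercept_adjustment_,
            }
            fpr, tpr, thr = _roc_points(y, fit.risks)
            _write_tsv(
                pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
                out / f"roc_{kind}_{model_id}.tsv",
                index=False,
            )
        _write_tsv(risks, out / f"risks_{kind}.tsv")
    _write_json(summary, out / "models.json")
    log.info("predict: %d subjects (%d excluded)", int(complete.sum()), n_excluded)


def _roc_points(y, risks):
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, risks)
    return fpr, tpr, thr


def stage_reclassify(cfg: RunConfig, out: Path) -> None:
    """5x5 reclassification tables and NRI per score kind."""
    for kind in ("unweighted", "weighted"):
        risks = pd.read_csv(out / f"risks_{kind}.tsv", sep="\t", index_col="subject_id")
        cats_without = pred.categorize_risk(
            risks["risk_clinical"], bounds=cfg.risk_bounds
        )
        cats_with = pred.categorize_risk(
            risks["risk_clinical_plus_cgs"], bounds=cfg.risk_bounds
        )
        status = risks["status"].to_numpy()
        res = pred.reclassification_table(
            cats_without, cats_with, status,
            n_categories=len(cfg.risk_bounds) + 1,
            category_bounds=cfg.risk_bounds,
        )
        res = pred.nri(res)
        if cfg.ci_method == "bootstrap":
            res.ci = pred.nri_bootstrap_ci(
                cats_without, cats_with, status,
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
        _write_tsv(res.table_cases, out / f"reclassification_cases_{kind}.tsv")
        _write_tsv(res.table_controls, out / f"reclassification_controls_{kind}.tsv")
        _write_json(
            {
                "nri": res.nri,
                "se": res.se,
                "ci": list(res.ci),
                "ci_method": cfg.ci_method,
                "p": res.p,
                "net_case": res.net_case,
                "net_control": res.net_control,
                "up_cases": res.up_cases,
                "down_cases": res.down_cases,
                "up_controls": res.up_controls,
                "down_controls": res.down_controls,
                "n_cases": res.n_cases,
                "n_controls": res.n_controls,
                "n_reclassified": res.n_reclassified,
                "category_bounds": list(res.category_bounds),
            },
            out / f"nri_{kind}.json",
        )
        log.info("reclassify (%s): NRI %.4f (p=%.3g)", kind, res.nri, res.p)


def stage_report(cfg: RunConfig, out: Path) -> None:
    """Quartile clinical-features table, score distributions, per-bin ORs
    and the machine summary."""
    dosages, phen = _load(out)
    y = phen["status"].to_numpy(dtype=float)
    cfg_record = cfg.to_dict()
    cfg_record.pop("out_dir")  # keep summaries byte-identical across run dirs
    summary: dict = {"seed": cfg.seed, "config": cfg_record}

    for kind in ("unweighted", "weighted"):
        scores = pd.read_csv(
            out / f"scores_{kind}.tsv", sep="\t", index_col="subject_id"
        )
        s = scores["rounded_score"].to_numpy()
        # quartile clinical-features table (cases only, quartiles over all)
        cases = phen["status"] == 1
        rows = []
        for q in sorted(np.unique(scores["quartile"])):
            in_q = (scores["quartile"] == q) & cases
            sub = phen[in_q]
            sq = scores.loc[in_q, "rounded_score"]
            rows.append(
                {
                    "quartile": int(q),
                    "n": int(in_q.sum()),
                    "score_median": float(sq.median()) if len(sq) else np.nan,
                    "score_min": float(sq.min()) if len(sq) else np.nan,
                    "score_max": float(sq.max()) if len(sq) else np.nan,
                    "male_pct": float(100 * sub["sex"].mean()) if len(sub) else np.nan,
                    "age_mean": float(sub["age"].mean()) if len(sub) else np.nan,
                    "bmi_mean": float(sub["bmi"].mean()) if len(sub) else np.nan,
                    "waist_mean": float(sub["waist"].mean()) if len(sub) else np.nan,
                }
            )
        _write_tsv(
            pd.DataFrame(rows), out / f"quartile_table_{kind}.tsv", index=False
        )

        # score distributions by status
        dist = (
            pd.crosstab(s, y)
            .rename(columns={0.0: "controls", 1.0: "cases"})
            .rename_axis(index="rounded_score")
        )
        _write_tsv(dist, out / f"score_distribution_{kind}.tsv")

        # tail-collapsed per-bin ORs against the lowest bin
        lower, upper = _default_tail_cuts(s)
        labels, bin_labels = scoring.bin_scores(s, lower, upper)
        bin_rows = []
        ref = labels == bin_labels[0]
        for lab in bin_labels[1:]:
            mask = ref | (labels == lab)
            exposed = (labels == lab)[mask]
            try:
                r = assoc.fit_logistic_additive(y[mask], exposed.astype(float))
                bin_rows.append(
                    {
                        "bin": lab, "n": int(exposed.sum()), "or": r.or_,
                        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                    }
                )
            except (assoc.FitError, ValueError):
                bin_rows.append(
                    {
                        "bin": lab, "n": int(exposed.sum()), "or": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    }
                )
        _write_tsv(pd.DataFrame(bin_rows), out / f"bin_or_{kind}.tsv", index=False)

        # per-allele CGS OR and score t-test
        cov = phen[list(cfg.assoc_covariates)].astype(float)
        r = assoc.fit_logistic_additive(y, s.astype(float), cov)
        t, p_t = assoc.t_test_scores(s[y == 1], s[y != 1])
        with open(out / f"nri_{kind}.json") as fh:
            nri_summary = json.load(fh)
        summary[kind] = {
            "per_allele_or": r.or_,
            "per_allele_ci": [r.ci_low, r.ci_high],
            "per_allele_p": r.p,
            "mean_cgs_cases": float(s[y == 1].mean()),
            "mean_cgs_controls": float(s[y != 1].mean()),
            "t_test": {"t": t, "p": p_t},
            "nri": nri_summary,
        }
    with open(out / "models.json") as fh:
        summary["models"] = json.load(fh)
    _write_json(summary, out / "summary.json")
    log.info("report: summary.json written")


def _default_tail_cuts(s: np.ndarray) -> tuple[int, int]:
    """Tail cuts placed so each collapsed tail holds >= ~2% of subjects."""
    smin, smax = int(s.min()), int(s.max())
    if smax <= smin:
        raise ValueError("constant scores cannot be binned")
    lo = max(int(np.floor(np.percentile(s, 2))), smin)
    hi = min(int(np.ceil(np.percentile(s, 98))), smax)
    if hi <= lo:
        lo, hi = smin, smax
    return lo, hi


_STAGE_FNS = {
    Stage.SIMULATE: stage_simulate,
    Stage.QC: stage_qc,
    Stage.ASSOCIATE: stage_associate,
    Stage.SCORE: stage_score,
    Stage.PREDICT: stage_predict,
    Stage.RECLASSIFY: stage_reclassify,
    Stage.REPORT: stage_report,
}

# association precedes scoring: the score uses the in-study betas
_EXEC_ORDER = (
    Stage.SIMULATE,
    Stage.QC,
    Stage.ASSOCIATE,
    Stage.SCORE,
    Stage.PREDICT,
    Stage.RECLASSIFY,
    Stage.REPORT,
)


def run_pipeline(cfg: RunConfig, stages=None) -> Path:
    """Run the requested stages (default: all) and return the run directory."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = _EXEC_ORDER if stages is None else [s for s in _EXEC_ORDER if s in stages]
    for stage in todo:
        _STAGE_FNS[stage](cfg, out)
    return out
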