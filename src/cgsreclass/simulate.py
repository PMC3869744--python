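"""Synthetic case-control cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes: control genotypes drawn genotype-wise from Hardy-Weinberg
proportions at a stated control risk-allele frequency, case genotypes from
Hardy-Weinberg proportions at the frequency implied by the allelic odds
ratio, covariates drawn independently of genotype, and dosages set missing
completely at random.

The module ships a default SNP panel (:func:`study_panel`) and control/case
covariate distributions that emulate a large Chinese type 2 diabetes
case-control study: 5882 cases drawn from a diabetes registry and 2569
controls pooled from adolescent, adult and elderly community cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "CohortSpec",
    "SimulationConfig",
    "Cohort",
    "TruthRecord",
    "case_allele_freq",
    "simulate_cohort",
    "study_panel",
    "STUDY_N_CASE",
    "STUDY_N_CONTROL",
]

#: sample sizes of the emulated case-control study
STUDY_N_CASE = 5882
STUDY_N_CONTROL = 2569

# Replicated T2D susceptibility panel: 14 beta-cell-function SNPs with
# control risk-allele frequencies and allelic odds ratios as estimated in
# the emulated study.  `significant` marks the 8 SNPs (P < 0.05) that enter
# the combined genetic score.
_STUDY_PANEL_ROWS = [
    # chrom, id, gene, risk, nonrisk, freq_controls, or_allelic, significant
    ("1", "rs10923931", "NOTCH2", "T", "G", 0.029, 1.24, False),
    ("3", "rs4607103", "ADAMTS9", "C", "T", 0.691, 0.97, False),
    ("3", "rs4402960", "IGF2BP2", "T", "G", 0.230, 1.16, True),
    ("4", "rs734312", "WFS1", "A", "G", 0.799, 1.14, True),
    ("6", "rs7756992", "CDKAL1", "G", "A", 0.459, 1.22, True),
    ("7", "rs864745", "JAZF1", "A", "G", 0.771, 1.08, False),
    ("8", "rs13266634", "SLC30A8", "C", "T", 0.527, 1.22, True),
    ("9", "rs10811661", "CDKN2A/B", "T", "C", 0.579, 1.21, True),
    ("10", "rs1111875", "HHEX", "G", "A", 0.274, 1.22, True),
    ("10", "rs7903146", "TCF7L2", "T", "C", 0.019, 2.09, True),
    ("11", "rs2237892", "KCNQ1", "C", "T", 0.656, 1.45, True),
    ("11", "rs5219", "KCNJ11", "T", "C", 0.325, 1.07, False),
    ("12", "rs7961581", "TSPAN8/LGR5", "C", "T", 0.229, 0.98, False),
    ("17", "rs4430796", "HNF1B", "G", "A", 0.254, 1.09, False),
]


def study_panel(significant_only: bool = False) -> pd.DataFrame:
    """Return the default SNP panel as a DataFrame.

    Parameters
    ----------
    significant_only
        If True, restrict to the 8 SNPs that enter the combined genetic
        score (allelic association P < 0.05 in the emulated study).

    Returns
    -------
    DataFrame with columns ``chrom, id, gene, risk_allele, nonrisk_allele,
    freq_controls, or_allelic, significant``.
    """
    df = pd.DataFrame(
        _STUDY_PANEL_ROWS,
        columns=[
            "chrom",
            "id",
            "gene",
            "risk_allele",
            "nonrisk_allele",
            "freq_controls",
            "or_allelic",
            "significant",
        ],
    )
    if significant_only:
        df = df[df["significant"]].reset_index(drop=True)
    return df


@dataclass(frozen=True)
class SnpSpec:
    """Per-SNP simulation parameters.

    Attributes
    ----------
    id : SNP identifier (e.g. an rsID).
    p_control : control risk-allele frequency, in (0, 1).
    or_allelic : allelic odds ratio of the risk allele, > 0.
    """

    id: str
    p_control: float
    or_allelic: float
    chrom: str = "."
    gene: str = ""
    risk_allele: str = "A"
    nonrisk_allele: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_control < 1.0:
            raise ValueError(
                f"{self.id}: p_control must lie in (0, 1), got {self.p_control}"
            )
        if not self.or_allelic > 0.0:
            raise ValueError(
                f"{self.id}: or_allelic must be positive, got {self.or_allelic}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Covariate distributions for one subject group.

    Ages and BMI are normal; sex is Bernoulli(male).  Fasting plasma
    glucose (mmol/l) is normal and fasting plasma insulin (pmol/l)
    log-normal where measured (None disables the trait for the group, as
    for the elderly controls and the cases in the emulated study).
    """

    label: str
    weight: float
    sex_male_p: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    fpg_mean: float | None = None
    fpg_sd: float | None = None
    log_fpi_mean: float | None = None
    log_fpi_sd: float | None = None


def _default_control_cohorts() -> tuple[CohortSpec, ...]:
    # Three community control cohorts: adolescents, adults, elderly.
    # log-FPI parameters back-calculated from median (IQR) of FPI in pmol/l:
    # adolescents 45.1 (35.5-60.5), adults 41.1 (26.0-58.3).
    return (
        CohortSpec(
            "adolescent", 1057 / 2569, 0.456, 15.3, 1.9, 19.9, 3.6,
            4.7, 0.4, float(np.log(45.1)), 0.395,
        ),
        CohortSpec(
            "adult", 586 / 2569, 0.451, 41.3, 10.5, 22.9, 3.3,
            4.8, 0.4, float(np.log(41.1)), 0.599,
        ),
        CohortSpec("elderly", 926 / 2569, 0.512, 72.3, 5.3, 23.2, 3.3),
    )


def _default_case_cohort() -> CohortSpec:
    return CohortSpec("case", 1.0, 0.455, 56.8, 13.3, 25.1, 3.9)


@dataclass
class SimulationConfig:
    """Configuration of a synthetic case-control cohort.

    Defaults emulate the study conditions: 5882 cases, 2569 controls,
    population prevalence 0.10, the 14-SNP panel, 2.7% missing dosages.
    """

    n_case: int = STUDY_N_CASE
    n_control: int = STUDY_N_CONTROL
    prevalence: float = 0.10
    snp_specs: tuple[SnpSpec, ...] = ()
    control_cohorts: tuple[CohortSpec, ...] = field(
        default_factory=_default_control_cohorts
    )
    case_cohort: CohortSpec = field(default_factory=_default_case_cohort)
    missing_rate: float = 0.027
    include_adolescents: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snp_specs:
            panel = study_panel()
            self.snp_specs = tuple(
                SnpSpec(
                    id=r.id,
                    p_control=r.freq_controls,
                    or_allelic=r.or_allelic,
                    chrom=r.chrom,
                    gene=r.gene,
                    risk_allele=r.risk_allele,
                    nonrisk_allele=r.nonrisk_allele,
                )
                for r in panel.itertuples()
            )
        self.validate()

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must each be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if len(self.snp_specs) == 0:
            raise ValueError("snp_specs must contain at least one SNP")
        cohorts = list(self.control_cohorts)
        if not self.include_adolescents:
            cohorts = [c for c in cohorts if c.label != "adolescent"]
        if not cohorts:
            raise ValueError("no control cohorts left after filtering")

    def panel(self) -> pd.DataFrame:
        """SNP panel implied by ``snp_specs`` (genotype-I/O layout)."""
        return pd.DataFrame(
            {
                "id": [s.id for s in self.snp_specs],
                "chrom": [s.chrom for s in self.snp_specs],
                "gene": [s.gene for s in self.snp_specs],
                "risk_allele": [s.risk_allele for s in self.snp_specs],
                "nonrisk_allele": [s.nonrisk_allele for s in self.snp_specs],
            }
        )


@dataclass
class Cohort:
    """A simulated (or loaded) case-control cohort.

    Attributes
    ----------
    phenotypes : DataFrame indexed by subject id with columns
        ``status`` (1 case / 0 control), ``cohort``, ``sex`` (1 male /
        0 female), ``age``, ``bmi``, ``waist``, ``fpg``, ``fpi``,
        ``hba1c``, ``scr``, ``age_at_diagnosis``.
    dosages : DataFrame (subjects x SNPs) of risk-allele counts, NaN for
        missing genotypes; index aligned with ``phenotypes``.
    """

    phenotypes: pd.DataFrame
    dosages: pd.DataFrame

    @property
    def status(self) -> pd.Series:
        return self.phenotypes["status"]


@dataclass
class TruthRecord:
    """Ground-truth parameters of a simulated cohort, for recovery tests."""

    snps: list[dict]
    prevalence: float
    n_case: int
    n_control: int
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def case_allele_freq(p_control: float, or_allelic: float) -> float:
    """Case risk-allele frequency implied by an allelic odds ratio.

    Under the additive (allelic) odds-ratio parameterization, sampling
    alleles from cases shifts the control frequency ``p`` to
    ``p * OR / (1 - p + p * OR)`` — the odds of drawing a risk allele are
    multiplied by OR.  Strictly increasing in OR; equal to ``p`` at OR = 1.
    """
    if not 0.0 < p_control < 1.0:
        raise ValueError(f"p_control must lie in (0, 1), got {p_control}")
    if not or_allelic > 0.0:
        raise ValueError(f"or_allelic must be positive, got {or_allelic}")
    odds = p_control / (1.0 - p_control) * or_allelic
    return odds / (1.0 + odds)


def _draw_covariates(
    rng: np.random.Generator, spec: CohortSpec, n: int, status: int
) -> pd.DataFrame:
    sex = rng.binomial(1, spec.sex_male_p, size=n)
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 1.0, None)
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, size=n), 12.0, None)
    # waist tracks BMI with a sex offset; central-obesity rates then fall in
    # a plausible range for both groups
    waist = 28.0 + 2.3 * bmi + 4.0 * sex + rng.normal(0.0, 5.0, size=n)
    if spec.fpg_mean is not None:
        fpg = np.clip(rng.normal(spec.fpg_mean, spec.fpg_sd, size=n), 2.0, None)
    else:
        fpg = np.full(n, np.nan)
    if spec.log_fpi_mean is not None:
        fpi = np.exp(rng.normal(spec.log_fpi_mean, spec.log_fpi_sd, size=n))
    else:
        fpi = np.full(n, np.nan)
    scr = np.clip(
        rng.normal(np.where(sex == 1, 85.0, 70.0), 15.0, size=n), 20.0, None
    )
    if status == 1:
        hba1c = np.clip(rng.normal(7.7, 1.8, size=n), 4.0, None)
        aad = np.minimum(
            np.clip(rng.normal(49.7, 12.6, size=n), 18.0, None), age
        )
    else:
        hba1c = np.clip(rng.normal(5.4, 0.4, size=n), 4.0, None)
        aad = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "status": status,
            "cohort": spec.label,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "waist": waist,
            "fpg": fpg,
            "fpi": fpi,
            "hba1c": hba1c,
            "scr": scr,
            "age_at_diagnosis": aad,
        }
    )


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, TruthRecord]:
    """Simulate a case-control cohort with known genetic architecture.

    Controls are drawn genotype-wise from Hardy-Weinberg proportions at
    each SNP's control frequency; cases from Hardy-Weinberg proportions at
    :func:`case_allele_freq` of that frequency and the SNP's allelic odds
    ratio.  Covariates are independent of genotype.  Each dosage is set
    missing independently with probability ``missing_rate``.  The same
    config and seed reproduce the cohort bit-for-bit.

    Returns
    -------
    (cohort, truth) where ``truth`` records every generating parameter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cohorts = list(config.control_cohorts)
    if not config.include_adolescents:
        cohorts = [c for c in cohorts if c.label != "adolescent"]
    total_w = sum(c.weight for c in cohorts)

    # controls: split n_control across cohorts by weight (largest remainder)
    raw = np.array([c.weight / total_w * config.n_control for c in cohorts])
    counts = np.floor(raw).astype(int)
    rem = config.n_control - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    frames = []
    for spec_c, n in zip(cohorts, counts):
        if n > 0:
            frames.append(_draw_covariates(rng, spec_c, int(n), status=0))
    frames.append(_draw_covariates(rng, config.case_cohort, config.n_case, status=1))
    phen = pd.concat(frames, ignore_index=True)
    phen.index = pd.Index(
        [f"S{i:06d}" for i in range(len(phen))], name="subject_id"
    )

    status = phen["status"].to_numpy()
    n_total = len(phen)
    dosage = np.empty((n_total, len(config.snp_specs)), dtype=float)
    truth_snps = []
    for j, snp in enumerate(config.snp_specs):
        p_case = case_allele_freq(snp.p_control, snp.or_allelic)
        p = np.where(status == 1, p_case, snp.p_control)
        dosage[:, j] = rng.binomial(2, p)
        truth_snps.append(
            {
                "id": snp.id,
                "p_control": snp.p_control,
                "p_case": p_case,
                "or_allelic": snp.or_allelic,
            }
        )
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    dosages = pd.DataFrame(
        dosage, index=phen.index, columns=[s.id for s in config.snp_specs]
    )
    truth = TruthRecord(
        snps=truth_snps,
        prevalence=config.prevalence,
        n_case=config.n_case,
        n_control=int(counts.sum()),
        seed=config.seed,
    )
    return Cohort(phenotypes=phen, dosages=dosages), truth
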