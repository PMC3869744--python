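"""Derived clinical traits and preprocessing transforms.

Homeostasis-model indices (HOMA-IR, HOMA-beta) from fasting glucose and
insulin, the abbreviated MDRD eGFR with the Chinese ethnicity coefficient,
stratum-wise winsorization at 4 SD, anthropometric flags, and the log
transforms applied to skewed insulin-derived traits.

Units: fasting plasma glucose mmol/l; fasting plasma insulin is recorded in
pmol/l and converted to mU/l (conventional divisor 6.0) before entering the
HOMA formulas; serum creatinine umol/l; eGFR ml/min/1.73 m^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "homa_indices",
    "egfr_mdrd_chinese",
    "winsorize_4sd",
    "derive_flags",
    "PMOL_PER_MU",
]

#: conventional insulin unit conversion: 1 mU/l = 6.0 pmol/l
PMOL_PER_MU = 6.0


def homa_indices(fpg, fpi_mU_per_l):
    """Homeostasis-model indices of insulin resistance and beta-cell function.

    HOMA-IR = FPI[mU/l] x FPG[mmol/l] / 22.5;
    HOMA-beta = FPI x 20 / (FPG - 3.5).

    HOMA-beta is undefined at FPG <= 3.5 mmol/l and returned as NaN there.
    Accepts scalars or arrays; NaN inputs propagate.
    """
    fpg = np.asarray(fpg, dtype=float)
    fpi = np.asarray(fpi_mU_per_l, dtype=float)
    if np.any(fpg[~np.isnan(fpg)] <= 0):
        raise ValueError("fpg must be positive")
    if np.any(fpi[~np.isnan(fpi)] < 0):
        raise ValueError("fpi must be non-negative")
    homa_ir = fpi * fpg / 22.5
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_beta = np.where(fpg > 3.5, fpi * 20.0 / (fpg - 3.5), np.nan)
    if homa_ir.ndim == 0:
        return float(homa_ir), float(homa_beta)
    return homa_ir, homa_beta


def egfr_mdrd_chinese(scr, age, female, chinese=True):
    """Abbreviated MDRD estimated GFR with ethnicity adjustment.

    eGFR = 186 x (S_CR x 0.011)^-1.154 x age^-0.203
           x 0.742 if female x 1.233 if Chinese,
    with serum creatinine S_CR in umol/l (the 0.011 factor converts to the
    mg/dl scale the MDRD equation was calibrated on).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr[~np.isnan(scr)] <= 0):
        raise ValueError("serum creatinine must be positive")
    if np.any(age[~np.isnan(age)] <= 0):
        raise ValueError("age must be positive")
    female = np.asarray(female, dtype=bool)
    chinese = np.asarray(chinese, dtype=bool)
    egfr = (
        186.0
        * (scr * 0.011) ** -1.154
        * age ** -0.203
        * np.where(female, 0.742, 1.0)
        * np.where(chinese, 1.233, 1.0)
    )
    return float(egfr) if egfr.ndim == 0 else egfr


def winsorize_4sd(values, groups=None, n_sd: float = 4.0):
    """Replace extreme values with the mean +/- ``n_sd``*SD bound, per stratum.

    The mean and SD are computed once from the pre-replacement data of each
    stratum (single pass), so re-running with the original bounds is a
    no-op.  Missing values are preserved.  Strata with fewer than two
    non-missing values are rejected.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    if groups is None:
        groups = pd.Series(np.zeros(len(values), dtype=int))
    else:
        groups = pd.Series(np.asarray(groups))
        if len(groups) != len(values):
            raise ValueError("groups must align with values")

    out = values.copy()
    for _, idx in groups.groupby(groups).groups.items():
        v = values.loc[idx]
        obs = v.dropna()
        if len(obs) < 2:
            raise ValueError(
                "winsorization requires >= 2 non-missing values per stratum"
            )
        m, s = obs.mean(), obs.std(ddof=1)
        out.loc[idx] = v.clip(lower=m - n_sd * s, upper=m + n_sd * s)
    return out.to_numpy()


def derive_flags(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Append derived trait columns to a phenotype table.

    Adds (prefix ``derived_``):

    * ``central_obesity`` — waist >= 90 cm (male) / >= 80 cm (female),
      boundaries inclusive;
    * ``overweight`` — BMI >= 25 kg/m^2;
    * ``fpi_mU_per_l`` — insulin converted from pmol/l;
    * ``homa_ir``, ``homa_beta`` — homeostasis-model indices;
    * ``log_fpi``, ``log_homa_ir``, ``log_homa_beta`` — natural logs of the
      skewed insulin-derived traits (NaN where the trait is 0 or missing);
    * ``egfr`` — MDRD-Chinese eGFR where creatinine is present.

    Required columns: ``sex`` (1 male / 0 female), ``bmi``, ``waist``;
    ``fpg``/``fpi``/``scr``/``age`` used where present.
    """
    for col in ("sex", "bmi", "waist"):
        if col not in phenotypes:
            raise ValueError(f"phenotype table lacks required column {col!r}")
    out = phenotypes.copy()
    male = out["sex"].astype(float) == 1
    out["derived_central_obesity"] = np.where(
        male, out["waist"] >= 90.0, out["waist"] >= 80.0
    )
    out["derived_overweight"] = out["bmi"] >= 25.0

    if "fpi" in out:
        fpi_mu = out["fpi"].astype(float) / PMOL_PER_MU
        out["derived_fpi_mU_per_l"] = fpi_mu
        if "fpg" in out:
            fpg = out["fpg"].astype(float)
            if np.any(fpg.dropna() <= 0):
                raise ValueError("fpg must be positive")
            ir, beta = homa_indices(
                fpg.fillna(np.nan).to_numpy(), fpi_mu.to_numpy()
            )
            out["derived_homa_ir"] = ir
            out["derived_homa_beta"] = beta
            with np.errstate(divide="ignore", invalid="ignore"):
                out["derived_log_fpi"] = _safe_log(fpi_mu)
                out["derived_log_homa_ir"] = _safe_log(ir)
                out["derived_log_homa_beta"] = _safe_log(beta)
    if "scr" in out and "age" in out:
        scr = out["scr"].astype(float)
        ok = scr.notna() & (scr > 0)
        egfr = np.full(len(out), np.nan)
        if ok.any():
            egfr[ok.to_numpy()] = egfr_mdrd_chinese(
                scr[ok].to_numpy(),
                out.loc[ok, "age"].astype(float).to_numpy(),
                ~male[ok].to_numpy(),
            )
        out["derived_egfr"] = egfr
    return out


def _safe_log(x):
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    if np.any(x[ok] < 0):
        raise ValueError("log transform requires non-negative values")
    pos = ok & (x > 0)
    out[pos] = np.log(x[pos])
    return out
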