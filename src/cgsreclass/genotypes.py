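"""Genotype I/O and quality control.

Dosage matrices are pandas DataFrames (subjects x SNPs) of risk-allele
counts 0/1/2 with NaN for missing genotypes.  The primary on-disk format is
a tab-separated table (header ``subject_id`` followed by SNP ids, missing
code ``NA``); a VCF dialect is accepted for reading, with dosages derived
from the GT field against the panel's risk allele.

QC follows the conventional case-control genotyping criteria: per-SNP call
rate, allele frequencies by status, and the two-sided exact test of
Hardy-Weinberg proportions in controls (probability-ordering over
heterozygote counts at fixed allele margins, as popularized by PLINK).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hwe_exact_test",
    "summarize_snps",
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "write_panel",
    "validate_panel",
    "GenotypeParseError",
]

MISSING_CODE = "NA"

PANEL_COLUMNS = ["id", "chrom", "gene", "risk_allele", "nonrisk_allele"]


class GenotypeParseError(ValueError):
    """Malformed genotype input; carries a line number where known."""


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check a SNP panel table: unique ids, risk != non-risk allele."""
    missing = [c for c in ("id", "risk_allele", "nonrisk_allele") if c not in panel]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    if panel["id"].duplicated().any():
        dups = panel.loc[panel["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate SNP ids in panel: {dups}")
    same = panel["risk_allele"] == panel["nonrisk_allele"]
    if same.any():
        bad = panel.loc[same, "id"].tolist()
        raise ValueError(f"risk allele equals non-risk allele for: {bad}")
    return panel


def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_nonrisk: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the allele margins, the heterozygote count under HWE
    follows the distribution

        P(n_het) = C * 2**n_het / (n_hom_risk! n_het! n_hom_nonrisk!)

    over all genotype configurations with the observed allele counts.  The
    two-sided p-value sums the probabilities of every heterozygote count
    whose probability does not exceed that of the observed count
    (probability-ordering definition, no mid-p correction).

    Returns a p-value in (0, 1].  Monomorphic sites return 1.0.
    """
    counts = (n_hom_risk, n_het, n_hom_nonrisk)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped subject is required")

    n_rare = min(2 * n_hom_risk + n_het, 2 * n_hom_nonrisk + n_het)
    if n_rare == 0:
        return 1.0

    probs = _hwe_het_probabilities(n, n_rare)
    obs_index = n_het // 2  # het counts share the parity of n_rare
    p_obs = probs[obs_index]
    # small relative slack so exact ties are included despite rounding
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _hwe_het_probabilities(n: int, n_rare: int) -> np.ndarray:
    """HWE probabilities of each admissible heterozygote count.

    Heterozygote counts run over ``n_rare % 2, n_rare % 2 + 2, ..., n_rare``;
    element ``i`` corresponds to ``het = n_rare % 2 + 2 i``.  Computed by the
    stable two-directional recurrence from the distribution's mode.
    """
    n_common = 2 * n - n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets), dtype=float)

    # mode of the conditional distribution (start the recurrence here so the
    # anchor probability cannot underflow)
    mid = int(n_rare * n_common / (2 * n))
    if mid % 2 != n_rare % 2:
        mid += 1
    mid = min(mid, n_rare)
    mid_index = (mid - hets[0]) // 2
    probs[mid_index] = 1.0

    # downward recurrence: P(het-2)/P(het) = het(het-1) / (4 (hr+1)(hc+1))
    for i in range(mid_index, 0, -1):
        het = hets[i]
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        probs[i - 1] = probs[i] * het * (het - 1) / (
            4.0 * (hom_rare + 1) * (hom_common + 1)
        )
    # upward recurrence: P(het+2)/P(het) = 4 hr hc / ((het+2)(het+1))
    for i in range(mid_index, len(hets) - 1):
        het = hets[i]
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        probs[i + 1] = probs[i] * 4.0 * hom_rare * hom_common / (
            (het + 2.0) * (het + 1.0)
        )
    return probs / probs.sum()


def summarize_snps(
    dosages: pd.DataFrame,
    status: pd.Series | np.ndarray,
    panel: pd.DataFrame | None = None,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.01,
) -> pd.DataFrame:
    """Per-SNP QC summary: call rate, allele frequencies, exact HWE.

    Parameters
    ----------
    dosages
        Subjects x SNPs risk-allele counts, NaN for missing.
    status
        Case (1) / control (0) labels aligned with the dosage rows.
    panel
        Optional panel table; when given, every dosage column must appear
        in it (a missing SNP raises ``KeyError``) and panel metadata is
        merged into the output.
    call_rate_min, hwe_p_min
        QC thresholds; SNPs failing are flagged in ``qc_pass``, never
        dropped.

    Returns a DataFrame indexed by SNP id with columns ``call_rate, maf,
    risk_allele_freq_cases, risk_allele_freq_controls, hwe_p_controls,
    qc_pass``.
    """
    status = np.asarray(status)
    if len(status) != len(dosages):
        raise ValueError("status labels must align with dosage rows")
    if panel is not None:
        validate_panel(panel)
        known = set(panel["id"])
        unknown = [c for c in dosages.columns if c not in known]
        if unknown:
            raise KeyError(f"SNPs absent from panel: {unknown}")

    is_case = status == 1
    rows = []
    for snp in dosages.columns:
        d = dosages[snp].to_numpy(dtype=float)
        obs = ~np.isnan(d)
        call_rate = obs.mean()
        raf = np.nan if not obs.any() else d[obs].mean() / 2.0
        raf_cases = _allele_freq(d[is_case])
        raf_controls = _allele_freq(d[~is_case])

        ctrl = d[~is_case]
        ctrl = ctrl[~np.isnan(ctrl)]
        if len(ctrl) > 0:
            hom_risk = int((ctrl == 2).sum())
            het = int((ctrl == 1).sum())
            hom_nonrisk = int((ctrl == 0).sum())
            hwe_p = hwe_exact_test(hom_risk, het, hom_nonrisk)
        else:
            hwe_p = np.nan
        maf = np.nan if np.isnan(raf) else min(raf, 1.0 - raf)
        rows.append(
            {
                "id": snp,
                "call_rate": call_rate,
                "maf": maf,
                "risk_allele_freq_cases": raf_cases,
                "risk_allele_freq_controls": raf_controls,
                "hwe_p_controls": hwe_p,
                "qc_pass": bool(
                    call_rate > call_rate_min
                    and (np.isnan(hwe_p) or hwe_p > hwe_p_min)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("id")


def _allele_freq(d: np.ndarray) -> float:
    d = d[~np.isnan(d)]
    return np.nan if len(d) == 0 else float(d.mean() / 2.0)


# ---------------------------------------------------------------------------
# I/O


def write_genotypes(dosages: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a dosage matrix; only the TSV dialect is writable."""
    if dialect != "tsv":
        raise ValueError(f"unsupported write dialect: {dialect!r}")
    out = dosages.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_CODE, float_format="%.10g")


def read_genotypes(
    path, dialect: str = "tsv", panel: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Read a dosage matrix from TSV or VCF.

    TSV: header ``subject_id`` then SNP ids; entries 0/1/2 (or imputed
    reals) with ``NA`` for missing.  VCF: one sample column per subject,
    dosage = count of the panel's risk allele in GT; any missing allele in
    GT (``./.`` or half-calls) yields a missing dosage.  The VCF dialect
    requires a panel to orient dosages.
    """
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        if panel is None:
            raise ValueError("the VCF dialect requires a SNP panel")
        return _read_vcf(path, panel)
    raise ValueError(f"unsupported dialect: {dialect!r}")


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=[MISSING_CODE], keep_default_na=False
    )
    if df.columns[0] != "subject_id":
        raise GenotypeParseError(
            f"line 1: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        line = int(df.index[df["subject_id"] == dup][1]) + 2
        raise GenotypeParseError(f"line {line}: duplicate subject id {dup!r}")
    df = df.set_index("subject_id")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise GenotypeParseError(
                f"line {line}: non-numeric dosage {df[col][bad].iloc[0]!r} "
                f"for SNP {col}"
            )
    return df.astype(float)


def _read_vcf(path, panel: pd.DataFrame) -> pd.DataFrame:
    import pysam

    validate_panel(panel)
    by_id = panel.set_index("id")
    with pysam.VariantFile(str(path)) as vcf:
        subjects = list(vcf.header.samples)
        data: dict[str, np.ndarray] = {}
        for rec in vcf:
            if rec.id is None or rec.id not in by_id.index:
                continue
            risk = by_id.loc[rec.id, "risk_allele"]
            nonrisk = by_id.loc[rec.id, "nonrisk_allele"]
            alleles = [rec.ref] + list(rec.alts or ())
            if risk not in alleles or nonrisk not in alleles:
                raise GenotypeParseError(
                    f"record {rec.id}: alleles {alleles} do not match panel "
                    f"({risk}/{nonrisk})"
                )
            col = np.full(len(subjects), np.nan)
            for i, sample in enumerate(subjects):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue  # missing or half-missing call
                col[i] = sum(1 for a in gt if alleles[a] == risk)
            data[rec.id] = col
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))


def write_panel(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, sep="\t", index=False, na_rep=MISSING_CODE)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(
        path, sep="\t", na_values=[MISSING_CODE], keep_default_na=False,
        dtype={"id": str, "chrom": str},
    )
    return validate_panel(panel)
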