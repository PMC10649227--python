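"""Quality filtering of peptide fits and protein-level rate aggregation.

A protein's turnover rate is the median of the rates of its peptides,
but individual peptide fits vary in quality (intensity fluctuations,
co-eluting contaminants, few quantified points).  This module provides:

* the built-in default filter: slow peptides (k < 0.01 day^-1) must
  have RMSE < 0.01; all others must have R^2 > 0.9, r > 0.9 and
  RMSE < 0.05 (for slow turnover R^2 is uninformative because the RIA
  barely moves);
* fully user-customizable threshold filtering on R^2, r, RMSE, SD,
  NDP, peptide abundance, isotope deviation and the number of
  experiments the peptide was identified in;
* iterative two-sided Grubbs outlier rejection among the surviving
  peptide rates;
* protein aggregation: median rate, harmonic-mean SD and a 95%
  confidence interval;
* readers/writers for the per-protein ``<Protein>.RateConst.csv``
  peptide tables and the ``Analyzed_Proteins_and_Their_Rates.csv``
  protein summary.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

__all__ = [
    "FilterCriteria",
    "PeptideRateRecord",
    "ProteinRateSummary",
    "default_filter",
    "custom_filter",
    "grubbs_critical_value",
    "grubbs_outliers",
    "aggregate_protein",
    "read_rateconst_csv",
    "write_rateconst_csv",
    "write_protein_summary",
    "read_protein_summary",
]

GRUBBS_ALPHA = 0.05
GRUBBS_MIN_N = 3


@dataclass
class PeptideRateRecord:
    """One row of a RateConst table: a peptide/charge fit and its GOF."""

    sequence: str
    charge: int
    k: float = math.nan
    ci_lower: float = math.nan
    ci_upper: float = math.nan
    pearson_r: float = math.nan
    R2: float = math.nan
    RMSE: float = math.nan
    SD: float = math.nan
    isotope_deviation: float = math.nan
    mz: float = math.nan
    NEH: float = math.nan
    NDP: float = math.nan
    avg_monoisotope_abundance: float = math.nan
    n_experiments: float = math.nan


@dataclass
class FilterCriteria:
    """User thresholds; ``None`` disables a criterion (always passes).

    ``strict`` selects the comparison sense: strict inequalities
    (">", "<") as in the built-in defaults, or inclusive (">=", "<=")
    as conventionally quoted for user thresholds.
    """

    min_R2: float | None = None
    min_r: float | None = None
    max_RMSE: float | None = None
    max_SD: float | None = None
    min_NDP: float | None = None
    min_abundance: float | None = None
    max_isotope_deviation: float | None = None
    min_experiments: float | None = None
    strict: bool = False

    def _ge(self, value: float, threshold: float) -> bool:
        if not np.isfinite(value):
            return False
        return value > threshold if self.strict else value >= threshold

    def _le(self, value: float, threshold: float) -> bool:
        if not np.isfinite(value):
            return False
        return value < threshold if self.strict else value <= threshold


def default_filter(rec: PeptideRateRecord) -> tuple[bool, list[str]]:
    """Built-in GOF filter used before protein aggregation.

    Slow-turnover peptides (k < 0.01 day^-1) pass iff RMSE < 0.01;
    all others pass iff R^2 > 0.9, r > 0.9 and RMSE < 0.05.  Returns
    the verdict and the list of failed clauses.
    """
    if not np.isfinite(rec.k) or not np.isfinite(rec.RMSE):
        return False, ["missing_metric"]
    reasons: list[str] = []
    if rec.k < 0.01:
        if not rec.RMSE < 0.01:
            reasons.append("RMSE")
    else:
        if not (np.isfinite(rec.R2) and np.isfinite(rec.pearson_r)):
            return False, ["missing_metric"]
        if not rec.R2 > 0.9:
            reasons.append("R2")
        if not rec.pearson_r > 0.9:
            reasons.append("r")
        if not rec.RMSE < 0.05:
            reasons.append("RMSE")
    return not reasons, reasons


def custom_filter(
    rec: PeptideRateRecord, crit: FilterCriteria
) -> tuple[bool, list[str]]:
    """Apply user thresholds; returns (pass, list of failed criteria)."""
    reasons: list[str] = []
    checks = [
        ("min_R2", rec.R2, crit._ge),
        ("min_r", rec.pearson_r, crit._ge),
        ("max_RMSE", rec.RMSE, crit._le),
        ("max_SD", rec.SD, crit._le),
        ("min_NDP", rec.NDP, crit._ge),
        ("min_abundance", rec.avg_monoisotope_abundance, crit._ge),
        ("max_isotope_deviation", rec.isotope_deviation, crit._le),
        ("min_experiments", rec.n_experiments, crit._ge),
    ]
    for name, value, compare in checks:
        threshold = getattr(crit, name)
        if threshold is None:
            continue
        if not compare(value, threshold):
            reasons.append(name)
    return not reasons, reasons


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n``."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    tq = student_t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(tq**2 / (n - 2 + tq**2))


def grubbs_outliers(rates, alpha: float = GRUBBS_ALPHA) -> set[int]:
    """Indices of outliers by the iterative two-sided Grubbs test.

    Repeatedly removes the most extreme value while its Grubbs
    statistic G = max|x - mean|/sd exceeds the critical value.  Fewer
    than three values, or zero variance, yields no outliers.
    """
    values = np.asarray(rates, dtype=float)
    active = [i for i in range(values.size) if np.isfinite(values[i])]
    outliers: set[int] = set()
    while len(active) >= GRUBBS_MIN_N:
        sub = values[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        pos = int(np.argmax(dev))
        if dev[pos] / sd > grubbs_critical_value(len(active), alpha):
            outliers.add(active.pop(pos))
        else:
            break
    return outliers


@dataclass
class ProteinRateSummary:
    protein_id: str
    k_protein: float
    n_peptides_used: int
    sd_protein: float
    ci95: tuple[float, float]
    all_outliers_warning: bool = False


def _harmonic_mean_sd(sds: np.ndarray) -> float:
    """Harmonic mean of the positive, finite SDs; NaN if none."""
    sds = sds[np.isfinite(sds) & (sds > 0)]
    if sds.size == 0:
        return math.nan
    return float(sds.size / np.sum(1.0 / sds))


def aggregate_protein(
    protein_id: str,
    records: list[PeptideRateRecord],
    alpha_grubbs: float = GRUBBS_ALPHA,
    level: float = 0.95,
) -> ProteinRateSummary:
    """Aggregate passing peptide records into one protein rate.

    After Grubbs outlier removal, the protein rate is the median of the
    remaining peptide rates and the protein SD the harmonic mean of
    their residual SDs (records with zero/missing SD are excluded from
    the harmonic mean but still count toward the median).  The CI is
    k +- t(1-(1-level)/2, n-1) * sd/sqrt(n), clamped below at zero; a
    single-peptide protein inherits that peptide's own CI.  If Grubbs
    removes every peptide, the pre-removal median is emitted with a
    warning flag.
    """
    if not records:
        raise ValueError("aggregate_protein needs at least one record")
    ks = np.array([r.k for r in records], dtype=float)
    out = grubbs_outliers(ks, alpha_grubbs)
    kept = [r for i, r in enumerate(records) if i not in out]
    warning = False
    if not kept:
        kept = list(records)
        warning = True
    k_vals = np.array([r.k for r in kept], dtype=float)
    k_protein = float(np.median(k_vals))
    sd_protein = _harmonic_mean_sd(np.array([r.SD for r in kept]))
    n = len(kept)
    if n == 1:
        ci = (kept[0].ci_lower, kept[0].ci_upper)
        if not (np.isfinite(ci[0]) and np.isfinite(ci[1])):
            ci = (k_protein, k_protein)
    elif np.isfinite(sd_protein):
        q = student_t.ppf(0.5 + level / 2.0, n - 1)
        half = q * sd_protein / math.sqrt(n)
        ci = (max(k_protein - half, 0.0), k_protein + half)
    else:
        ci = (k_protein, k_protein)
    return ProteinRateSummary(
        protein_id=protein_id,
        k_protein=k_protein,
        n_peptides_used=n,
        sd_protein=sd_protein,
        ci95=ci,
        all_outliers_warning=warning,
    )


# ---------------------------------------------------------------------------
# RateConst.csv dialect

_RATECONST_COLUMNS: dict[str, str] = {
    # canonical header -> record attribute
    "Peptide": "sequence",
    "Charge": "charge",
    "RateConstant": "k",
    "CI_Lower": "ci_lower",
    "CI_Upper": "ci_upper",
    "Correlation": "pearson_r",
    "R2": "R2",
    "RMSE": "RMSE",
    "SD": "SD",
    "IsotopeDeviation": "isotope_deviation",
    "m/z": "mz",
    "NEH": "NEH",
    "NDP": "NDP",
    "Abundance": "avg_monoisotope_abundance",
    "NumberOfExperiments": "n_experiments",
}

# tolerant aliases: normalized header -> attribute
_HEADER_ALIASES: dict[str, str] = {
    "peptide": "sequence", "peptides": "sequence", "sequence": "sequence",
    "charge": "charge", "z": "charge", "chargestate": "charge",
    "rateconstant": "k", "rate": "k", "k": "k", "kday1": "k",
    "cilower": "ci_lower", "lowerci": "ci_lower", "ci95lower": "ci_lower",
    "ciupper": "ci_upper", "upperci": "ci_upper", "ci95upper": "ci_upper",
    "correlation": "pearson_r", "r": "pearson_r", "pearson": "pearson_r",
    "pearsonr": "pearson_r",
    "r2": "R2", "rsquared": "R2", "coefficientofdetermination": "R2",
    "rmse": "RMSE", "rootmeansquarederror": "RMSE",
    "sd": "SD", "standarddeviation": "SD",
    "isotopedeviation": "isotope_deviation", "isodev": "isotope_deviation",
    "mz": "mz", "masstocharge": "mz",
    "neh": "NEH", "accessiblehydrogens": "NEH",
    "ndp": "NDP", "numberofdatapoints": "NDP", "datapoints": "NDP",
    "abundance": "avg_monoisotope_abundance",
    "averageabundance": "avg_monoisotope_abundance",
    "avgmonoisotopeabundance": "avg_monoisotope_abundance",
    "numberofexperiments": "n_experiments", "nexperiments": "n_experiments",
    "experiments": "n_experiments",
}

_MANDATORY = ("sequence", "charge", "k")


def _normalize_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.strip().lower())


def read_rateconst_csv(path) -> list[PeptideRateRecord]:
    """Read one per-protein RateConst.csv into peptide records.

    Header names are matched tolerantly against documented aliases;
    unknown columns are ignored; unparseable numeric cells become NaN.
    Missing mandatory columns (sequence, charge, rate constant) raise
    ``ValueError`` naming them.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    mapping: dict[str, str] = {}
    for col in df.columns:
        attr = _HEADER_ALIASES.get(_normalize_header(str(col)))
        if attr is not None and attr not in mapping.values():
            mapping[col] = attr
    missing = [m for m in _MANDATORY if m not in mapping.values()]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory RateConst columns: {', '.join(missing)}"
        )
    numeric_attrs = {
        f.name for f in fields(PeptideRateRecord) if f.name != "sequence"
    }
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for col, attr in mapping.items():
            value = row[col]
            if attr == "sequence":
                kwargs[attr] = str(value)
            elif attr == "charge":
                try:
                    kwargs[attr] = int(float(value))
                except (TypeError, ValueError):
                    kwargs[attr] = 0
            elif attr in numeric_attrs:
                kwargs[attr] = pd.to_numeric(value, errors="coerce")
        records.append(PeptideRateRecord(**kwargs))
    return records


def write_rateconst_csv(records: list[PeptideRateRecord], path) -> None:
    """Write peptide records in the RateConst.csv dialect."""
    rows = [
        {header: getattr(rec, attr) for header, attr in _RATECONST_COLUMNS.items()}
        for rec in records
    ]
    df = pd.DataFrame(rows, columns=list(_RATECONST_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6g")


_SUMMARY_COLUMNS = [
    "Protein", "RateConstant", "NumberOfPeptides", "CI95_Lower",
    "CI95_Upper", "SD",
]


def write_protein_summary(summaries: list[ProteinRateSummary], path) -> None:
    """Write the protein-level summary CSV, rows sorted by protein id."""
    rows = [
        {
            "Protein": s.protein_id,
            "RateConstant": s.k_protein,
            "NumberOfPeptides": s.n_peptides_used,
            "CI95_Lower": s.ci95[0],
            "CI95_Upper": s.ci95[1],
            "SD": s.sd_protein,
        }
        for s in sorted(summaries, key=lambda s: s.protein_id)
    ]
    df = pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_protein_summary(path) -> pd.DataFrame:
    """Read back a protein summary CSV as a DataFrame."""
    return pd.read_csv(path)
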