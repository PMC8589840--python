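"""URA3-loss LOH rate metrics from CFU plate counts.

The rate at a timepoint T is the percentage of plated cells that lost the
URA3 marker, R_T = 100 * CFU_5FOA,T / CFU_YPD,T (colony-forming units per
mL on counterselective 5-FOA plates over permissive YPD plates). RTG
efficiency is summarised by the LOH ratio R_T6 / R_T0 and the LOH
difference R_T6 - R_T0, both computed on replicate means; a natural-log
ratio is also reported. Significance of the T6-over-T0 increase uses a
one-sided Welch t test on log-transformed replicate rates (the log
stabilises the multiplicative replicate CV), with a one-sided rank-sum
fallback whenever a replicate rate is 0 (log undefined); the test used is
recorded in the result. Both paired and unpaired replicate modes are
available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .markers import ValidationError

__all__ = ["CFUAssay", "LOHMetrics", "loh_rate", "loh_metrics", "progression_correlation"]


@dataclass(frozen=True)
class CFUAssay:
    """One plating record of the URA3-loss assay."""

    strain: str
    timepoint: str  # "T0" | "T6" | "T12" | "T24"
    replicate: int
    cfu_5foa: float  # CFU per mL on 5-FOA
    cfu_ypd: float  # CFU per mL on YPD

    def __post_init__(self) -> None:
        if self.cfu_5foa < 0 or self.cfu_ypd < 0:
            raise ValidationError("negative CFU count")


@dataclass(frozen=True)
class LOHMetrics:
    r_t0: float  # mean rate over replicates, % of cells
    r_t6: float
    sd_t0: float
    sd_t6: float
    ratio: float  # R_T6 / R_T0 on replicate means; NaN when R_T0 = 0
    difference: float  # R_T6 - R_T0, % of cells
    ln_ratio: float
    per_replicate_ratios: np.ndarray | None  # paired mode only
    p_increase: float  # one-sided test of R_T6 > R_T0
    test: str
    negative_difference: bool  # flagged "non-significant/negative"
    ratio_undefined: bool


def loh_rate(record: CFUAssay) -> float:
    """LOH rate as % of plated cells: 100 * CFU_5FOA / CFU_YPD."""
    if record.cfu_ypd <= 0:
        raise ValidationError(f"{record.strain} {record.timepoint}: CFU_YPD must be > 0")
    return 100.0 * record.cfu_5foa / record.cfu_ypd


def loh_metrics(
    rates_t0, rates_t6, paired: bool = False
) -> LOHMetrics:
    """LOH ratio / difference and the significance of the T6 increase.

    ``rates_t0`` / ``rates_t6`` are replicate rate arrays (%, e.g. from
    :func:`loh_rate`). The ratio and difference are computed on replicate
    means; per-replicate ratios are emitted additionally in paired mode.
    """
    t0 = np.asarray(rates_t0, dtype=float)
    t6 = np.asarray(rates_t6, dtype=float)
    if t0.size < 1 or t6.size < 1:
        raise ValidationError("need >= 1 replicate per timepoint")
    if paired and t0.size != t6.size:
        raise ValidationError("paired mode needs equal replicate counts")
    m0, m6 = float(t0.mean()), float(t6.mean())
    ratio_undefined = m0 == 0.0
    if ratio_undefined:
        warnings.warn("all R_T0 = 0: LOH ratio undefined, difference still reported")
        ratio, ln_ratio = float("nan"), float("nan")
    else:
        ratio = m6 / m0
        ln_ratio = math.log(ratio) if ratio > 0 else float("-inf")
    diff = m6 - m0
    per_rep = t6 / t0 if (paired and (t0 > 0).all()) else None

    if (t0 > 0).all() and (t6 > 0).all() and t0.size >= 2 and t6.size >= 2:
        if paired:
            res = st.ttest_rel(np.log(t6), np.log(t0), alternative="greater")
        else:
            res = st.ttest_ind(
                np.log(t6), np.log(t0), equal_var=False, alternative="greater"
            )
        test = "one-sided Welch t on log rates" if not paired else "one-sided paired t on log rates"
        p = float(res.pvalue)
        if math.isnan(p):  # zero variance in both groups
            p = 1.0 if diff <= 0 else 0.0
            p = max(p, 0.5) if diff == 0 else p
    elif t0.size >= 2 and t6.size >= 2:
        res = st.mannwhitneyu(t6, t0, alternative="greater")
        test = "one-sided Wilcoxon rank-sum (zero rates present)"
        p = float(res.pvalue)
    else:
        test = "none (single replicate)"
        p = float("nan")
    return LOHMetrics(
        r_t0=m0,
        r_t6=m6,
        sd_t0=float(t0.std(ddof=1)) if t0.size > 1 else 0.0,
        sd_t6=float(t6.std(ddof=1)) if t6.size > 1 else 0.0,
        ratio=ratio,
        difference=diff,
        ln_ratio=ln_ratio,
        per_replicate_ratios=per_rep,
        p_increase=p,
        test=test,
        negative_difference=diff < 0,
        ratio_undefined=ratio_undefined,
    )


def progression_correlation(records: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pearson correlation between meiotic progression and the LOH metrics.

    ``records`` columns: strain, progression (% of cells past MI+MII at
    12 h), loh_difference, ln_ratio. Records with a negative LOH difference
    are excluded before correlating (they would bias the correlation); the
    difference is correlated on a log scale. Returns
    {"difference": (r, p), "ln_ratio": (r, p)} with two-sided p values.
    """
    required = {"progression", "loh_difference", "ln_ratio"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records lack columns {required - set(records.columns)}")
    if ((records["progression"] < 0) | (records["progression"] > 100)).any():
        raise ValidationError("progression must lie in [0, 100]")
    usable = records[records["loh_difference"] > 0]
    if len(usable) < 3:
        raise ValidationError("fewer than 3 records after excluding non-positive differences")
    out = {}
    r, p = st.pearsonr(usable["progression"], np.log(usable["loh_difference"]))
    out["difference"] = (float(r), float(p))
    r, p = st.pearsonr(usable["progression"], usable["ln_ratio"])
    out["ln_ratio"] = (float(r), float(p))
    return out
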