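"""Growth-phenotype normalisation, heterosis classes and LOD linkage mapping.

Phenotypes are spatially normalised log2 population doubling times,
D_r = log2(D) - log2(D_control,local); higher D_r means slower growth.
Growth classes relative to the ancestral hybrid use the fixed thresholds
0.25 / 1 / -0.25 / -1 (see :func:`classify_growth` for the boundary
conventions).

The linkage scan regresses the phenotype on the LOH genotype at each marker
(single-marker regression) and reports LOD = (n/2) * log10(RSS0 / RSS1).
The default genotype coding is additive, HET = 0, HOM_P1 = +1, HOM_P2 = -1;
a two-degree-of-freedom genotype-factor coding is available. Genome-wide
significance uses a permutation threshold: the phenotype rows are permuted
against the genotype rows, the maximum LOD of each permuted scan is
recorded, and the threshold is the 95th-percentile order statistic of those
maxima. QTL confidence intervals are LOD-drop support intervals (default
drop 1.5), expanded to the flanking markers just outside the drop region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

import scipy.stats as st

from .markers import HET, HOM_P1, HOM_P2, MISSING, ValidationError

__all__ = [
    "GrowthClass",
    "QTLPeak",
    "QTLResult",
    "normalize_growth",
    "classify_growth",
    "heterosis",
    "filter_markers",
    "lod_scan",
    "permutation_threshold",
    "qtl_interval",
    "scan_environment",
]

GROWTH_LABELS = (
    "highly inferior",
    "inferior",
    "neutral",
    "superior",
    "highly superior",
)


@dataclass(frozen=True)
class GrowthClass:
    label: str
    heterosis: str  # "best-parent" | "worse-parent" | "none" | "not evaluable"


@dataclass(frozen=True)
class QTLPeak:
    marker_index: int
    position: tuple[str, int]
    lod: float
    interval: tuple[int, int]  # bp, LOD-drop support interval
    one_sided: bool  # peak at a scan edge


@dataclass(frozen=True)
class QTLResult:
    environment: str
    lod: np.ndarray
    threshold: float
    peaks: list[QTLPeak]
    coding: str


def normalize_growth(d: float, d_control_local: float) -> float:
    """Normalised doubling time D_r = log2(D) - log2(D_control,local)."""
    if d <= 0 or d_control_local <= 0:
        raise ValidationError("doubling times must be > 0")
    return math.log2(d) - math.log2(d_control_local)


def classify_growth(d_r: float) -> str:
    """Growth label from D_r normalised to the ancestral hybrid.

    Thresholds: highly inferior when D_r >= 1; inferior when
    0.25 <= D_r < 1; neutral when |D_r| < 0.25; superior when
    -1 < D_r <= -0.25; highly superior when D_r <= -1.

    Boundary conventions: at |D_r| = 1 both the plain and the "highly"
    band nominally apply and the more extreme label wins; at |D_r| = 0.25
    the non-neutral label applies (the neutral band is open).
    """
    if not math.isfinite(d_r):
        raise ValidationError("D_r must be finite")
    if d_r >= 1:
        return "highly inferior"
    if d_r >= 0.25:
        return "inferior"
    if d_r <= -1:
        return "highly superior"
    if d_r <= -0.25:
        return "superior"
    return "neutral"


def heterosis(
    clone_reps,
    parent1_reps,
    parent2_reps,
    alpha: float = 0.05,
) -> str:
    """Best-/worse-parent heterosis from replicate doubling times.

    Higher D_r = slower growth, so a clone shows *worse-parent* heterosis
    when its doubling time is significantly higher than both parents', and
    *best-parent* heterosis when significantly lower than both (one-sided
    Welch tests at ``alpha``). Missing parent data -> "not evaluable".
    """
    if parent1_reps is None or parent2_reps is None:
        return "not evaluable"
    clone = np.asarray(clone_reps, dtype=float)
    p1 = np.asarray(parent1_reps, dtype=float)
    p2 = np.asarray(parent2_reps, dtype=float)
    if min(clone.size, p1.size, p2.size) < 2:
        return "not evaluable"

    def worse(x, y):  # clone x significantly slower than parent y
        return st.ttest_ind(x, y, equal_var=False, alternative="greater").pvalue < alpha

    def better(x, y):
        return st.ttest_ind(x, y, equal_var=False, alternative="less").pvalue < alpha

    if worse(clone, p1) and worse(clone, p2):
        return "worse-parent"
    if better(clone, p1) and better(clone, p2):
        return "best-parent"
    return "none"


# ---------------------------------------------------------------------------
# Linkage scan
# ---------------------------------------------------------------------------


def filter_markers(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Marker filters for the linkage scan.

    ``genotypes`` is a clones x markers int matrix of genotype codes.
    Removes markers with no genotype call in any clone and markers
    homozygous in fewer than two clones (a single homozygous sample cannot
    support linkage; a fully heterozygous marker carries no variance).
    Returns (filtered matrix, kept column indices, removal log).
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValidationError("need a clones x markers matrix with >= 2 clones")
    called = (g != MISSING).sum(axis=0)
    hom = ((g == HOM_P1) | (g == HOM_P2)).sum(axis=0)
    keep = (called > 0) & (hom >= 2)
    log = {
        "n_markers": g.shape[1],
        "removed_no_genotype": int((called == 0).sum()),
        "removed_low_hom": int(((called > 0) & (hom < 2)).sum()),
        "kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValidationError("no markers survive filtering")
    return g[:, keep], np.flatnonzero(keep), log


def _additive_code(g: np.ndarray) -> np.ndarray:
    x = np.zeros(g.shape, dtype=float)
    x[g == HOM_P1] = 1.0
    x[g == HOM_P2] = -1.0
    return x


def lod_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    coding: str = "additive",
) -> np.ndarray:
    """Single-marker LOD scan, LOD = (n/2) * log10(RSS0 / RSS1).

    Clones with a missing (NaN) phenotype are dropped; clones with a
    MISSING genotype are dropped per marker. Markers with zero genotype
    variance get LOD = 0.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    if g.shape[0] != y.size:
        raise ValidationError("genotype/phenotype clone counts differ")
    ok = np.isfinite(y)
    g, y = g[ok], y[ok]
    if y.size < 8:
        raise ValidationError("need >= 8 clones with phenotype")
    valid = g != MISSING
    n = valid.sum(axis=0).astype(float)  # clones used per marker
    yv = np.where(valid, y[:, None], 0.0)
    sy = yv.sum(axis=0)
    syy = (yv**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss0 = syy - sy**2 / n
        if coding == "additive":
            x = np.where(valid, _additive_code(g), 0.0)
            sx = x.sum(axis=0)
            sxx = (x**2).sum(axis=0)
            sxy = (x * yv).sum(axis=0)
            cov = sxy - sx * sy / n
            varx = sxx - sx**2 / n
            rss1 = rss0 - np.where(varx > 0, cov**2 / np.where(varx > 0, varx, 1.0), 0.0)
        elif coding == "factor":
            rss1 = np.zeros(g.shape[1])
            for level in (HET, HOM_P1, HOM_P2):
                m = valid & (g == level)
                ng = m.sum(axis=0).astype(float)
                sg = np.where(m, y[:, None], 0.0).sum(axis=0)
                sgg = np.where(m, y[:, None] ** 2, 0.0).sum(axis=0)
                rss1 += np.where(ng > 0, sgg - sg**2 / np.where(ng > 0, ng, 1.0), 0.0)
        else:
            raise ValidationError(f"unknown coding {coding!r}")
        lod = np.where(
            (rss1 > 0) & (rss0 > 0),
            (n / 2.0) * np.log10(np.where(rss1 > 0, rss0 / np.where(rss1 > 0, rss1, 1.0), 1.0)),
            0.0,
        )
        # perfect fit (rss1 == 0) with real variance reduction: infinite LOD
        perfect = (rss0 > 0) & (rss1 <= 1e-12 * np.maximum(rss0, 1.0))
        lod = np.where(perfect, np.inf, lod)
    return np.maximum(np.nan_to_num(lod, nan=0.0, posinf=np.inf), 0.0)


def permutation_threshold(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int | np.random.Generator = 0,
    coding: str = "additive",
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype rows are permuted against the genotype rows ``n_perm``
    times; the genome-wide maximum LOD of each permuted scan is recorded
    and the threshold is the ceil(quantile * n_perm)-th order statistic of
    the sorted maxima (the 950th of 1000 at the default 95th percentile).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        maxima[i] = lod_scan(genotypes, perm, coding=coding).max()
    maxima.sort()
    k = int(math.ceil(quantile * n_perm))
    return float(maxima[k - 1])


def qtl_interval(
    positions: np.ndarray,
    lod: np.ndarray,
    peak: int,
    drop: float = 1.5,
) -> tuple[int, int, bool]:
    """LOD-drop support interval around a peak marker.

    Returns (start bp, end bp, one_sided): the contiguous marker run around
    the peak with LOD >= peak LOD - drop, expanded to the flanking markers
    just outside; ``one_sided`` flags a peak whose interval hits a scan
    edge.
    """
    lod = np.asarray(lod, dtype=float)
    positions = np.asarray(positions)
    cut = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < lod.size - 1 and lod[hi + 1] >= cut:
        hi += 1
    one_sided = lo == 0 or hi == lod.size - 1
    lo = max(0, lo - 1)  # expand to the flanking markers just outside
    hi = min(lod.size - 1, hi + 1)
    return int(positions[lo]), int(positions[hi]), one_sided


def scan_environment(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    marker_positions,
    environment: str = "env",
    n_perm: int = 1000,
    quantile: float = 0.95,
    drop: float = 1.5,
    seed: int | np.random.Generator = 0,
    coding: str = "additive",
) -> QTLResult:
    """Full per-environment scan: filter, LOD, permutation threshold, peaks.

    ``marker_positions`` is a sequence of (chrom, pos) aligned to the
    genotype matrix columns. Peaks are per-chromosome LOD maxima above the
    genome-wide threshold.
    """
    g, kept, _ = filter_markers(genotypes)
    pos = [marker_positions[j] for j in kept]
    lod = lod_scan(g, phenotype, coding=coding)
    thr = permutation_threshold(g, phenotype, n_perm, quantile, seed, coding=coding)
    peaks: list[QTLPeak] = []
    chroms = np.asarray([c for c, _ in pos], dtype=object)
    bp = np.asarray([p for _, p in pos], dtype=np.int64)
    for chrom in pd_unique(chroms):
        m = np.flatnonzero(chroms == chrom)
        j = m[int(np.argmax(lod[m]))]
        if lod[j] > thr:
            start, end, one_sided = qtl_interval(bp[m], lod[m], int(np.argmax(lod[m])), drop)
            peaks.append(
                QTLPeak(
                    marker_index=int(kept[j]),
                    position=(str(chrom), int(bp[j])),
                    lod=float(lod[j]),
                    interval=(start, end),
                    one_sided=one_sided,
                )
            )
    return QTLResult(environment=environment, lod=lod, threshold=thr, peaks=peaks, coding=coding)


def pd_unique(values: np.ndarray) -> list:
    """Order-preserving unique (first occurrence order)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
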