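"""Synthetic return-to-growth (RTG) recombination with full ground truth.

The generator emulates the RTG mechanism in a diploid hybrid: after meiotic
S-phase each homolog is present as two sister chromatids (four chromatids
per chromosome, two carrying each parental haplotype). Spo11-induced
double-strand breaks (DSBs) are drawn Poisson over the genome, preferentially
inside recombination-hotspot intervals in proportion to their hit counts.
Each DSB is repaired off the homolog; the heteroduplex formed during repair
carries one mismatch per marker in the repair tract, and the recombination
event is rejected with probability 1 - (1 - rho)^mismatches — the
mismatch-repair anti-recombination mechanism, switched off by the msh2
deletion flag. Surviving DSBs resolve either as a reciprocal crossover (CO,
exchanging everything distal to the break between one chromatid of each
homolog) or as a non-reciprocal conversion tract (NCO, geometric length,
copied one way). The cell then buds: chromatids segregate 2+2 into a mother
and a daughter, each keeping one centromere of each homolog per chromosome
(mitotic-like segregation) and no further replication occurs. A CO therefore
produces complementary *terminal* homozygosity in the two cells, an NCO an
*interstitial* homozygous tract in one cell.

Centromeres stay heterozygous: DSBs are suppressed in a pericentromeric
zone that extends from the centromere by at least the suppression radius
and always past the nearest flanking marker on each side, and conversion
tracts grow distally (away from the centromere), so no event can touch a
centromere-flanking marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import (
    HET,
    HOM_P1,
    HOM_P2,
    GenomeLayout,
    GenotypeTrack,
    HotspotTrack,
    MarkerMap,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthSegment",
    "RTGPair",
    "yeast_layout",
    "simulate_marker_map",
    "simulate_hotspots",
    "simulate_rtg_pair",
    "simulate_rtg_pairs",
    "simulate_mitotic_track",
    "simulate_phenotypes",
]

# Approximate S. cerevisiae chromosome lengths and centromere midpoints (bp).
_YEAST_CHROMS = [
    ("chrI", 230_000, 151_500),
    ("chrII", 813_000, 238_200),
    ("chrIII", 317_000, 114_400),
    ("chrIV", 1_532_000, 449_700),
    ("chrV", 577_000, 152_000),
    ("chrVI", 270_000, 148_500),
    ("chrVII", 1_091_000, 497_000),
    ("chrVIII", 563_000, 105_600),
    ("chrIX", 440_000, 355_700),
    ("chrX", 746_000, 436_300),
    ("chrXI", 667_000, 440_100),
    ("chrXII", 1_078_000, 150_900),
    ("chrXIII", 924_000, 268_000),
    ("chrXIV", 784_000, 628_800),
    ("chrXV", 1_091_000, 326_600),
    ("chrXVI", 948_000, 556_000),
]


def yeast_layout(mask: int = 20_000) -> GenomeLayout:
    """A yeast-like 16-chromosome genome layout (~12.1 Mb).

    ``mask`` bp at each chromosome end are flagged subtelomeric/telomeric
    and excluded from LOH calling.
    """
    return GenomeLayout(
        lengths={c: n for c, n, _ in _YEAST_CHROMS},
        centromeres={c: (m - 60, m + 60) for c, _, m in _YEAST_CHROMS},
        mask_left={c: mask for c, _, _ in _YEAST_CHROMS},
        mask_right={c: mask for c, _, _ in _YEAST_CHROMS},
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable parameters of the RTG generator.

    dsb_rate
        Mean number of DSBs per cell per (aborted) meiosis, Poisson.
    hotspot_weight
        Probability that a DSB lands inside a hotspot interval (chosen
        proportional to its hits H); the remainder is uniform background.
    cen_radius
        Minimum pericentromeric DSB-suppression distance (bp).
    p_co
        Probability a surviving DSB resolves as a crossover; otherwise it
        becomes a one-way conversion tract.
    tract_mean
        Mean conversion/repair tract length (bp, geometric).
    rho
        Per-mismatch probability that heteroduplex rejection aborts the
        recombination event; ``msh2_null=True`` forces rho = 0.
    mitotic_rate
        Background mitotic LOH events per genome per cell division (used by
        :func:`simulate_mitotic_track` defaults).
    """

    dsb_rate: float = 160.0
    hotspot_weight: float = 0.8
    cen_radius: int = 10_000
    p_co: float = 0.05
    tract_mean: float = 2_000.0
    rho: float = 0.1
    msh2_null: bool = False
    mitotic_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dsb_rate < 0:
            raise ValidationError("dsb_rate must be >= 0")
        if not 0 <= self.p_co <= 1:
            raise ValidationError("p_co must lie in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValidationError("rho must lie in [0, 1]")
        if self.tract_mean <= 0:
            raise ValidationError("tract_mean must be > 0")
        if not 0 <= self.hotspot_weight <= 1:
            raise ValidationError("hotspot_weight must lie in [0, 1]")

    @property
    def effective_rho(self) -> float:
        return 0.0 if self.msh2_null else self.rho


@dataclass(frozen=True)
class TruthEvent:
    """One resolved DSB: its kind, location and the chromatids it touched."""

    chrom: str
    kind: str  # "CO" | "NCO"
    pos: int
    chromatids: tuple[int, int]  # CO: exchanged pair; NCO: (donor, recipient)
    tract: tuple[int, int] | None  # NCO conversion tract (bp, inclusive)


@dataclass(frozen=True)
class TruthSegment:
    """A maximal homozygous marker run in one cell, from the chromatid arrays."""

    cell: str  # "mother" | "daughter"
    chrom: str
    parent: int  # HOM_P1 | HOM_P2
    first: int  # position of first marker in the run (bp)
    last: int
    n_markers: int
    terminal: bool


@dataclass
class RTGPair:
    """A mother/daughter RTG pair with complete ground truth.

    ``nco_marker_indices`` are the (global) marker-map row indices at which
    conversion tracts left the four-chromatid allele dosage unbalanced;
    these are exactly the markers a reciprocity check flags as
    non-reciprocal between mother and daughter.
    """

    mother: GenotypeTrack
    daughter: GenotypeTrack
    events: list[TruthEvent]
    truth_segments: list[TruthSegment]
    nco_marker_indices: np.ndarray


# ---------------------------------------------------------------------------
# Marker map and hotspot generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_marker_map(
    layout: GenomeLayout, divergence: float, seed: int | np.random.Generator = 0
) -> MarkerMap:
    """Draw a biallelic marker map at per-bp heterozygosity ``divergence``.

    Marker positions follow a Bernoulli(theta) process per bp, realised via
    geometric inter-marker gaps; alleles are random distinct bases.
    """
    if divergence < 0:
        raise ValidationError("divergence must be >= 0")
    if divergence > 0.2:
        raise ValidationError("divergence above 0.2 is not a marker regime")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for chrom in layout.chromosomes:
        length = layout.length(chrom)
        if divergence == 0:
            continue
        # geometric gaps on {1,2,...} <=> Bernoulli(theta) per bp
        n_expect = int(length * divergence)
        gaps = rng.geometric(divergence, size=max(16, int(n_expect * 1.3) + 32))
        pos = np.cumsum(gaps)
        while pos.size and pos[-1] <= length:
            more = rng.geometric(divergence, size=max(16, n_expect // 4 + 16))
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        pos = pos[pos <= length]
        if pos.size == 0:
            continue
        a1 = rng.integers(0, 4, size=pos.size)
        a2 = (a1 + rng.integers(1, 4, size=pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele1": _BASES[a1],
                    "allele2": _BASES[a2],
                }
            )
        )
    if not frames:
        return MarkerMap(
            pd.DataFrame(columns=["chrom", "pos", "allele1", "allele2"])
        )
    return MarkerMap(pd.concat(frames, ignore_index=True))


def simulate_hotspots(
    layout: GenomeLayout,
    n_per_mb: float = 300.0,
    width: int = 500,
    seed: int | np.random.Generator = 0,
) -> HotspotTrack:
    """Random hotspot intervals with exponential-tailed hit counts.

    Defaults emulate the density of the genome-wide Spo11 DSB hotspot map
    in budding yeast (~3,600 hotspots of a few hundred bp over ~12 Mb).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for chrom in layout.chromosomes:
        length = layout.length(chrom)
        n = rng.poisson(n_per_mb * length / 1e6)
        if n == 0:
            continue
        starts = rng.integers(1, max(2, length - width), size=n)
        hits = np.ceil(rng.exponential(100.0, size=n)).astype(int)
        for s, h in zip(starts, hits):
            rows.append({"chrom": chrom, "start": int(s), "end": int(s) + width - 1, "hits": float(h)})
    return HotspotTrack(pd.DataFrame(rows, columns=list(HotspotTrack.COLUMNS)))


# ---------------------------------------------------------------------------
# RTG pair simulation
# ---------------------------------------------------------------------------


def _suppression_zone(
    layout: GenomeLayout, marker_map: MarkerMap, chrom: str, radius: int
) -> tuple[int, int]:
    """Pericentromeric interval (inclusive) where DSBs are suppressed.

    Extends at least ``radius`` bp from the centromere and always past the
    nearest marker on each side, so centromere-flanking markers can never be
    caught in a distal exchange or conversion tract.
    """
    cs, ce = layout.centromere(chrom)
    pos = marker_map.positions(chrom)
    lo = cs - radius
    hi = ce + radius
    left = pos[pos < cs]
    right = pos[pos > ce]
    if left.size:
        lo = min(lo, int(left[-1]))
    if right.size:
        hi = max(hi, int(right[0]))
    return lo, hi


def _draw_dsb_positions(
    n: int,
    layout: GenomeLayout,
    hotspots: HotspotTrack | None,
    zones: dict[str, tuple[int, int]],
    w: float,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    chroms = layout.chromosomes
    lens = np.array([layout.length(c) for c in chroms], dtype=float)
    if hotspots is not None and len(hotspots):
        for c in hotspots.table["chrom"].unique():
            if c not in layout.lengths:
                raise ValidationError(f"hotspot chromosome {c!r} absent from layout")
        hs = hotspots.table
        hw = hs["hits"].to_numpy().astype(float)
        hw_total = hw.sum()
    else:
        hw_total = 0.0
    out: list[tuple[str, int]] = []
    for _ in range(n):
        for _try in range(1000):
            if hw_total > 0 and rng.random() < w:
                i = rng.choice(len(hs), p=hw / hw_total)
                chrom = hs["chrom"].iloc[i]
                pos = int(rng.integers(hs["start"].iloc[i], hs["end"].iloc[i] + 1))
            else:
                ci = rng.choice(len(chroms), p=lens / lens.sum())
                chrom = chroms[ci]
                pos = int(rng.integers(1, layout.length(chrom) + 1))
            lo, hi = zones[chrom]
            if pos < lo or pos > hi:
                out.append((chrom, pos))
                break
        else:  # pragma: no cover - pathological zone covering the genome
            warnings.warn(f"could not place DSB outside suppression zones")
    return out


def _scan_truth_segments(
    cell: str,
    marker_map: MarkerMap,
    calls: np.ndarray,
) -> list[TruthSegment]:
    """Maximal homozygous runs over non-masked markers, from the truth side."""
    segments: list[TruthSegment] = []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        keep = ~marker_map.masked(chrom)
        if not keep.any():
            continue
        pos = marker_map.positions(chrom)[keep]
        g = calls[sl][keep]
        hom = g > 0  # HOM_P1 or HOM_P2
        if not hom.any():
            continue
        # run boundaries where hom-status or parent changes
        change = np.flatnonzero(np.r_[True, (g[1:] != g[:-1]), True])
        for a, b in zip(change[:-1], change[1:]):
            if g[a] <= 0:
                continue
            segments.append(
                TruthSegment(
                    cell=cell,
                    chrom=chrom,
                    parent=int(g[a]),
                    first=int(pos[a]),
                    last=int(pos[b - 1]),
                    n_markers=int(b - a),
                    terminal=bool(a == 0 or b == g.size),
                )
            )
    return segments


def simulate_rtg_pair(
    marker_map: MarkerMap,
    hotspots: HotspotTrack | None,
    layout: GenomeLayout,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    clone_prefix: str = "rtg",
) -> RTGPair:
    """Simulate one RTG mother/daughter pair under ``config``.

    Returns the two genotype tracks plus ground truth: the resolved DSB
    events, the per-cell homozygous marker runs they imply, and the marker
    indices left non-reciprocal by conversion tracts.
    """
    if len(marker_map) == 0 and config.dsb_rate > 0:
        raise ValidationError("empty marker map with dsb_rate > 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rho = config.effective_rho

    zones = {
        c: _suppression_zone(layout, marker_map, c, config.cen_radius)
        for c in layout.chromosomes
    }
    # chromatid allele arrays: rows 0,1 carry the P1 haplotype/centromere,
    # rows 2,3 the P2 haplotype; entry is 0 (P1 allele) or 1 (P2 allele).
    chromatids: dict[str, np.ndarray] = {}
    for chrom in layout.chromosomes:
        m = marker_map.positions(chrom).size
        arr = np.zeros((4, m), dtype=np.int8)
        arr[2:, :] = 1
        chromatids[chrom] = arr

    n_dsb = rng.poisson(config.dsb_rate)
    events: list[TruthEvent] = []
    for chrom, x in _draw_dsb_positions(
        n_dsb, layout, hotspots, zones, config.hotspot_weight, rng
    ):
        pos = marker_map.positions(chrom)
        cs, ce = layout.centromere(chrom)
        left_arm = x < cs
        # repair tract, growing distally (away from the centromere)
        tract_len = int(rng.geometric(1.0 / config.tract_mean))
        if left_arm:
            t_lo, t_hi = max(1, x - tract_len + 1), x
        else:
            t_lo, t_hi = x, min(layout.length(chrom), x + tract_len - 1)
        in_tract = (pos >= t_lo) & (pos <= t_hi)
        mismatches = int(in_tract.sum())
        if rho > 0 and rng.random() > (1.0 - rho) ** mismatches:
            continue  # heteroduplex rejected: anti-recombination
        arr = chromatids[chrom]
        a = int(rng.integers(0, 2))  # chromatid carrying the P1 centromere
        b = int(rng.integers(2, 4))  # chromatid carrying the P2 centromere
        if rng.random() < config.p_co:
            distal = (pos <= x) if left_arm else (pos >= x)
            tmp = arr[a, distal].copy()
            arr[a, distal] = arr[b, distal]
            arr[b, distal] = tmp
            events.append(TruthEvent(chrom, "CO", x, (a, b), None))
        else:
            donor, recipient = (a, b) if rng.random() < 0.5 else (b, a)
            arr[recipient, in_tract] = arr[donor, in_tract]
            events.append(
                TruthEvent(chrom, "NCO", x, (donor, recipient), (t_lo, t_hi))
            )

    # mitotic-like 2+2 segregation: each cell keeps one centromere per homolog
    mother_calls = np.empty(len(marker_map), dtype=np.int8)
    daughter_calls = np.empty(len(marker_map), dtype=np.int8)
    nco_unbalanced: list[np.ndarray] = []
    for chrom in layout.chromosomes:
        sl = marker_map.chrom_slice(chrom)
        arr = chromatids[chrom]
        mi = int(rng.integers(0, 2))
        mj = int(rng.integers(2, 4))
        di, dj = 1 - mi, 5 - mj
        mother_calls[sl] = _genotype(arr[mi], arr[mj])
        daughter_calls[sl] = _genotype(arr[di], arr[dj])
        dosage = arr.sum(axis=0)  # P2-allele count over the 4 chromatids
        idx = np.flatnonzero(dosage != 2) + sl.start
        if idx.size:
            nco_unbalanced.append(idx)

    mother = GenotypeTrack(f"{clone_prefix}_mother", mother_calls)
    daughter = GenotypeTrack(f"{clone_prefix}_daughter", daughter_calls)
    truth = _scan_truth_segments("mother", marker_map, mother_calls)
    truth += _scan_truth_segments("daughter", marker_map, daughter_calls)
    return RTGPair(
        mother=mother,
        daughter=daughter,
        events=events,
        truth_segments=truth,
        nco_marker_indices=(
            np.concatenate(nco_unbalanced) if nco_unbalanced else np.empty(0, dtype=int)
        ),
    )


def _genotype(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    out = np.full(u.shape, HET, dtype=np.int8)
    out[(u == 0) & (v == 0)] = HOM_P1
    out[(u == 1) & (v == 1)] = HOM_P2
    return out


def simulate_rtg_pairs(
    n_pairs: int,
    marker_map: MarkerMap,
    hotspots: HotspotTrack | None,
    layout: GenomeLayout,
    config: SimulationConfig,
) -> list[RTGPair]:
    """Simulate a population of pairs; clone index is mixed into the RNG
    stream so each pair is reproducible independently of the others."""
    pairs = []
    for i in range(n_pairs):
        rng = np.random.default_rng([config.seed, i])
        pairs.append(
            simulate_rtg_pair(
                marker_map, hotspots, layout, config, rng=rng, clone_prefix=f"rtg{i:03d}"
            )
        )
    return pairs


def simulate_mitotic_track(
    marker_map: MarkerMap,
    layout: GenomeLayout,
    rate: float,
    generations: int,
    seed: int | np.random.Generator = 0,
    tract_mean: float = 2_000.0,
    clone: str = "t0",
) -> GenotypeTrack:
    """Background mitotic LOH control (a T0 clone).

    Events arrive Poisson with mean ``rate * generations`` per genome,
    uniformly placed; extents follow the conversion-tract distribution.
    """
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = np.full(len(marker_map), HET, dtype=np.int8)
    n = rng.poisson(rate * generations)
    chroms = layout.chromosomes
    lens = np.array([layout.length(c) for c in chroms], dtype=float)
    for _ in range(n):
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        chrom = chroms[ci]
        x = int(rng.integers(1, layout.length(chrom) + 1))
        tract = int(rng.geometric(1.0 / tract_mean))
        parent = HOM_P1 if rng.random() < 0.5 else HOM_P2
        pos = marker_map.positions(chrom)
        sl = marker_map.chrom_slice(chrom)
        hit = (pos >= x) & (pos <= x + tract - 1)
        calls[sl.start : sl.stop][hit] = parent
    return GenotypeTrack(clone, calls)


def simulate_phenotypes(
    tracks: Sequence[GenotypeTrack],
    marker_map: MarkerMap,
    qtl: Sequence[tuple[tuple[str, int], float, int]],
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    environment: str = "env1",
) -> pd.DataFrame:
    """Phenotypes with planted QTL effects.

    ``qtl`` entries are ((chrom, pos), effect, homozygous_parent): a clone
    gains ``effect`` when homozygous for that parent at the marker.
    Returns a tidy frame (clone, environment, phenotype).
    """
    key = marker_map.table.set_index(["chrom", "pos"]).index
    idx = []
    for (chrom, pos), _, parent in qtl:
        try:
            idx.append(key.get_loc((chrom, pos)))
        except KeyError:
            raise ValidationError(f"QTL marker {chrom}:{pos} not in map") from None
        if parent not in (HOM_P1, HOM_P2):
            raise ValidationError("QTL direction must be HOM_P1 or HOM_P2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for track in tracks:
        track.check_against(marker_map)
        value = 0.0
        for j, ((_, _), effect, parent) in zip(idx, qtl):
            if track.calls[j] == parent:
                value += effect
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        rows.append({"clone": track.clone, "environment": environment, "phenotype": value})
    return pd.DataFrame(rows)
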