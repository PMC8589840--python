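"""Domain types, genome layout and tabular/interval I/O.

Coordinate convention: all internal coordinates are 1-based inclusive.
BED files (0-based half-open on disk) are converted at the I/O boundary,
so an on-disk record ``chrII 0 100`` becomes the internal interval
``[1, 100]`` of length 100. Strand is ignored throughout: every input is
treated as an unstranded genomic interval.

Genotype calls are encoded as small integers (:data:`HET`, :data:`HOM_P1`,
:data:`HOM_P2`, :data:`MISSING`) and serialised as the corresponding string
labels in TSV files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HET",
    "HOM_P1",
    "HOM_P2",
    "MISSING",
    "GENOTYPE_LABELS",
    "GenomeLayout",
    "MarkerMap",
    "GenotypeTrack",
    "HotspotTrack",
    "read_layout",
    "write_layout",
    "read_marker_map",
    "write_marker_map",
    "apply_masks",
    "read_intervals",
    "write_intervals",
    "read_genotype_track",
    "write_genotype_track",
]

# Genotype call codes. MISSING is negative so that "is a call" is `code >= 0`.
HET: int = 0
HOM_P1: int = 1
HOM_P2: int = 2
MISSING: int = -1

GENOTYPE_LABELS: dict[int, str] = {
    HET: "HET",
    HOM_P1: "HOM_P1",
    HOM_P2: "HOM_P2",
    MISSING: "MISSING",
}
_LABEL_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths, centromere intervals and subtelomere masks.

    Parameters
    ----------
    lengths
        chromosome name -> length in bp.
    centromeres
        chromosome name -> (start, end), 1-based inclusive.
    mask_left, mask_right
        chromosome name -> masked bp at the left / right chromosome end.
        Markers within these distances of a chromosome end are excluded
        from LOH calling and terminal-extent determination.
    """

    lengths: Mapping[str, int]
    centromeres: Mapping[str, tuple[int, int]]
    mask_left: Mapping[str, int] = field(default_factory=dict)
    mask_right: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"{chrom}: non-positive length {length}")
            cs, ce = self.centromeres.get(chrom, (0, 0))
            if not (1 <= cs <= ce <= length):
                raise ValidationError(
                    f"{chrom}: centromere [{cs}, {ce}] outside [1, {length}]"
                )
            ml = self.mask_left.get(chrom, 0)
            mr = self.mask_right.get(chrom, 0)
            if ml < 0 or mr < 0 or ml + mr >= length:
                raise ValidationError(
                    f"{chrom}: invalid masks left={ml} right={mr} for length {length}"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def length(self, chrom: str) -> int:
        return int(self.lengths[chrom])

    def centromere(self, chrom: str) -> tuple[int, int]:
        return tuple(self.centromeres[chrom])

    def masks(self, chrom: str) -> tuple[int, int]:
        return int(self.mask_left.get(chrom, 0)), int(self.mask_right.get(chrom, 0))

    def total_length(self) -> int:
        return int(sum(self.lengths.values()))


class MarkerMap:
    """Ordered biallelic marker positions separating the parental subgenomes.

    Thin wrapper around a DataFrame with columns ``chrom, pos, allele1,
    allele2, masked``, sorted by (chrom, pos). Positions are strictly
    increasing within a chromosome and every marker is biallelic.
    """

    COLUMNS = ("chrom", "pos", "allele1", "allele2", "masked")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "masked" not in df.columns:
            df["masked"] = False
        missing = [c for c in ("chrom", "pos", "allele1", "allele2") if c not in df.columns]
        if missing:
            raise ValidationError(f"marker table lacks columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)]
        df["pos"] = df["pos"].astype(np.int64)
        df["masked"] = df["masked"].astype(bool)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(["chrom", "pos"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate marker position {row['chrom']}:{row['pos']}"
            )
        same = df["allele1"].astype(str) == df["allele2"].astype(str)
        if same.any():
            row = df[same].iloc[0]
            raise ValidationError(
                f"non-biallelic marker at {row['chrom']}:{row['pos']} "
                f"(allele1 == allele2 == {row['allele1']})"
            )
        if len(df) == 0:
            warnings.warn("empty marker map", stacklevel=2)
        self.table = df
        # chromosome -> positional slice into the sorted table
        self._slices: dict[str, slice] = {}
        if len(df):
            chroms = df["chrom"].to_numpy()
            bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1], True])
            for i in range(len(bounds) - 1):
                self._slices[chroms[bounds[i]]] = slice(bounds[i], bounds[i + 1])

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerMap) and self.table.equals(other.table)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        """Positional slice of this chromosome's markers in the sorted table."""
        return self._slices.get(chrom, slice(0, 0))

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return self.table["pos"].to_numpy()
        return self.table["pos"].to_numpy()[self.chrom_slice(chrom)]

    def masked(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            return self.table["masked"].to_numpy()
        return self.table["masked"].to_numpy()[self.chrom_slice(chrom)]

    def n_unmasked(self) -> int:
        return int((~self.table["masked"]).sum())


@dataclass
class GenotypeTrack:
    """Per-clone genotype call at every marker of an associated map.

    ``calls`` is an int8 array aligned to the marker map row order; MISSING
    calls are carried through and never imputed.
    """

    clone: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = ~np.isin(self.calls, [HET, HOM_P1, HOM_P2, MISSING])
        if bad.any():
            raise ValidationError(
                f"clone {self.clone}: invalid genotype code {self.calls[bad][0]}"
            )

    def check_against(self, marker_map: MarkerMap) -> None:
        if len(self.calls) != len(marker_map):
            raise ValidationError(
                f"clone {self.clone}: {len(self.calls)} calls for "
                f"{len(marker_map)} markers"
            )


class HotspotTrack:
    """Genomic intervals with Spo11 DSB intensity hits H.

    Internal coordinates are 1-based inclusive; ``hits`` is the mapped hit
    count of the interval (dimensionless, >= 0).
    """

    COLUMNS = ("chrom", "start", "end", "hits")

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        if "hits" not in df.columns:
            df["hits"] = 1.0
        df = df.loc[:, list(self.COLUMNS)]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["hits"] = df["hits"].astype(float)
        if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
            raise ValidationError("interval with start < 1 or end < start")
        if (df["hits"] < 0).any():
            raise ValidationError("negative intensity hits")
        self.table = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.table)

    def lengths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"] + 1).to_numpy()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_layout(path: str | Path) -> GenomeLayout:
    """Read a genome layout TSV: chrom, length, cen_start, cen_end, mask_left, mask_right."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "cen_start", "cen_end"}
    if not required.issubset(df.columns):
        raise ValidationError(f"layout file lacks columns {required - set(df.columns)}")
    for col in ("mask_left", "mask_right"):
        if col not in df.columns:
            df[col] = 0
    return GenomeLayout(
        lengths={r.chrom: int(r.length) for r in df.itertuples()},
        centromeres={r.chrom: (int(r.cen_start), int(r.cen_end)) for r in df.itertuples()},
        mask_left={r.chrom: int(r.mask_left) for r in df.itertuples()},
        mask_right={r.chrom: int(r.mask_right) for r in df.itertuples()},
    )


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    rows = [
        {
            "chrom": c,
            "length": layout.length(c),
            "cen_start": layout.centromere(c)[0],
            "cen_end": layout.centromere(c)[1],
            "mask_left": layout.masks(c)[0],
            "mask_right": layout.masks(c)[1],
        }
        for c in layout.chromosomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker map TSV (chrom, pos, allele1, allele2 [, masked])."""
    df = pd.read_csv(path, sep="\t")
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def apply_masks(marker_map: MarkerMap, layout: GenomeLayout) -> MarkerMap:
    """Flag markers lying within a subtelomeric mask distance of a chromosome end.

    Masked markers are retained in the table but excluded from LOH calling
    and from terminal-extent determination. Idempotent.
    """
    df = marker_map.table.copy()
    masked = np.zeros(len(df), dtype=bool)
    for chrom in marker_map.chromosomes:
        if chrom not in layout.lengths:
            raise ValidationError(f"marker chromosome {chrom!r} absent from layout")
        sl = marker_map.chrom_slice(chrom)
        pos = marker_map.positions(chrom)
        ml, mr = layout.masks(chrom)
        length = layout.length(chrom)
        masked[sl] = (pos <= ml) | (pos > length - mr)
    df["masked"] = masked
    return MarkerMap(df)


def read_intervals(path: str | Path, score_column: int | None = 5) -> HotspotTrack:
    """Read a BED3+ file into a :class:`HotspotTrack`.

    On-disk coordinates are 0-based half-open and converted to the internal
    1-based inclusive convention. ``score_column`` (1-based column index,
    default 5) is parsed as the intensity hits H when present; rows without
    it get H = 1.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start0 < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate")
            if start0 >= end0:
                raise ValidationError(f"{path}:{lineno}: start >= end")
            hits = 1.0
            if score_column is not None and len(parts) >= score_column:
                try:
                    hits = float(parts[score_column - 1])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-numeric score column"
                    ) from exc
            rows.append({"chrom": chrom, "start": start0 + 1, "end": end0, "hits": hits})
    return HotspotTrack(pd.DataFrame(rows, columns=list(HotspotTrack.COLUMNS)))


def write_intervals(track: HotspotTrack, path: str | Path) -> None:
    """Write intervals as BED (0-based half-open) with hits in column 5."""
    with open(path, "w") as fh:
        for r in track.table.itertuples():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t.\t{r.hits:g}\n")


def read_genotype_track(path: str | Path, marker_map: MarkerMap, clone: str | None = None) -> GenotypeTrack:
    """Read a per-clone genotype TSV (chrom, pos, genotype) aligned to ``marker_map``."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if len(df) != len(marker_map):
        raise ValidationError(
            f"{path}: {len(df)} genotype rows for {len(marker_map)} markers"
        )
    if not (
        (df["chrom"].to_numpy() == marker_map.table["chrom"].to_numpy()).all()
        and (df["pos"].to_numpy() == marker_map.table["pos"].to_numpy()).all()
    ):
        raise ValidationError(f"{path}: marker coordinates do not match the map")
    try:
        calls = df["genotype"].map(_LABEL_CODES).astype(np.int8).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unknown genotype label") from exc
    return GenotypeTrack(clone or Path(path).stem, calls)


def write_genotype_track(
    track: GenotypeTrack, marker_map: MarkerMap, path: str | Path
) -> None:
    track.check_against(marker_map)
    out = marker_map.table[["chrom", "pos"]].copy()
    out["genotype"] = [GENOTYPE_LABELS[int(c)] for c in track.calls]
    out.to_csv(path, sep="\t", index=False)
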