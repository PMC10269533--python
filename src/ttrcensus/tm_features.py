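"""Transmembrane-region geometry: detection, length, surface area, raft flag.

When TM segments are not supplied (TMHMM-style file), a sliding-window
Kyte–Doolittle hydropathy predictor provides them.  For every protein
with at least one TM region the module computes the pooled surface area
per residue (Å²/residue, residue-weighted over all TM residues) and a
raft-propensity flag: membrane proteins whose TM helix buries a small
surface area partition preferentially into liquid-ordered (lipid-raft)
membrane domains, and the census flags TM regions at or below a
threshold of 172 Å²/residue.

The per-residue area constants are a published maximum accessible
surface area scale rescaled by a single calibration factor so that a
designated anchor TM interval scores exactly the threshold value; see
:func:`calibrate_area_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .io_annotation import CANONICAL_RESIDUES, InputFormatError

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Theoretical maximum accessible surface area per residue, Å² (Tien et
#: al. 2013).  This is the base scale; the shipped table is this scale
#: times a calibration factor.
TIEN_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class TMRegion:
    """One membrane-spanning segment, 1-based inclusive coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad TM region {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TMParams:
    """Tunable constants of the TM predictor and the raft threshold.

    ``hydropathy_window`` (odd, residues) and ``hydropathy_threshold``
    control the sliding-window detector; ``min_region_length`` drops
    short candidate regions; ``merge_gap`` fuses regions separated by at
    most that many residues; ``raft_threshold`` is the surface-area
    cutoff in Å²/residue (inclusive).
    """

    hydropathy_window: int = 19
    hydropathy_threshold: float = 1.6
    min_region_length: int = 15
    merge_gap: int = 3
    raft_threshold: float = 172.0

    def __post_init__(self) -> None:
        if self.hydropathy_window < 5 or self.hydropathy_window % 2 == 0:
            raise ValueError("hydropathy_window must be odd and >= 5")
        if self.raft_threshold <= 0:
            raise ValueError("raft_threshold must be positive")


class AreaTable:
    """Per-residue surface-area constants (Å²) for the 20 canonical
    residues, with the mean of the 20 as the fallback for X."""

    def __init__(self, values: dict, calibration_factor: float = 1.0):
        missing = set(CANONICAL_RESIDUES) - set(values)
        if missing:
            raise ValueError(f"area table missing residues: {sorted(missing)}")
        if any(v <= 0 for v in values.values()):
            raise ValueError("area table constants must all be positive")
        self._values = {aa: float(values[aa]) for aa in CANONICAL_RESIDUES}
        self._values["X"] = sum(self._values.values()) / 20.0
        self.calibration_factor = float(calibration_factor)

    def __getitem__(self, residue: str) -> float:
        return self._values[residue]

    def min(self) -> float:
        return min(self._values[aa] for aa in CANONICAL_RESIDUES)

    def max(self) -> float:
        return max(self._values[aa] for aa in CANONICAL_RESIDUES)

    def scaled(self, factor: float) -> "AreaTable":
        return AreaTable(
            {aa: self._values[aa] * factor for aa in CANONICAL_RESIDUES},
            calibration_factor=self.calibration_factor * factor,
        )

    def as_dict(self) -> dict:
        return {aa: self._values[aa] for aa in CANONICAL_RESIDUES}

    @classmethod
    def base(cls) -> "AreaTable":
        """The uncalibrated published scale."""
        return cls(TIEN_MAX_ASA)

    @classmethod
    def from_yaml(cls, path) -> "AreaTable":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(cfg["areas"], calibration_factor=cfg.get("calibration_factor", 1.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "calibration_factor": self.calibration_factor,
                    "areas": {aa: float(v) for aa, v in self.as_dict().items()},
                },
                fh,
                sort_keys=True,
            )


@dataclass(frozen=True)
class TMProfile:
    """Aggregated TM geometry for one protein.

    ``sa_per_aa`` and ``raft_flag`` are ``None`` for proteins without TM
    regions.
    """

    n_regions: int
    regions: tuple
    mean_length: float | None
    sa_per_aa: float | None
    raft_flag: bool | None


# ---------------------------------------------------------------------------
# prediction


def predict_tm_regions(sequence: str, params: TMParams | None = None) -> list:
    """Predict TM regions with a sliding-window hydropathy rule.

    The mean Kyte–Doolittle hydropathy is computed at every position
    where a full window fits; maximal runs of window centers with mean at
    or above the threshold are expanded to full window extent, expanded
    regions separated by at most ``merge_gap`` residues are merged, and
    regions shorter than ``min_region_length`` are dropped.
    """
    if not sequence:
        raise ValueError("cannot predict TM regions for an empty sequence")
    params = params or TMParams()
    w = params.hydropathy_window
    n = len(sequence)
    if n < w:
        return []
    half = w // 2
    # the scale is in tenths, so integer window sums make the threshold
    # comparison exact (a window mean can equal the threshold precisely)
    tenths = np.array(
        [int(round(KYTE_DOOLITTLE[aa] * 10)) for aa in sequence], dtype=np.int64
    )
    window_sums = np.convolve(tenths, np.ones(w, dtype=np.int64), mode="valid")
    hot = window_sums >= params.hydropathy_threshold * 10 * w - 1e-9
    # maximal runs of hot centers, expanded to window extent (0-based)
    raw: list = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            raw.append([i, j + 2 * half])  # centers i..j span residues i..j+w-1
            i = j + 1
        else:
            i += 1
    merged: list = []
    for s, e in raw:
        if merged and s - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        TMRegion(start=s + 1, end=e + 1)
        for s, e in merged
        if e - s + 1 >= params.min_region_length
    ]


# ---------------------------------------------------------------------------
# geometry


def _check_regions(sequence: str, regions) -> None:
    for r in regions:
        if r.end > len(sequence):
            raise ValueError(
                f"TM region {r.start}..{r.end} exceeds sequence length {len(sequence)}"
            )


def surface_area_per_aa(sequence: str, regions, table: AreaTable) -> float:
    """Pooled surface area per TM residue (Å²/residue).

    All residues inside any region contribute equally, so the value is
    residue-weighted across regions (not a mean of per-region means).
    Independent of region order.
    """
    if not regions:
        raise ValueError("no TM residues: cannot compute surface area per residue")
    _check_regions(sequence, regions)
    total = 0.0
    n_res = 0
    for r in regions:
        for aa in sequence[r.start - 1 : r.end]:
            total += table[aa]
            n_res += 1
    return total / n_res


def raft_propensity(sa_per_aa: float, params: TMParams | None = None) -> bool:
    """True iff the surface area is at or below the raft threshold."""
    params = params or TMParams()
    if not np.isfinite(sa_per_aa):
        raise ValueError("surface area must be finite")
    return sa_per_aa <= params.raft_threshold


def tm_profile(
    sequence: str,
    regions,
    params: TMParams | None = None,
    table: AreaTable | None = None,
) -> TMProfile:
    """Aggregate TM count, mean length, surface area and raft flag."""
    params = params or TMParams()
    table = table or AreaTable.base()
    regions = tuple(sorted(regions, key=lambda r: r.start))
    _check_regions(sequence, regions)
    if not regions:
        return TMProfile(0, (), None, None, None)
    sa = surface_area_per_aa(sequence, regions, table)
    return TMProfile(
        n_regions=len(regions),
        regions=regions,
        mean_length=sum(r.length for r in regions) / len(regions),
        sa_per_aa=sa,
        raft_flag=raft_propensity(sa, params),
    )


# ---------------------------------------------------------------------------
# calibration


def calibration_factor(
    sequence: str, region: TMRegion, base_table: AreaTable, target: float = 172.0
) -> float:
    """Multiplicative factor scaling ``base_table`` so that the anchor
    interval scores exactly ``target`` Å²/residue."""
    raw = surface_area_per_aa(sequence, [region], base_table)
    return target / raw


def calibrate_area_table(
    sequence: str,
    region: TMRegion,
    base_table: AreaTable | None = None,
    target: float = 172.0,
) -> AreaTable:
    """Rescale the base area table against a named anchor TM interval.

    Returns a new table whose calibration factor is recorded so output
    metadata can report it.
    """
    base_table = base_table or AreaTable.base()
    return base_table.scaled(calibration_factor(sequence, region, base_table, target))
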