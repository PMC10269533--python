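"""Shipped data resources: domain registry, area tables, calibration anchor.

The calibration anchor is a *synthetic* single-pass membrane-regulator
sequence (no public sequence is bundled); its fixed TM interval is the
reference against which the shipped area table is scaled so the interval
scores exactly 172 Å²/residue.  The calibration machinery itself is
general: any sequence plus TM interval can serve as the anchor via
:func:`ttrcensus.tm_features.calibrate_area_table`.
"""

from __future__ import annotations

from importlib import resources as _ir

from .io_annotation import load_registry, read_proteome_fasta
from .tm_features import AreaTable, TMRegion

#: TM interval of the synthetic calibration anchor (1-based inclusive).
ANCHOR_TM_START = 172
ANCHOR_TM_END = 194
ANCHOR_ID = "anchor_tm_synthetic"


def _data_path(name: str):
    return _ir.files("ttrcensus.data").joinpath(name)


def default_registry():
    """The shipped domain registry (editable YAML stand-in)."""
    with _ir.as_file(_data_path("registry.yaml")) as p:
        return load_registry(p)


def default_registry_path() -> str:
    with _ir.as_file(_data_path("registry.yaml")) as p:
        return str(p)


def load_anchor():
    """The synthetic calibration-anchor protein and its TM interval."""
    with _ir.as_file(_data_path("anchor_tm_synthetic.fasta")) as p:
        rec = read_proteome_fasta(p, default_genome_id="anchor")[0]
    return rec, TMRegion(start=ANCHOR_TM_START, end=ANCHOR_TM_END)


def default_area_table() -> AreaTable:
    """The vendored calibrated area table (anchor TM == 172 Å²/residue)."""
    with _ir.as_file(_data_path("area_table_calibrated.yaml")) as p:
        return AreaTable.from_yaml(p)


def default_area_table_path() -> str:
    with _ir.as_file(_data_path("area_table_calibrated.yaml")) as p:
        return str(p)
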