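"""Packaged field datasets: the published pooled pair-count tables.

Two association types were sampled in the hot season at Cape d'Aguilar
(Hong Kong) and pooled across four sites:

* trail-following pairs (marker → tracker) on rising and falling tides,
  for *Echinolittorina malaccana* and *E. radiata*;
* two-snail towers (bottom → top) before the rising and after the falling
  tide, for the same two species.

Combination keys always read role-1 sex then role-2 sex: for trails
``FM`` is a female marker followed by a male tracker; for towers ``FM``
is a female at the bottom with a male on top.  The *E. radiata*
falling-tide trail table is published without its FF row; the reader
infers FF = 33 from the declared total of 120 pairs and flags it.
"""

from __future__ import annotations

from importlib.resources import files

from .io import read_pairs
from .pairing import PairCountTable

__all__ = ["load_trail_pairs", "load_towers", "load_field_tables"]


def _load(name: str) -> dict[tuple[str, str], PairCountTable]:
    path = files("highshore").joinpath("data", name)
    return {(t.species, t.tide_phase): t for t in read_pairs(str(path))}


def load_trail_pairs() -> dict[tuple[str, str], PairCountTable]:
    """Trail-following pair tables keyed by (species, tide_phase)."""
    return _load("trail_pairs.csv")


def load_towers() -> dict[tuple[str, str], PairCountTable]:
    """Two-snail tower tables keyed by (species, tide_phase)."""
    return _load("towers.csv")


def load_field_tables() -> dict[tuple[str, str, str], PairCountTable]:
    """All eight tables keyed by (association_type, species, tide_phase)."""
    out = {}
    for tables in (load_trail_pairs(), load_towers()):
        for (species, phase), t in tables.items():
            out[(t.association_type, species, phase)] = t
    return out
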