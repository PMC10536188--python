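"""Structure-derived physicochemical descriptors.

Molecular weight and topological polar surface area (TPSA) computed from a
composition record: element counts plus counts of polar functional groups.
TPSA follows the Ertl fragment-contribution scheme, in which the polar
surface area is an additive sum of published per-fragment contributions for
O- and N-containing groups.  For oleanolic acid (C30H48O3; one carboxylic
acid, one hydroxyl) this yields MW = 456.7 g/mol and TPSA = 57.53 Å².

The input is deliberately a composition/group-count record, not a SMILES
string: automatic functional-group perception is out of scope, and any
perception layer (e.g. RDKit) can populate :class:`MoleculeComposition`
externally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("bbbkit.data").joinpath(name).read_text()
    table = json.loads(text)
    table.pop("_comment", None)
    return table


#: IUPAC 2021 conventional standard atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = _load_table("atomic_weights.json")

#: Ertl TPSA fragment contributions, Å², keyed by polar-group name.
ERTL_CONTRIBUTIONS: dict[str, float] = _load_table("ertl_tpsa.json")


class UnknownElementError(KeyError):
    """An element symbol without a packaged standard atomic weight."""


class UnknownGroupError(KeyError):
    """A polar-group name without a packaged Ertl contribution."""


@dataclass(frozen=True)
class MoleculeComposition:
    """Elemental formula plus polar-group counts of one molecule.

    ``element_counts`` holds the full elemental formula (hydrogens of polar
    groups included); ``polar_groups`` counts O/N-containing functional
    groups for the TPSA sum.  A carboxylic acid counts as a single group
    contributing both its carbonyl-type and hydroxyl-type oxygen to TPSA.

    Parameters
    ----------
    element_counts
        Map element symbol -> non-negative integer count.
    polar_groups
        Map group name (see :data:`ERTL_CONTRIBUTIONS`) -> count.
    """

    element_counts: Mapping[str, int]
    polar_groups: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table, kind in ((self.element_counts, "element"),
                            (self.polar_groups, "polar group")):
            for key, count in table.items():
                if int(count) != count or count < 0:
                    raise ValueError(
                        f"{kind} count for {key!r} must be a non-negative "
                        f"integer, got {count!r}")

    @classmethod
    def from_record(cls, record: Mapping) -> "MoleculeComposition":
        """Build from a JSON-like record ``{"elements": ..., "groups": ...}``."""
        return cls(element_counts=dict(record.get("elements", {})),
                   polar_groups=dict(record.get("groups", {})))


#: Oleanolic acid: pentacyclic triterpenoid C30H48O3 with one carboxylic
#: acid and one secondary hydroxyl group.
OLEANOLIC_ACID = MoleculeComposition(
    element_counts={"C": 30, "H": 48, "O": 3},
    polar_groups={"carboxylic_acid": 1, "hydroxyl": 1},
)


def molecular_weight(composition: MoleculeComposition) -> float:
    """Molecular weight in g/mol as the sum of standard atomic weights.

    Raises
    ------
    UnknownElementError
        If an element symbol has no packaged atomic weight.
    ValueError
        If the composition has no elements.
    """
    if not composition.element_counts:
        raise ValueError("element_counts is empty")
    total = 0.0
    for symbol, count in composition.element_counts.items():
        try:
            weight = ATOMIC_WEIGHTS[symbol]
        except KeyError:
            raise UnknownElementError(
                f"no standard atomic weight packaged for element {symbol!r}"
            ) from None
        total += count * weight
    return total


def tpsa_ertl(composition: MoleculeComposition) -> float:
    """Topological polar surface area in Å² (Ertl fragment sum).

    Pure hydrocarbons (no polar groups) return 0.  Only O- and N-containing
    contributions are packaged; an unknown group name raises
    :class:`UnknownGroupError`.
    """
    total = 0.0
    for group, count in composition.polar_groups.items():
        try:
            contribution = ERTL_CONTRIBUTIONS[group]
        except KeyError:
            raise UnknownGroupError(
                f"no Ertl TPSA contribution packaged for group {group!r}"
            ) from None
        total += count * contribution
    return total
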