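"""Electrode role assignment and the canonical comparison pairs.

Roles: AG (lowest-impedance retained gelled electrode, the primary
reference), AG2 (second gelled), MX-Near / MX-Far (retained dry channel
nearest / farthest from AG), MX-Neighbor (dry channel nearest MX-Near) and
the four array corners MX-Q1 (top right) through MX-Q4 (bottom right,
counter-clockwise).  When a role's natural channel was rejected, the next
closest retained dry channel substitutes.  Ties break by label sort order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ioformats import DRY, GELLED, ElectrodeLayout, ValidationError

__all__ = ["RoleError", "RoleAssignment", "PairTable", "assign_roles", "build_pairs", "pair_distances"]

ROLE_NAMES = ("AG", "AG2", "MX-Near", "MX-Neighbor", "MX-Far", "MX-Q1", "MX-Q2", "MX-Q3", "MX-Q4")

#: The six canonical similarity pairs (role, role).
CANONICAL_PAIRS = (
    ("AG", "AG2"),
    ("AG", "MX-Near"),
    ("AG", "MX-Far"),
    ("MX-Near", "MX-Neighbor"),
    ("MX-Q1", "MX-Q3"),
    ("MX-Q2", "MX-Q4"),
)

#: Extra event-related-potential comparison combining the two corner pairs
#: (both have the same inter-electrode distance).
ERP_CORNER_PAIRS = (("MX-Q1", "MX-Q3"), ("MX-Q2", "MX-Q4"))


class RoleError(ValidationError):
    """Role assignment impossible (no gelled channel, all dry rejected, ...)."""


@dataclass(frozen=True)
class RoleAssignment:
    """Mapping role -> channel label.  Roles may coincide when geometry forces it."""

    roles: dict

    def __getitem__(self, role: str) -> str:
        return self.roles[role]

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.roles, fh, indent=1)


@dataclass(frozen=True)
class PairTable:
    """Ordered canonical pairs resolved to channel labels, with distances (mm)."""

    pairs: tuple  # ((name, label_a, label_b, distance_mm), ...)
    erp_corner: tuple  # same structure, the combined-corner comparison

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": n, "a": a, "b": b, "distance_mm": d, "use": "similarity"}
            for n, a, b, d in self.pairs
        ] + [
            {"pair": n, "a": a, "b": b, "distance_mm": d, "use": "erp"}
            for n, a, b, d in self.erp_corner
        ]
        return pd.DataFrame(rows)

    def names(self) -> list[str]:
        return [p[0] for p in self.pairs]

    def get(self, name: str) -> tuple[str, str]:
        for n, a, b, _ in self.pairs + self.erp_corner:
            if n == name:
                return a, b
        raise KeyError(name)


def _nearest(
    target: np.ndarray, candidates: list, exclude: set[str] = frozenset()
) -> str:
    pool = [ch for ch in candidates if ch.label not in exclude]
    if not pool:
        raise RoleError("no retained dry channel available for role substitution")
    pool.sort(key=lambda ch: (float(np.linalg.norm(ch.position - target)), ch.label))
    return pool[0].label


def assign_roles(
    layout: ElectrodeLayout,
    impedance: dict | None = None,
    rejected: set | None = None,
) -> RoleAssignment:
    """Assign the canonical electrode roles.

    ``impedance`` maps gelled labels to kOhm (falls back to the layout's
    stored impedances, then to label order); ``rejected`` is the set of
    rejected channel labels from preprocessing.
    """
    rejected = set(rejected or ())
    gelled = [ch for ch in layout.of_kind(GELLED) if ch.label not in rejected]
    dry = [ch for ch in layout.of_kind(DRY) if ch.label not in rejected]
    if not gelled:
        raise RoleError("no retained gelled channel; cannot assign the primary reference")
    if len(dry) < 2:
        raise RoleError("need at least 2 retained dry channels")

    def imp(ch) -> float:
        if impedance and ch.label in impedance:
            return float(impedance[ch.label])
        if ch.impedance_kohm is not None:
            return float(ch.impedance_kohm)
        return np.inf

    gelled_sorted = sorted(gelled, key=lambda ch: (imp(ch), ch.label))
    roles: dict[str, str] = {"AG": gelled_sorted[0].label}
    if len(gelled_sorted) > 1:
        roles["AG2"] = gelled_sorted[1].label

    ag_pos = layout[roles["AG"]].position
    roles["MX-Near"] = _nearest(ag_pos, dry)
    # farthest: same tie-break discipline, inverted distance
    far = sorted(dry, key=lambda ch: (-float(np.linalg.norm(ch.position - ag_pos)), ch.label))
    roles["MX-Far"] = far[0].label
    near_pos = layout[roles["MX-Near"]].position
    roles["MX-Neighbor"] = _nearest(near_pos, dry, exclude={roles["MX-Near"]})

    # Corner roles: nearest retained dry channel to each extreme corner of the
    # full dry-grid bounding box (so rejected corners fall back gracefully).
    all_dry_pos = np.array([ch.position for ch in layout.of_kind(DRY)])
    x0, y0 = all_dry_pos.min(axis=0)
    x1, y1 = all_dry_pos.max(axis=0)
    corners = {
        "MX-Q1": np.array([x1, y1]),  # top right
        "MX-Q2": np.array([x0, y1]),  # top left
        "MX-Q3": np.array([x0, y0]),  # bottom left
        "MX-Q4": np.array([x1, y0]),  # bottom right
    }
    for role, corner in corners.items():
        roles[role] = _nearest(corner, dry)
    return RoleAssignment(roles)


def build_pairs(layout: ElectrodeLayout, roles: RoleAssignment) -> PairTable:
    """Resolve the canonical pairs to labels and center-to-center distances."""
    pairs = []
    for ra, rb in CANONICAL_PAIRS:
        if ra not in roles or rb not in roles:
            continue  # AG:AG2 absent without a second gelled channel
        a, b = roles[ra], roles[rb]
        d = layout.distance(a, b)
        if d == 0 and a != b:
            raise ValidationError(f"pair {ra}:{rb} has coincident electrodes {a}, {b}")
        pairs.append((f"{ra}:{rb}", a, b, d))
    erp = []
    for ra, rb in ERP_CORNER_PAIRS:
        a, b = roles[ra], roles[rb]
        erp.append((f"{ra}:{rb}", a, b, layout.distance(a, b)))
    return PairTable(pairs=tuple(pairs), erp_corner=tuple(erp))


def pair_distances(table: PairTable) -> dict:
    """Center-to-center distance (mm) per canonical pair name."""
    return {name: d for name, _, _, d in table.pairs + table.erp_corner}
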