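"""Tree crown polygons keyed to tree identifiers with measured traits."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from shapely.geometry import Polygon


@dataclass
class CrownSet:
    """Crown polygons plus the per-tree foliar trait table.

    ``traits`` is indexed by ``tree_id`` and holds one column per trait
    (N %, P %, N:P, SLA mm2/mg by default).  ``deviations``, when present,
    records the tree-level deviation of each crown's trait from the
    underlying trait surface — bookkeeping used by the synthetic
    generator so tests can verify the sampling model.
    """

    polygons: dict[str, Polygon]
    traits: pd.DataFrame
    deviations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.traits.index.name != "tree_id":
            raise ValueError("traits must be indexed by 'tree_id'")
        missing = set(self.polygons) ^ set(self.traits.index)
        if missing:
            raise ValueError(f"polygon / trait table tree_id mismatch: {sorted(missing)}")
        for tid, poly in self.polygons.items():
            if poly.is_empty or poly.area <= 0:
                raise ValueError(f"degenerate crown polygon for tree {tid!r}")

    @property
    def tree_ids(self) -> list[str]:
        return sorted(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.traits.columns:
            raise KeyError(f"trait {trait!r} not in crown trait table")
        return self.traits[trait]

    def total_overlap_area(self) -> float:
        """Summed pairwise intersection area between distinct crowns (m^2)."""
        ids = self.tree_ids
        total = 0.0
        for i, a in enumerate(ids):
            pa = self.polygons[a]
            for b in ids[i + 1:]:
                total += pa.intersection(self.polygons[b]).area
        return total
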