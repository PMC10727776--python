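"""Region atlas and zone bookkeeping.

The analyses operate on a small limbic subnetwork split into two zones:
a ventral "Zone I" (temporal pole, parahippocampal gyrus, hippocampus,
amygdala; bilateral) and a dorsal "Zone II" (anterior, medial and posterior
cingulate cortices; bilateral). Link, trimer and tetramer statistics are
classified by the zone membership of the regions involved, so the atlas is
threaded through every downstream module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZoneAtlas",
    "default_limbic_atlas",
    "link_index",
    "link_pairs",
    "classify_link",
    "classify_trimer",
    "classify_tetramer",
]


@dataclass(frozen=True)
class ZoneAtlas:
    """Ordered region list with a two-zone partition.

    Parameters
    ----------
    region_names
        Ordered region labels; downstream matrices follow this order.
    zone
        Per-region zone label, ``"I"`` or ``"II"``.
    hemisphere
        Per-region hemisphere label, ``"L"``, ``"R"`` or ``"none"``.
    """

    region_names: tuple[str, ...]
    zone: tuple[str, ...]
    hemisphere: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.region_names) != len(self.zone):
            raise ValueError("region_names and zone must have equal length")
        if not set(self.zone) <= {"I", "II"}:
            raise ValueError(f"zone labels must be 'I' or 'II', got {set(self.zone)}")
        if self.hemisphere and len(self.hemisphere) != len(self.region_names):
            raise ValueError("hemisphere must match region_names in length")
        if not self.hemisphere:
            object.__setattr__(
                self, "hemisphere", tuple("none" for _ in self.region_names)
            )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_links(self) -> int:
        n = self.n_regions
        return n * (n - 1) // 2

    def zone_indices(self, which: str) -> np.ndarray:
        """Integer indices of regions in zone ``which`` ('I' or 'II')."""
        return np.array([i for i, z in enumerate(self.zone) if z == which], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_names,
                "zone": self.zone,
                "hemisphere": self.hemisphere,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZoneAtlas":
        return cls(
            region_names=tuple(df["region"].astype(str)),
            zone=tuple(df["zone"].astype(str)),
            hemisphere=tuple(df.get("hemisphere", pd.Series(["none"] * len(df))).astype(str)),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ZoneAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


_ZONE1_STEMS = ["TPOsup", "TPOmid", "PHG", "HIP", "AMYG"]
_ZONE2_STEMS = ["ACC", "MCC", "PCC"]


def default_limbic_atlas() -> ZoneAtlas:
    """16-region bilateral limbic atlas: 10 Zone-I and 6 Zone-II regions."""
    names, zones, hemis = [], [], []
    for stem in _ZONE1_STEMS:
        for h in ("L", "R"):
            names.append(f"{stem}.{h}")
            zones.append("I")
            hemis.append(h)
    for stem in _ZONE2_STEMS:
        for h in ("L", "R"):
            names.append(f"{stem}.{h}")
            zones.append("II")
            hemis.append(h)
    return ZoneAtlas(tuple(names), tuple(zones), tuple(hemis))


def link_pairs(n: int) -> np.ndarray:
    """(l, 2) array of region index pairs (i < j) in link-id order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def link_index(n: int) -> dict[tuple[int, int], int]:
    """Map unordered region pair (i < j) -> link id in 0..l-1."""
    return {(int(i), int(j)): k for k, (i, j) in enumerate(link_pairs(n))}


def classify_link(atlas: ZoneAtlas, i: int, j: int) -> str:
    """'intrazone' if both regions share a zone, else 'interzone'."""
    return "intrazone" if atlas.zone[i] == atlas.zone[j] else "interzone"


def zone_class_per_link(atlas: ZoneAtlas) -> np.ndarray:
    """Per-link fine class: 'intra-I', 'intra-II' or 'inter'."""
    out = []
    for i, j in link_pairs(atlas.n_regions):
        zi, zj = atlas.zone[i], atlas.zone[j]
        out.append(f"intra-{zi}" if zi == zj else "inter")
    return np.array(out)


def classify_trimer(atlas: ZoneAtlas, root: int, leaf_a: int, leaf_b: int) -> str:
    """Trimer class by leaf/root zones.

    - ``within-zone``: root and both leaves in the same zone;
    - ``leaves-same-zone``: both leaves share a zone different from the root's;
    - ``leaves-two-zones``: leaves in different zones.
    """
    zr, za, zb = atlas.zone[root], atlas.zone[leaf_a], atlas.zone[leaf_b]
    if za != zb:
        return "leaves-two-zones"
    return "within-zone" if za == zr else "leaves-same-zone"


def classify_tetramer(atlas: ZoneAtlas, base: tuple[int, int], partner: tuple[int, int]) -> str | None:
    """Tetramer class: both links intrazone -> 'base-within-zone'; both
    interzone -> 'base-between-zones'; mixed combinations return None
    (excluded from the class tables)."""
    c1 = classify_link(atlas, *base)
    c2 = classify_link(atlas, *partner)
    if c1 == "intrazone" and c2 == "intrazone":
        return "base-within-zone"
    if c1 == "interzone" and c2 == "interzone":
        return "base-between-zones"
    return None
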