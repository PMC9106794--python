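"""Region sets: the node labels of every network in the package.

The default parcellation covers 18 whole-body regions: 11 organ ROIs
(including the whole brain) plus 7 brain sub-regions, which yields
18*(18-1)/2 = 153 undirected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORGAN_REGIONS: tuple[str, ...] = (
    "brain",
    "left_ventricle",
    "lung",
    "liver",
    "pancreas",
    "spleen",
    "kidney_left",
    "kidney_right",
    "muscle",
    "spine",
    "blood",
)

BRAIN_SUBREGIONS: tuple[str, ...] = (
    "brainstem",
    "cerebellum",
    "csf",
    "white_matter",
    "caudate",
    "putamen",
    "frontal_cortex",
)

DEFAULT_REGIONS: tuple[str, ...] = ORGAN_REGIONS + BRAIN_SUBREGIONS


@dataclass(frozen=True)
class RegionSet:
    """An ordered, immutable collection of unique region labels.

    Parameters
    ----------
    names
        Region labels in canonical order. Must be unique, non-empty and
        at least three (a correlation network needs >= 3 nodes).
    """

    names: tuple[str, ...] = field(default=DEFAULT_REGIONS)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 3:
            raise ValueError(f"need at least 3 regions, got {len(names)}")
        if any(not n for n in names):
            raise ValueError("region labels must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")

    @property
    def m(self) -> int:
        """Number of regions M."""
        return len(self.names)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges, M*(M-1)/2."""
        return self.m * (self.m - 1) // 2

    def __len__(self) -> int:
        return self.m

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, label: str) -> bool:
        return label in self.names

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"unknown region {label!r}") from None

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Unordered region pairs in canonical (row-major upper-triangle) order."""
        iu, ju = np.triu_indices(self.m, k=1)
        return [(self.names[i], self.names[j]) for i, j in zip(iu, ju)]


def default_region_set() -> RegionSet:
    """The 18-region whole-body parcellation used throughout."""
    return RegionSet(DEFAULT_REGIONS)
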