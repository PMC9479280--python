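"""Fixed ROI membership of the fronto-parietal and default-mode networks.

The two networks are encoded as ordered lists of bilateral anatomical
regions (LPBA40-style gray-matter parcels): the fronto-parietal /
central-executive network (FPN) has 11 regions, the default-mode network
(DMN) has 12.  Each region contributes a left and a right column, so the
analysis matrices have 22 (FPN) and 24 (DMN) columns.  The precuneus, the
angular gyrus and the prefrontal segment of the superior frontal gyrus
belong to both networks.

Membership ships as a versioned, human-readable CSV fixture
(``data/network_rois.csv``, one row per region x hemisphere x network);
``load_network_spec`` reads it verbatim and never recomputes anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["HEMISPHERES", "NetworkSpec", "load_network_spec", "network_union_columns"]

HEMISPHERES: tuple[str, str] = ("left", "right")

_VALID_NETWORKS = ("FPN", "DMN")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered ROI membership of one brain network.

    ``regions`` are region slugs (snake_case); ``columns`` interleaves
    hemispheres in region order: ``<region>_left, <region>_right, ...``.
    ``display_names`` maps slugs to the anatomical names used in reports.
    """

    name: str
    regions: tuple[str, ...]
    display_names: dict[str, str] = field(repr=False)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(f"{r}_{h}" for r in self.regions for h in HEMISPHERES)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError(f"duplicate regions in network {self.name}")


def _fixture_table() -> pd.DataFrame:
    with resources.files("netmdmr.data").joinpath("network_rois.csv").open() as fh:
        return pd.read_csv(fh)


def load_network_spec(name: str) -> NetworkSpec:
    """Return the ROI membership fixture for ``name`` ('FPN' or 'DMN')."""
    key = str(name).upper()
    if key not in _VALID_NETWORKS:
        raise ValueError(f"unknown network {name!r}; expected one of {_VALID_NETWORKS}")
    tab = _fixture_table()
    sub = tab[tab["network"] == key]
    regions = tuple(dict.fromkeys(sub["region"]))  # preserves fixture order
    display = dict(zip(sub["region"], sub["display_name"]))
    return NetworkSpec(name=key, regions=regions, display_names=display)


def network_union_columns() -> tuple[str, ...]:
    """All distinct region x hemisphere columns across both networks.

    FPN columns first (in FPN order), then DMN columns not already present.
    Shared regions (precuneus, angular gyrus, prefrontal superior frontal
    gyrus) appear once.  This is the column schema the synthetic cohort
    generator emits.
    """
    cols = list(load_network_spec("FPN").columns)
    for c in load_network_spec("DMN").columns:
        if c not in cols:
            cols.append(c)
    return tuple(cols)
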