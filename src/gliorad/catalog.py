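"""The 489-entry radiomic feature catalog.

The default catalog enumerates, in a fixed documented order:

========== ================================================== =====
family     breakdown                                          count
========== ================================================== =====
firstorder 7 stats x 5 channels x 2 VOIs                        70
GLCM       5 stats x offsets {1,2,3} x {mean,SD} x 10 combos   300
GLRLM      10 direction-averaged stats x 10 combos             100
shape      7 descriptors x 2 VOIs                               14
location   5 atlas-region occupancy rates (core VOI)             5
total                                                          489
========== ================================================== =====

Names follow ``{channel}_{voi}_{family}{stat}[_{offset}_{agg}]``; the
spelling ``homogeniety`` is preserved verbatim for catalog compatibility
with the published feature names (e.g. ``T2_core_GLCMhomogeniety_3_SD``).
The breakdown is reconstructed to this total and is swappable via
:class:`CatalogConfig`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd

from .preprocess import CHANNELS, VOIS
from .texture import GLCM_STATS, GLRLM_STATS

FIRSTORDER_STATS = ("mean", "SD", "median", "skewness", "kurtosis", "energy", "entropy")
SHAPE_STATS = (
    "volume",
    "surface",
    "sphericity",
    "compactness",
    "elongation",
    "flatness",
    "maxdiameter",
)
DEFAULT_GLCM_OFFSETS = (1, 2, 3)
GLCM_AGGS = ("mean", "SD")
DEFAULT_N_LOCATION_REGIONS = 5


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: channel x VOI x family plus family parameters."""

    name: str
    family: str  # firstorder | GLCM | GLRLM | shape | location
    channel: str | None = None
    voi: str | None = None
    stat: str | None = None
    offset: int | None = None
    agg: str | None = None
    region: int | None = None


@dataclass
class CatalogConfig:
    channels: tuple[str, ...] = CHANNELS
    vois: tuple[str, ...] = VOIS
    glcm_offsets: tuple[int, ...] = DEFAULT_GLCM_OFFSETS
    n_location_regions: int = DEFAULT_N_LOCATION_REGIONS
    strict_count: int | None = 489  # None disables the count check


@dataclass
class FeatureCatalog:
    """Ordered registry of feature specifications."""

    specs: list[FeatureSpec]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    def content_hash(self) -> str:
        """Stable hash of the ordered names, embedded in tables and models."""
        h = hashlib.sha256("\n".join(self.names).encode())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        """Data-dictionary view (name, family, params) for TSV export."""
        return pd.DataFrame(
            {
                "name": self.names,
                "family": [s.family for s in self.specs],
                "channel": [s.channel or "" for s in self.specs],
                "voi": [s.voi or "" for s in self.specs],
                "stat": [s.stat or "" for s in self.specs],
                "offset": [s.offset if s.offset is not None else "" for s in self.specs],
                "agg": [s.agg or "" for s in self.specs],
                "region": [s.region if s.region is not None else "" for s in self.specs],
            }
        )


class CatalogError(ValueError):
    """Raised for a catalog configuration that violates its contract."""


def build_catalog(config: CatalogConfig | None = None) -> FeatureCatalog:
    """Enumerate the default 489-feature catalog in stable order.

    Raises :class:`CatalogError` if ``config.strict_count`` is set and the
    configured breakdown does not total it.
    """
    cfg = config or CatalogConfig()
    specs: list[FeatureSpec] = []
    for ch in cfg.channels:
        for voi in cfg.vois:
            for stat in FIRSTORDER_STATS:
                specs.append(
                    FeatureSpec(
                        name=f"{ch}_{voi}_FO{stat}",
                        family="firstorder",
                        channel=ch,
                        voi=voi,
                        stat=stat,
                    )
                )
    for ch in cfg.channels:
        for voi in cfg.vois:
            for stat in GLCM_STATS:
                for offset in cfg.glcm_offsets:
                    for agg in GLCM_AGGS:
                        specs.append(
                            FeatureSpec(
                                name=f"{ch}_{voi}_GLCM{stat}_{offset}_{agg}",
                                family="GLCM",
                                channel=ch,
                                voi=voi,
                                stat=stat,
                                offset=offset,
                                agg=agg,
                            )
                        )
    for ch in cfg.channels:
        for voi in cfg.vois:
            for stat in GLRLM_STATS:
                specs.append(
                    FeatureSpec(
                        name=f"{ch}_{voi}_GLRLM{stat}",
                        family="GLRLM",
                        channel=ch,
                        voi=voi,
                        stat=stat,
                    )
                )
    for voi in cfg.vois:
        for stat in SHAPE_STATS:
            specs.append(
                FeatureSpec(name=f"shape_{voi}_{stat}", family="shape", voi=voi, stat=stat)
            )
    for region in range(1, cfg.n_location_regions + 1):
        specs.append(
            FeatureSpec(
                name=f"location_core_region{region}",
                family="location",
                voi="core",
                region=region,
            )
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise CatalogError("catalog names are not unique")
    if cfg.strict_count is not None and len(specs) != cfg.strict_count:
        raise CatalogError(
            f"catalog totals {len(specs)} features, expected {cfg.strict_count}"
        )
    return FeatureCatalog(specs=specs)
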