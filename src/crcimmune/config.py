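"""Pipeline configuration.

All spatial parameters are physical lengths in micrometers (μm) in slide
space, so the same configuration applies regardless of raster resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Constants governing every stage of the scoring pipeline.

    Attributes
    ----------
    count_radius_um:
        Radius around tumor cells within which an immune cell contributes to
        the region scores (unique counting; each immune cell is attributed to
        its nearest tumor cell).
    max_profile_radius_um, profile_bin_um:
        Extent and bin width of the descriptive distance-to-tumor profiles.
    front_band_halfwidth_um:
        Half-width of the invasive-front band: tumor cells within this
        distance of the estimated front line belong to the tumor front
        (a 1000 μm diameter band for the default 500 μm).
    iel_dilation_um, connective_dilation_um:
        Disk radii used to build the intraepithelial region: union of disks
        around tumor epithelial cells minus disks around connective cells.
    cluster_link_radius_um:
        Linkage radius for single-link clustering of lymphocytes into
        lymphoid structures.
    aggregate_min_cells, lymphnode_min_cells:
        Strictly-exclusive component-size thresholds: a component is a
        lymphoid aggregate when its size exceeds ``aggregate_min_cells`` and
        a lymph node when it exceeds ``lymphnode_min_cells``.
    adjacency_radius_um:
        Radius defining "adjacent" for the IEL ratio (tumor cells with at
        least one intraepithelial lymphocyte this close count as IEL-positive).
    min_front_length_um:
        Minimum surviving polyline length for the front estimate; shorter
        fragments are discarded as segmentation noise.
    norm_lo_percentile, norm_hi_percentile:
        Percentiles of the stage II score distribution used as min/max for
        per-cohort scaling.
    followup_cutoff_months:
        Administrative cutoff for time-to-recurrence; later events are
        recoded as censored at the cutoff.
    """

    count_radius_um: float = 200.0
    max_profile_radius_um: float = 500.0
    profile_bin_um: float = 10.0
    front_band_halfwidth_um: float = 500.0
    iel_dilation_um: float = 25.0
    connective_dilation_um: float = 12.5
    cluster_link_radius_um: float = 20.0
    aggregate_min_cells: int = 500
    lymphnode_min_cells: int = 50_000
    adjacency_radius_um: float = 25.0
    min_front_length_um: float = 500.0
    norm_lo_percentile: float = 5.0
    norm_hi_percentile: float = 95.0
    followup_cutoff_months: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lengths = {
            "count_radius_um": self.count_radius_um,
            "max_profile_radius_um": self.max_profile_radius_um,
            "profile_bin_um": self.profile_bin_um,
            "front_band_halfwidth_um": self.front_band_halfwidth_um,
            "iel_dilation_um": self.iel_dilation_um,
            "connective_dilation_um": self.connective_dilation_um,
            "cluster_link_radius_um": self.cluster_link_radius_um,
            "adjacency_radius_um": self.adjacency_radius_um,
            "followup_cutoff_months": self.followup_cutoff_months,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        n_bins = self.max_profile_radius_um / self.profile_bin_um
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError(
                "profile_bin_um must divide max_profile_radius_um evenly"
            )
        if not self.aggregate_min_cells < self.lymphnode_min_cells:
            raise ValueError("aggregate_min_cells must be < lymphnode_min_cells")
        if not self.norm_lo_percentile < self.norm_hi_percentile:
            raise ValueError("norm_lo_percentile must be < norm_hi_percentile")

    @property
    def n_profile_bins(self) -> int:
        return int(round(self.max_profile_radius_um / self.profile_bin_um))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
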