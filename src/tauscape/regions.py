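"""Atlas assignment, regional tau density and density rankings.

Spots are assigned to atlas regions by the label under their centroid voxel
(the registration platform receives centroid point clouds, so centroid
assignment is the native granularity).  Regional density is the summed spot
intensity per region volume (/mm^3); regions are pooled into medium-sized
anatomical groups, subregions of above-mean groups are selected, and
per-sample rankings by descending log10 density feed the gradient consensus
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Atlas, SpotTable, TauSpot, ValidationError, logger

__all__ = [
    "RegionDensity",
    "SpotAssignment",
    "RankingSet",
    "assign_spots",
    "regional_density",
    "medium_region_profile",
    "select_above_mean_subregions",
    "build_ranking_set",
]


@dataclass(frozen=True)
class RegionDensity:
    """Tau burden of one atlas region.

    ``density_per_mm3`` = integrated spot intensity / region volume (mm^3);
    ``volume_ratio`` = summed spot volume (um^3) / region volume (um^3);
    ``log10_density`` is NaN when the density is zero.
    """

    region_id: int
    integrated_intensity: float
    density_per_mm3: float
    volume_ratio: float

    @property
    def log10_density(self) -> float:
        if self.density_per_mm3 > 0:
            return math.log10(self.density_per_mm3)
        return float("nan")


@dataclass
class SpotAssignment:
    """Spots grouped by region, plus the count dropped by exclusion rules."""

    by_region: dict[int, list[TauSpot]]
    dropped: int
    total: int

    @property
    def assigned(self) -> int:
        return sum(len(v) for v in self.by_region.values())


def assign_spots(spots: SpotTable, atlas: Atlas) -> SpotAssignment:
    """Assign each spot to the atlas region under its centroid voxel.

    Spots landing on background (label 0) or in excluded regions are
    dropped and counted.  A centroid outside the grid is an error.
    """
    pitch = np.asarray(atlas.voxel_pitch_um)
    shape = atlas.labels.shape
    excluded = atlas.excluded_ids
    by_region: dict[int, list[TauSpot]] = {}
    dropped = 0
    for spot in spots.spots:
        vox = tuple(int(np.floor(c / p)) for c, p in zip(spot.centroid_um, pitch))
        if any(v < 0 or v >= shape[a] for a, v in enumerate(vox)):
            raise ValidationError(
                f"spot {spot.label} centroid {spot.centroid_um} outside atlas grid {shape}"
            )
        label = int(atlas.labels[vox])
        if label == 0 or label in excluded:
            dropped += 1
            continue
        by_region.setdefault(label, []).append(spot)
    logger.info("assign: %d spot(s) assigned, %d dropped (background/excluded)",
                sum(len(v) for v in by_region.values()), dropped)
    return SpotAssignment(by_region=by_region, dropped=dropped, total=len(spots))


def regional_density(assignment: SpotAssignment, atlas: Atlas) -> list[RegionDensity]:
    """Density metrics for every non-excluded region (zero when spotless)."""
    out = []
    for row in atlas.regions.itertuples(index=False):
        if row.excluded:
            continue
        members = assignment.by_region.get(int(row.region_id), [])
        intensity = sum(s.total_intensity for s in members)
        spot_um3 = sum(s.volume_um3 for s in members)
        vol_mm3 = float(row.volume_mm3)
        out.append(
            RegionDensity(
                region_id=int(row.region_id),
                integrated_intensity=intensity,
                density_per_mm3=intensity / vol_mm3,
                volume_ratio=spot_um3 / (vol_mm3 * 1e9),
            )
        )
    return out


def densities_to_frame(densities: list[RegionDensity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.region_id, d.integrated_intensity, d.density_per_mm3, d.volume_ratio,
             d.log10_density)
            for d in densities
        ],
        columns=["region_id", "integrated_intensity", "density_per_mm3", "volume_ratio",
                 "log10_density"],
    )


def frame_to_densities(df: pd.DataFrame) -> list[RegionDensity]:
    required = {"region_id", "integrated_intensity", "density_per_mm3", "volume_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"density table missing column(s): {', '.join(sorted(missing))}")
    return [
        RegionDensity(
            region_id=int(r.region_id),
            integrated_intensity=float(r.integrated_intensity),
            density_per_mm3=float(r.density_per_mm3),
            volume_ratio=float(r.volume_ratio),
        )
        for r in df.itertuples(index=False)
    ]


def medium_region_profile(
    density_lists: list[list[RegionDensity]],
    atlas: Atlas,
    pooling: str = "volume-weighted",
) -> pd.DataFrame:
    """Pool subregion densities into medium groups and average across samples.

    Per sample, a group's density is volume-weighted: summed intensity of
    member regions divided by their summed volume (an unweighted mean of
    member densities is available via ``pooling='mean'``).  Group densities
    are then averaged arithmetically across samples.  Returns a frame with
    columns medium_group_id, density_per_mm3 (sorted descending) and the
    across-group mean in ``df.attrs['mean_density']``.
    """
    if pooling not in ("volume-weighted", "mean"):
        raise ValidationError("pooling must be 'volume-weighted' or 'mean'")
    meta = atlas.regions.set_index("region_id")
    group_values: dict[int, list[float]] = {}
    for densities in density_lists:
        intensity: dict[int, float] = {}
        volume: dict[int, float] = {}
        member: dict[int, list[float]] = {}
        for d in densities:
            gid = int(meta.loc[d.region_id, "medium_group_id"])
            intensity[gid] = intensity.get(gid, 0.0) + d.integrated_intensity
            volume[gid] = volume.get(gid, 0.0) + float(meta.loc[d.region_id, "volume_mm3"])
            member.setdefault(gid, []).append(d.density_per_mm3)
        for gid in intensity:
            if pooling == "volume-weighted":
                value = intensity[gid] / volume[gid]
            else:
                value = float(np.mean(member[gid]))
            group_values.setdefault(gid, []).append(value)
    rows = [(gid, float(np.mean(vals))) for gid, vals in group_values.items()]
    df = pd.DataFrame(rows, columns=["medium_group_id", "density_per_mm3"])
    df = df.sort_values(["density_per_mm3", "medium_group_id"],
                        ascending=[False, True]).reset_index(drop=True)
    df.attrs["mean_density"] = float(df["density_per_mm3"].mean()) if len(df) else 0.0
    return df


def select_above_mean_subregions(profile: pd.DataFrame, atlas: Atlas) -> set[int]:
    """Subregions of medium groups whose density strictly exceeds the mean."""
    mean = profile.attrs.get("mean_density")
    if mean is None:
        mean = float(profile["density_per_mm3"].mean()) if len(profile) else 0.0
    hot = set(profile.loc[profile["density_per_mm3"] > mean, "medium_group_id"].astype(int))
    members = atlas.regions[
        atlas.regions["medium_group_id"].isin(hot) & ~atlas.regions["excluded"]
    ]
    return set(members["region_id"].astype(int))


@dataclass
class RankingSet:
    """Per-sample strict orderings of a shared region set.

    ``orderings[s]`` lists region ids in descending order of that sample's
    log10 tau density; ``densities[s]`` is aligned with ``orderings[s]``.
    """

    region_ids: list[int]
    orderings: list[list[int]]
    densities: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        base = set(self.region_ids)
        if len(base) != len(self.region_ids):
            raise ValidationError("region_ids must be distinct")
        for i, order in enumerate(self.orderings):
            if set(order) != base or len(order) != len(base):
                raise ValidationError(f"ordering {i} is not a permutation of the region set")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def k_samples(self) -> int:
        return len(self.orderings)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, order in enumerate(self.orderings):
            dens = self.densities[s] if self.densities else [float("nan")] * len(order)
            for rank, (rid, d) in enumerate(zip(order, dens)):
                rows.append((s, rank, rid, d))
        return pd.DataFrame(rows, columns=["sample", "rank", "region_id", "density_per_mm3"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankingSet":
        required = {"sample", "rank", "region_id"}
        if required - set(df.columns):
            raise ValidationError("ranking table needs columns sample, rank, region_id")
        orderings, densities = [], []
        for s in sorted(df["sample"].unique()):
            sub = df[df["sample"] == s].sort_values("rank")
            orderings.append(sub["region_id"].astype(int).tolist())
            if "density_per_mm3" in sub.columns:
                densities.append(sub["density_per_mm3"].astype(float).tolist())
        region_ids = sorted(orderings[0]) if orderings else []
        return cls(region_ids=region_ids, orderings=orderings, densities=densities)


def build_ranking_set(
    density_lists: list[list[RegionDensity]],
    region_subset: set[int] | list[int],
) -> RankingSet:
    """Rank the subset regions by descending log10 density in every sample.

    Zero densities are rejected (log10 undefined) — pre-filter the subset.
    Ties within a sample are broken by ascending region id and logged.
    """
    subset = sorted(int(r) for r in region_subset)
    orderings, values = [], []
    for s, densities in enumerate(density_lists):
        lookup = {d.region_id: d for d in densities}
        missing = [r for r in subset if r not in lookup]
        if missing:
            raise ValidationError(f"sample {s} missing region(s) {missing}")
        zero = [r for r in subset if not lookup[r].density_per_mm3 > 0]
        if zero:
            raise ValidationError(
                f"sample {s}: zero density in region(s) {zero}; log10 undefined "
                "(pre-filter the region subset)"
            )
        pairs = sorted(((lookup[r].density_per_mm3, r) for r in subset),
                       key=lambda t: (-t[0], t[1]))
        dens = [p[0] for p in pairs]
        if len(set(dens)) != len(dens):
            logger.warning("rank: density ties in sample %d broken by region id", s)
        orderings.append([p[1] for p in pairs])
        values.append(dens)
    return RankingSet(region_ids=subset, orderings=orderings, densities=values)
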