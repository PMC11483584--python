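"""Synthetic data with known ground truth for every pipeline stage.

The raw whole-brain light-sheet volumes behind the original study are not
publicly deposited, so each downstream stage is exercised on generated
inputs whose truth is known exactly:

* :func:`make_toy_atlas` — an ellipsoidal "brain" partitioned into labelled
  regions over a zero background, with exact voxel-derived volumes;
* :func:`make_tau_volume` — Gaussian tau-deposit blobs over a smooth
  two-level background (bright inside the brain, dim outside) plus
  clipped Gaussian noise, with a ground-truth mask of the blob footprints;
* :func:`make_ranking_set` — per-sample random rankings containing a
  planted order-conserved subsequence, densities exponentially spaced so
  log10 densities are linear and tie-free;
* :func:`make_tac_pair` — two-region time-activity curves on the 20-frame
  PET schedule (4 x 1 min, 8 x 2 min, 8 x 5 min).

Every generator takes an explicit seed; none touches global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import Atlas, TimeActivityCurve, ValidationError, Volume3D
from .regions import RankingSet

__all__ = [
    "PlantedSpotSpec",
    "PlantedConsensusSpec",
    "DEFAULT_FRAME_SCHEDULE_MIN",
    "make_toy_atlas",
    "make_tau_volume",
    "random_spot_specs",
    "make_ranking_set",
    "frame_mid_times",
    "make_tac_pair",
]


@dataclass(frozen=True)
class PlantedSpotSpec:
    """One planted Gaussian tau blob: centre voxel, peak amplitude, width."""

    center_vox: tuple[int, int, int]
    amplitude: float
    sigma_vox: float = 1.2
    region_id: int | None = None

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValidationError("blob amplitude must be > 0")
        if not self.sigma_vox > 0:
            raise ValidationError("blob sigma must be > 0")


@dataclass(frozen=True)
class PlantedConsensusSpec:
    """Parameters of a ranking set with a planted order-conserved chain."""

    n_regions: int
    k_samples: int
    planted_sequence: tuple[int, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        seq = tuple(int(r) for r in self.planted_sequence)
        if len(set(seq)) != len(seq):
            raise ValidationError("planted sequence ids must be distinct")
        if len(seq) > self.n_regions:
            raise ValidationError("planted sequence longer than the region set")
        if any(r < 1 or r > self.n_regions for r in seq):
            raise ValidationError("planted ids must lie in 1..n_regions")
        object.__setattr__(self, "planted_sequence", seq)


# --------------------------------------------------------------------------
# Atlas
# --------------------------------------------------------------------------

def make_toy_atlas(
    shape: tuple[int, int, int] = (32, 32, 32),
    pitch_um: float = 8.3,
    n_regions: int = 4,
    layout: str = "layered-boxes",
    excluded_ids: set[int] | None = None,
    n_groups: int | None = None,
) -> Atlas:
    """Ellipsoidal brain partitioned into ``n_regions`` contiguous regions.

    ``layered-boxes`` slices the brain into bands along z; ``nested-shells``
    splits it by normalized ellipsoid radius.  Region ids run 1..n; region
    volumes are exact voxel counts converted to mm^3.  Regions are pooled
    into ``n_groups`` medium groups (default: up to 4) in id order.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    if layout not in ("layered-boxes", "nested-shells"):
        raise ValidationError("layout must be 'layered-boxes' or 'nested-shells'")
    excluded_ids = excluded_ids or set()
    shape = tuple(int(s) for s in shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.46
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    r2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    brain = r2 <= 1.0
    n_brain = int(brain.sum())
    if n_brain < n_regions:
        raise ValidationError(f"n_regions={n_regions} larger than {n_brain} brain voxels")
    labels = np.zeros(shape, dtype=np.int64)
    if layout == "layered-boxes":
        # split by z so each band holds ~equal numbers of brain voxels
        z_of = zz[brain]
        cuts = np.quantile(z_of, np.linspace(0, 1, n_regions + 1))
        band = np.clip(np.searchsorted(cuts[1:-1], z_of, side="right"), 0, n_regions - 1)
        labels[brain] = band + 1
    else:
        r_of = r2[brain]
        cuts = np.quantile(r_of, np.linspace(0, 1, n_regions + 1))
        shell = np.clip(np.searchsorted(cuts[1:-1], r_of, side="right"), 0, n_regions - 1)
        labels[brain] = shell + 1
    present = set(np.unique(labels)) - {0}
    if len(present) != n_regions:
        raise ValidationError(
            f"layout produced {len(present)} non-empty regions, expected {n_regions}"
        )
    vox_mm3 = (pitch_um**3) / 1e9
    if n_groups is None:
        n_groups = min(4, n_regions)
    per_group = int(np.ceil(n_regions / n_groups))
    rows = []
    for rid in range(1, n_regions + 1):
        count = int(np.sum(labels == rid))
        rows.append(
            {
                "region_id": rid,
                "acronym": f"R{rid}",
                "medium_group_id": (rid - 1) // per_group + 1,
                "volume_mm3": count * vox_mm3,
                "excluded": rid in excluded_ids,
            }
        )
    regions = pd.DataFrame(rows)
    return Atlas(labels=labels, voxel_pitch_um=(pitch_um,) * 3, regions=regions)


# --------------------------------------------------------------------------
# Tau volumes
# --------------------------------------------------------------------------

def make_tau_volume(
    atlas: Atlas,
    spots: list[PlantedSpotSpec],
    brain_background: float = 10.0,
    outside_background: float = 1.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[Volume3D, np.ndarray]:
    """Planted-blob tau channel plus its ground-truth footprint mask.

    The volume is ``outside_background`` outside the brain,
    ``brain_background`` inside, plus a Gaussian blob per spot and
    zero-mean Gaussian noise clipped at zero.  The truth mask marks voxels
    within 2 x sigma of any blob centre (Euclidean, in voxels).
    """
    brain = atlas.labels > 0
    shape = brain.shape
    data = np.where(brain, float(brain_background), float(outside_background))
    truth = np.zeros(shape, dtype=bool)
    coords = [np.arange(s, dtype=np.float64) for s in shape]
    for spec in spots:
        c = tuple(int(v) for v in spec.center_vox)
        if any(v < 0 or v >= shape[a] for a, v in enumerate(c)):
            raise ValidationError(f"spot centre {c} outside the volume")
        if not brain[c]:
            raise ValidationError(f"spot centre {c} outside the brain mask")
        # build the blob in a local window of +/- 4 sigma
        r = max(1, int(np.ceil(4 * spec.sigma_vox)))
        sl = tuple(slice(max(0, c[a] - r), min(shape[a], c[a] + r + 1)) for a in range(3))
        local = [coords[a][sl[a]] - c[a] for a in range(3)]
        d2 = (
            local[0][:, None, None] ** 2
            + local[1][None, :, None] ** 2
            + local[2][None, None, :] ** 2
        )
        data[sl] += spec.amplitude * np.exp(-d2 / (2 * spec.sigma_vox**2))
        truth[sl] |= d2 <= (2 * spec.sigma_vox) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(data, 0.0, None)
    return Volume3D(data=data, voxel_pitch_um=atlas.voxel_pitch_um), truth


def random_spot_specs(
    atlas: Atlas,
    n_spots: int,
    amplitude: float = 200.0,
    sigma_vox: float = 1.2,
    seed: int | None = None,
    mask_erosion_iterations: int = 10,
    min_separation_vox: float = 9.0,
) -> list[PlantedSpotSpec]:
    """Place ``n_spots`` blob centres deep inside the brain, well separated.

    Centres are drawn uniformly from the placement core: the brain mask
    eroded the same way the extraction stage erodes it
    (``mask_erosion_iterations`` face-connected erosions), shrunk further
    by one blob support radius (4 x sigma, via the Euclidean distance
    transform) so every planted footprint survives masking intact.  A
    minimum pairwise centre distance of roughly twice the suprathreshold
    footprint radius keeps deposits resolvable as distinct components.
    """
    rng = np.random.default_rng(seed)
    brain = atlas.labels > 0
    core = (
        ndi.binary_erosion(brain, iterations=mask_erosion_iterations)
        if mask_erosion_iterations
        else brain
    )
    support = 4.0 * sigma_vox
    core = ndi.distance_transform_edt(core) > support + 1.0
    candidates = np.argwhere(core)
    if len(candidates) == 0:
        raise ValidationError("placement core is empty; shrink the brain margins")
    chosen: list[np.ndarray] = []
    for _ in range(50):  # random sequential placement with restarts
        chosen = []
        attempts = 0
        while len(chosen) < n_spots and attempts < 2_000 * n_spots:
            attempts += 1
            c = candidates[rng.integers(len(candidates))]
            if all(np.linalg.norm(c - p) >= min_separation_vox for p in chosen):
                chosen.append(c)
        if len(chosen) == n_spots:
            break
    if len(chosen) < n_spots:
        raise ValidationError("could not place spots with the requested separation")
    return [
        PlantedSpotSpec(
            center_vox=tuple(int(v) for v in c),
            amplitude=amplitude,
            sigma_vox=sigma_vox,
            region_id=int(atlas.labels[tuple(c)]),
        )
        for c in chosen
    ]


def detection_scores(
    spot_table,
    specs: list[PlantedSpotSpec],
    pitch_um: float = 8.3,
    support_sigma_factor: float = 4.0,
    hit_radius_vox: float = 1.0,
) -> dict:
    """Deposit-level detection accuracy against the planted ground truth.

    A predicted spot is associated with a planted deposit when its centroid
    lies within the deposit's support radius (``support_sigma_factor`` x
    sigma, the extent over which the generator deposits blob intensity);
    spots outside every support are false positives, deposits with no
    associated spot are false negatives.  A deposit counts as *recovered*
    when some associated centroid lies within ``hit_radius_vox`` of its
    planted centre.  Returns precision, recall, f, n_recovered and the
    worst centroid error (in voxels) over recovered deposits.
    """
    centers = np.asarray([s.center_vox for s in specs], dtype=np.float64)
    support = np.asarray([support_sigma_factor * s.sigma_vox for s in specs])
    centroids = np.asarray(
        [np.asarray(s.centroid_um) / pitch_um - 0.5 for s in spot_table.spots]
    )
    if centroids.size == 0:
        return {"precision": 0.0, "recall": 0.0, "f": 0.0, "n_recovered": 0,
                "max_centroid_error_vox": float("nan")}
    dist = np.linalg.norm(centroids[:, None, :] - centers[None, :, :], axis=2)
    associated = dist <= support[None, :]
    fp = int(np.sum(~associated.any(axis=1)))
    hit = associated.any(axis=0)
    fn = int(np.sum(~hit))
    tp = int(np.sum(associated.any(axis=1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = int(hit.sum()) / len(specs)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    nearest = dist.min(axis=0)
    recovered = nearest <= hit_radius_vox
    return {
        "precision": precision,
        "recall": recall,
        "f": f,
        "n_recovered": int(recovered.sum()),
        "max_centroid_error_vox": float(nearest[recovered].max()) if recovered.any()
        else float("nan"),
    }


# --------------------------------------------------------------------------
# Ranking sets with a planted consensus
# --------------------------------------------------------------------------

def make_ranking_set(spec: PlantedConsensusSpec) -> RankingSet:
    """Random rankings containing the planted chain in order in every sample.

    Each sample is a uniform random permutation of the non-planted ids
    merged with the planted sequence kept in order at uniformly random
    positions, so the planted chain is order-conserved by construction and
    the maximal consensus length is at least its length.  Densities are
    exponentially spaced along each ordering (log10-linear, strictly
    decreasing, tie-free).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_regions, spec.k_samples
    planted = list(spec.planted_sequence)
    others = [r for r in range(1, n + 1) if r not in set(planted)]
    orderings = []
    densities = []
    for _ in range(k):
        shuffled = list(rng.permutation(others)) if others else []
        slots = sorted(rng.choice(n, size=len(planted), replace=False)) if planted else []
        order: list[int] = []
        pi = oi = 0
        slot_set = set(slots)
        for pos in range(n):
            if pos in slot_set:
                order.append(planted[pi])
                pi += 1
            else:
                order.append(int(shuffled[oi]))
                oi += 1
        orderings.append(order)
        # density at rank r: 10^(4 - 0.05 r) -> log10 linear, strictly decreasing
        densities.append([10.0 ** (4.0 - 0.05 * r) for r in range(n)])
    return RankingSet(region_ids=list(range(1, n + 1)), orderings=orderings,
                      densities=densities)


# --------------------------------------------------------------------------
# PET time-activity curves
# --------------------------------------------------------------------------

#: 60-minute dynamic PET frame durations (min): 4 x 1, 8 x 2, 8 x 5.
DEFAULT_FRAME_SCHEDULE_MIN: tuple[float, ...] = (1.0,) * 4 + (2.0,) * 8 + (5.0,) * 8


def frame_mid_times(schedule_min=DEFAULT_FRAME_SCHEDULE_MIN) -> np.ndarray:
    """Frame mid-times implied by a duration schedule summing to 60 min."""
    durations = np.asarray(schedule_min, dtype=np.float64)
    if not np.isclose(durations.sum(), 60.0):
        raise ValidationError(f"frame schedule sums to {durations.sum()} min, expected 60")
    ends = np.cumsum(durations)
    return ends - durations / 2.0


def make_tac_pair(
    target_curve,
    reference_curve,
    dose_kbq: float = 17_200.0,
    body_weight_g: float = 25.0,
    schedule_min=DEFAULT_FRAME_SCHEDULE_MIN,
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """Sample two activity curves on the 20-frame schedule.

    ``target_curve`` / ``reference_curve`` are callables of time (min)
    returning kBq/cc, or sequences already on the frame grid.  The default
    dose matches a typical injected activity of ~17.2 MBq in a 25 g mouse.
    """
    if not dose_kbq > 0:
        raise ValidationError("dose_kbq must be > 0")
    if not body_weight_g > 0:
        raise ValidationError("body_weight_g must be > 0")
    times = frame_mid_times(schedule_min)

    def sample(curve, name):
        if callable(curve):
            values = np.asarray([float(curve(t)) for t in times])
        else:
            values = np.asarray(curve, dtype=np.float64)
            if values.shape != times.shape:
                raise ValidationError(
                    f"{name} curve has {values.size} frames, schedule implies {times.size}"
                )
        if np.any(values <= 0):
            raise ValidationError(f"{name} curve must be positive")
        return values

    target = TimeActivityCurve(
        frame_mid_times_min=times,
        activity_kbq_per_cc=sample(target_curve, "target"),
        dose_kbq=dose_kbq,
        body_weight_g=body_weight_g,
        region="target",
    )
    reference = TimeActivityCurve(
        frame_mid_times_min=times,
        activity_kbq_per_cc=sample(reference_curve, "reference"),
        dose_kbq=dose_kbq,
        body_weight_g=body_weight_g,
        region="reference",
    )
    return target, reference
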