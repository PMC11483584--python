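"""End-to-end pipeline: extract -> aggregate -> rank -> consensus -> graph.

A :class:`RunConfig` (JSON-serializable, unknown keys rejected) drives the
whole run; a manifest records every threshold, kernel size and seed used so
a run is reproducible from the manifest plus the inputs alone.  One global
seed expands deterministically into independent per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import __version__
from .consensus import build_graph, max_consensus, permutation_null, unique_patterns
from .extraction import compute_brain_mask, extract_spots, gaussian_mean_difference, \
    mean_kernel_width_vox, resample_to_standard
from .io import Atlas, ExtractionParams, TauscapeError, ValidationError, logger, \
    read_atlas, read_volume, write_spot_table
from .regions import assign_spots, build_ranking_set, densities_to_frame, \
    medium_region_profile, regional_density, select_above_mean_subregions

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(TauscapeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full pipeline configuration.

    ``volumes`` lists one input volume per sample; ``atlas_labels`` /
    ``atlas_regions`` point at the shared pre-aligned atlas.  The global
    ``seed`` expands into per-stage seeds via a seed sequence.
    """

    volumes: list[str] = field(default_factory=list)
    atlas_labels: str = ""
    atlas_regions: str = ""
    extraction: dict = field(default_factory=dict)
    n_perm: int = 10_000
    alpha: float = 0.05
    weight_total: float = 250.0
    min_consensus_length: int | None = None   # default: the null threshold
    subregion_selection: str = "above-mean-groups"  # | "all-positive"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        allowed = {f.name for f in fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        ExtractionParams.from_dict(cfg.extraction)  # reject unknown nested keys
        return cfg

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @property
    def extraction_params(self) -> ExtractionParams:
        return ExtractionParams.from_dict(self.extraction)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(2)
    return {
        "null": int(children[0].generate_state(1)[0] % (2**31)),
        "layout": int(children[1].generate_state(1)[0] % (2**31)),
    }


def _file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run every stage for >= 1 samples and write artifacts plus a manifest.

    Stages: per-sample extraction -> regional density aggregation ->
    above-mean subregion selection -> rankings -> maximal consensus +
    unique patterns -> permutation null -> consensus graph.  Any stage
    error aborts with the stage name.  Returns the manifest dict.
    """
    os.makedirs(out_dir, exist_ok=True)
    params = config.extraction_params
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "seeds": seeds,
        "inputs": {},
        "stages": {},
    }

    if not config.volumes:
        raise StageError("stage extract: no input volumes configured")
    if not config.atlas_labels or not os.path.exists(config.atlas_labels):
        raise StageError(f"stage aggregate: atlas not found ({config.atlas_labels!r})")

    try:
        atlas = read_atlas(config.atlas_labels, config.atlas_regions)
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise StageError(f"stage aggregate: {exc}") from exc
    manifest["inputs"]["atlas_labels"] = _file_sha256(config.atlas_labels)
    manifest["inputs"]["atlas_regions"] = _file_sha256(config.atlas_regions)

    density_lists = []
    extract_info = []
    for i, vol_path in enumerate(config.volumes):
        try:
            volume = read_volume(vol_path)
            volume = resample_to_standard(volume, params.target_pitch_um)
            diff = gaussian_mean_difference(volume, params)
            mask = compute_brain_mask(volume, params)
            spots = extract_spots(diff, volume, mask, params)
        except Exception as exc:
            raise StageError(f"stage extract: sample {i}: {exc}") from exc
        spots.sample_id = f"sample{i}"
        csv_path = os.path.join(out_dir, f"spots_sample{i}.csv")
        write_spot_table(spots, csv_path)
        manifest["inputs"][f"volume{i}"] = _file_sha256(vol_path)
        outside_mean = float(volume.data[~mask.mask].mean())
        extract_info.append({
            "n_spots": len(spots),
            "mask_threshold": params.mask_threshold_factor * float(volume.data.mean()),
            "spot_threshold": params.spot_threshold_factor * outside_mean,
            "mean_kernel_vox": mean_kernel_width_vox(params),
            "erosion_iterations": params.erosion_iterations,
        })
        try:
            assignment = assign_spots(spots, atlas)
            densities = regional_density(assignment, atlas)
        except Exception as exc:
            raise StageError(f"stage aggregate: sample {i}: {exc}") from exc
        densities_to_frame(densities).to_csv(
            os.path.join(out_dir, f"densities_sample{i}.csv"), index=False
        )
        density_lists.append(densities)
    manifest["stages"]["extract"] = extract_info

    try:
        if config.subregion_selection not in ("above-mean-groups", "all-positive"):
            raise ValidationError(
                f"unknown subregion_selection {config.subregion_selection!r}"
            )
        profile = medium_region_profile(density_lists, atlas)
        if config.subregion_selection == "above-mean-groups":
            subset = select_above_mean_subregions(profile, atlas)
        else:
            subset = {d.region_id for d in density_lists[0]}
        positive = {
            r for r in subset
            if all(
                next(d for d in dl if d.region_id == r).density_per_mm3 > 0
                for dl in density_lists
            )
        }
        if not positive:
            raise ValidationError("no above-mean subregion has positive density in all samples")
        rankings = build_ranking_set(density_lists, positive)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage rank: {exc}") from exc
    rankings.to_frame().to_csv(os.path.join(out_dir, "rankings.csv"), index=False)
    manifest["stages"]["rank"] = {
        "n_regions": rankings.n_regions,
        "k_samples": rankings.k_samples,
        "group_mean_density": profile.attrs["mean_density"],
    }

    try:
        null = permutation_null(
            rankings.n_regions, rankings.k_samples,
            n_perm=config.n_perm, alpha=config.alpha, seed=seeds["null"],
        )
        length, witness = max_consensus(rankings)
        min_len = config.min_consensus_length or null.threshold_length or 2
        min_len = min(min_len, length)
        patterns = unique_patterns(rankings, min_length=min_len)
    except Exception as exc:
        raise StageError(f"stage consensus: {exc}") from exc
    manifest["stages"]["consensus"] = {
        "max_length": length,
        "witness": list(witness.region_ids),
        "threshold_length": null.threshold_length,
        "p_at_threshold": null.p_at.get(null.threshold_length)
        if null.threshold_length else None,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "null_seed": seeds["null"],
        "patterns_per_length": {str(L): len(v) for L, v in patterns.items()},
    }
    with open(os.path.join(out_dir, "sequences.json"), "w") as fh:
        json.dump({str(L): [list(s.region_ids) for s in v] for L, v in patterns.items()},
                  fh, indent=2)

    try:
        mean_density = {
            r: float(np.mean([
                next(d for d in dl if d.region_id == r).density_per_mm3
                for dl in density_lists
            ]))
            for r in rankings.region_ids
        }
        ranks = {
            r: i for i, r in enumerate(
                sorted(mean_density, key=lambda x: -mean_density[x])
            )
        }
        top = patterns.get(length, [witness])
        graph = build_graph(top or [witness], mean_density_ranks=ranks,
                            weight_total=config.weight_total)
    except Exception as exc:
        raise StageError(f"stage graph: {exc}") from exc
    graph_json = {
        "weight_total": graph.weight_total,
        "nodes": [
            {"region_id": int(nid), "rank": data["rank"]}
            for nid, data in graph.graph.nodes(data=True)
        ],
        "edges": [
            {"source": int(u), "target": int(v),
             "adjacency": d["adjacency"], "weight": d["weight"]}
            for u, v, d in graph.graph.edges(data=True)
        ],
    }
    with open(os.path.join(out_dir, "graph.json"), "w") as fh:
        json.dump(graph_json, fh, indent=2)
    manifest["stages"]["graph"] = {
        "n_nodes": graph.graph.number_of_nodes(),
        "n_edges": graph.graph.number_of_edges(),
        "weight_total": graph.weight_total,
    }

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline: manifest written to %s", manifest_path)
    return manifest
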