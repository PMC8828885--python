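"""Config-driven orchestration of the full pipeline.

A run is described by one YAML file plus a channel-metadata CSV.  Stages run
in a fixed order — extract, normalise, mask, segment, phenotype, cluster,
spatial, pixel — and every stage reads its inputs from the output directory
(or from externally supplied files named in the config) and writes its
outputs back there.  Because each stage is keyed only on files, any subset of
stages can be re-run or replaced by external data: running a prefix of stages
and later resuming the suffix produces byte-identical CSVs to a single full
run.

Per-sample seeds are derived deterministically from the master seed and the
sample id, so parallel and serial execution would give identical outputs;
execution here is serial.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConfigurationError
from .expressions import (
    parse_gate_expression,
    parse_mask_expression,
    referenced_names,
)
from .io import (
    ChannelStack,
    _sanitise,
    parse_imc_text,
    read_channel_table,
    read_stack,
    write_channels,
)
from .phenotyping import (
    ClusterParams,
    GateSpec,
    OverlapRule,
    assign_compartment,
    assign_type_by_highest_overlap,
    cluster_cells,
    gate_cells,
)
from .pixel_area import positive_area
from .preprocess import (
    BinaryMask,
    MaskRecipe,
    NormalisationParams,
    RecipeStep,
    channel_percentiles,
    normalise_percentile,
    run_mask_recipe,
)
from .segmentation import (
    LabelImage,
    SegmentationParams,
    detect_nuclei,
    expand_cells,
    extract_features,
)
from .spatial import (
    HomotypicParams,
    classify_proximity,
    compare_groups,
    comparisons_to_frame,
    homotypic_clusters,
    nearest_distances,
    permutation_tests,
    permutations_to_frame,
)

logger = logging.getLogger(__name__)

STAGES = (
    "extract",
    "normalise",
    "mask",
    "segment",
    "phenotype",
    "cluster",
    "spatial",
    "pixel",
)


@dataclass
class SampleConfig:
    sample_id: str
    group: str | None = None
    imc_text: str | None = None
    images: list[str] = field(default_factory=list)
    label_image: str | None = None
    cell_table: str | None = None


@dataclass
class RunConfig:
    config_dir: Path
    output_dir: Path
    seed: int
    pixel_size_um: float
    channels_path: Path
    samples: list[SampleConfig]
    normalisation: NormalisationParams | None
    mask_recipes: list[MaskRecipe]
    segmentation: dict[str, Any] | None
    compartments: list[OverlapRule]
    retain_compartment: str | None
    cell_type_rules: list[OverlapRule]
    gates: list[GateSpec]
    clustering: dict[str, Any] | None
    spatial: dict[str, Any] | None
    pixel_area: list[dict[str, str]]

    @property
    def channel_names(self) -> list[str]:
        return [c.channel_name for c in read_channel_table(self.channels_path)]

    def sample_seed(self, sample_id: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(sample_id.encode())) % (2**31)


def _resolve(base: Path, p: str) -> Path:
    path = Path(p)
    return path if path.is_absolute() else base / path


def validate_config(path: str | Path) -> RunConfig:
    """Parse and cross-check a YAML run configuration.

    Every name referenced by a later stage must be defined by an earlier one
    (or supplied externally); the first dangling reference is reported.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    base = path.parent

    def require(key):
        if key not in raw:
            raise ConfigurationError(f"{path}: missing required key {key!r}")
        return raw[key]

    channels_path = _resolve(base, require("channels"))
    if not channels_path.exists():
        raise ConfigurationError(f"channels file not found: {channels_path}")
    channel_names = [c.channel_name for c in read_channel_table(channels_path)]

    samples = []
    for s in require("samples"):
        sample = SampleConfig(
            sample_id=str(s["sample_id"]),
            group=s.get("group"),
            imc_text=s.get("imc_text"),
            images=list(s.get("images", [])),
            label_image=s.get("label_image"),
            cell_table=s.get("cell_table"),
        )
        for attr in ("imc_text", "label_image", "cell_table"):
            value = getattr(sample, attr)
            if value is not None and not _resolve(base, value).exists():
                raise ConfigurationError(
                    f"sample {sample.sample_id}: {attr} file not found: {value}"
                )
        for img in sample.images:
            if not _resolve(base, img).exists():
                raise ConfigurationError(
                    f"sample {sample.sample_id}: image not found: {img}"
                )
        samples.append(sample)
    if len({s.sample_id for s in samples}) != len(samples):
        raise ConfigurationError("duplicate sample_id in samples table")

    norm = None
    if raw.get("normalisation") is not None:
        n = raw["normalisation"]
        norm = NormalisationParams(
            percentile=float(n.get("percentile", 99)),
            scope=str(n.get("scope", "per_image")),
        )

    recipes: list[MaskRecipe] = []
    defined_masks: list[str] = []
    for m in raw.get("masks", []) or []:
        steps = tuple(
            RecipeStep(step["op"], tuple(step.get("args", [])))
            for step in m["steps"]
        )
        recipe = MaskRecipe(
            name=str(m["name"]), sources=tuple(m["sources"]), steps=steps
        )
        for src in recipe.sources:
            if src not in channel_names and src not in defined_masks:
                raise ConfigurationError(
                    f"mask {recipe.name!r}: source {src!r} is neither a channel "
                    "nor a previously defined mask"
                )
        for i, step in enumerate(recipe.steps):
            if step.op in ("subtract", "intersect") and step.args[0] not in defined_masks:
                raise ConfigurationError(
                    f"mask {recipe.name!r} step {i}: unknown mask {step.args[0]!r}"
                )
        recipes.append(recipe)
        defined_masks.append(recipe.name)

    seg = raw.get("segmentation")
    if seg is not None:
        if seg.get("nucleus_channel") not in channel_names:
            raise ConfigurationError(
                f"segmentation: unknown nucleus channel {seg.get('nucleus_channel')!r}"
            )
        membrane = seg.get("membrane_mask")
        if membrane is not None and membrane not in defined_masks:
            raise ConfigurationError(
                f"segmentation: unknown membrane mask {membrane!r}"
            )

    compartments = [
        OverlapRule(str(c["mask"]), float(c["min_fraction"]))
        for c in raw.get("compartments", []) or []
    ]
    for rule in compartments:
        if rule.mask_name not in defined_masks:
            raise ConfigurationError(
                f"compartment rule references unknown mask {rule.mask_name!r}"
            )
    retain = raw.get("retain_compartment")
    if retain is not None and retain not in [r.mask_name for r in compartments]:
        raise ConfigurationError(
            f"retain_compartment {retain!r} has no matching compartment rule"
        )

    cell_type_rules = [
        OverlapRule(str(c["mask"]), float(c["min_fraction"]))
        for c in raw.get("cell_types", []) or []
    ]
    for rule in cell_type_rules:
        if rule.mask_name not in defined_masks:
            raise ConfigurationError(
                f"cell-type rule references unknown mask {rule.mask_name!r}"
            )

    gates = []
    gate_names: list[str] = []
    for g in raw.get("gates", []) or []:
        gate = GateSpec(
            name=str(g["name"]),
            expression=str(g["expression"]),
            parent_gate=g.get("parent"),
        )
        for name in referenced_names(parse_gate_expression(gate.expression)):
            if name not in channel_names:
                raise ConfigurationError(
                    f"gate {gate.name!r}: unknown channel {name!r}"
                )
        if gate.parent_gate is not None and gate.parent_gate not in gate_names:
            raise ConfigurationError(
                f"gate {gate.name!r}: parent {gate.parent_gate!r} not defined earlier"
            )
        gates.append(gate)
        gate_names.append(gate.name)

    clustering = raw.get("clustering")
    if clustering is not None:
        for m in clustering.get("markers", []):
            if m not in channel_names:
                raise ConfigurationError(f"clustering: unknown marker {m!r}")

    known_types = set(gate_names) | {r.mask_name for r in cell_type_rules}
    spatial_cfg = raw.get("spatial")
    external_cells = any(s.cell_table for s in samples)
    if spatial_cfg is not None and known_types and not external_cells:
        for h in spatial_cfg.get("homotypic", []) or []:
            if h["cell_type"] not in known_types:
                raise ConfigurationError(
                    f"homotypic analysis references unknown cell type {h['cell_type']!r}"
                )
        het = spatial_cfg.get("heterotypic")
        if het:
            for pair in het.get("comparisons", []):
                for t in pair:
                    if t not in known_types:
                        raise ConfigurationError(
                            f"heterotypic comparison references unknown cell type {t!r}"
                        )

    pixel_cfg = []
    for p in raw.get("pixel_area", []) or []:
        entry = {
            "numerator": str(p["numerator"]),
            "denominator": str(p.get("denominator", "image")),
        }
        for name in referenced_names(parse_mask_expression(entry["numerator"])):
            if name not in defined_masks:
                raise ConfigurationError(
                    f"pixel_area numerator references unknown mask {name!r}"
                )
        if entry["denominator"] != "image" and entry["denominator"] not in defined_masks:
            raise ConfigurationError(
                f"pixel_area denominator references unknown mask {entry['denominator']!r}"
            )
        pixel_cfg.append(entry)

    return RunConfig(
        config_dir=base,
        output_dir=_resolve(base, str(raw.get("output_dir", "output"))),
        seed=int(raw.get("seed", 0)),
        pixel_size_um=float(raw.get("pixel_size_um", 1.0)),
        channels_path=channels_path,
        samples=samples,
        normalisation=norm,
        mask_recipes=recipes,
        segmentation=seg,
        compartments=compartments,
        retain_compartment=retain,
        cell_type_rules=cell_type_rules,
        gates=gates,
        clustering=clustering,
        spatial=spatial_cfg,
        pixel_area=pixel_cfg,
    )


# ---------------------------------------------------------------------------
# Artefact loading (stage-resume support)

def _stack_dir_candidates(cfg: RunConfig, normalised_ok: bool) -> list[tuple[Path, bool]]:
    dirs = []
    if normalised_ok:
        dirs.append((cfg.output_dir / "normalised", True))
    dirs.append((cfg.output_dir / "extract", False))
    return dirs


def _load_stack(cfg: RunConfig, sample: SampleConfig, normalised_ok: bool = True) -> ChannelStack:
    channels = read_channel_table(cfg.channels_path)
    for directory, is_norm in _stack_dir_candidates(cfg, normalised_ok):
        marker = directory / f"{sample.sample_id}_channels.csv"
        if marker.exists():
            paths = [
                directory / f"{sample.sample_id}_{_sanitise(c.channel_name, c.index)}.tiff"
                for c in channels
            ]
            return read_stack(
                paths,
                channels,
                pixel_size_um=cfg.pixel_size_um,
                sample_id=sample.sample_id,
                normalised=is_norm,
            )
    if sample.images:
        return read_stack(
            [_resolve(cfg.config_dir, p) for p in sample.images],
            channels,
            pixel_size_um=cfg.pixel_size_um,
            sample_id=sample.sample_id,
        )
    if sample.imc_text:
        return parse_imc_text(
            _resolve(cfg.config_dir, sample.imc_text),
            channels,
            pixel_size_um=cfg.pixel_size_um,
            sample_id=sample.sample_id,
        )
    raise ConfigurationError(
        f"stage needs an image stack for sample {sample.sample_id!r}: expected "
        f"{cfg.output_dir / 'extract' / (sample.sample_id + '_channels.csv')} "
        "or images/imc_text in the config"
    )


def _load_masks(cfg: RunConfig, sample: SampleConfig) -> dict[str, BinaryMask]:
    masks = {}
    mask_dir = cfg.output_dir / "masks"
    for recipe in cfg.mask_recipes:
        p = mask_dir / f"{sample.sample_id}_{recipe.name}.tiff"
        if not p.exists():
            raise ConfigurationError(
                f"mask stage output missing for sample {sample.sample_id!r}: {p}"
            )
        masks[recipe.name] = BinaryMask(
            tifffile.imread(p) > 0, recipe.name, provenance=str(p)
        )
    return masks


def _load_labels(cfg: RunConfig, sample: SampleConfig) -> LabelImage:
    if sample.label_image:
        data = tifffile.imread(_resolve(cfg.config_dir, sample.label_image))
        return LabelImage(data.astype(np.int32))
    p = cfg.output_dir / "segment" / f"{sample.sample_id}_labels.tiff"
    if not p.exists():
        raise ConfigurationError(
            f"segment stage output missing for sample {sample.sample_id!r}: {p}"
        )
    return LabelImage(tifffile.imread(p).astype(np.int32))


def _load_cells(cfg: RunConfig, sample: SampleConfig, phenotyped: bool = True) -> pd.DataFrame:
    candidates = []
    if phenotyped:
        candidates.append(cfg.output_dir / "phenotype" / f"{sample.sample_id}_cells.csv")
    candidates.append(cfg.output_dir / "cells" / f"{sample.sample_id}_cells.csv")
    for p in candidates:
        if p.exists():
            return _read_cells_csv(p)
    if sample.cell_table:
        return _read_cells_csv(_resolve(cfg.config_dir, sample.cell_table))
    raise ConfigurationError(
        f"cell table missing for sample {sample.sample_id!r}: run the segment "
        f"stage first (expected one of {[str(c) for c in candidates]}) or supply "
        "an external cell_table in the config"
    )


def _read_cells_csv(path: Path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    for col in ("compartment", "cell_type"):
        if col in cells.columns:
            cells[col] = cells[col].astype(object)
    if "cluster_id" in cells.columns:
        cells["cluster_id"] = cells["cluster_id"].astype("Int64")
    return cells


def _write_cells(cells: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stages

def _stage_extract(cfg: RunConfig) -> None:
    out = cfg.output_dir / "extract"
    channels = read_channel_table(cfg.channels_path)
    for sample in cfg.samples:
        if sample.imc_text:
            stack = parse_imc_text(
                _resolve(cfg.config_dir, sample.imc_text),
                channels,
                pixel_size_um=cfg.pixel_size_um,
                sample_id=sample.sample_id,
            )
        elif sample.images:
            stack = read_stack(
                [_resolve(cfg.config_dir, p) for p in sample.images],
                channels,
                pixel_size_um=cfg.pixel_size_um,
                sample_id=sample.sample_id,
            )
        else:
            continue  # cell-table-only sample
        write_channels(stack, out, overwrite=True)


def _stage_normalise(cfg: RunConfig) -> None:
    if cfg.normalisation is None:
        return
    out = cfg.output_dir / "normalised"
    stacks = [
        _load_stack(cfg, s, normalised_ok=False)
        for s in cfg.samples
        if s.imc_text
        or s.images
        or (cfg.output_dir / "extract" / f"{s.sample_id}_channels.csv").exists()
    ]
    percentiles = None
    if cfg.normalisation.scope == "pooled_across_samples":
        percentiles = channel_percentiles(stacks, cfg.normalisation)
    for stack in stacks:
        normalised = normalise_percentile(stack, cfg.normalisation, percentiles)
        write_channels(normalised, out, overwrite=True)


def _stage_mask(cfg: RunConfig) -> None:
    out = cfg.output_dir / "masks"
    out.mkdir(parents=True, exist_ok=True)
    for sample in cfg.samples:
        if not (sample.imc_text or sample.images):
            continue
        stack = _load_stack(cfg, sample)
        built: dict[str, BinaryMask] = {}
        for recipe in cfg.mask_recipes:
            mask = run_mask_recipe(stack, recipe, built)
            built[recipe.name] = mask
            tifffile.imwrite(
                out / f"{sample.sample_id}_{recipe.name}.tiff",
                (mask.pixels.astype(np.uint8) * 255),
            )


def _segmentation_params(cfg: RunConfig, masks: dict[str, BinaryMask]) -> SegmentationParams:
    seg = cfg.segmentation or {}
    membrane_name = seg.get("membrane_mask")
    return SegmentationParams(
        nucleus_channel=seg["nucleus_channel"],
        nucleus_threshold=seg.get("nucleus_threshold", "otsu"),
        min_diameter_px=float(seg.get("min_diameter_px", 4)),
        max_diameter_px=float(seg.get("max_diameter_px", 60)),
        expansion=seg.get("expansion", "isotropic"),
        expansion_px=float(seg.get("expansion_px", 5)),
        membrane_mask=masks.get(membrane_name) if membrane_name else None,
    )


def _stage_segment(cfg: RunConfig) -> None:
    if cfg.segmentation is None:
        return
    seg_dir = cfg.output_dir / "segment"
    cells_dir = cfg.output_dir / "cells"
    seg_dir.mkdir(parents=True, exist_ok=True)
    for sample in cfg.samples:
        if not (sample.imc_text or sample.images):
            continue
        stack = _load_stack(cfg, sample)
        if sample.label_image:
            labels = _load_labels(cfg, sample)
        else:
            masks = _load_masks(cfg, sample) if cfg.mask_recipes else {}
            params = _segmentation_params(cfg, masks)
            nuclei = detect_nuclei(stack, params)
            labels = expand_cells(nuclei, stack, params)
        tifffile.imwrite(
            seg_dir / f"{sample.sample_id}_labels.tiff",
            labels.pixels.astype(np.int32),
        )
        cells = extract_features(labels, stack)
        _write_cells(cells, cells_dir / f"{sample.sample_id}_cells.csv")


def _stage_phenotype(cfg: RunConfig) -> None:
    out = cfg.output_dir / "phenotype"
    for sample in cfg.samples:
        cells = _load_cells(cfg, sample, phenotyped=False)
        if sample.imc_text or sample.images:
            labels = _load_labels(cfg, sample)
            masks = _load_masks(cfg, sample) if cfg.mask_recipes else {}
            for rule in cfg.compartments:
                unassigned = cells["compartment"].isna()
                updated = assign_compartment(cells, labels, rule, masks[rule.mask_name])
                cells.loc[unassigned, "compartment"] = updated.loc[
                    unassigned, "compartment"
                ]
            if cfg.retain_compartment:
                cells = cells[cells["compartment"] == cfg.retain_compartment].copy()
            if cfg.cell_type_rules:
                cells = assign_type_by_highest_overlap(
                    cells, labels, cfg.cell_type_rules, masks
                )
        gate_results: dict[str, pd.DataFrame] = {}
        for gate in cfg.gates:
            parent = gate_results.get(gate.parent_gate) if gate.parent_gate else None
            subset = gate_cells(cells, gate, parent=parent)
            gate_results[gate.name] = subset
            cells.loc[cells["cell_id"].isin(subset["cell_id"]), "cell_type"] = gate.name
            _write_cells(
                subset, out / f"{sample.sample_id}_gate_{gate.name}.csv"
            )
        _write_cells(cells, out / f"{sample.sample_id}_cells.csv")


def _stage_cluster(cfg: RunConfig) -> None:
    if cfg.clustering is None:
        return
    out = cfg.output_dir / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    frames = [_load_cells(cfg, s) for s in cfg.samples]
    cells = pd.concat(frames, ignore_index=True)
    subset_type = cfg.clustering.get("subset_cell_type")
    if subset_type:
        cells = cells[cells["cell_type"] == subset_type].copy()
    params = ClusterParams(
        markers=tuple(cfg.clustering["markers"]),
        scale=bool(cfg.clustering.get("scale", True)),
        n_pcs=int(cfg.clustering.get("n_pcs", min(10, len(cfg.clustering["markers"])))),
        k_neighbours=int(cfg.clustering.get("k_neighbours", 20)),
        resolution=float(cfg.clustering.get("resolution", 1.0)),
        seed=cfg.seed,
    )
    labels, profile = cluster_cells(cells, params)
    cells = cells.copy()
    cells["cluster_id"] = labels
    _write_cells(cells, out / "cells_clustered.csv")
    profile.to_csv(out / "cluster_profiles.csv", index=False)


def _stage_spatial(cfg: RunConfig) -> None:
    if cfg.spatial is None:
        return
    out = cfg.output_dir / "spatial"
    out.mkdir(parents=True, exist_ok=True)
    frames = [_load_cells(cfg, s) for s in cfg.samples]
    cells = pd.concat(frames, ignore_index=True)

    for h in cfg.spatial.get("homotypic", []) or []:
        params = HomotypicParams(
            min_points=int(h.get("min_points", 5)),
            density_per_mm2=h.get("density_per_mm2"),
            eps_um=h.get("eps_um"),
        )
        rows = []
        for sample_id, sub in cells[cells["cell_type"] == h["cell_type"]].groupby(
            "sample_id", sort=True
        ):
            sub = sub.copy()
            sub["homotypic_cluster"] = homotypic_clusters(sub, params)
            rows.append(sub)
        result = (
            pd.concat(rows, ignore_index=True)
            if rows
            else cells.iloc[0:0].assign(homotypic_cluster=[])
        )
        result.to_csv(out / f"homotypic_{h['cell_type']}.csv", index=False)

    het = cfg.spatial.get("heterotypic")
    if het:
        all_distances = []
        for source_type, target_type in het.get("comparisons", []):
            src = cells[cells["cell_type"] == source_type]
            tgt = cells[cells["cell_type"] == target_type]
            dist = nearest_distances(src, tgt, source_type, target_type)
            if het.get("cutoff_um"):
                dist = dist.copy()
                dist["proximity"] = classify_proximity(dist, float(het["cutoff_um"]))
            dist.to_csv(
                out / f"distances_{source_type}_{target_type}.csv", index=False
            )
            all_distances.append(dist)
        group_map = {
            s.sample_id: s.group for s in cfg.samples if s.group is not None
        }
        if all_distances and len(set(group_map.values())) == 2:
            pooled = pd.concat(all_distances, ignore_index=True)
            comparisons = [tuple(c) for c in het.get("comparisons", [])]
            results = compare_groups(
                pooled,
                group_map,
                comparisons,
                relevance_um=float(het.get("relevance_um", 8.0)),
                q_cutoff=float(het.get("q_cutoff", 0.1)),
            )
            comparisons_to_frame(results).to_csv(
                out / "group_comparisons.csv", index=False
            )
            k = int(het.get("n_permutations", 0))
            if k > 0:
                perms = permutation_tests(
                    cells, group_map, comparisons, n_permutations=k, seed=cfg.seed
                )
                permutations_to_frame(perms).to_csv(
                    out / "permutation_tests.csv", index=False
                )
                for r in perms:
                    pd.DataFrame({"null_delta_um": r.null_deltas}).to_csv(
                        out / f"null_{r.source_type}_{r.target_type}.csv",
                        index=False,
                    )


def _stage_pixel(cfg: RunConfig) -> None:
    if not cfg.pixel_area:
        return
    out = cfg.output_dir / "pixel"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in cfg.samples:
        if not (sample.imc_text or sample.images):
            continue
        masks = _load_masks(cfg, sample)
        for entry in cfg.pixel_area:
            result = positive_area(
                masks,
                entry["numerator"],
                entry["denominator"],
                sample_id=sample.sample_id,
            )
            rows.append(vars(result))
    pd.DataFrame(rows).to_csv(out / "pixel_area.csv", index=False)


_STAGE_FUNCS = {
    "extract": _stage_extract,
    "normalise": _stage_normalise,
    "mask": _stage_mask,
    "segment": _stage_segment,
    "phenotype": _stage_phenotype,
    "cluster": _stage_cluster,
    "spatial": _stage_spatial,
    "pixel": _stage_pixel,
}


def run(cfg: RunConfig, stages: Sequence[str] | None = None) -> Path:
    """Execute the requested stages in canonical order; returns the output dir."""
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ConfigurationError(f"unknown stage {s!r}; valid: {STAGES}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    executed = []
    for stage in STAGES:
        if stage in requested:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](cfg)
            executed.append(stage)
    log = {
        "tissuemux_version": __version__,
        "seed": cfg.seed,
        "pixel_size_um": cfg.pixel_size_um,
        "stages": executed,
        "samples": [s.sample_id for s in cfg.samples],
        "sample_seeds": {s.sample_id: cfg.sample_seed(s.sample_id) for s in cfg.samples},
    }
    with open(cfg.output_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return cfg.output_dir
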