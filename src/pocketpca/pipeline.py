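"""End-to-end reproduction pipeline: load → encode → fit → orient → project →
partition → logos → composition profiles, with a YAML config and a manifest.

The default run fits the PCA on the 117 cross-species binding-site sequences
(the human isotype panel excluded from the fit), orients PC1 on the fungal
Thr-23/Gly-26 feature and PC2 on the Ser-277 feature, partitions the fitting
set into sensitivity groups by feature-seeded nearest-centroid clustering,
places the isotype panel by variance-scaled distance to the fitted groups,
and writes deterministic TSV outputs plus a JSON manifest that suffices to
re-execute the run bit-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .dataset_io import (
    PBSRecord,
    column_of,
    family_counts,
    load_bundled_dataset,
    write_projection_table,
)
from .errors import ConfigError
from .grouping_logos import (
    GroupAssignment,
    LogoMatrix,
    assign_feature_seeded,
    assign_nearest_centroid,
    assign_quadrant,
    assign_scaled_centroid,
    carrier_mask,
    dominant_transitions,
    logo_matrix,
    orient_axes,
)
from .seqspace_pca import (
    CompositionProfile,
    PCAModel,
    composition_profile,
    fit_pca,
    onehot_encode,
    project,
)

logger = logging.getLogger("pocketpca.pipeline")

#: Default orientation features, as (residue number, letter) pairs on the
#: bundled dataset's variable positions.
DEFAULT_PC1_FEATURE = ((23, "T"), (26, "G"))
DEFAULT_PC2_FEATURE = ((277, "S"),)


@dataclass
class PipelineConfig:
    """Validated configuration of a reproduction run."""

    pdb_path: str | None = None  # optional: extract the binding site from a structure
    ligand: str | None = None  # "chain:resname" or "chain:resnum"
    cutoff: float = 5.0
    include_isotypes_in_fit: bool = False
    centering: str = "centered"
    orientation_pc1: tuple[tuple[int, str], ...] = DEFAULT_PC1_FEATURE
    orientation_pc2: tuple[tuple[int, str], ...] = DEFAULT_PC2_FEATURE
    assignment_method: str = "feature-seeded"
    isotype_assignment: str = "scaled-centroid"
    composition_t_values: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError(f"cutoff must be positive, got {self.cutoff}")
        if self.pdb_path is not None and not Path(self.pdb_path).exists():
            raise ConfigError(f"pdb_path {self.pdb_path!r} does not exist")
        if self.pdb_path is not None and self.ligand is None:
            raise ConfigError("pdb_path given without a ligand selector")
        if self.centering not in ("centered", "raw"):
            raise ConfigError(f"centering must be 'centered' or 'raw', got {self.centering!r}")
        if self.assignment_method not in ("feature-seeded", "quadrant"):
            raise ConfigError(f"unknown assignment_method {self.assignment_method!r}")
        if self.isotype_assignment not in ("scaled-centroid", "nearest-centroid", "quadrant"):
            raise ConfigError(f"unknown isotype_assignment {self.isotype_assignment!r}")


_CONFIG_TYPES: dict[str, type | tuple[type, ...]] = {
    "pdb_path": str,
    "ligand": str,
    "cutoff": (int, float),
    "include_isotypes_in_fit": bool,
    "centering": str,
    "orientation_pc1": list,
    "orientation_pc2": list,
    "assignment_method": str,
    "isotype_assignment": str,
    "composition_t_values": list,
    "out_dir": str,
    "seed": int,
}


def validate_config(source: str | Path | dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or a dict; unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        if raw is None:
            raw = {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key, value in raw.items():
        if key not in _CONFIG_TYPES:
            raise ConfigError(f"unknown config key {key!r}")
        expected = _CONFIG_TYPES[key]
        if value is not None and not isinstance(value, expected):
            raise ConfigError(
                f"config key {key!r}: expected {expected}, got {type(value).__name__}"
            )
    for key in ("orientation_pc1", "orientation_pc2"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple((int(p), str(c)) for p, c in raw[key])
    if "composition_t_values" in raw and raw["composition_t_values"] is not None:
        raw["composition_t_values"] = tuple(float(t) for t in raw["composition_t_values"])
    config = PipelineConfig(**raw)
    config.validate()
    return config


@dataclass
class ReproductionResult:
    """Everything a reproduction run computes."""

    records: list[PBSRecord]
    fit_records: list[PBSRecord]
    model: PCAModel
    projections: np.ndarray  # (n_records, 2), oriented, in config's centering mode
    assignments: list[GroupAssignment]
    family_logos: dict[str, LogoMatrix]
    group_logos: dict[str, LogoMatrix]
    profiles: dict[int, CompositionProfile]
    manifest: dict[str, Any]

    def assignment_of(self, organism: str) -> GroupAssignment:
        for rec, a in zip(self.records, self.assignments):
            if rec.organism == organism:
                return a
        raise KeyError(organism)


def _stage(name: str, start: float, n_in: int, n_out: int) -> None:
    logger.info("stage=%s in=%d out=%d elapsed=%.3fs", name, n_in, n_out, time.time() - start)


def run_reproduction(config: PipelineConfig | None = None) -> ReproductionResult:
    """Execute the full reproduction workflow on the bundled dataset."""
    config = config or PipelineConfig()
    config.validate()

    t0 = time.time()
    records = load_bundled_dataset(include_isotypes=True)
    fit_records = records if config.include_isotypes_in_fit else [
        r for r in records if not r.is_isotype
    ]
    _stage("load", t0, 0, len(records))

    contact_numbers: list[int] | None = None
    if config.pdb_path is not None:
        from .binding_site import extract_contact_residues, parse_structure

        t0 = time.time()
        chain, sel = config.ligand.split(":")
        selector = (chain, int(sel)) if sel.isdigit() else (chain, sel)
        structure = parse_structure(config.pdb_path)
        contacts = extract_contact_residues(structure, selector, cutoff=config.cutoff)
        contact_numbers = contacts.residue_numbers
        _stage("extract-site", t0, len(structure), len(contact_numbers))

    t0 = time.time()
    enc_fit = onehot_encode(fit_records)
    enc_all = onehot_encode(records)
    model = fit_pca(enc_fit)
    _stage("fit", t0, len(fit_records), model.eigenvalues.shape[0])

    t0 = time.time()
    features = {
        1: [(column_of(p), c) for p, c in config.orientation_pc1],
        2: [(column_of(p), c) for p, c in config.orientation_pc2],
    }
    model, _ = orient_axes(model, enc_fit, features)
    proj = np.column_stack(
        [project(model, enc_all, k, centering=config.centering) for k in (1, 2)]
    )
    _stage("orient+project", t0, len(records), proj.shape[0])

    # quadrant partitioning is defined on centered coordinates; under raw
    # centering the constant offset ā·V_k is removed before taking quadrants
    t0 = time.time()
    quad_coords = proj.copy()
    if config.centering == "raw":
        offset = np.array([model.means @ model.pc(k) for k in (1, 2)])
        quad_coords = proj - offset

    is_isotype = np.array([r.is_isotype for r in records])
    fit_mask = (
        np.ones(len(records), dtype=bool) if config.include_isotypes_in_fit else ~is_isotype
    )
    if config.assignment_method == "feature-seeded":
        training = assign_feature_seeded(
            quad_coords[fit_mask],
            carrier_mask(enc_all, features[1])[fit_mask],
            carrier_mask(enc_all, features[2])[fit_mask],
        )
    else:
        training = assign_quadrant(quad_coords[fit_mask], oriented=model.oriented)

    out_of_sample_idx = [i for i in range(len(records)) if not fit_mask[i]]
    if not out_of_sample_idx:
        oos_assignments: list[GroupAssignment] = []
    elif config.isotype_assignment == "scaled-centroid":
        oos_assignments = assign_scaled_centroid(quad_coords[out_of_sample_idx], training)
    elif config.isotype_assignment == "nearest-centroid":
        oos_assignments = assign_nearest_centroid(quad_coords[out_of_sample_idx], training)
    else:
        oos_assignments = assign_quadrant(
            quad_coords[out_of_sample_idx], oriented=model.oriented
        )

    assignments = []
    training_iter, oos_iter = iter(training), iter(oos_assignments)
    for i in range(len(records)):
        assignments.append(next(training_iter) if fit_mask[i] else next(oos_iter))
    _stage("assign", t0, len(records), len(assignments))

    t0 = time.time()
    family_logos = {
        fam: logo_matrix([r.pbs_string for r in records if r.family == fam])
        for fam in sorted({r.family for r in records})
    }
    group_logos = {
        g: logo_matrix(
            [r.pbs_string for r, a in zip(records, assignments) if a.group == g]
        )
        for g in sorted({a.group for a in assignments})
    }
    profiles = {
        k: composition_profile(model, k, config.composition_t_values) for k in (1, 2)
    }
    _stage("logos+profiles", t0, len(records), len(family_logos) + len(group_logos))

    manifest = {
        "package": "pocketpca",
        "version": __version__,
        "numpy": np.__version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "out_dir"},
            "orientation_pc1": [list(p) for p in config.orientation_pc1],
            "orientation_pc2": [list(p) for p in config.orientation_pc2],
            "composition_t_values": list(config.composition_t_values),
        },
        "n_records": len(records),
        "n_fit": len(fit_records),
        "contact_residues": contact_numbers,
        "family_counts": family_counts(records),
        "sign_flips": list(model.sign_flips),
        "orientation_flips": list(model.orientation_flips),
        "eigenvalue_top5": [float(v) for v in model.eigenvalues[:5]],
        "group_sizes": {
            g: sum(a.group == g for a in assignments)
            for g in sorted({a.group for a in assignments})
        },
    }

    result = ReproductionResult(
        records=records,
        fit_records=fit_records,
        model=model,
        projections=proj,
        assignments=assignments,
        family_logos=family_logos,
        group_logos=group_logos,
        profiles=profiles,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: ReproductionResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_projection_table(
        result.records,
        result.projections,
        out_dir / "projections.tsv",
        groups=[a.group for a in result.assignments],
    )
    lines = ["organism\tfamily\tpc1\tpc2\tgroup\tmethod\ttable_group\tmatches_table"]
    for rec, a in zip(result.records, result.assignments):
        match = "" if rec.group is None else str(a.group == rec.group).lower()
        lines.append(
            f"{rec.organism}\t{rec.family}\t{a.pc1:.6f}\t{a.pc2:.6f}"
            f"\t{a.group}\t{a.method}\t{rec.group or ''}\t{match}"
        )
    (out_dir / "groups.tsv").write_text("\n".join(lines) + "\n")

    logo_dir = out_dir / "logos"
    logo_dir.mkdir(exist_ok=True)
    for name, logo in {**result.family_logos, **{f"group_{g}": l for g, l in result.group_logos.items()}}.items():
        logo.to_frame().to_csv(logo_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.6f")

    for k, prof in result.profiles.items():
        prof.to_frame().to_csv(
            out_dir / f"composition_pc{k}.tsv", sep="\t", index=False, float_format="%.6f"
        )

    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")


def transitions_between(result: ReproductionResult, group_a: str, group_b: str):
    """Dominant majority-letter transitions between two assigned groups."""
    return dominant_transitions(result.group_logos[group_a], result.group_logos[group_b])
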