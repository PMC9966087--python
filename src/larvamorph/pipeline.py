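"""End-to-end analysis pipeline and its on-disk artifacts.

The chain mirrors the classic outline-morphometrics workflow: ingest
closed outlines (from files or the synthetic generator), resample, run
elliptic Fourier decomposition and normalization, fit the PCA
morphospace, and compute per-epoch occupation statistics.  Every run
writes a fixed artifact set — coefficients TSV, scores TSV, model JSON,
occupation JSON, a manifest with config/versions/checksums — and reruns
with the same config and inputs are bit-identical for tables and JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .efa import (
    EFACoefficients,
    coeffs_to_vector,
    efa_decompose,
    efa_normalize,
)
from .morphospace import (
    DEFAULT_PC_RULE,
    EffectivePcRule,
    MorphospaceModel,
    coefficient_matrix,
    fit_morphospace,
)
from .occupation import (
    accumulation_curve,
    group_occupation,
    hull_overlap,
    saturation_slope,
    subset_comparison,
    SATURATION_SLOPE_THRESHOLD,
)
from .outlines import OutlineContour, read_outline, resample_contour
from .specimens import load_paper_metadata
from .synthetic import CohortConfig, DEFAULT_COHORT, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "decompose_contours",
    "analyze_cohort",
    "run_pipeline",
    "write_coefficients_tsv",
    "read_coefficients_tsv",
    "write_scores_tsv",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``outline_dir`` + ``metadata_path`` (CSV/SVG/chain outlines on
    disk, named ``<specimen_id>.<ext>``) or a synthetic ``cohort``
    provide the input.  All settings are echoed into the run manifest.
    """

    output_dir: str | Path = "larvamorph_run"
    outline_dir: str | Path | None = None
    metadata_path: str | Path | None = None
    cohort: CohortConfig | None = None
    structure_class: str = "head_with_stylets"
    n_harmonics: int = 20
    n_points: int = 128
    standardize_reflection: bool = False
    pc_rule: EffectivePcRule = field(default_factory=lambda: DEFAULT_PC_RULE)
    occupation_pcs: tuple[int, int] = (1, 2)
    n_resamples: int = 100
    seed: int = 0
    make_plots: bool = True
    skip_missing: bool = False

    def validate(self) -> None:
        if self.cohort is None and self.outline_dir is None:
            raise ValueError("config needs either a cohort or an outline_dir")
        if self.cohort is not None and self.outline_dir is not None:
            raise ValueError("config cannot mix synthetic and on-disk inputs")
        if not 1 <= self.n_harmonics <= 64:
            raise ValueError("n_harmonics must lie in 1..64")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")


@dataclass
class PipelineResult:
    """In-memory view of a finished run."""

    model: MorphospaceModel
    coeffs: list[EFACoefficients]
    labels: list[dict]
    occupations: list
    artifacts: dict[str, Path]


def decompose_contours(
    contours: list[OutlineContour],
    n_harmonics: int = 20,
    n_points: int = 128,
    *,
    standardize_reflection: bool = False,
) -> list[EFACoefficients]:
    """Resample, decompose and normalize a batch of outlines."""
    out = []
    for c in contours:
        res = resample_contour(c, n_points) if c.n_points != n_points else c
        raw = efa_decompose(res, n_harmonics)
        norm, _ = efa_normalize(raw, standardize_reflection=standardize_reflection)
        out.append(norm)
    return out


def analyze_cohort(
    contours: list[OutlineContour],
    labels: list[dict],
    *,
    n_harmonics: int = 20,
    n_points: int = 128,
    pc_rule: EffectivePcRule = DEFAULT_PC_RULE,
    standardize_reflection: bool = False,
    structure_class: str | None = None,
) -> tuple[MorphospaceModel, list[EFACoefficients]]:
    """Outlines + labels -> fitted morphospace (the library-level core)."""
    if len(contours) != len(labels):
        raise ValueError("contours and labels length mismatch")
    coeffs = decompose_contours(
        contours,
        n_harmonics,
        n_points,
        standardize_reflection=standardize_reflection,
    )
    matrix = coefficient_matrix(coeffs)
    ids = tuple(lab["specimen_id"] for lab in labels)
    model = fit_morphospace(
        matrix, pc_rule, specimen_ids=ids, structure_class=structure_class
    )
    return model, coeffs


# ---------------------------------------------------------------------------
# tables


def _coeff_columns(n_harmonics: int) -> list[str]:
    cols = ["specimen_id", "A0", "C0"]
    for n in range(1, n_harmonics + 1):
        cols += [f"a{n}", f"b{n}", f"c{n}", f"d{n}"]
    return cols


def write_coefficients_tsv(
    coeffs: list[EFACoefficients], ids: list[str], path: str | Path
) -> None:
    """SHAPE-style coefficient table: one row per specimen.

    Column order: specimen_id, A0, C0, a1, b1, c1, d1, a2, ... dN.
    Floats are written with full precision (repr) so the table
    round-trips bit-exactly.
    """
    n_h = coeffs[0].n_harmonics
    lines = ["\t".join(_coeff_columns(n_h))]
    for cid, c in zip(ids, coeffs):
        vals = [c.A0, c.C0, *coeffs_to_vector(c)]
        lines.append("\t".join([cid, *(repr(float(v)) for v in vals)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients_tsv(path: str | Path) -> tuple[list[EFACoefficients], list[str]]:
    df = pd.read_csv(
        path, sep="\t", dtype={"specimen_id": str}, float_precision="round_trip"
    )
    n_h = (df.shape[1] - 3) // 4
    coeffs, ids = [], []
    for row in df.itertuples(index=False):
        vec = np.array(row[3:], dtype=float)
        coeffs.append(
            EFACoefficients(
                harmonics=vec.reshape(n_h, 4),
                A0=float(row.A0),
                C0=float(row.C0),
                normalized=bool(
                    abs(vec[0] - 1.0) < 1e-9 and abs(vec[1]) < 1e-9
                ),
            )
        )
        ids.append(row.specimen_id)
    return coeffs, ids


def write_scores_tsv(
    model: MorphospaceModel, labels: list[dict], path: str | Path
) -> None:
    """Scores table: specimen_id, epoch, PC1..PCk (full precision)."""
    k = model.scores.shape[1]
    header = ["specimen_id", "epoch"] + [f"PC{i}" for i in range(1, k + 1)]
    lines = ["\t".join(header)]
    for lab, row in zip(labels, model.scores):
        lines.append(
            "\t".join(
                [lab["specimen_id"], str(lab.get("epoch", ""))]
                + [repr(float(v)) for v in row]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the runner


def _load_disk_inputs(config: PipelineConfig) -> tuple[list[OutlineContour], list[dict]]:
    records = load_paper_metadata(config.metadata_path)
    outline_dir = Path(config.outline_dir)
    contours, labels, missing = [], [], []
    for rec in records:
        if not rec.included_in_analysis:
            logger.warning("specimen %s excluded from analysis", rec.specimen_no)
            continue
        sid = rec.repository_id.replace(" ", "_") or f"specimen_{rec.specimen_no}"
        found = None
        for ext in ("csv", "svg", "chain"):
            p = outline_dir / f"{sid}.{ext}"
            if p.exists():
                found = p
                break
        if found is None:
            missing.append(sid)
            continue
        contours.append(read_outline(found, specimen_id=sid))
        labels.append(
            {
                "specimen_id": sid,
                "epoch": rec.epoch.value,
                "morphotype": rec.labrum_morphotype.value,
            }
        )
    if missing and not config.skip_missing:
        raise FileNotFoundError(
            f"missing outlines for {len(missing)} included specimen(s): "
            f"{', '.join(missing[:5])}{' ...' if len(missing) > 5 else ''}"
        )
    return contours, labels


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain and write all artifacts to ``config.output_dir``."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        cohort = dataclasses.replace(
            config.cohort,
            seed=config.seed,
            n_harmonics=config.n_harmonics,
            n_points=config.n_points,
        )
        contours, labels, _ = generate_cohort(cohort)
        logger.info("generated synthetic cohort: %d specimens", len(contours))
    else:
        contours, labels = _load_disk_inputs(config)
        logger.info("ingested %d outlines", len(contours))

    model, coeffs = analyze_cohort(
        contours,
        labels,
        n_harmonics=config.n_harmonics,
        n_points=config.n_points,
        pc_rule=config.pc_rule,
        standardize_reflection=config.standardize_reflection,
        structure_class=config.structure_class,
    )
    ids = [lab["specimen_id"] for lab in labels]
    epochs = [lab.get("epoch", "all") for lab in labels]

    occs = group_occupation(model.scores, epochs, config.occupation_pcs)
    overlap = {
        a.group: {b.group: hull_overlap(a, b) for b in occs} for a in occs
    }
    i, j = config.occupation_pcs[0] - 1, config.occupation_pcs[1] - 1
    plane = model.scores[:, [i, j]]
    curves = {}
    for occ in occs:
        if occ.n >= 3 and not occ.degenerate:
            pts = plane[np.array([e == occ.group for e in epochs])]
            curve = accumulation_curve(
                pts, n_resamples=config.n_resamples, seed=config.seed
            )
            curves[occ.group] = curve
        else:
            logger.warning(
                "group %s degenerate (n=%d): no accumulation curve",
                occ.group,
                occ.n,
            )

    artifacts: dict[str, Path] = {}
    artifacts["coefficients"] = outdir / "coefficients.tsv"
    write_coefficients_tsv(coeffs, ids, artifacts["coefficients"])
    artifacts["scores"] = outdir / "scores.tsv"
    write_scores_tsv(model, labels, artifacts["scores"])
    artifacts["model"] = outdir / "model.json"
    model.to_json(artifacts["model"])
    artifacts["occupation"] = outdir / "occupation.json"
    _write_occupation_json(artifacts["occupation"], occs, overlap, curves)

    if config.make_plots:
        from .viz import plot_morphospace

        artifacts["morphospace_plot"] = outdir / "morphospace.png"
        plot_morphospace(
            model.scores,
            epochs,
            occs,
            variance_explained=model.variance_explained,
            pcs=config.occupation_pcs,
            path=artifacts["morphospace_plot"],
        )

    artifacts["manifest"] = outdir / "manifest.json"
    _write_manifest(artifacts["manifest"], config, artifacts)
    return PipelineResult(
        model=model,
        coeffs=coeffs,
        labels=labels,
        occupations=occs,
        artifacts=artifacts,
    )


def _write_occupation_json(path: Path, occs, overlap, curves) -> None:
    payload = {
        "groups": [
            {
                "group": o.group,
                "n": o.n,
                "area": o.area,
                "degenerate": o.degenerate,
                "hull_vertices": o.hull_vertices.tolist(),
            }
            for o in occs
        ],
        "overlap": overlap,
        "accumulation": {
            g: {
                "k": c.k.tolist(),
                "mean_area": c.mean_area.tolist(),
                "ci_low": c.ci_low.tolist(),
                "ci_high": c.ci_high.tolist(),
                "n_resamples": c.n_resamples,
                "seed": c.seed,
                "saturation_slope": (
                    saturation_slope(c) if len(c.k) >= 5 and c.full_area > 0 else None
                ),
                "saturated": (
                    bool(saturation_slope(c) < SATURATION_SLOPE_THRESHOLD)
                    if len(c.k) >= 5 and c.full_area > 0
                    else None
                ),
            }
            for g, c in curves.items()
        },
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["pc_rule"] = repr(config.pc_rule)
    for key in ("output_dir", "outline_dir", "metadata_path"):
        if d[key] is not None:
            d[key] = str(d[key])
    return d


def _write_manifest(path: Path, config: PipelineConfig, artifacts: dict) -> None:
    checksums = {}
    for name, p in artifacts.items():
        if p != path and p.exists():
            checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": {"larvamorph": __version__, "numpy": np.__version__},
        "artifact_checksums": checksums,
    }
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
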