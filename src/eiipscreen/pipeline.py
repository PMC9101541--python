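"""End-to-end screening workflow: filter → rank → interactions → ADMET.

Mirrors the funnel of the 5HT6 campaign: an EIIP/AQVN window filter over
the input library, PCA centroid-distance ranking of the survivors against
a learning set (top ten per window), geometric interaction reports on
externally docked poses, and rule-based ADMET profiling.  Docking itself
is an explicit external gap — the pipeline consumes user-supplied docked
poses rather than silently skipping the interaction stage.

The pipeline is a pure function of (inputs, config, seed): repeated runs
produce identical reports.  Every stage logs its counts, and a run
manifest (config hash, package version, seed, per-stage counts) is written
next to the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admet import druglikeness_report
from .chem_io import read_pdb_complex, read_property_table, read_sdf, read_smiles_table
from .eiip import DomainWindow, ValenceTable, screen_library
from .interactions import (
    DEFAULT_SITE_CENTER,
    GeometryThresholds,
    detect_all,
    interaction_fingerprint,
    select_binding_site,
)
from .pca_screen import DescriptorMatrix, centroid_distance_rank, fit_pca, select_top_k

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_screening_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a screening run needs, serializable to/from YAML."""

    library: Optional[str] = None  # SDF or SMILES table
    windows: list[dict] = field(
        default_factory=lambda: [
            {"label": "2.55", "center": 2.55, "halfwidth": 0.005},
            {"label": "2.72", "center": 2.72, "halfwidth": 0.005},
            {"label": "2.99", "center": 2.99, "halfwidth": 0.005},
        ]
    )
    learning_csv: Optional[str] = None
    candidates_csv: Optional[str] = None
    components: int = 5
    top: int = 10
    poses: list[dict] = field(default_factory=list)  # {path, ligand, center?, radius?}
    site_radius: float = 15.0
    site_center: Optional[list[float]] = None
    thresholds: dict = field(default_factory=dict)
    property_csv: Optional[str] = None
    temperature: float = 298.0
    seed: int = 0
    outdir: str = "results"

    def domain_windows(self) -> list[DomainWindow]:
        return [
            DomainWindow(
                label=str(w["label"]),
                aqvn_center=float(w["center"]),
                aqvn_halfwidth=float(w.get("halfwidth", 0.005)),
                eiip_min=w.get("eiip_min"),
                eiip_max=w.get("eiip_max"),
            )
            for w in self.windows
        ]

    def geometry_thresholds(self) -> GeometryThresholds:
        return GeometryThresholds(**self.thresholds)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _read_descriptor_csv(path: str) -> DescriptorMatrix:
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    return DescriptorMatrix(ids=ids, X=X, descriptor_names=list(df.columns[1:]))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    try:
        windows = config.domain_windows()
    except (KeyError, ValueError, TypeError) as exc:
        return [f"windows: {exc}"]
    for i, a in enumerate(windows):
        for b in windows[i + 1 :]:
            if a.aqvn_lo <= b.aqvn_hi and b.aqvn_lo <= a.aqvn_hi:
                problems.append(f"windows: {a.label!r} and {b.label!r} overlap in AQVN")
    for name in ("library", "learning_csv", "candidates_csv", "property_csv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: path {p!r} does not exist")
    for pose in config.poses:
        if "path" not in pose or "ligand" not in pose:
            problems.append("poses: each pose needs 'path' and 'ligand'")
        elif not Path(pose["path"]).exists():
            problems.append(f"poses: path {pose['path']!r} does not exist")
    if config.components < 1:
        problems.append("components: must be >= 1")
    if config.learning_csv and Path(config.learning_csv).exists():
        try:
            learning = _read_descriptor_csv(config.learning_csv)
            if config.components > min(learning.X.shape[0] - 1, learning.X.shape[1]):
                problems.append(
                    f"components: {config.components} exceeds the usable rank of "
                    f"the learning matrix {learning.X.shape}"
                )
        except Exception as exc:  # malformed CSV is a config problem, not a crash
            problems.append(f"learning_csv: {exc}")
    if config.top < 1:
        problems.append("top: must be >= 1")
    if config.temperature <= 0:
        problems.append("temperature: must be > 0")
    try:
        config.geometry_thresholds()
    except (TypeError, ValueError) as exc:
        problems.append(f"thresholds: {exc}")
    return problems


def run_screening_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage and write reports under ``config.outdir``.

    Returns the report bundle (also serialized as JSON/TSV files).  Any
    stage failure raises with the stage name; partial outputs from earlier
    stages are retained on disk.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"stages": {}, "counts": {}}
    windows = config.domain_windows()

    # stage 1: EIIP/AQVN filter
    if config.library:
        stage = "screen"
        try:
            path = Path(config.library)
            if path.suffix.lower() in (".smi", ".smiles", ".txt"):
                records, _ = read_smiles_table(path)
            else:
                records, _ = read_sdf(path)
            result = screen_library(records, windows, ValenceTable())
            rows = []
            for label, pairs in result.survivors.items():
                for rec, desc in pairs:
                    rows.append(
                        {"id": rec.id, "aqvn": round(desc.aqvn, 4),
                         "eiip": round(desc.eiip, 4), "window": label}
                    )
            pd.DataFrame(rows, columns=["id", "aqvn", "eiip", "window"]).to_csv(
                outdir / "screen.tsv", sep="\t", index=False
            )
            bundle["stages"][stage] = rows
            bundle["counts"]["library"] = result.n_input
            bundle["counts"]["filter_survivors"] = result.n_survivors
            logger.info(
                "screen: %d molecules in, %d survivors", result.n_input, result.n_survivors
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'screen' failed: {exc}") from exc

    # stage 2: PCA centroid-distance ranking
    if config.learning_csv and config.candidates_csv:
        stage = "rank"
        try:
            learning = _read_descriptor_csv(config.learning_csv)
            candidates = _read_descriptor_csv(config.candidates_csv)
            survivors = {
                r["id"] for r in bundle["stages"].get("screen", [])
            }
            if survivors and survivors & set(candidates.ids):
                keep = [i for i, cid in enumerate(candidates.ids) if cid in survivors]
                candidates = DescriptorMatrix(
                    ids=[candidates.ids[i] for i in keep],
                    X=candidates.X[keep],
                    descriptor_names=candidates.descriptor_names,
                )
            model = fit_pca(learning, k=config.components)
            ranked = centroid_distance_rank(model, candidates)
            top = select_top_k(ranked, config.top)
            df = pd.DataFrame(
                [(rid, d, i + 1) for i, (rid, d) in enumerate(ranked)],
                columns=["id", "distance", "rank"],
            )
            df.to_csv(outdir / "rank.tsv", sep="\t", index=False)
            bundle["stages"][stage] = {
                "ranked": ranked,
                "top": top,
                "explained_variance": model.cumulative_explained_variance,
            }
            bundle["counts"]["ranked"] = len(ranked)
            bundle["counts"]["top_k"] = len(top)
            logger.info("rank: %d candidates, top %d selected", len(ranked), len(top))
        except Exception as exc:
            raise RuntimeError(f"stage 'rank' failed: {exc}") from exc

    # stage 3: interaction reports on docked poses
    if config.poses:
        stage = "interactions"
        try:
            thresholds = config.geometry_thresholds()
            center = tuple(config.site_center) if config.site_center else DEFAULT_SITE_CENTER
            reports = {}
            for pose in config.poses:
                c = read_pdb_complex(pose["path"], pose["ligand"])
                site = select_binding_site(
                    c, pose.get("center", center), pose.get("radius", config.site_radius)
                )
                records = detect_all(site, thresholds)
                fp = interaction_fingerprint(site, thresholds)
                reports[pose["path"]] = {
                    "records": [
                        {"type": r.type, "residue": r.receptor_residue,
                         "distance": round(r.distance, 3),
                         "angles": {k: round(v, 2) for k, v in r.angles.items()}}
                        for r in records
                    ],
                    "fingerprint": {str(k): sorted(v) for k, v in fp.items()},
                }
            (outdir / "interactions.json").write_text(json.dumps(reports, indent=2))
            bundle["stages"][stage] = reports
            bundle["counts"]["poses"] = len(reports)
        except Exception as exc:
            raise RuntimeError(f"stage 'interactions' failed: {exc}") from exc

    # stage 4: ADMET rule profiling
    if config.property_csv:
        stage = "admet"
        try:
            rows = read_property_table(config.property_csv)
            reports, summary = druglikeness_report(rows)
            df = pd.DataFrame(
                [
                    {"id": r.id, "vrf": r.vrf, "vrt": r.vrt,
                     "vrf_reasons": ";".join(r.vrf_reasons),
                     "vrt_reasons": ";".join(r.vrt_reasons),
                     "bbb_in_range": r.bbb_in_range}
                    for r in reports
                ]
            )
            df.to_csv(outdir / "admet.tsv", sep="\t", index=False)
            bundle["stages"][stage] = {
                "max_violations": summary,
                "n_rows": len(reports),
            }
            bundle["counts"]["admet_rows"] = len(reports)
            logger.info("admet: %d rows, max violations %s", len(reports), summary)
        except Exception as exc:
            raise RuntimeError(f"stage 'admet' failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "counts": bundle["counts"],
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
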