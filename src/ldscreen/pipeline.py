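"""End-to-end orchestration: simulate -> (segment -> features) -> score ->
call hits -> report, with a manifest sufficient to reproduce the run."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .imaging import segment_cells, segment_nuclei, segment_puncta
from .io import RunConfig, read_field_tiff, write_features, write_hits, write_scores
from .morphometry import aggregate_well, object_features
from .screenstats import PARAMETERS, call_hits, score_plate, zprime
from .synthgen import (
    PROFILES,
    PhenotypeProfile,
    SceneSpec,
    build_plate,
    make_default_plate,
)

__all__ = ["run_pipeline", "planted_profiles", "segment_field", "features_from_images"]


def planted_profiles(planted_cfg: dict) -> dict[str, PhenotypeProfile]:
    """Config planted-effect entries -> profiles.

    Each value is either the name of a preset profile or a mapping of
    PhenotypeProfile keyword arguments."""
    out: dict[str, PhenotypeProfile] = {}
    for cid, val in planted_cfg.items():
        if isinstance(val, str):
            out[cid] = PROFILES[val]
        else:
            kwargs = dict(val)
            kwargs.setdefault("name", cid)
            out[cid] = PhenotypeProfile(**kwargs)
    return out


def segment_field(img, seg_cfg: dict):
    """Run the three-stage segmentation on one field; returns (nuclei, cells,
    puncta) label maps."""
    nuclei = segment_nuclei(img, **seg_cfg.get("nuclei", {}))
    cells = segment_cells(img, nuclei, **seg_cfg.get("cells", {}))
    puncta = segment_puncta(img, cells, **seg_cfg.get("puncta", {}))
    return nuclei, cells, puncta


def features_from_images(field_index: pd.DataFrame, seg_cfg: dict) -> pd.DataFrame:
    """Segment every field listed in ``field_index`` and aggregate per well."""
    rows = []
    for (well,), grp in field_index.groupby(["well"], sort=True):
        feats, counts, orphans = [], [], 0
        for _, rec in grp.sort_values("field").iterrows():
            img = read_field_tiff(rec["path"])
            _, cells, puncta = segment_field(img, seg_cfg)
            feats.append(object_features(puncta, img.pixel_size))
            counts.append(cells.n_objects)
            orphans += puncta.qc.get("orphan_puncta", 0)
        ws = aggregate_well(feats, counts, well=well, orphan_puncta=orphans)
        first = grp.iloc[0]
        rows.append({"well": well, "role": first["role"],
                     "cell_line": first["cell_line"],
                     "compound_id": first["compound_id"],
                     "concentration_uM": 10.0, **ws.as_dict()})
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain described by ``config``; returns the manifest.

    Artifacts written under ``config.out_dir``: features.csv, scores.csv,
    hits.csv, scatter_<parameter>.csv (value vs score, for the per-parameter
    scatter plots), qc.json (Z' per control line, excluded wells) and
    manifest.json (inputs, parameters, seed, version, per-stage counts,
    output checksums).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = SceneSpec(**{"seed": config.seed, **config.scene})
    plate = make_default_plate(
        n_compounds=config.n_compounds, seed=config.seed, base_scene=scene,
        fields_per_well=config.fields_per_well, **config.plate,
    )
    planted = planted_profiles(config.planted)

    if config.mode == "features":
        features, gen_manifest = build_plate(plate, planted, mode="features",
                                             noise_model=config.noise)
    else:
        img_dir = out / "images"
        field_index, gen_manifest = build_plate(plate, planted, mode="images",
                                                out_dir=img_dir)
        field_index.to_csv(out / "fields.csv", index=False)
        features = features_from_images(field_index, config.segmentation)
    feat_path = write_features(features, out / "features.csv")

    scores = score_plate(features, **config.scoring)
    score_path = write_scores(scores, out / "scores.csv")
    hits = call_hits(scores, thresholds=config.thresholds,
                     directions=config.directions)
    hits_path = write_hits(hits, out / "hits.csv")

    for p in PARAMETERS:
        scatter = scores.scores[["compound_id", f"value_{p}", f"z_{p}"]]
        scatter.to_csv(out / f"scatter_{p}.csv", index=False)

    qc: dict = {"zprime": {}, "excluded_wells": sorted(
        features.loc[features["qc_flags"].astype(str) != "", "well"].tolist())}
    neg = features[features["role"] == "negative_control"]["ld_total_area"]
    for line, grp in features[features["role"] == "positive_control"].groupby("cell_line"):
        if len(grp) >= 2 and len(neg) >= 2:
            zp = zprime(grp["ld_total_area"], neg)
            qc["zprime"][line] = {"value": zp.value, "n_pos": zp.n_pos,
                                  "n_neg": zp.n_neg, "flags": zp.flags}
    (out / "qc.json").write_text(json.dumps(qc, indent=1))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "generator": gen_manifest,
        "counts": {
            "wells": int(len(features)),
            "compound_wells": int((features["role"] == "compound").sum()),
            "scored_compounds": int(len(scores.scores)),
            "hits": int(hits["hit"].sum()),
            "excluded_compounds": int(hits["excluded"].sum()),
        },
        "outputs": {p.name: _sha256(p) for p in (feat_path, score_path, hits_path)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
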