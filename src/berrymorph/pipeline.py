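"""End-to-end orchestration: simulate -> phenotype -> ph -> blup -> scan.

A run is driven by a single YAML/dict config with one top-level seed that
fans out to fixed per-stage child seeds, so stages can be rerun
independently yet reproducibly.  Each stage reads only files written by
upstream stages; a JSON manifest records the config hash, per-stage
timings and the SHA-256 checksum of every artifact, so identical configs
can be verified to reproduce identical outputs.

Two phenotype modes exist: ``images`` renders scene PNGs and measures
them through the segmentation + topology stages (the full pipeline), and
``tabular`` simulates the seven trait values directly (fast; used when
image analysis itself is not under study).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .genetics import genotype_means, fit_all_traits, kinship
from .mask import BinaryMask
from .phenotyping import SegmentationConfig, phenotype_scene
from .qtl import (calc_genoprob, collocate, hk_scan, models_to_table,
                  perm_threshold, stepwise_additive)
from .synthetic import (PlantedQTL, SceneSpec, ShapeArchitecture, TraitModel,
                        compose_scene, make_linkage_map, shape_params_from_row,
                        simulate_cross, simulate_fruit_geometry,
                        simulate_phenotypes)
from .topology import PHConfig, fit_pca, ph_descriptor

TRAIT_COLS = ["length", "width", "area", "lw_ratio", "eccentricity", "pc1", "pc2"]

# fixed per-stage seed offsets: rerunning one stage reuses the same stream
STAGE_SEED = {"simulate": 11, "phenotype": 23, "ph": 37, "scan": 53}


class StageDependencyError(RuntimeError):
    """An enabled stage is missing an upstream artifact."""


def default_config() -> dict:
    """Demo-scale configuration: 48 genotypes on a 2-LG map."""
    return {
        "seed": 1,
        "out_dir": "runs/demo",
        "stages": {"simulate": True, "phenotype": True, "ph": True,
                   "blup": True, "scan": True, "collocate": True, "report": True},
        "scene": {"px_per_mm": 3.0, "ref_diameter_mm": 25.4, "n_fruit": 25,
                  "image_size": [900, 1200]},
        "cross": {"n_genotypes": 48, "n_lg": 2, "n_markers": 62,
                  "lg_length_cm": 60.0},
        "phenotype": {"n_years": 2, "mode": "images",
                      "qtl": {"lg": 2, "cm": 30.0, "var_frac": 0.25,
                              "target": "elong"},
                      "polygenic_h2": 0.3},
        "ph": {"annuli": 4, "levels": 30, "bandwidth_frac": 0.2},
        "scan": {"step_cm": 2.0, "n_perm": 200, "alpha": 0.05, "max_qtl": 4},
        "collocate": {"window_cm": 8.0, "min_years": 2},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageDependencyError(f"stage {stage!r} needs missing artifact {path}")
    return path


def _architecture(cfg: dict) -> ShapeArchitecture:
    ph_cfg = cfg["phenotype"]
    q = ph_cfg.get("qtl")
    size = TraitModel("size", polygenic_h2=ph_cfg.get("polygenic_h2", 0.3))
    elong = TraitModel("elong", polygenic_h2=ph_cfg.get("polygenic_h2", 0.3))
    if q:
        planted = PlantedQTL(q["lg"], float(q["cm"]), var_frac=float(q["var_frac"]))
        target = size if q.get("target", "elong") == "size" else elong
        target.qtls.append(planted)
    return ShapeArchitecture(size, elong)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    cfg = json.loads(json.dumps(config))  # deep copy; also ensures JSON-ability
    out = Path(out_dir or cfg.get("out_dir", "runs/run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", {})
    manifest: dict = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "stages": {},
    }

    def record(name: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "status": "done",
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    def skipped(name: str) -> None:
        manifest["stages"][name] = {"status": "skipped"}

    scene_cfg = cfg["scene"]
    cross_cfg = cfg["cross"]
    ph_cfg = cfg["phenotype"]
    mode = ph_cfg.get("mode", "images")
    n_years = int(ph_cfg.get("n_years", 2))
    years = [2014 + k for k in range(n_years)]

    # ---- simulate -------------------------------------------------------
    if stages.get("simulate", True):
        t0 = time.time()
        gmap = make_linkage_map(int(cross_cfg["n_markers"]), int(cross_cfg["n_lg"]),
                                float(cross_cfg["lg_length_cm"]))
        q = ph_cfg.get("qtl")
        extra = [(q["lg"], float(q["cm"]))] if q else []
        cross = simulate_cross(gmap, int(cross_cfg["n_genotypes"]),
                               seed + STAGE_SEED["simulate"], extra_loci=extra)
        bio.write_fourway_csv(cross, out / "cross.csv")
        outputs = [out / "cross.csv"]
        if mode == "images":
            arch = _architecture(cfg)
            geom = simulate_fruit_geometry(
                cross, arch, n_years=n_years,
                n_fruit=int(scene_cfg.get("n_fruit", 25)),
                seed=seed + STAGE_SEED["simulate"] + 1)
            geom.to_csv(out / "geometry_truth.csv", index=False)
            scenes_dir = out / "scenes"
            scenes_dir.mkdir(exist_ok=True)
            outputs.append(out / "geometry_truth.csv")
            for i, ((gid, yr), sub) in enumerate(geom.groupby(["genotype", "year"],
                                                              sort=True)):
                fruits = [shape_params_from_row(r) for _, r in sub.iterrows()]
                spec = SceneSpec(
                    fruits=fruits,
                    px_per_mm=float(scene_cfg["px_per_mm"]),
                    ref_diameter_mm=float(scene_cfg["ref_diameter_mm"]),
                    image_size=tuple(scene_cfg["image_size"]),
                )
                img, _truth = compose_scene(spec, seed + STAGE_SEED["simulate"] + 2 + i)
                p = scenes_dir / f"{gid}_{yr}.png"
                bio.write_scene_png(img, p)
                outputs.append(p)
        else:
            models = [
                TraitModel(t, polygenic_h2=ph_cfg.get("polygenic_h2", 0.3))
                for t in TRAIT_COLS
            ]
            if q:
                target = {"size": "length", "elong": "lw_ratio"}.get(
                    q.get("target", "elong"), q.get("target"))
                for m in models:
                    if m.name == target:
                        m.qtls.append(PlantedQTL(q["lg"], float(q["cm"]),
                                                 var_frac=float(q["var_frac"])))
            per_fruit, _ = simulate_phenotypes(
                cross, models, n_years=n_years,
                n_fruit=int(scene_cfg.get("n_fruit", 25)),
                seed=seed + STAGE_SEED["simulate"] + 1)
            per_fruit.to_csv(out / "fruit_traits.csv", index=False)
            outputs.append(out / "fruit_traits.csv")
        record("simulate", t0, outputs)
    else:
        skipped("simulate")

    # ---- phenotype (segmentation + basic descriptors) -------------------
    if stages.get("phenotype", True) and mode == "images":
        t0 = time.time()
        scenes_dir = _need(out / "scenes", "phenotype")
        masks_dir = out / "masks"
        masks_dir.mkdir(exist_ok=True)
        ref_d_px = float(scene_cfg["ref_diameter_mm"]) * float(scene_cfg["px_per_mm"])
        seg_cfg = SegmentationConfig(expected_ref_diameter_px=ref_d_px)
        rows = []
        outputs = []
        for p in sorted(scenes_dir.glob("*.png")):
            gid, yr = p.stem.rsplit("_", 1)
            img = bio.read_scene_png(p)
            table, masks = phenotype_scene(
                img, float(scene_cfg["ref_diameter_mm"]), seg_cfg, scene_id=p.stem)
            table.insert(0, "genotype", gid)
            table.insert(1, "year", int(yr))
            rows.append(table)
            for k, m in enumerate(masks):
                mp = masks_dir / f"{p.stem}_f{k:02d}.png"
                bio.write_mask_png(m.grid, mp)
            outputs.append(p)  # scenes are inputs; keep list small: skip masks hash
        traits = pd.concat(rows, ignore_index=True)
        traits["mm_per_px"] = np.nan
        traits = traits.rename(columns={"length_mm": "length", "width_mm": "width",
                                        "area_mm2": "area"})
        traits.to_csv(out / "fruit_traits.csv", index=False)
        record("phenotype", t0, [out / "fruit_traits.csv"])
    else:
        skipped("phenotype")

    # ---- ph (topological descriptors + PCA scores) ----------------------
    if stages.get("ph", True) and mode == "images":
        t0 = time.time()
        masks_dir = _need(out / "masks", "ph")
        traits = pd.read_csv(_need(out / "fruit_traits.csv", "ph"))
        ph_conf = PHConfig(int(cfg["ph"]["annuli"]), int(cfg["ph"]["levels"]),
                           float(cfg["ph"]["bandwidth_frac"]))
        descs = []
        keys = []
        for p in sorted(masks_dir.glob("*.png")):
            stem, fid = p.stem.rsplit("_f", 1)
            gid, yr = stem.rsplit("_", 1)
            grid = bio.read_mask_png(p)
            descs.append(ph_descriptor(BinaryMask(grid), ph_conf))
            keys.append((gid, int(yr), int(fid)))
        D = np.vstack(descs)
        key_df = pd.DataFrame(keys, columns=["genotype", "year", "fruit_id"])
        desc_df = pd.concat(
            [key_df, pd.DataFrame(D, columns=[f"v{i + 1}" for i in range(D.shape[1])])],
            axis=1)
        desc_df.to_csv(out / "descriptors.csv", index=False)
        # PCA per year (scores comparable within a year's panel)
        scores = np.full((len(key_df), 2), np.nan)
        for yr in key_df["year"].unique():
            sel = (key_df["year"] == yr).to_numpy()
            model = fit_pca(D[sel])
            scores[sel] = model.scores[:, :2]
        key_df[["pc1", "pc2"]] = scores
        key_df.to_csv(out / "scores.csv", index=False)
        traits = traits.merge(key_df, on=["genotype", "year", "fruit_id"], how="left")
        traits.to_csv(out / "fruit_traits.csv", index=False)
        record("ph", t0, [out / "descriptors.csv", out / "scores.csv",
                          out / "fruit_traits.csv"])
    else:
        skipped("ph")

    # ---- blup -----------------------------------------------------------
    if stages.get("blup", True):
        t0 = time.time()
        traits = pd.read_csv(_need(out / "fruit_traits.csv", "blup"))
        cross = bio.read_fourway_csv(_need(out / "cross.csv", "blup"))
        trait_cols = [c for c in TRAIT_COLS if c in traits.columns]
        means = genotype_means(traits, trait_cols)
        K = kinship(cross.geno, cross.ids)
        pd.DataFrame(K.A, index=K.ids, columns=K.ids).to_csv(out / "kinship.csv")
        blups, h2 = fit_all_traits(means, K, trait_cols)
        blups.to_csv(out / "blups.csv", index=False)
        h2.to_csv(out / "h2.csv", index=False)
        record("blup", t0, [out / "kinship.csv", out / "blups.csv", out / "h2.csv"])
    else:
        skipped("blup")

    # ---- scan -----------------------------------------------------------
    if stages.get("scan", True):
        t0 = time.time()
        cross = bio.read_fourway_csv(_need(out / "cross.csv", "scan"))
        blups = pd.read_csv(_need(out / "blups.csv", "scan"))
        scan_cfg = cfg["scan"]
        probs = calc_genoprob(cross, float(scan_cfg["step_cm"]))
        wide = blups.pivot_table(index=["genotype", "year"], columns="trait",
                                 values="blup").reset_index()
        models = []
        scan_rows = []
        trait_cols = [c for c in TRAIT_COLS if c in wide.columns]
        for ti, trait in enumerate(trait_cols):
            for yi, yr in enumerate(sorted(wide["year"].unique())):
                sub = wide[wide["year"] == yr].set_index("genotype").reindex(probs.ids)
                y = sub[trait].to_numpy(dtype=float)
                sc = hk_scan(probs, y, trait=trait, year=yr)
                t = sc.table.copy()
                t.insert(0, "trait", trait)
                t.insert(1, "year", yr)
                scan_rows.append(t)
                pen = perm_threshold(
                    probs, y, n_perm=int(scan_cfg["n_perm"]),
                    alpha=float(scan_cfg["alpha"]),
                    seed=seed + STAGE_SEED["scan"] + 97 * ti + yi)
                models.append(stepwise_additive(
                    probs, y, pen, max_qtl=int(scan_cfg["max_qtl"]),
                    trait=trait, year=yr))
        pd.concat(scan_rows, ignore_index=True).to_csv(out / "scans.csv", index=False)
        models_to_table(models).to_csv(out / "qtl.csv", index=False)
        record("scan", t0, [out / "scans.csv", out / "qtl.csv"])
    else:
        skipped("scan")

    # ---- collocate ------------------------------------------------------
    if stages.get("collocate", True) and stages.get("scan", True):
        t0 = time.time()
        qtl_tab = pd.read_csv(_need(out / "qtl.csv", "collocate"),
                              keep_default_na=False)
        rep = collocate(qtl_tab, float(cfg["collocate"]["window_cm"]),
                        int(cfg["collocate"]["min_years"]))
        rep.to_csv(out / "collocation.csv", index=False)
        record("collocate", t0, [out / "collocation.csv"])
    else:
        skipped("collocate")

    # ---- report ---------------------------------------------------------
    if stages.get("report", True):
        t0 = time.time()
        outputs = report(out)
        record("report", t0, outputs)
    else:
        skipped("report")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(out: str | Path) -> list[Path]:
    """Summary tables and per-LG scan plots for a completed run.

    Writes a per-trait-year heritability table, the BLUP trait-correlation
    matrix, and one LOD-track plot per linkage group with 1.5-LOD support
    intervals marked.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    outputs: list[Path] = []
    if (out / "h2.csv").exists():
        h2 = pd.read_csv(out / "h2.csv")
        h2.to_csv(out / "report_h2.csv", index=False)
        outputs.append(out / "report_h2.csv")
    if (out / "blups.csv").exists():
        blups = pd.read_csv(out / "blups.csv")
        wide = blups.pivot_table(index=["genotype", "year"], columns="trait",
                                 values="blup")
        corr = wide.corr()
        corr.to_csv(out / "report_trait_correlation.csv")
        outputs.append(out / "report_trait_correlation.csv")
    if (out / "scans.csv").exists():
        scans = pd.read_csv(out / "scans.csv")
        qtl = (pd.read_csv(out / "qtl.csv", keep_default_na=False)
               if (out / "qtl.csv").exists() else pd.DataFrame())
        for lg in scans["lg"].unique():
            sub = scans[scans["lg"] == lg]
            fig, ax = plt.subplots(figsize=(7, 3))
            for (trait, yr), s in sub.groupby(["trait", "year"]):
                ax.plot(s["cm"], s["lod"], lw=0.8, label=f"{trait} {yr}")
            if not qtl.empty:
                hits = qtl[qtl["lg"] == lg]
                for _, q in hits.iterrows():
                    ax.axvspan(q["ci_lo"], q["ci_hi"], color="0.85", zorder=0)
                    ax.axvline(q["peak_cm"], color="0.4", ls="--", lw=0.6)
            ax.set_xlabel("position (cM)")
            ax.set_ylabel("LOD")
            ax.set_title(f"LG {lg}")
            if sub.groupby(["trait", "year"]).ngroups <= 8:
                ax.legend(fontsize=6)
            fig.tight_layout()
            p = out / f"report_scan_LG{lg}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            outputs.append(p)
    return outputs
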