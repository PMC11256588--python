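"""End-to-end driver: phantom/input cohort -> fractions -> parcellation
-> pseudodiffusivity -> fine mapping -> cohort statistics.

Every stage is recorded in a JSON manifest (counts, seeds, config hash);
nothing is dropped silently. Re-running with the same configuration and
seed rewrites byte-identical tabular outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import ANAT
from .config import PipelineConfig
from .fractions import build_fractions, csf_mask, pseudo_t2
from .finemap import ZoneScheme, assign_zones, find_third_ventricle_start, zone_mpd
from .io import read_subject, write_volume
from .parcellation import apply_exclusion_rule, propagate_labels
from .pdiff import fit_pdiff_map, intraparenchymal_volume, region_mpd
from .stats import (
    associate_regions, bh_adjust, cohort_bootstrap_acat,
    interregional_correlation, mpd_cbf_profile_correlation,
    sex_difference, voxel_bootstrap_cov, z_transform,
)

__all__ = ["run_pipeline"]


def _check_common_grid(subjects: list[dict]) -> None:
    ref = subjects[0]
    for s in subjects[1:]:
        for key in ("anat", "free_water", "cfa", "cbf"):
            if s[key].shape != ref[key].shape or s[key].spacing != ref[key].spacing:
                raise ValueError(
                    f"grid mismatch: {s['subject_id']}/{key} has shape {s[key].shape} "
                    f"spacing {s[key].spacing} vs {ref[key].shape} {ref[key].spacing}")


def run_pipeline(config: PipelineConfig) -> dict:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash,
        "config": json.loads(config.to_json()),
        "stages": [],
    }

    def record(name: str, **counts) -> None:
        manifest["stages"].append({"name": name, "status": "complete", **counts})

    def fail(name: str, err: Exception):
        manifest["stages"].append({"name": name, "status": f"failed: {err}"})
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    master = np.random.SeedSequence(config.seed)
    cov_seed, boot_seed = master.spawn(2)
    manifest["seeds"] = {"master": config.seed, "cov_spawn_key": 0, "bootstrap_spawn_key": 1}

    stage = "load"
    try:
        in_dir = Path(config.input_dir)
        subject_dirs = sorted(d for d in in_dir.iterdir() if d.is_dir() and (d / "anat.nii.gz").exists())
        if not subject_dirs:
            raise FileNotFoundError(f"no subject directories under {in_dir}")
        subjects = [read_subject(d, b_max=config.b_max) for d in subject_dirs]
        covariates = pd.read_csv(in_dir / "covariates.csv", index_col=0)
        _check_common_grid(subjects)
        record(stage, n_subjects=len(subjects))

        stage = "fractions"
        n_clipped_total = 0
        for s in subjects:
            anat = s["anat"]
            brain = np.isin(anat.data, (ANAT.LEFT_WM, ANAT.RIGHT_WM, ANAT.LEFT_GM, ANAT.RIGHT_GM))
            fr = build_fractions(s["free_water"], s["cfa"], brain)
            n_clipped_total += fr.n_clipped
            s["pseudo_t2"] = pseudo_t2(fr.gm, fr.csf)
            s["csf_mask"] = csf_mask(s["free_water"], anat, config.fw_threshold, config.fw_comparator)
        record(stage, n_clipped_voxels=n_clipped_total,
               n_mask_voxels=int(sum(s["csf_mask"].n_voxels for s in subjects)))

        stage = "parcellation"
        for s in subjects:
            s["parcellation"] = propagate_labels(s["atlas"], s["csf_mask"].mask.data, s["anat"])
        record(stage, n_regions=len(subjects[0]["parcellation"].regions))

        stage = "pdiff"
        region_rows = []
        for s in subjects:
            pm = fit_pdiff_map(s["series"], s["free_water"], s["csf_mask"].mask.data,
                               config.fw_threshold, config.fw_comparator, b_max=config.b_max)
            s["pdiff"] = pm
            tbl = region_mpd(pm, s["parcellation"])
            tbl.insert(0, "subject", s["subject_id"])
            region_rows.append(tbl)
            write_volume(pm.dstar, maps_dir / f"{s['subject_id']}_dstar.nii.gz")
            write_volume(s["parcellation"].labels, maps_dir / f"{s['subject_id']}_parcellation.nii.gz")
        region_table = pd.concat(region_rows, ignore_index=True)

        counts = region_table.pivot(index="region", columns="subject", values="n_voxels")
        status, missing = apply_exclusion_rule(counts, config.min_voxels, config.subject_fraction)
        kept_regions = sorted(status.index[~status["dropped"]])
        mpd_wide = region_table.pivot(index="region", columns="subject", values="mpd")
        mpd_wide = mpd_wide.mask(missing).loc[kept_regions]
        scheme = subjects[0]["series"].scheme
        record(stage,
               n_bvalues_used=scheme.n_distinct_low_b(config.b_max),
               n_fit_voxels=int(sum(np.isfinite(s["pdiff"].dstar.data).sum() for s in subjects)),
               n_regions_dropped=int(status["dropped"].sum()),
               n_subject_region_missing=int(missing.loc[~status["dropped"]].to_numpy().sum()))

        stage = "finemap"
        zscheme = ZoneScheme(config.zone_edges_mm, config.dilation_voxels, config.dilation_connectivity)
        zone_rows = []
        for s in subjects:
            anat = s["anat"].data
            lat = np.isin(anat, (ANAT.LEFT_LATERAL_VENTRICLE, ANAT.RIGHT_LATERAL_VENTRICLE))
            third = anat == ANAT.THIRD_VENTRICLE
            seed = find_third_ventricle_start(lat, third, config.dilation_voxels,
                                              config.dilation_connectivity)
            za = assign_zones(seed, lat, third, s["anat"].spacing, zscheme)
            zt = zone_mpd(s["pdiff"], za)
            zt.insert(0, "subject", s["subject_id"])
            zone_rows.append(zt)
        zone_table = pd.concat(zone_rows, ignore_index=True)
        record(stage, n_zone_rows=len(zone_table))

        stage = "stats"
        # cohort frame: MPD per kept region + zone MPDs + covariates + CBF
        frame = mpd_wide.T
        frame.columns = [f"mpd_{r}" for r in frame.columns]
        for (vent, zone), grp in zone_table.groupby(["ventricle", "zone"]):
            col = grp.set_index("subject")["mpd"]
            frame[f"{vent}_zone{zone}"] = col.where(~grp.set_index("subject")["missing"])
        atlas0 = subjects[0]["atlas"]
        merged_atlas = sorted({r.merged_name for r in atlas0.regions.values()})
        for s in subjects:
            gm_vox = np.isin(s["anat"].data, (ANAT.LEFT_GM, ANAT.RIGHT_GM))
            frame.loc[s["subject_id"], "cortical_cbf"] = float(np.median(s["cbf"].data[gm_vox]))
            lab = s["atlas"].labels.data
            for m in merged_atlas:
                codes = [c for c, r in s["atlas"].regions.items() if r.merged_name == m]
                vox = np.isin(lab, codes)
                frame.loc[s["subject_id"], f"cbf_{m}"] = (
                    float(np.median(s["cbf"].data[vox])) if vox.any() else np.nan)
            vol, _ = intraparenchymal_volume(s["anat"])
            frame.loc[s["subject_id"], "ipv_mm3"] = vol
        frame = frame.join(covariates, how="left")
        frame.index.name = "subject"

        # reproducibility: CoV of regional MPD under voxel subsampling
        cov_rows = []
        cov_children = cov_seed.spawn(len(subjects))
        for s, child in zip(subjects, cov_children):
            rng = np.random.default_rng(child)
            d = s["pdiff"].dstar.data
            labels = s["parcellation"].labels.data
            by_merged: dict[str, np.ndarray] = {}
            for code, r in s["parcellation"].regions.items():
                vals = d[labels == code]
                vals = vals[np.isfinite(vals)]
                by_merged[r.merged_name] = np.concatenate([by_merged.get(r.merged_name, np.empty(0)), vals])
            for region in sorted(by_merged):
                vals = by_merged[region]
                if region not in kept_regions or vals.size < config.min_voxels:
                    continue
                cov_rows.append({
                    "subject": s["subject_id"], "region": region,
                    "cov": voxel_bootstrap_cov(vals, config.cov_subsample, config.cov_reps, rng),
                    "n_voxels": int(vals.size),
                })
        cov_table = pd.DataFrame(cov_rows)

        mpd_cols = [f"mpd_{r}" for r in kept_regions]
        R, P, Padj = interregional_correlation(frame[mpd_cols])
        boot = cohort_bootstrap_acat(frame[mpd_cols], config.bootstrap_subsample,
                                     config.bootstrap_reps, np.random.default_rng(boot_seed))

        zframe = z_transform(frame, exclude=("sex",))
        zone_cols = [c for c in frame.columns if "_zone" in c]
        assoc_parts = []
        for outcome in config.outcomes:
            a = associate_regions(zframe, mpd_cols, outcome, config.covariates)
            a.insert(0, "family", "regions")
            assoc_parts.append(a)
            az = associate_regions(zframe, zone_cols, outcome, config.covariates)
            az.insert(0, "family", "zones")
            assoc_parts.append(az)
        age_a = associate_regions(zframe, mpd_cols, "age", ())  # age: unadjusted
        age_a.insert(0, "family", "regions")
        assoc_parts.append(age_a)
        associations = pd.concat(assoc_parts, ignore_index=True)

        sex_rows = []
        for col in mpd_cols:
            stat, p = sex_difference(frame, col)
            sex_rows.append({"region": col, "statistic": stat, "p_value": p})
        sex_table = pd.DataFrame(sex_rows)
        sex_table["p_adjusted"] = bh_adjust(sex_table["p_value"].to_numpy())

        profile_regions = [f"mpd_{m}" for m in merged_atlas if f"mpd_{m}" in frame.columns]
        prof_frame = frame.rename(columns={f"cbf_{m}": f"cbf_mpd_{m}" for m in merged_atlas})
        per_subject_r, age_assoc = mpd_cbf_profile_correlation(prof_frame, profile_regions)
        profile = per_subject_r.to_frame()
        profile["age_slope"] = age_assoc.slope if age_assoc else np.nan
        profile["age_p"] = age_assoc.p_value if age_assoc else np.nan

        region_table.to_csv(out_dir / "region_table.csv", index=False)
        zone_table.to_csv(out_dir / "zone_table.csv", index=False)
        status.to_csv(out_dir / "region_status.csv")
        frame.to_csv(out_dir / "cohort.csv")
        cov_table.to_csv(out_dir / "reproducibility_cov.csv", index=False)
        R.to_csv(out_dir / "correlation_r.csv")
        P.to_csv(out_dir / "correlation_p.csv")
        Padj.to_csv(out_dir / "correlation_p_adjusted.csv")
        boot.to_csv(out_dir / "bootstrap_acat.csv", index=False)
        associations.to_csv(out_dir / "associations.csv", index=False)
        sex_table.to_csv(out_dir / "sex_differences.csv", index=False)
        profile.to_csv(out_dir / "mpd_cbf_profile.csv")
        record(stage, n_associations=len(associations), n_pairs=len(boot),
               n_cov_rows=len(cov_table))
    except Exception as err:  # record the failing stage, keep prior outputs
        fail(stage, err)
        raise

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
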