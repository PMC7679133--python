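"""Reading and writing the pipeline's on-disk formats.

Tidy profile CSV: columns ``disc_id, genotype, x_um, channel, intensity``.
Region CSV: columns ``disc_id, genotype, channel, region, replicate_idx,
mean_intensity`` with region in {clone, anterior, ap_border, posterior}.
Aligned-set CSV: long format with per-disc, mean, sem and n rows.
Scalars, landmarks and provenance go to JSON; configs to YAML; images
to single-channel TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import AlignedProfileSet, APProfile, DecompositionResult, LandmarkSet, RegionMeasurement

REGION_FIELDS = {
    "clone": "clone_means",
    "anterior": "anterior_means",
    "ap_border": "ap_border_means",
    "posterior": "posterior_means",
}


def write_profiles_csv(profiles: list[APProfile], path) -> None:
    rows = []
    for p in profiles:
        for channel, arr in p.channels.items():
            rows.append(
                pd.DataFrame(
                    {
                        "disc_id": p.disc_id,
                        "genotype": p.genotype,
                        "x_um": p.x,
                        "channel": channel,
                        "intensity": arr,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path) -> list[APProfile]:
    df = pd.read_csv(path)
    required = {"disc_id", "genotype", "x_um", "channel", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for disc_id, sub in df.groupby("disc_id", sort=True):
        channels = {}
        x = None
        for channel, chsub in sub.groupby("channel", sort=True):
            chsub = chsub.sort_values("x_um")
            channels[channel] = chsub["intensity"].to_numpy()
            x = chsub["x_um"].to_numpy()
        profiles.append(
            APProfile(
                disc_id=str(disc_id),
                genotype=str(sub["genotype"].iloc[0]),
                x=x,
                channels=channels,
            )
        )
    return profiles


def write_truth_json(profiles: list[APProfile], path) -> None:
    """Ground-truth sidecar for synthetic datasets (arrays as lists)."""
    out = {}
    for p in profiles:
        entry = {}
        for key, val in p.meta.items():
            if isinstance(val, np.ndarray):
                entry[key] = val.tolist()
            elif dataclasses.is_dataclass(val) and not isinstance(val, type):
                entry[key] = dataclasses.asdict(val)
            elif isinstance(val, (int, float, str, dict, list)):
                entry[key] = val
        out[p.disc_id] = entry
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


def write_regions_csv(measurements: list[RegionMeasurement], path) -> None:
    rows = []
    for m in measurements:
        for region, attr in REGION_FIELDS.items():
            for i, val in enumerate(getattr(m, attr)):
                rows.append(
                    {
                        "disc_id": m.disc_id,
                        "genotype": m.genotype,
                        "channel": m.channel,
                        "region": region,
                        "replicate_idx": i,
                        "mean_intensity": val,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_regions_csv(path) -> list[RegionMeasurement]:
    df = pd.read_csv(path)
    required = {"disc_id", "genotype", "channel", "region", "replicate_idx", "mean_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region CSV missing columns: {sorted(missing)}")
    out = []
    for (disc_id, channel), sub in df.groupby(["disc_id", "channel"], sort=True):
        kwargs: dict[str, Any] = {r: [] for r in REGION_FIELDS.values()}
        for region, rsub in sub.groupby("region", sort=True):
            if region not in REGION_FIELDS:
                raise ValueError(f"unknown region {region!r} in {path}")
            kwargs[REGION_FIELDS[region]] = (
                rsub.sort_values("replicate_idx")["mean_intensity"].tolist()
            )
        out.append(
            RegionMeasurement(
                disc_id=str(disc_id),
                genotype=str(sub["genotype"].iloc[0]),
                channel=str(channel),
                **kwargs,
            )
        )
    return out


def write_aligned_csv(aligned: AlignedProfileSet, path) -> None:
    frames = []
    for disc_id, channels in sorted(aligned.per_disc.items()):
        for channel, arr in sorted(channels.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "series": disc_id,
                        "genotype": aligned.genotype,
                        "x_um": aligned.grid,
                        "channel": channel,
                        "intensity": arr,
                    }
                )
            )
    for stat, data in (("mean", aligned.mean), ("sem", aligned.sem)):
        for channel, arr in sorted(data.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "series": stat,
                        "genotype": aligned.genotype,
                        "x_um": aligned.grid,
                        "channel": channel,
                        "intensity": arr,
                    }
                )
            )
    frames.append(
        pd.DataFrame(
            {
                "series": "n",
                "genotype": aligned.genotype,
                "x_um": aligned.grid,
                "channel": "all",
                "intensity": aligned.n.astype(float),
            }
        )
    )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def landmarks_to_dict(lm: LandmarkSet) -> dict[str, float]:
    return dataclasses.asdict(lm)


def write_decomposition(result: DecompositionResult, csv_path, json_path) -> None:
    pd.DataFrame(
        {
            "x_um": result.grid,
            "c_resistant_avg": result.c_resistant_avg,
            "reduction": result.reduction,
            "c_wt": result.c_wt,
            "c_wt_sem": result.c_wt_sem,
            "c_nored": result.c_nored,
            "inhibition_fraction": result.inhibition_fraction,
        }
    ).to_csv(csv_path, index=False)
    scalars = {
        "c_max_anterior": result.c_max_anterior,
        "x_first_inh": result.x_first_inh,
        "x_half_inh": result.x_half_inh,
        "x_full_inh": result.x_full_inh,
        "anterior_window": list(result.anterior_window),
        "provenance": result.provenance,
    }
    Path(json_path).write_text(json.dumps(scalars, indent=1, sort_keys=True))


def write_image_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_config_yaml(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
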