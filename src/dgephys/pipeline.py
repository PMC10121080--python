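"""End-to-end study orchestration.

:func:`run_study` wires the stages together for the reference design: a
simulated two-genotype paired-pulse inhibition field study, per-subject
Boltzmann fits with R^2 gating, level interpolation, and the group
statistics, written out as CSVs plus a summary table shaped like a
statistical-results table and a manifest with content hashes.  All
randomness flows from the single config seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import boltzmann as bz
from . import simulate, stats
from .model import ValidationError

_KNOWN_KEYS = {
    "seed", "out_dir", "n_subjects_per_group", "noise_cv",
    "between_subject_v50_sd_ms", "group_v50_ms", "group_top", "group_k_ms",
    "ipis_ms", "fit_range_max_ms", "stages",
}


@dataclass
class StudyConfig:
    """Configuration for a simulated two-group PPI field study."""

    seed: int = 0
    out_dir: str = "study_out"
    n_subjects_per_group: dict = field(default_factory=lambda: {"WT": 17, "KO": 16})
    group_v50_ms: dict = field(default_factory=lambda: {"WT": 41.3, "KO": 45.8})
    group_top: dict = field(default_factory=lambda: {"WT": 110.0, "KO": 110.0})
    group_k_ms: dict = field(default_factory=lambda: {"WT": 5.0, "KO": 5.0})
    noise_cv: float = 0.05
    between_subject_v50_sd_ms: float = 4.0
    ipis_ms: tuple = simulate.DEFAULT_IPIS_MS
    fit_range_max_ms: float = 100.0
    stages: tuple = ("simulate", "fit", "stats")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


def fit_ppi_per_subject(ppi: pd.DataFrame,
                        fit_range_max_ms: float = 100.0) -> pd.DataFrame:
    """Per-subject Boltzmann fit of the PPI curve with level crossings.

    Returns one row per subject: Top, v50, k, R^2, the interpolated
    50/75/100% interpulse intervals, and the inclusion flag (R^2 > 0.8).
    """
    rows = []
    for sid, sub in ppi.groupby("subject"):
        fit = bz.fit_ppi(sub["ipi_ms"].to_numpy(),
                         sub["ppi_percent"].to_numpy(),
                         fit_range_max_ms=fit_range_max_ms)
        lv = (bz.interpolate_levels(fit) if fit.included
              else bz.LevelCrossings(None, None, None))
        rows.append({"subject": sid, "group": sub["group"].iloc[0],
                     "top": fit.top, "v50_ms": fit.v50, "k_ms": fit.k,
                     "r_squared": fit.r_squared, "included": fit.included,
                     "ipi_at_50_ms": lv.ipi_at_50, "ipi_at_75_ms": lv.ipi_at_75,
                     "ipi_at_100_ms": lv.ipi_at_100})
    return pd.DataFrame(rows)


def ppi_group_stats(fits: pd.DataFrame,
                    orientation=("WT", "KO")) -> pd.DataFrame:
    """Group comparisons of per-subject v50 and level crossings."""
    inc = fits[fits["included"]]
    rows = []
    for col, label in (("v50_ms", "PPI v50 (ms)"),
                       ("ipi_at_50_ms", "PPI 50% IPI (ms)"),
                       ("ipi_at_75_ms", "PPI 75% IPI (ms)"),
                       ("ipi_at_100_ms", "PPI 100% IPI (ms)")):
        g1 = inc.loc[inc["group"] == orientation[0], col].dropna().to_numpy()
        g2 = inc.loc[inc["group"] == orientation[1], col].dropna().to_numpy()
        if g1.size < 2 or g2.size < 2:
            continue
        res = stats.welch_t(g1, g2)
        rows.append({
            "measure": label, "test": res.test_name,
            f"n_{orientation[0]}": g1.size, f"n_{orientation[1]}": g2.size,
            f"mean_{orientation[0]}": float(np.mean(g1)),
            f"mean_{orientation[1]}": float(np.mean(g2)),
            "difference": res.estimate, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p": res.p_value})
    return pd.DataFrame(rows)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: Optional[StudyConfig] = None) -> dict:
    """Run simulate -> fit -> stats and write the report bundle.

    Returns a dict with the output tables and the manifest.  Reruns with
    the same config are bit-identical.
    """
    cfg = config or StudyConfig()
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs = {}

    truth = {g: simulate.FieldGroupTruth(ppi_v50_ms=cfg.group_v50_ms[g],
                                         ppi_top=cfg.group_top[g],
                                         ppi_k_ms=cfg.group_k_ms[g])
             for g in cfg.n_subjects_per_group}
    study = simulate.simulate_field_experiment(
        n_subjects_per_group=cfg.n_subjects_per_group, group_truth=truth,
        ipis_ms=cfg.ipis_ms, noise_cv=cfg.noise_cv,
        between_subject_v50_sd_ms=cfg.between_subject_v50_sd_ms, seed=cfg.seed)
    outputs["ppi"] = study.ppi
    outputs["io"] = study.io

    if "fit" in cfg.stages:
        fits = fit_ppi_per_subject(study.ppi, cfg.fit_range_max_ms)
        outputs["fits"] = fits
        if "stats" in cfg.stages:
            outputs["summary"] = ppi_group_stats(
                fits, orientation=tuple(cfg.n_subjects_per_group))

    files = []
    for name, df in outputs.items():
        path = os.path.join(cfg.out_dir, f"{name}.csv")
        df.to_csv(path, index=False)
        files.append(path)

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {os.path.basename(p): _sha256(p) for p in files},
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    outputs["manifest"] = manifest
    return outputs
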