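"""End-to-end orchestration: simulate -> connectivity -> features ->
decoding -> statistics, with manifests and a summary report.

Condition contrasts are decoded per subject by default (accuracies then
averaged across subjects); fast/slow reaction-time contrasts pool trials
across subjects after per-subject RT normalization.
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
import yaml

from . import stats as wstats
from .cohort import CohortSpec, generate_cohort, read_cohort_hdf5, write_cohort_hdf5
from .decoding import (
    DecodingConfig,
    FeatureTable,
    permutation_test,
    pth_scan,
    rt_classes,
    run_decoding,
)
from .defs import BANDS, CONDITIONS, FEATURE_NAMES
from .features import build_feature_table
from .graph_metrics import PTH_DEFAULT_RANGE

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

log = logging.getLogger("wmdecode")

#: Condition contrasts in the order they are reported.
CONDITION_CONTRASTS = (
    ("spatial", "identity"),
    ("temporal", "identity"),
    ("spatial", "temporal"),
)


@dataclass
class PipelineConfig:
    cohort: CohortSpec | None = None
    input_path: str | None = None
    bands: tuple[str, ...] = tuple(BANDS)
    pths: tuple[float, ...] = PTH_DEFAULT_RANGE
    contrasts: tuple[str, ...] = (
        "spatial-identity",
        "temporal-identity",
        "spatial-temporal",
        "fast-slow",
    )
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    max_order: int = 15
    n_shuffles: int = 0  # permutation null disabled unless > 0
    r_perm: int = 10
    per_subject: bool = True
    binomial_convention: str = "paper_compat"
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.cohort is None and self.input_path is None:
            raise ValueError("either a cohort spec or an input path is required")
        for contrast in self.contrasts:
            if contrast == "fast-slow":
                continue
            parts = contrast.split("-")
            if len(parts) != 2 or any(p not in CONDITIONS for p in parts):
                raise ValueError(f"malformed contrast {contrast!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        decoding = raw.pop("decoding", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if cohort is not None:
            cfg.cohort = CohortSpec.from_dict(cohort)
        if decoding is not None:
            cfg.decoding = DecodingConfig(**decoding)
        cfg.bands = tuple(cfg.bands)
        cfg.pths = tuple(cfg.pths)
        cfg.contrasts = tuple(cfg.contrasts)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _tables_by_pth(
    frame: pd.DataFrame, band: str, label_column: str, classes: tuple[str, str]
) -> dict[float, FeatureTable]:
    tables = {}
    for pth, sub in frame[frame["band"] == band].groupby("pth"):
        sub = sub[sub[label_column].isin(classes)]
        counts = sub[label_column].value_counts()
        if len(counts) < 2 or counts.min() < 10:
            continue
        tables[float(pth)] = FeatureTable.from_frame(sub, label_column, classes)
    return tables


def _decode_contrast(
    frame: pd.DataFrame,
    band: str,
    label_column: str,
    classes: tuple[str, str],
    config: PipelineConfig,
) -> dict | None:
    """Scan thresholds and decode one band x contrast, per subject or pooled."""
    cfg = dataclasses.replace(config.decoding, seed=config.seed)
    if config.per_subject and label_column == "condition":
        per_subject = []
        for subject, sub in frame.groupby("subject_id"):
            tables = _tables_by_pth(sub, band, label_column, classes)
            if not tables:
                log.warning(
                    "contrast=%s band=%s subject=%s: too few trials, skipped",
                    classes, band, subject,
                )
                continue
            best_pth, run, freq, _ = pth_scan(tables, cfg)
            per_subject.append(
                {
                    "subject": int(subject),
                    "pth": best_pth,
                    "accuracy": run.mean_accuracy,
                    "counts": freq.counts,
                    "accuracies": run.accuracies,
                }
            )
        if not per_subject:
            return None
        counts = np.mean([r["counts"] for r in per_subject], axis=0)
        return {
            "mean_accuracy": float(np.mean([r["accuracy"] for r in per_subject])),
            "chosen_pth": float(np.median([r["pth"] for r in per_subject])),
            "selection_counts": counts,
            "per_subject": per_subject,
            "subject_accuracies": [r["accuracy"] for r in per_subject],
        }
    tables = _tables_by_pth(frame, band, label_column, classes)
    if not tables:
        return None
    best_pth, run, freq, _ = pth_scan(tables, cfg)
    result = {
        "mean_accuracy": run.mean_accuracy,
        "chosen_pth": best_pth,
        "selection_counts": freq.counts.astype(float),
        "subject_accuracies": [run.mean_accuracy],
    }
    if config.n_shuffles > 0:
        null = permutation_test(
            tables[best_pth], cfg, n_shuffles=config.n_shuffles,
            r_perm=config.r_perm,
        )
        result["p_perm"] = null.p_value
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every band x contrast; returns the summary
    bundle and writes all artifacts plus a hashed manifest to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=simulate")
    if config.input_path is not None:
        trials = read_cohort_hdf5(config.input_path)
        ground_truth = []
    else:
        assert config.cohort is not None
        trials, ground_truth = generate_cohort(config.cohort)
        write_cohort_hdf5(out / "cohort.h5", trials, config.cohort, ground_truth)

    nyquist = trials[0].sampling_rate / 2.0
    bands = []
    for band in config.bands:
        if BANDS[band][1] > nyquist + 1e-9:
            log.warning("band=%s above Nyquist %.1f Hz, skipped", band, nyquist)
            continue
        bands.append(band)

    log.info("stage=features bands=%s pths=%d", bands, len(config.pths))
    frame = build_feature_table(
        trials, bands=bands, pths=config.pths,
        max_order=config.max_order, correct_only=True,
    )
    frame.to_csv(out / "features.csv", index=False)

    # fast/slow labels per condition (pooled across subjects, correct only)
    frame["rt_class"] = "excluded"
    for condition in CONDITIONS:
        sel = frame["condition"] == condition
        trials_in_cond = frame.loc[sel, ["trial", "subject_id", "rt_ms"]
                                   ].drop_duplicates("trial")
        if len(trials_in_cond) < 8:
            continue
        labels = rt_classes(
            trials_in_cond["rt_ms"].to_numpy(),
            trials_in_cond["subject_id"].to_numpy(),
        )
        mapping = dict(zip(trials_in_cond["trial"], labels))
        frame.loc[sel, "rt_class"] = frame.loc[sel, "trial"].map(mapping)

    log.info("stage=decode")
    summary_rows = []
    counts_rows = []
    for contrast in config.contrasts:
        if contrast == "fast-slow":
            jobs = [
                (f"fast-slow:{c}", "rt_class", ("fast", "slow"), c)
                for c in CONDITIONS
            ]
        else:
            a, b = contrast.split("-")
            jobs = [(contrast, "condition", (a, b), None)]
        for name, label_column, classes, condition in jobs:
            for band in bands:
                sub = frame if condition is None else frame[
                    frame["condition"] == condition
                ]
                res = _decode_contrast(sub, band, label_column, classes, config)
                if res is None:
                    log.warning("contrast=%s band=%s: skipped (no data)", name, band)
                    continue
                row = {
                    "contrast": name,
                    "band": band,
                    "chosen_pth": res["chosen_pth"],
                    "mean_accuracy": res["mean_accuracy"],
                    "p_perm": res.get("p_perm", np.nan),
                }
                summary_rows.append(row)
                counts_rows.append(
                    {
                        "contrast": name,
                        "band": band,
                        **dict(zip(FEATURE_NAMES, res["selection_counts"])),
                    }
                )

    summary = pd.DataFrame(summary_rows)
    counts = pd.DataFrame(counts_rows)
    summary.to_csv(out / "summary.csv", index=False)
    counts.to_csv(out / "selection_counts.csv", index=False)

    log.info("stage=stats")
    stats_out: dict = {"band_comparison": {}, "significant_features": {}}
    for contrast, sub in summary.groupby("contrast"):
        if len(sub) >= 2:
            groups = [np.atleast_1d(v) for v in sub["mean_accuracy"]]
            try:
                h_stat, p = wstats.kruskal_wallis(groups)
                stats_out["band_comparison"][contrast] = {"H": h_stat, "p": p}
            except ValueError:
                pass
    critical = wstats.binomial_critical_count(
        config.decoding.n_repeats,
        config.decoding.n_selected / len(FEATURE_NAMES),
        0.05,
        config.binomial_convention,
    )
    stats_out["binomial_critical_count"] = critical
    for row in counts_rows:
        vals = np.array([row[f] for f in FEATURE_NAMES])
        flagged = [
            f for f, v in zip(FEATURE_NAMES, vals) if v >= critical
        ]
        stats_out["significant_features"][f"{row['contrast']}|{row['band']}"] = flagged
    (out / "stats.json").write_text(json.dumps(stats_out, indent=2))

    config_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    (out / "config.json").write_text(config_json)
    manifest = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_trials": len(trials),
        "ground_truth_edges": len(ground_truth),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"summary": summary, "selection_counts": counts, "stats": stats_out,
            "manifest": manifest}


def write_report(results_dir: str | Path, out_name: str = "report") -> list[Path]:
    """Selection-count heatmaps (region x metric) per contrast and band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .defs import METRIC_ORDER, REGION_ORDER

    results_dir = Path(results_dir)
    counts = pd.read_csv(results_dir / "selection_counts.csv")
    written = []
    for _, row in counts.iterrows():
        mat = np.array(
            [[row[f"{r}.{m}"] for m in METRIC_ORDER] for r in REGION_ORDER]
        )
        fig, ax = plt.subplots(figsize=(8, 3))
        im = ax.imshow(mat, aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(REGION_ORDER)), REGION_ORDER)
        ax.set_xticks(range(len(METRIC_ORDER)), METRIC_ORDER, rotation=45,
                      ha="right")
        ax.set_title(f"{row['contrast']} / {row['band']}")
        fig.colorbar(im, ax=ax, label="selection count")
        fig.tight_layout()
        path = results_dir / f"{out_name}_{row['contrast']}_{row['band']}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
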