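"""End-to-end orchestration: simulate -> extract -> correlate -> cluster/sweep.

A single master seed drives every stage, so a run is fully reproducible;
the run report lists every output file with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import SHIPPED_FLAVORS, extract_features, features_to_table, get_flavor
from .harmonization import (build_registry, fit_feature_correlations,
                            records_to_frame, registry_to_frame,
                            select_reproducible)
from .image_io import FeatureTable, write_feature_table
from .stability import (assemble_signature, clustering_similarity,
                        default_threshold_grid, threshold_sweep,
                        ward_two_groups)
from .synthetic import CohortConfig, LongitudinalCase, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "extract_cohort_table"]

log = logging.getLogger("radstab.pipeline")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    flavors: tuple[str, ...] = ("reference", "ibex-emulation", "mazda-emulation")
    thresholds: tuple[float, ...] = (0.901, 0.965)
    grid: np.ndarray | None = None
    mode: str = "stacked"
    out_dir: str | Path = "radstab_run"
    write_images: bool = True
    image_format: str = "nii"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.flavors) < 2:
            raise ValueError("need at least 2 flavors (first is the reference)")
        if any(not (0 <= t < 1) for t in self.thresholds):
            raise ValueError(f"thresholds must lie in [0, 1): {self.thresholds}")


def extract_cohort_table(cases: list[LongitudinalCase], flavor_name: str,
                         ) -> FeatureTable:
    """Extract one flavor's feature table for every (patient, timepoint)."""
    flavor = get_flavor(flavor_name)
    rows = []
    for case in cases:
        for t, image, mask in case.series:
            rows.append((case.patient_id, t, extract_features(image, mask, flavor)))
    return features_to_table(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    report: dict = {"seed": config.cohort.seed, "flavors": list(config.flavors)}

    log.info("stage=simulate patients=%d timepoints=%d seed=%d",
             config.cohort.n_patients, config.cohort.n_timepoints,
             config.cohort.seed)
    cases = generate_cohort(config.cohort)
    if config.write_images:
        manifest = write_cohort(cases, out / "cohort", fmt=config.image_format)
        artifacts.append(out / "cohort" / "manifest.csv")
    else:
        manifest = pd.DataFrame(
            [{"patient_id": c.patient_id, "timepoint": t, "group_label": c.group_label}
             for c in cases for t, _, _ in c.series])
        manifest.to_csv(out / "manifest.csv", index=False)
        artifacts.append(out / "manifest.csv")

    tables: dict[str, FeatureTable] = {}
    for name in config.flavors:
        table = extract_cohort_table(cases, name)
        path = out / f"features_{name}.csv"
        write_feature_table(table, path)
        artifacts.append(path)
        tables[name] = table
        log.info("stage=extract flavor=%s rows=%d features=%d",
                 name, table.data.shape[0], table.data.shape[1])

    ref_name = config.flavors[0]
    patients = tables[ref_name].patients
    report["n_patients"] = len(patients)
    report["comparisons"] = {}

    for name in config.flavors[1:]:
        # self-comparison (same flavor twice) is allowed and gives r = 1
        registry = build_registry(get_flavor(ref_name), get_flavor(name))
        records = fit_feature_correlations(tables[ref_name], tables[name], registry)
        corr_path = out / f"correlations_{ref_name}_vs_{name}.csv"
        records_to_frame(records).to_csv(corr_path, index=False)
        artifacts.append(corr_path)
        log.info("stage=correlate alt=%s pairs=%d defined=%d",
                 name, len(records), sum(r.defined for r in records))

        comp: dict = {"n_shared_pairs": len(registry), "thresholds": {}}
        for thr in config.thresholds:
            kept = select_reproducible(records, thr)
            if not kept:
                comp["thresholds"][str(thr)] = {"n_features": 0,
                                                "similarity_percent": None}
                continue
            sig_ref = assemble_signature(tables[ref_name], patients,
                                         [p.feature_a for p in kept],
                                         mode=config.mode)
            sig_alt = assemble_signature(tables[name], patients,
                                         [p.feature_b for p in kept],
                                         mode=config.mode)
            asg_ref = ward_two_groups(sig_ref)
            asg_alt = ward_two_groups(sig_alt)
            sim = clustering_similarity(asg_ref, asg_alt)
            asg_path = out / f"assignments_{name}_thr{thr}.csv"
            pd.DataFrame({
                "patient_id": sig_ref.patients,
                "group_ref": [asg_ref.groups[p] for p in sig_ref.patients],
                "group_alt": [asg_alt.groups[p] for p in sig_ref.patients],
            }).to_csv(asg_path, index=False)
            artifacts.append(asg_path)
            comp["thresholds"][str(thr)] = {"n_features": len(kept),
                                            "similarity_percent": sim}
            log.info("stage=cluster alt=%s threshold=%.3f kept=%d similarity=%.2f",
                     name, thr, len(kept), sim)

        grid = config.grid if config.grid is not None else default_threshold_grid()
        sweep = threshold_sweep(tables[ref_name], tables[name], records,
                                patients, grid=grid, mode=config.mode)
        sweep_path = out / f"sweep_{ref_name}_vs_{name}.csv"
        sweep.to_frame().to_csv(sweep_path, index=False)
        artifacts.append(sweep_path)
        comp["sweep_csv"] = sweep_path.name
        report["comparisons"][name] = comp

    report["artifacts"] = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
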