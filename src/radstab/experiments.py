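"""Canned end-to-end experiments on synthetic cohorts.

These reproduce, at phantom scale, the qualitative behaviour of the
cross-software stability analysis: with every shared feature highly
correlated between flavors the two clusterings agree, while a block of
mutually correlated but poorly cross-correlated "distractor" features
drags the clusterings apart at a permissive reproducibility threshold
and is eliminated by a stringent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import get_flavor
from .harmonization import (CorrelationRecord, SharedFeaturePair,
                            build_registry, fit_feature_correlations)
from .image_io import FeatureId, FeatureTable
from .pipeline import extract_cohort_table
from .stability import SweepResult, default_threshold_grid, threshold_sweep
from .synthetic import CohortConfig, generate_cohort

__all__ = ["DistractorExperiment", "distractor_sweep_experiment", "distort_table"]


def distort_table(table: FeatureTable, target_r: float, seed: int,
                  flavor_name: str = "distorted") -> FeatureTable:
    """A noisy copy of a feature table with per-column correlation ~target_r.

    Each finite column is mixed with Gaussian noise so that the
    correlation between original and copy approaches ``target_r``;
    non-finite entries are preserved.  Emulates a well-matched alternative
    software package.
    """
    if not 0 < target_r <= 1:
        raise ValueError(f"target_r must be in (0, 1]: {target_r}")
    rng = np.random.default_rng(seed)
    out = {}
    for col in table.data.columns:
        x = table.data[col].to_numpy(dtype=np.float64)
        fid = FeatureId.parse(str(col))
        new_id = str(FeatureId(flavor_name, fid.klass, fid.name, fid.distance))
        finite = np.isfinite(x)
        y = x.copy()
        xs = x[finite]
        sd = xs.std(ddof=0)
        if sd > 0 and finite.sum() > 1:
            noise = rng.standard_normal(finite.sum()) * sd
            y[finite] = (target_r * (xs - xs.mean())
                         + np.sqrt(1.0 - target_r ** 2) * noise) + xs.mean()
        out[new_id] = y
    return FeatureTable(pd.DataFrame(out, index=table.data.index))


@dataclass
class DistractorExperiment:
    sweep: SweepResult
    records: list[CorrelationRecord]
    n_distractors: int
    distractor_r: np.ndarray

    def similarity_at(self, threshold: float) -> float:
        for res in self.sweep.results:
            if abs(res.threshold - threshold) < 1e-9:
                return res.similarity_percent
        raise KeyError(f"threshold {threshold} not on the sweep grid")

    def n_features_at(self, threshold: float) -> int:
        for res in self.sweep.results:
            if abs(res.threshold - threshold) < 1e-9:
                return res.n_features
        raise KeyError(f"threshold {threshold} not on the sweep grid")


def _distractor_blocks(index: pd.Index, patients: list[str], rng,
                       n_distractors: int, jitter: float, coupling: float,
                       flavor_a: str, flavor_b: str):
    """Two blocks of mutually correlated features encoding independent
    fake patient groupings, weakly coupled across flavors."""
    pat = index.get_level_values(0)

    def base_vector():
        labels = rng.permutation([1.0, -1.0] * (len(patients) // 2)
                                 + [1.0] * (len(patients) % 2))
        lookup = dict(zip(patients, labels))
        return np.array([lookup[p] for p in pat])

    base_a, base_b = base_vector(), base_vector()
    cols_a, cols_b = {}, {}
    for k in range(n_distractors):
        xa = base_a + jitter * rng.standard_normal(len(pat))
        xb = base_b + jitter * rng.standard_normal(len(pat)) + coupling * xa
        cols_a[str(FeatureId(flavor_a, "DISTRACTOR", f"D{k:04d}"))] = xa
        cols_b[str(FeatureId(flavor_b, "DISTRACTOR", f"D{k:04d}"))] = xb
    return (pd.DataFrame(cols_a, index=index), pd.DataFrame(cols_b, index=index))


def distractor_sweep_experiment(seed: int = 0, n_patients: int = 36,
                                n_timepoints: int = 8,
                                n_distractors: int = 200,
                                distractor_jitter: float = 0.3,
                                distractor_coupling: float = 0.3,
                                alt_flavor: str = "ibex-emulation",
                                grid: np.ndarray | None = None,
                                mode: str = "stacked") -> DistractorExperiment:
    """Full pipeline with an injected non-reproducible feature block.

    Generates a phantom cohort with planted groups, extracts the reference
    and alternative flavor feature tables, appends ``n_distractors``
    distractor features per side (each side's block encodes its own fake
    patient grouping, so it misleads the two clusterings differently),
    fits all shared-pair correlations and sweeps the reproducibility
    threshold.
    """
    config = CohortConfig(n_patients=n_patients, n_timepoints=n_timepoints,
                          seed=seed)
    cases = generate_cohort(config)
    table_ref = extract_cohort_table(cases, "reference")
    table_alt = extract_cohort_table(cases, alt_flavor)

    registry = build_registry(get_flavor("reference"), get_flavor(alt_flavor))
    records = fit_feature_correlations(table_ref, table_alt, registry)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    block_a, block_b = _distractor_blocks(
        table_ref.data.index, table_ref.patients, rng, n_distractors,
        distractor_jitter, distractor_coupling, "reference", alt_flavor)
    full_ref = FeatureTable(pd.concat([table_ref.data, block_a], axis=1))
    full_alt = FeatureTable(pd.concat([table_alt.data, block_b], axis=1))

    distractor_pairs = [
        SharedFeaturePair(feature_a=a, feature_b=b, klass="DISTRACTOR",
                          match_basis="identical-name")
        for a, b in zip(block_a.columns, block_b.columns)]
    distractor_records = fit_feature_correlations(full_ref, full_alt,
                                                  distractor_pairs)
    all_records = records + distractor_records

    sweep = threshold_sweep(full_ref, full_alt, all_records,
                            table_ref.patients, grid=grid, mode=mode)
    return DistractorExperiment(
        sweep=sweep, records=all_records, n_distractors=n_distractors,
        distractor_r=np.array([r.r for r in distractor_records]))
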