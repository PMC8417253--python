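"""Shared-feature registries and cross-flavor linear correlation.

The registry pairs features of a reference flavor with features of an
alternative flavor, class by class (co-occurrence features pair per
distance).  Curated dissimilar-name aliases — the documented pairs whose
names differ between packages although the quantity matches — are
applied first; remaining features pair by identical name.  The registry
is data independent.

For every pair a linear fit across all (patient, timepoint) observations
yields a Pearson correlation; observations where either value is
non-finite are excluded pairwise.  Features whose correlation exceeds a
reproducibility threshold (strictly) are selected as interchangeable
between the two flavors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features.flavors import FlavorConfig
from .image_io import FeatureId, FeatureTable

__all__ = ["SharedFeaturePair", "CorrelationRecord", "CURATED_ALIASES",
           "build_registry", "fit_feature_correlations", "select_reproducible",
           "registry_to_frame", "records_to_frame"]

# (class, reference name, alternative name) — dissimilar-name pairs whose
# equations correspond across packages.
CURATED_ALIASES: tuple[tuple[str, str, str], ...] = (
    ("SHAPE", "Flatness", "Roundness"),
    ("SHAPE", "Volume", "Area"),
    ("SHAPE", "VoxelVolume", "VoxelSize"),
    ("SHAPE", "SurfaceArea", "Perimeter"),
    ("SHAPE", "SurfaceVolumeRatio", "SurfaceAreaDensity"),
    ("SHAPE", "Maximum3DDiameter", "FerretDiameter"),
    ("GLCM", "SumSquares", "Variance"),
    ("GLCM", "InverseDifference", "Homogeneity1"),
    ("GLCM", "InverseDifferenceMoment", "Homogeneity2"),
    ("GLCM", "JointEnergy", "AngularSecondMoment"),
    ("GLCM", "ClusterTendency", "JointEnergy"),
    ("GLRLM", "RunPercentage", "Fraction"),
)


@dataclass(frozen=True)
class SharedFeaturePair:
    feature_a: str  # full feature id in the reference flavor
    feature_b: str  # full feature id in the other flavor
    klass: str
    match_basis: str  # identical-name | dissimilar-name-curated
    distance: int | None = None


@dataclass(frozen=True)
class CorrelationRecord:
    pair: SharedFeaturePair
    r: float
    slope: float
    intercept: float
    n_used: int
    n_excluded: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.r))


def _known_name_universe(*flavor_configs) -> dict[str, set[str]]:
    """All feature names known anywhere: shipped flavors plus the arguments."""
    from .features.flavors import SHIPPED_FLAVORS

    universe: dict[str, set[str]] = {}
    for fl in (*SHIPPED_FLAVORS.values(), *flavor_configs):
        for klass, names in fl.feature_lists.items():
            universe.setdefault(klass, set()).update(names)
    return universe


def _validate_aliases(aliases, known_names: dict[str, set[str]]) -> None:
    for klass, name_a, name_b in aliases:
        pool = known_names.get(klass, set())
        if name_a not in pool or name_b not in pool:
            raise ValueError(
                f"alias table entry references unknown features: "
                f"({klass}, {name_a}, {name_b})"
            )


def build_registry(flavor_a: FlavorConfig, flavor_b: FlavorConfig,
                   aliases: tuple[tuple[str, str, str], ...] = CURATED_ALIASES,
                   ) -> list[SharedFeaturePair]:
    """Pair the features of two flavors, class by class.

    Curated aliases take precedence; leftover features pair by identical
    name.  Co-occurrence pairs are replicated once per common distance.
    Alias entries that reference names unknown to either flavor's whole
    name universe raise ``ValueError``.
    """
    _validate_aliases(aliases, _known_name_universe(flavor_a, flavor_b))

    pairs: list[SharedFeaturePair] = []
    for klass in ("IHIST", "SHAPE", "GLCM", "GLRLM", "NGTDM"):
        names_a = list(flavor_a.feature_lists.get(klass, ()))
        names_b = list(flavor_b.feature_lists.get(klass, ()))
        if not names_a or not names_b:
            continue
        taken_a: set[str] = set()
        taken_b: set[str] = set()
        matched: list[tuple[str, str, str]] = []
        for alias_klass, name_a, name_b in aliases:
            if alias_klass != klass:
                continue
            # an alias only fires across genuinely different vocabularies;
            # when both flavors carry both names (e.g. a flavor against
            # itself) identical-name matching is the correct reading
            if name_a in names_b and name_b in names_a:
                continue
            if name_a in names_a and name_b in names_b \
                    and name_a not in taken_a and name_b not in taken_b:
                basis = ("identical-name" if name_a == name_b
                         else "dissimilar-name-curated")
                matched.append((name_a, name_b, basis))
                taken_a.add(name_a)
                taken_b.add(name_b)
        for name in names_a:
            if name in taken_a or name in taken_b:
                continue
            if name in names_b:
                matched.append((name, name, "identical-name"))
                taken_a.add(name)
                taken_b.add(name)

        if klass == "GLCM":
            distances = tuple(d for d in flavor_a.texture_spec.distances
                              if d in flavor_b.texture_spec.distances)
            for d in distances:
                for name_a, name_b, basis in matched:
                    pairs.append(SharedFeaturePair(
                        feature_a=str(FeatureId(flavor_a.flavor_name, klass, name_a, d)),
                        feature_b=str(FeatureId(flavor_b.flavor_name, klass, name_b, d)),
                        klass=klass, match_basis=basis, distance=d))
        else:
            for name_a, name_b, basis in matched:
                pairs.append(SharedFeaturePair(
                    feature_a=str(FeatureId(flavor_a.flavor_name, klass, name_a)),
                    feature_b=str(FeatureId(flavor_b.flavor_name, klass, name_b)),
                    klass=klass, match_basis=basis))
    return pairs


def fit_feature_correlations(table_a: FeatureTable, table_b: FeatureTable,
                             registry: list[SharedFeaturePair],
                             ) -> list[CorrelationRecord]:
    """Ordinary least squares per shared pair across all observations.

    Rows where either value is non-finite are excluded pairwise and
    counted in ``n_excluded``.  Records with fewer than 3 usable rows or
    a constant column are flagged undefined (NaN statistics) rather than
    fitted.
    """
    idx_a = table_a.data.index
    idx_b = table_b.data.index
    if set(idx_a) != set(idx_b):
        raise ValueError("feature tables do not share identical row keys")
    b_aligned = table_b.data.reindex(idx_a)

    records: list[CorrelationRecord] = []
    for pair in registry:
        if pair.feature_a not in table_a.data.columns:
            raise KeyError(f"registry feature missing from table A: {pair.feature_a}")
        if pair.feature_b not in b_aligned.columns:
            raise KeyError(f"registry feature missing from table B: {pair.feature_b}")
        x = table_a.data[pair.feature_a].to_numpy(dtype=np.float64)
        y = b_aligned[pair.feature_b].to_numpy(dtype=np.float64)
        ok = np.isfinite(x) & np.isfinite(y)
        n_used = int(ok.sum())
        n_excluded = int(x.size - n_used)
        xs, ys = x[ok], y[ok]
        if n_used < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            records.append(CorrelationRecord(pair, np.nan, np.nan, np.nan,
                                             n_used, n_excluded))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = stats.linregress(xs, ys)
        records.append(CorrelationRecord(pair, float(fit.rvalue),
                                         float(fit.slope), float(fit.intercept),
                                         n_used, n_excluded))
    return records


def select_reproducible(records: list[CorrelationRecord],
                        threshold: float) -> list[SharedFeaturePair]:
    """Pairs with finite Pearson r strictly greater than ``threshold``.

    Undefined records are never selected.
    """
    return [rec.pair for rec in records
            if np.isfinite(rec.r) and rec.r > threshold]


# ---------------------------------------------------------------------------
# tabular exports


def registry_to_frame(registry: list[SharedFeaturePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"feature_a": p.feature_a, "feature_b": p.feature_b, "class": p.klass,
          "distance": p.distance, "match_basis": p.match_basis}
         for p in registry]
    )


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    frame = registry_to_frame([rec.pair for rec in records])
    frame["r"] = [rec.r for rec in records]
    frame["slope"] = [rec.slope for rec in records]
    frame["intercept"] = [rec.intercept for rec in records]
    frame["n_used"] = [rec.n_used for rec in records]
    frame["n_excluded"] = [rec.n_excluded for rec in records]
    return frame
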