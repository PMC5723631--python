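"""Species-by-trait tables: coding, specialization indices, coverage
filtering, nearest-neighbour imputation and tropical-affinity classification.

Qualitative observations ("Yes" / "Yes minus" / "No") are coded 1 / 0.5 / 0
and averaged across literature records weighted by occurrence. Ordinal
multi-modality traits (e.g. foraging height scored ground=1, shrubs=2,
trees=3) are summarized per species by a specialization index: one minus the
occurrence-weighted variance of the modality scores, so a species always
recorded in one modality scores 1 (fully specialized) and a species spread
across extreme modalities scores near 0. Missingness is carried as an
explicit boolean mask, never a sentinel value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitDescriptor",
    "TraitMatrix",
    "TropicalAffinity",
    "code_qualitative",
    "specialization_index",
    "altitudinal_specialization",
    "filter_low_coverage",
    "impute_nearest_neighbor",
    "classify_tropical",
    "MissingValueError",
    "UnresolvableCellError",
    "MAX_ALTITUDE_M",
]

#: Highest maximum altitude across the compiled dataset, metres.
MAX_ALTITUDE_M = 4950.0

QUALITATIVE_CODES = {"Yes": 1.0, "YesMinus": 0.5, "Yes minus": 0.5, "No": 0.0}


class MissingValueError(ValueError):
    """Raised where a computation would need at least one observation."""


class UnresolvableCellError(ValueError):
    """Raised when no donor species exists for a missing cell."""


@dataclass
class TraitDescriptor:
    """Metadata for one trait column.

    kind is one of {"quantitative", "qualitative", "ordinal-modality",
    "specialization-index"}; modality_scale lists the ordered numeric scores
    of an ordinal trait; documentation_fraction is the share of species with
    a recorded value.
    """

    name: str
    kind: str = "quantitative"
    modality_scale: tuple | None = None
    documentation_fraction: float | None = None

    KINDS = ("quantitative", "qualitative", "ordinal-modality",
             "specialization-index")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.modality_scale is not None:
            scale = tuple(float(s) for s in self.modality_scale)
            if any(b <= a for a, b in zip(scale, scale[1:])):
                raise ValueError("modality_scale must be strictly increasing")
            self.modality_scale = scale
        if self.documentation_fraction is not None and not (
            0.0 <= self.documentation_fraction <= 1.0
        ):
            raise ValueError("documentation_fraction must lie in [0, 1]")


@dataclass
class TropicalAffinity:
    """Fraction of a species' distribution area inside the tropics."""

    species: str
    tropical_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.tropical_fraction <= 1.0:
            raise ValueError("tropical_fraction must lie in [0, 1]")

    @property
    def is_tropical(self) -> bool:
        return classify_tropical(self.tropical_fraction)


class TraitMatrix:
    """A species x trait grid with an explicit observed-mask.

    Parameters
    ----------
    values : (n_species, n_traits) float array; entries under an unobserved
        mask cell are ignored (and stored as NaN).
    observed_mask : same-shape boolean array, True = documented.
    species : ordered species identifiers.
    traits : list of TraitDescriptor (or plain names).
    """

    MISSING_TOKEN = "NA"

    def __init__(self, values, species, traits, observed_mask=None,
                 source_weights=None):
        self.values = np.array(values, dtype=float)
        self.species = list(species)
        self.traits = [
            t if isinstance(t, TraitDescriptor) else TraitDescriptor(str(t))
            for t in traits
        ]
        n, m = self.values.shape
        if len(self.species) != n or len(self.traits) != m:
            raise ValueError("species/trait lists inconsistent with grid shape")
        if observed_mask is None:
            observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(observed_mask, dtype=bool)
        if self.observed_mask.shape != self.values.shape:
            raise ValueError("observed_mask shape mismatch")
        self.values[~self.observed_mask] = np.nan
        self.source_weights = source_weights

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def coverage(self) -> np.ndarray:
        """Fraction of documented traits per species."""
        return self.observed_mask.mean(axis=1)

    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species,
                            columns=self.trait_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, traits=None) -> "TraitMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index),
                   traits if traits is not None else list(df.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep=self.MISSING_TOKEN,
                               index_label="species")

    @classmethod
    def read_csv(cls, path, metadata_path=None) -> "TraitMatrix":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0,
                         na_values=[cls.MISSING_TOKEN])
        traits: list = list(df.columns)
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path)
            desc = {}
            for _, row in meta.iterrows():
                scale = row.get("modality_scale")
                scale_t = (tuple(float(x) for x in str(scale).split("|"))
                           if isinstance(scale, str) and scale else None)
                desc[row["trait"]] = TraitDescriptor(
                    row["trait"], row.get("kind", "quantitative"), scale_t
                )
            traits = [desc.get(c, TraitDescriptor(c)) for c in df.columns]
        return cls.from_frame(df, traits)

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.values.copy(), list(self.species),
                           list(self.traits), self.observed_mask.copy(),
                           self.source_weights)

    def subset_species(self, keep: list[str]) -> "TraitMatrix":
        idx = [self.species.index(s) for s in keep]
        return TraitMatrix(self.values[idx], keep, list(self.traits),
                           self.observed_mask[idx], self.source_weights)


# ----------------------------------------------------------------------
def code_qualitative(records) -> float:
    """Weight-normalized mean of qualitative codes (Yes=1, Yes minus=0.5,
    No=0) across literature records.

    records : iterable of (label, weight) pairs with positive weights.
    Returns NaN for an empty record list (a missing value, not an absence).
    """
    records = list(records)
    if not records:
        return np.nan
    total = 0.0
    wsum = 0.0
    for label, weight in records:
        if weight <= 0:
            raise ValueError("record weights must be positive")
        if label not in QUALITATIVE_CODES:
            raise ValueError(f"unknown qualitative label {label!r}")
        total += QUALITATIVE_CODES[label] * weight
        wsum += weight
    return total / wsum


def specialization_index(modality_scores, weights=None) -> float:
    """One minus the occurrence-weighted (population) variance of modality
    scores, clipped to [0, 1].

    A species always observed in one modality has zero variance, hence index
    1; spread across distant modalities drives the index toward 0. Weights
    are occurrence counts and are normalized internally, so the index is
    invariant to their uniform rescaling. NaN for an empty score list.
    """
    scores = np.asarray(list(modality_scores), dtype=float)
    if scores.size == 0:
        return np.nan
    if weights is None:
        weights = np.ones_like(scores)
    w = np.asarray(list(weights), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if w.shape != scores.shape:
        raise ValueError("weights must match scores")
    w = w / w.sum()
    mu = float(w @ scores)
    var = float(w @ (scores - mu) ** 2)
    index = 1.0 - var
    if index < 0.0:
        warnings.warn(
            "weighted variance exceeds 1 for this modality scale; "
            "specialization index clipped to 0",
            UserWarning,
        )
    return float(np.clip(index, 0.0, 1.0))


def altitudinal_specialization(min_alt: float, max_alt: float,
                               dataset_max: float = MAX_ALTITUDE_M) -> float:
    """1 - (altitudinal range / dataset-wide maximum altitude)."""
    if max_alt < min_alt:
        raise ValueError("max_alt must be >= min_alt")
    if min_alt < 0 or max_alt > dataset_max:
        raise ValueError("altitudes must lie in [0, dataset_max]")
    return 1.0 - (max_alt - min_alt) / dataset_max


def classify_tropical(tropical_fraction: float) -> bool:
    """True iff strictly more than half the distribution is tropical."""
    if not 0.0 <= tropical_fraction <= 1.0:
        raise ValueError("tropical_fraction must lie in [0, 1]")
    return tropical_fraction > 0.5


# ----------------------------------------------------------------------
def filter_low_coverage(matrix: TraitMatrix, min_fraction: float = 0.5):
    """Drop species documented for less than `min_fraction` of traits.

    Returns (kept_matrix, excluded_species); survivor order is preserved.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    cov = matrix.coverage()
    keep = [s for s, c in zip(matrix.species, cov) if c >= min_fraction]
    excluded = [s for s, c in zip(matrix.species, cov) if c < min_fraction]
    if not keep:
        raise MissingValueError("coverage filter excluded every species")
    return matrix.subset_species(keep), excluded


def _gower_distances(values, mask, ranges) -> np.ndarray:
    """Pairwise Gower distance over co-observed traits (range-normalized
    absolute differences averaged across shared traits; NaN if none shared)."""
    n = values.shape[0]
    scaled = values / ranges  # ranges are >= 1e-12, zero-range traits -> 0 diff
    out = np.full((n, n), np.nan)
    for i in range(n):
        shared = mask[i] & mask
        diff = np.abs(scaled[i] - scaled)
        diff[~shared] = 0.0
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = diff.sum(axis=1) / cnt
        d[cnt == 0] = np.nan
        out[i] = d
    np.fill_diagonal(out, np.inf)  # a species never donates to itself
    return out


def impute_nearest_neighbor(matrix: TraitMatrix) -> TraitMatrix:
    """Fill missing cells from the most similar species (Gower distance over
    co-observed traits); ties among equally close donors are averaged.

    Observed cells are returned unchanged, so the operation is idempotent.
    Raises UnresolvableCellError when a missing cell has no documented donor
    sharing at least one observed trait.
    """
    if matrix.is_complete():
        return matrix.copy()
    vals = matrix.values.copy()
    mask = matrix.observed_mask
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(np.where(mask, vals, np.nan), axis=0)
        hi = np.nanmax(np.where(mask, vals, np.nan), axis=0)
    if np.any(np.isnan(lo)):
        bad = [matrix.trait_names[j] for j in np.flatnonzero(np.isnan(lo))]
        raise UnresolvableCellError(f"traits with no observations: {bad}")
    ranges = np.maximum(hi - lo, 1e-12)
    work = np.where(mask, vals, 0.0)
    dist = _gower_distances(work, mask, ranges)
    out = vals.copy()
    for i, j in zip(*np.where(~mask)):
        eligible = mask[:, j] & np.isfinite(dist[i])
        if not eligible.any():
            raise UnresolvableCellError(
                f"no donor for species {matrix.species[i]!r}, "
                f"trait {matrix.trait_names[j]!r}"
            )
        d = np.where(eligible, dist[i], np.inf)
        best = d.min()
        donors = np.flatnonzero(d <= best + 1e-12)
        out[i, j] = float(vals[donors, j].mean())
    return TraitMatrix(out, list(matrix.species), list(matrix.traits),
                       np.ones_like(mask, dtype=bool), matrix.source_weights)


def read_tropical_affinity(path) -> pd.Series:
    """Two-column CSV (species, tropical_fraction) -> boolean Series keyed by
    species, True = tropical affinity."""
    df = pd.read_csv(path)
    frac = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    return frac.map(classify_tropical)
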