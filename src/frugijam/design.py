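"""Design- and response-matrix preparation.

Encoding conventions (chosen so the joint model's species coefficients read
directly as per-species consumption indices):

* bat species: one-hot over all three levels, NO global intercept;
* sex: single 0/1 column (male = 1);
* reproductive condition: single 0/1 column (reproductive = 1);
* age class: two dummies (subadult, juvenile) against the adult reference;
* forearm and mass: standardized to mean 0, sd 1 (constants retained so the
  transform can be inverted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    FRACTIONAL_COMPOSITION,
    PRESENCE_ABSENCE,
    BatRecord,
    DietMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["species", "age_class", "sex", "repro", "mass", "forearm"]

_CATEGORICAL = {"species", "age_class", "sex", "repro"}
_CONTINUOUS = {"mass", "forearm"}


@dataclass
class DesignMatrix:
    """n x K design matrix with the constants needed to undo standardization."""

    values: np.ndarray
    column_labels: list[str]
    centers: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_labels):
            raise ValidationError("design matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("design matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def destandardize(self, column: str) -> np.ndarray:
        """Recover a continuous covariate on its original scale."""
        j = self.column_labels.index(column)
        return self.values[:, j] * self.scales[column] + self.centers[column]


def encode_design(
    records: Sequence[BatRecord],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[DesignMatrix, list[int]]:
    """Encode bat records into a design matrix.

    Records with a missing modeled continuous covariate are dropped (listwise
    deletion) and the kept row indices are returned alongside the matrix so the
    response matrix can be subset to match.
    """
    unknown = set(covariates) - (_CATEGORICAL | _CONTINUOUS)
    if unknown:
        raise ValidationError(f"unknown covariates: {sorted(unknown)}")

    needs_continuous = [c for c in covariates if c in _CONTINUOUS]
    kept = [
        i for i, r in enumerate(records)
        if all(getattr(r, c) is not None for c in needs_continuous)
    ]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("encode_design: dropped %d record(s) with missing covariates", dropped)
    use = [records[i] for i in kept]
    if not use:
        raise ValidationError("no records remain after dropping incomplete ones")

    columns: list[np.ndarray] = []
    labels: list[str] = []
    centers: dict[str, float] = {}
    scales: dict[str, float] = {}

    for cov in covariates:
        if cov == "species":
            levels = ("perspicillata", "sowelli", "castanea")
            present = {r.species for r in use}
            if len(present) < 2:
                raise ValidationError("species has a single level; cannot encode")
            for lev in levels:
                col = np.array([1.0 if r.species == lev else 0.0 for r in use])
                if col.sum() == 0:
                    raise ValidationError(f"species level {lev!r} absent from data")
                columns.append(col)
                labels.append(lev)
        elif cov == "age_class":
            vals = [r.age_class for r in use]
            if len(set(vals)) < 2:
                raise ValidationError("age_class has a single level; cannot encode")
            for lev in ("subadult", "juvenile"):
                col = np.array([1.0 if v == lev else 0.0 for v in vals])
                if 0 < col.sum():
                    columns.append(col)
                    labels.append(f"age_{lev}")
        elif cov == "sex":
            col = np.array([1.0 if r.sex == "male" else 0.0 for r in use])
            if col.std() == 0:
                raise ValidationError("sex has a single level; cannot encode")
            columns.append(col)
            labels.append("sex_male")
        elif cov == "repro":
            col = np.array([1.0 if r.repro == "reproductive" else 0.0 for r in use])
            if col.std() == 0:
                raise ValidationError("repro has a single level; cannot encode")
            columns.append(col)
            labels.append("repro_reproductive")
        else:  # continuous
            raw = np.array([float(getattr(r, cov)) for r in use])
            mu, sd = raw.mean(), raw.std(ddof=0)
            if sd == 0:
                raise ValidationError(f"{cov} has zero variance; cannot standardize")
            columns.append((raw - mu) / sd)
            labels.append(cov)
            centers[cov] = float(mu)
            scales[cov] = float(sd)

    X = np.column_stack(columns)
    if X.shape[0] < X.shape[1]:
        raise ValidationError(
            f"n={X.shape[0]} < K={X.shape[1]}: design is under-determined"
        )
    return DesignMatrix(X, labels, centers, scales), kept


def filter_rare_species(
    Y: DietMatrix, threshold: float
) -> tuple[DietMatrix, list[str]]:
    """Drop plant columns whose share of total presences falls below ``threshold``.

    The share is computed on presence observations (column presences divided by
    total presences across all columns), not on individuals.  Returns the
    filtered matrix and the list of dropped labels.
    """
    if Y.mode != PRESENCE_ABSENCE:
        raise ValidationError("rare-species filtering expects a presence/absence matrix")
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must lie in [0,1)")
    totals = Y.values.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("diet matrix has no presences at all")
    share = totals / grand
    keep = share >= threshold if threshold > 0 else np.ones(Y.n_species, bool)
    if not keep.any():
        raise ValidationError("rare-species filter would drop every column")
    dropped = [lab for lab, k in zip(Y.species_labels, keep) if not k]
    if dropped:
        logger.info("filter_rare_species: dropped %s", dropped)
    kept_labels = [lab for lab, k in zip(Y.species_labels, keep) if k]
    return DietMatrix(Y.values[:, keep], PRESENCE_ABSENCE, kept_labels), dropped


def to_fractional(Y: DietMatrix) -> DietMatrix:
    """Convert presence/absence rows to equal-weight compositions (1/k per present).

    All-absent rows stay all-zero; they are detectable through
    :attr:`DietMatrix.all_absent_rows`.  This equal-weighting is an assumption:
    fecal data record presence only, so any composition beyond 1/k would be
    invented information.
    """
    if Y.mode != PRESENCE_ABSENCE:
        raise ValidationError("to_fractional expects a presence/absence matrix")
    counts = Y.values.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(counts > 0, Y.values / counts, 0.0)
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.info("to_fractional: %d all-absent row(s) left at zero", n_empty)
    return DietMatrix(frac, FRACTIONAL_COMPOSITION, Y.species_labels)


def diet_prevalence(
    records: Sequence[BatRecord],
    diet: DietMatrix,
    genus_filter: set[str] | None = None,
) -> pd.DataFrame:
    """Percent of individuals per bat species with >= 1 filtered plant present."""
    if genus_filter is None:
        genus_filter = set(diet.species_labels)
    if not genus_filter:
        raise ValidationError("genus_filter is empty")
    missing = genus_filter - set(diet.species_labels)
    if missing:
        raise ValidationError(f"filter labels not in diet matrix: {sorted(missing)}")
    cols = [j for j, lab in enumerate(diet.species_labels) if lab in genus_filter]
    any_present = diet.values[:, cols].sum(axis=1) > 0
    rows = []
    bat_species = [r.species for r in records]
    for sp in ("perspicillata", "sowelli", "castanea"):
        mask = np.array([s == sp for s in bat_species])
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "bat_species": sp,
                "n": int(mask.sum()),
                "n_with_presence": int((any_present & mask).sum()),
                "percent": 100.0 * (any_present & mask).sum() / mask.sum(),
            }
        )
    if not rows:
        raise ValidationError("no records for any bat species")
    return pd.DataFrame(rows)


def shape_index(length: float, width: float) -> float:
    """Dimensionless elongation: length / width (width must be > 0)."""
    if not width > 0:
        raise ValidationError(f"width must be positive, got {width}")
    return length / width


def shape_index_from_measurements(
    lengths: Sequence[float], widths: Sequence[float]
) -> float:
    """Aggregate replicate measurements: average first, then take the ratio."""
    lengths = np.asarray(lengths, float)
    widths = np.asarray(widths, float)
    if lengths.size == 0 or widths.size == 0:
        raise ValidationError("need at least one measurement")
    return shape_index(float(lengths.mean()), float(widths.mean()))
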