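"""In-memory cohort container and covariate design construction.

A cohort bundles the three tables every stage of the analysis consumes:

* ``dosages`` — samples × markers fractional genotypes in [0, 2]
  (expected minor-allele counts from imputation);
* ``samples`` — per-sample phenotype and covariates: case/control status,
  recruitment center (stratum), gender, and carrier status at the major
  HLA locus (tag-SNP derived, 0/1);
* ``markers`` — the marker map (id, chromosome, position, alleles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "status", "center", "gender", "drb1_status"]
MARKER_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    causal_marker_ids: list[str]
    causal_log_ors: dict[str, float]
    liability: np.ndarray  # true linear predictor per sample
    seed: int


@dataclass
class Cohort:
    dosages: pd.DataFrame
    samples: pd.DataFrame
    markers: pd.DataFrame
    truth: CohortTruth | None = None

    def __post_init__(self):
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        if len(self.samples) != len(self.dosages):
            raise ValueError(
                f"sample table has {len(self.samples)} rows but dosage matrix "
                f"has {len(self.dosages)}"
            )
        if not (self.samples["sample_id"].values == self.dosages.index.values).all():
            raise ValueError("sample order differs between dosages and sample table")
        extra = set(self.dosages.columns) - set(self.markers["id"])
        if extra:
            raise ValueError(f"dosage markers absent from marker map: {sorted(extra)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def y(self) -> np.ndarray:
        return self.samples["status"].to_numpy(dtype=float)

    def center_levels(self) -> list[str]:
        return sorted(self.samples["center"].astype(str).unique())

    def subset(self, sample_idx: Sequence[int]) -> "Cohort":
        idx = np.asarray(sample_idx)
        truth = self.truth
        if truth is not None:
            truth = CohortTruth(
                truth.causal_marker_ids,
                truth.causal_log_ors,
                truth.liability[idx],
                truth.seed,
            )
        return Cohort(
            self.dosages.iloc[idx],
            self.samples.iloc[idx].reset_index(drop=True),
            self.markers,
            truth,
        )


def covariate_design(
    samples: pd.DataFrame,
    *,
    condition_on_drb1: bool = False,
    center_levels: list[str] | None = None,
    drop_constant: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Covariate block of every model: intercept, center dummies, gender.

    Center is coded as treatment dummies against the first (sorted) level;
    gender as an indicator for female.  With ``condition_on_drb1`` the HLA
    carrier indicator is appended, implementing conditioning on major-locus
    status as a fixed covariate.

    ``center_levels`` fixes the dummy coding (needed when applying a
    trained model to new data); an unseen center raises ``KeyError``
    listing the valid labels.
    """
    centers = samples["center"].astype(str)
    if center_levels is None:
        center_levels = sorted(centers.unique())
    unknown = sorted(set(centers.unique()) - set(center_levels))
    if unknown:
        raise KeyError(
            f"unknown center label(s) {unknown}; valid labels: {center_levels}"
        )
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for lev in center_levels[1:]:
        cols.append((centers == lev).to_numpy(dtype=float))
        names.append(f"center[{lev}]")
    female = samples["gender"].astype(str).str.upper().isin(["F", "FEMALE", "1"])
    cols.append(female.to_numpy(dtype=float))
    names.append("gender[F]")
    if condition_on_drb1:
        cols.append(samples["drb1_status"].to_numpy(dtype=float))
        names.append("drb1")
    X = np.column_stack(cols)
    if drop_constant:
        # a constant covariate (single-gender cohort, universal carrier
        # status) is collinear with the intercept and carries no information
        keep = [0] + [j for j in range(1, X.shape[1]) if X[:, j].std() > 0]
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names
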