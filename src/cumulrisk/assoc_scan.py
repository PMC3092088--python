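"""Stage I: per-marker association scan and the dual-model filter.

Every marker is tested one at a time in a logistic model with an additive
dosage term, under two covariate models:

* ``base`` — center + gender;
* ``conditioned`` — center + gender + major-locus (DRB1-type) carrier
  status, which conditions out the baseline HLA risk and de-weights
  markers that merely tag it.

The marker p-value is the 1-df likelihood-ratio test of the dosage term.
Markers below the significance threshold (default P < 0.001) in *both*
models pass to the independence screen.  The genomic-control inflation
factor λ (median association chi-square over its null median) is reported
as a stratification diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import batched_marker_fits
from .cohort import Cohort, covariate_design
from .glm_core import fit_logistic

__all__ = ["scan_markers", "scan_both_models", "genomic_inflation", "stage1_filter", "ScanResult"]

MODEL_TAGS = ("base", "conditioned")

#: median of the chi-square distribution with 1 df
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class ScanResult:
    """Per-marker results under both covariate models plus diagnostics."""

    results: pd.DataFrame  # one row per (marker, model_tag)
    inflation_lambda: float
    n_selected: int
    p_threshold: float

    def by_model(self, tag: str) -> pd.DataFrame:
        return self.results[self.results["model_tag"] == tag].set_index("marker_id")


def scan_markers(
    cohort: Cohort,
    model_tag: str = "base",
    *,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Single-marker logistic scan under one covariate model.

    Returns a DataFrame with one row per marker: ``beta``, LR ``p_value``,
    ``neg_log10_p``, ``odds_ratio`` with Wald confidence limits, and a
    ``monomorphic`` flag (monomorphic markers get p = 1, not an error).
    Results do not depend on marker evaluation order.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"model_tag must be one of {MODEL_TAGS}")
    X_base, _ = covariate_design(
        cohort.samples, condition_on_drb1=(model_tag == "conditioned")
    )
    y = cohort.y
    D = cohort.dosages.to_numpy(dtype=float)
    if D.size and (D.min() < 0 or D.max() > 2):
        raise ValueError("dosages outside [0, 2]")

    null_dev = fit_logistic(X_base, y, check_rank=False).deviance
    beta, se, dev, conv = batched_marker_fits(X_base, D, y)
    mono = np.isnan(beta)
    lr = np.maximum(null_dev - dev, 0.0)
    p = stats.chi2.sf(lr, 1)
    p[mono] = 1.0
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    with np.errstate(over="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {
                "marker_id": cohort.dosages.columns,
                "beta": beta,
                "p_value": p,
                "neg_log10_p": -np.log10(np.maximum(p, 1e-300)),
                "odds_ratio": np.exp(beta),
                "lower_cl": np.exp(beta - z * se),
                "upper_cl": np.exp(beta + z * se),
                "model_tag": model_tag,
                "monomorphic": mono,
            }
        )
    return out


def scan_both_models(
    cohort: Cohort, p_threshold: float = 0.001
) -> ScanResult:
    """Run the base and conditioned scans and apply the dual-model filter."""
    frames = [scan_markers(cohort, tag) for tag in MODEL_TAGS]
    results = pd.concat(frames, ignore_index=True)
    p_base = frames[0]["p_value"].to_numpy()
    lam = genomic_inflation(p_base) if p_base.size >= 100 else float("nan")
    selected = stage1_filter(results, p_threshold)
    return ScanResult(
        results=results,
        inflation_lambda=lam,
        n_selected=len(selected),
        p_threshold=p_threshold,
    )


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic-control λ: median observed 1-df chi-square / null median.

    λ ≈ 1 for a well-calibrated scan; λ substantially above 1 indicates
    population stratification (or pervasive polygenic signal).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values to estimate lambda")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / _CHI2_1_MEDIAN)


def stage1_filter(
    scan_results: pd.DataFrame, p_threshold: float = 0.001
) -> list[str]:
    """Markers below threshold in *both* covariate models.

    Returns marker ids sorted by conditioned-model p-value (ties broken
    by marker id).
    """
    present = set(scan_results["model_tag"])
    if not set(MODEL_TAGS) <= present:
        raise ValueError(f"scan must contain both model tags {MODEL_TAGS}")
    wide = scan_results.pivot(index="marker_id", columns="model_tag", values="p_value")
    hit = wide[(wide["base"] < p_threshold) & (wide["conditioned"] < p_threshold)]
    order = hit.sort_values(["conditioned", "marker_id"], kind="stable")
    return order.index.tolist()


def fdr_at_threshold(p_values: np.ndarray, p_threshold: float) -> float:
    """Benjamini–Hochberg q-value at the selection threshold (descriptive).

    The scan selects on raw p; this reports the FDR that the chosen raw-p
    cutoff corresponds to, as context for threshold choice.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    k = np.searchsorted(p, p_threshold, side="right")
    if k == 0:
        return 0.0
    return float(min(1.0, p_threshold * p.size / k))
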