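"""Stages III-IV: stepwise risk-profile construction, the cumulative
genetic-risk score (P-Hat), classification, calibration and validation.

The risk profile is an ordered marker list with logistic coefficients.
For individual *i* the linear predictor is

    Yhat_i = intercept + b_center·X_center + b_gender·X_gender
             + sum_j b_j · X_ij

with X_ij the fractional dosage of marker j, and the cumulative genetic
risk is P-Hat = 1 / (1 + exp(-Yhat_i)).  An individual with Yhat > 0
(P-Hat > 0.5) is classified as a case.

Markers enter by stepwise selection from the independent set: forward
steps add the most significant remaining marker while it clears the
entry threshold, backward steps drop included markers that no longer
retain significance, alternating until the model is stable.  Reporting
covers sensitivity/specificity at the fixed 0.5 threshold, P-Hat
quantiles by group, rank-based AUC, the Hosmer-Lemeshow calibration
test, and a Nagelkerke-R² variance partition over ordered predictor
blocks.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import score_test_candidates
from .cohort import Cohort, covariate_design
from .glm_core import GlmFit, fit_logistic, nagelkerke_r2

__all__ = [
    "RiskModel",
    "ClassificationSummary",
    "CalibrationResult",
    "stepwise_select",
    "score",
    "classify_and_summarize",
    "auc_mann_whitney",
    "roc_points",
    "hosmer_lemeshow",
    "variance_partition",
    "apply_to_cohort",
    "write_model",
    "read_model",
]


@dataclass
class RiskModel:
    """Ordered marker list + coefficients defining the risk score."""

    marker_ids: list[str]
    marker_betas: np.ndarray
    covariate_betas: dict[str, float]  # center dummies + gender, by design name
    intercept: float
    center_levels: list[str]
    selection_config: dict = field(default_factory=dict)
    training_fit: GlmFit | None = None

    def __post_init__(self):
        self.marker_betas = np.asarray(self.marker_betas, dtype=float)
        if len(self.marker_ids) != self.marker_betas.size:
            raise ValueError("marker_ids and marker_betas differ in length")


@dataclass
class ClassificationSummary:
    sensitivity: float
    specificity: float
    case_quantiles: tuple[float, float, float]  # P-Hat at 25/50/75%
    control_quantiles: tuple[float, float, float]
    auc: float
    n_cases: int
    n_controls: int


@dataclass
class CalibrationResult:
    hl_statistic: float
    df: int
    p_value: float
    bins: pd.DataFrame  # per-bin n, observed, expected
    n_bins_merged: int = 0


def _covariate_column(samples, name: str) -> np.ndarray:
    """Materialise one covariate design column from its term name."""
    if name.startswith("center[") and name.endswith("]"):
        lev = name[len("center["):-1]
        return (samples["center"].astype(str) == lev).to_numpy(dtype=float)
    if name == "gender[F]":
        return (
            samples["gender"].astype(str).str.upper().isin(["F", "FEMALE", "1"])
        ).to_numpy(dtype=float)
    if name == "drb1":
        return samples["drb1_status"].to_numpy(dtype=float)
    raise KeyError(f"unknown covariate term {name!r}")


def stepwise_select(
    cohort: Cohort,
    accepted_markers: list[str],
    entry_p: float = 0.05,
    stay_p: float = 0.05,
    *,
    forward_method: str = "score",
    max_steps: int | None = None,
) -> RiskModel:
    """Forward/backward stepwise logistic selection over the accepted set.

    Forward sweeps use the Rao score test (one fit per step, no refit per
    candidate; ``forward_method="lr"`` switches to exact likelihood-ratio
    refits).  Backward elimination always uses the partial LR test.
    Center and gender stay in the model unconditionally.
    """
    if entry_p > stay_p:
        raise ValueError("entry_p must be <= stay_p")
    missing = [m for m in accepted_markers if m not in cohort.dosages.columns]
    if missing:
        raise KeyError(f"markers absent from cohort: {missing[:5]}")
    X_cov, cov_names = covariate_design(cohort.samples)
    y = cohort.y
    dcols = cohort.dosages
    info = cohort.markers.set_index("id")
    pos_key = {
        m: (int(info.loc[m, "chrom"]), int(info.loc[m, "pos"]), m)
        for m in accepted_markers
    }

    current: list[str] = []
    if max_steps is None:
        max_steps = 4 * len(accepted_markers) + 10
    seen: set[frozenset] = set()

    def design(markers):
        if not markers:
            return X_cov
        return np.column_stack([X_cov] + [dcols[m].to_numpy() for m in markers])

    fit = fit_logistic(design(current), y, check_rank=False)
    for _ in range(max_steps):
        changed = False
        # ---- forward
        cand = [m for m in accepted_markers if m not in current]
        if cand and entry_p > 0:
            X_cur = design(current)
            mu = 1.0 / (1.0 + np.exp(-(X_cur @ fit.coefficients)))
            D = dcols[cand].to_numpy(dtype=float)
            if forward_method == "score":
                chi = score_test_candidates(mu, X_cur, D, y)
                p = stats.chi2.sf(chi, 1)
            else:
                dev0 = fit.deviance
                from ._batch import batched_marker_fits

                _, _, dev_m, _ = batched_marker_fits(X_cur, D, y)
                p = stats.chi2.sf(np.maximum(dev0 - dev_m, 0.0), 1)
            order = sorted(range(len(cand)), key=lambda i: (p[i],) + pos_key[cand[i]])
            best = order[0]
            if p[best] < entry_p:
                current.append(cand[best])
                fit = fit_logistic(design(current), y, check_rank=False)
                changed = True
        # ---- backward
        while current:
            dev_full = fit.deviance
            worst, worst_p = None, -1.0
            for m in current:
                red = fit_logistic(
                    design([x for x in current if x != m]), y, check_rank=False
                )
                pm = float(stats.chi2.sf(max(red.deviance - dev_full, 0.0), 1))
                if pm > worst_p:
                    worst, worst_p = m, pm
            if worst_p >= stay_p:
                current.remove(worst)
                fit = fit_logistic(design(current), y, check_rank=False)
                changed = True
            else:
                break
        key = frozenset(current)
        if not changed or key in seen:
            break
        seen.add(key)

    fit = fit_logistic(design(current), y, check_rank=False)
    k = len(cov_names)
    return RiskModel(
        marker_ids=list(current),
        marker_betas=fit.coefficients[k:],
        covariate_betas=dict(zip(cov_names[1:], fit.coefficients[1:k])),
        intercept=float(fit.coefficients[0]),
        center_levels=sorted(cohort.samples["center"].astype(str).unique()),
        selection_config={"entry_p": entry_p, "stay_p": stay_p,
                          "forward_method": forward_method},
        training_fit=fit,
    )


def score(
    model: RiskModel, cohort: Cohort, *, allow_unseen_centers: bool = False
) -> pd.DataFrame:
    """Linear predictor, P-Hat and the 0.5-threshold label per sample."""
    missing = [m for m in model.marker_ids if m not in cohort.dosages.columns]
    if missing:
        raise KeyError(f"model markers absent from cohort: {missing}")
    seen = set(cohort.samples["center"].astype(str).unique())
    unseen = sorted(seen - set(model.center_levels)) if model.center_levels else []
    if unseen:
        if not allow_unseen_centers:
            raise KeyError(
                f"unknown center label(s) {unseen}; valid labels: "
                f"{model.center_levels}"
            )
        warnings.warn(
            f"centers {unseen} unseen in training; their coefficient set to 0",
            stacklevel=2,
        )
    y_hat = np.full(len(cohort.samples), model.intercept)
    for name, beta in model.covariate_betas.items():
        y_hat = y_hat + beta * _covariate_column(cohort.samples, name)
    if model.marker_ids:
        y_hat = y_hat + cohort.dosages[model.marker_ids].to_numpy() @ model.marker_betas
    p_hat = 1.0 / (1.0 + np.exp(-y_hat))
    return pd.DataFrame(
        {
            "sample_id": cohort.samples["sample_id"].values,
            "y_hat": y_hat,
            "p_hat": p_hat,
            "predicted_label": (y_hat > 0).astype(int),
        }
    )


def auc_mann_whitney(values: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability that a random case outscores a
    random control, ties counted one half."""
    y = np.asarray(y)
    v = np.asarray(values, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one outcome group is empty")
    ranks = stats.rankdata(v)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(values: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve (fpr, tpr, threshold), thresholds descending."""
    y = np.asarray(y)
    v = np.asarray(values, dtype=float)
    order = np.argsort(-v, kind="stable")
    yv = y[order]
    vv = v[order]
    distinct = np.r_[np.flatnonzero(np.diff(vv)), yv.size - 1]
    tp = np.cumsum(yv == 1)[distinct]
    fp = np.cumsum(yv == 0)[distinct]
    n1, n0 = (y == 1).sum(), (y == 0).sum()
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, vv[distinct]],
            "fpr": np.r_[0.0, fp / n0],
            "tpr": np.r_[0.0, tp / n1],
        }
    )


def classify_and_summarize(scores: pd.DataFrame, truth: np.ndarray) -> ClassificationSummary:
    """Sensitivity/specificity at the fixed threshold, P-Hat quantiles by
    group (linear-interpolation quartiles) and rank-based AUC."""
    y = np.asarray(truth)
    if len(y) != len(scores):
        raise ValueError("scores and truth differ in length")
    case = y == 1
    ctrl = y == 0
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    pred = scores["predicted_label"].to_numpy()
    p_hat = scores["p_hat"].to_numpy()
    q = [0.25, 0.5, 0.75]
    return ClassificationSummary(
        sensitivity=float((pred[case] == 1).mean()),
        specificity=float((pred[ctrl] == 0).mean()),
        case_quantiles=tuple(np.quantile(p_hat[case], q)),
        control_quantiles=tuple(np.quantile(p_hat[ctrl], q)),
        auc=auc_mann_whitney(p_hat, y),
        n_cases=int(case.sum()),
        n_controls=int(ctrl.sum()),
    )


def hosmer_lemeshow(
    scores: pd.DataFrame | np.ndarray, truth: np.ndarray, g: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow decile-of-risk calibration test.

    Samples are binned by P-Hat quantiles into ``g`` groups; the statistic
    sums (O - E)² / (E(1 - E/n_bin)) over bins, equivalent to the Pearson
    sum over the bin × outcome cells, and is referred to chi-square with
    g - 2 df.  Bins whose expected count is 0 (or that are empty) are
    merged with their neighbour and recorded.
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    p_hat = (
        scores["p_hat"].to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    )
    y = np.asarray(truth, dtype=float)
    if p_hat.shape != y.shape:
        raise ValueError("scores and truth differ in length")
    edges = np.unique(np.quantile(p_hat, np.linspace(0, 1, g + 1)))
    if len(edges) < 2:  # constant scores: a single bin
        edges = np.array([edges[0], edges[0]])
    idx = np.clip(np.searchsorted(edges, p_hat, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        rows.append((int(mask.sum()), float(y[mask].sum()), float(p_hat[mask].sum())))
    # merge degenerate bins (empty, or expected count 0 on either side)
    merged = 0
    out: list[list[float]] = []
    for n_b, o, e in rows:
        degenerate = n_b == 0 or e <= 0 or e >= n_b
        if degenerate and out:
            out[-1][0] += n_b
            out[-1][1] += o
            out[-1][2] += e
            merged += 1
        else:
            out.append([n_b, o, e])
    while len(out) > 1 and (out[0][0] == 0 or out[0][2] <= 0 or out[0][2] >= out[0][0]):
        n_b, o, e = out.pop(0)
        out[0][0] += n_b
        out[0][1] += o
        out[0][2] += e
        merged += 1
    stat = 0.0
    for n_b, o, e in out:
        denom = e * (1.0 - e / n_b)
        if denom <= 0:
            continue
        stat += (o - e) ** 2 / denom
    df = max(len(out) - 2, 1)
    return CalibrationResult(
        hl_statistic=float(stat),
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        bins=pd.DataFrame(out, columns=["n", "observed", "expected"]),
        n_bins_merged=merged,
    )


def variance_partition(
    cohort: Cohort, blocks: list[tuple[str, object]]
) -> pd.DataFrame:
    """Nagelkerke-R² increments over ordered predictor blocks.

    Each block is ``(name, spec)`` where spec is one of the tokens
    ``"center"``, ``"gender"``, ``"drb1"`` or a list of marker ids.  The
    k-th increment is R²(blocks 1..k) - R²(blocks 1..k-1), both against
    the intercept-only null, so the increments telescope to the
    full-model R².
    """
    y = cohort.y
    n = len(y)
    samples = cohort.samples
    null_fit = fit_logistic(np.ones((n, 1)), y, check_rank=False)
    cols: list[np.ndarray] = []
    records = []
    r2_prev = 0.0
    centers = samples["center"].astype(str)
    levels = sorted(centers.unique())
    for name, spec_ in blocks:
        if isinstance(spec_, str):
            if spec_ == "center":
                new = [
                    (centers == lev).to_numpy(dtype=float) for lev in levels[1:]
                ]
            elif spec_ == "gender":
                new = [
                    samples["gender"].astype(str).str.upper()
                    .isin(["F", "FEMALE", "1"]).to_numpy(dtype=float)
                ]
            elif spec_ == "drb1":
                new = [samples["drb1_status"].to_numpy(dtype=float)]
            else:
                raise ValueError(f"unknown block token {spec_!r}")
        else:
            new = [cohort.dosages[m].to_numpy(dtype=float) for m in spec_]
        cols.extend(new)
        X = np.column_stack([np.ones(n)] + cols)
        fit = fit_logistic(X, y, check_rank=False)
        r2 = nagelkerke_r2(fit, null_fit)
        records.append(
            {"block": name, "r2_cumulative": r2, "r2_increment": r2 - r2_prev}
        )
        r2_prev = r2
    return pd.DataFrame(records)


def apply_to_cohort(
    model: RiskModel, validation_cohort: Cohort, mode: str = "refit"
) -> tuple[RiskModel, ClassificationSummary]:
    """Apply a trained profile to a validation cohort.

    ``frozen`` reuses the training coefficients (unseen centers get
    coefficient 0 with a warning); ``refit`` re-estimates coefficients
    for the same marker list on the validation cohort with its own
    covariates.  Returns the model actually used and the classification
    summary.
    """
    if mode not in ("frozen", "refit"):
        raise ValueError("mode must be 'frozen' or 'refit'")
    missing = [m for m in model.marker_ids if m not in validation_cohort.dosages.columns]
    if missing:
        raise KeyError(f"model markers absent from validation cohort: {missing}")
    if mode == "frozen":
        used = model
        sc = score(model, validation_cohort, allow_unseen_centers=True)
    else:
        X_cov, cov_names = covariate_design(validation_cohort.samples)
        X = np.column_stack(
            [X_cov]
            + [validation_cohort.dosages[m].to_numpy() for m in model.marker_ids]
        ) if model.marker_ids else X_cov
        fit = fit_logistic(X, validation_cohort.y, check_rank=False)
        k = len(cov_names)
        used = RiskModel(
            marker_ids=list(model.marker_ids),
            marker_betas=fit.coefficients[k:],
            covariate_betas=dict(zip(cov_names[1:], fit.coefficients[1:k])),
            intercept=float(fit.coefficients[0]),
            center_levels=sorted(
                validation_cohort.samples["center"].astype(str).unique()
            ),
            selection_config={**model.selection_config, "mode": "refit"},
            training_fit=fit,
        )
        sc = score(used, validation_cohort)
    return used, classify_and_summarize(sc, validation_cohort.y)


# ------------------------------------------------------------- model file

def write_model(model: RiskModel, path: str | Path) -> Path:
    """TSV model file: '#'-prefixed metadata then term/coefficient rows."""
    path = Path(path)
    h = hashlib.sha256()
    h.update(",".join(model.marker_ids).encode())
    h.update(model.marker_betas.tobytes())
    lines = [
        f"# selection_config\t{model.selection_config}",
        f"# center_levels\t{','.join(model.center_levels)}",
        f"# model_hash\t{h.hexdigest()[:16]}",
        "term\tcoefficient",
        f"intercept\t{float(model.intercept)!r}",
    ]
    for name, b in model.covariate_betas.items():
        lines.append(f"{name}\t{float(b)!r}")
    for m, b in zip(model.marker_ids, model.marker_betas):
        lines.append(f"marker:{m}\t{float(b)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_model(path: str | Path) -> RiskModel:
    import ast

    meta = {}
    terms: list[tuple[str, float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key] = val
            continue
        name, _, val = line.partition("\t")
        if name == "term":
            continue
        try:
            terms.append((name, float(val)))
        except ValueError:
            raise ValueError(f"malformed model file at line {ln}: {line!r}") from None
    d = dict(terms)
    intercept = d.pop("intercept")
    markers = [(k[len("marker:"):], v) for k, v in d.items() if k.startswith("marker:")]
    covs = {k: v for k, v in d.items() if not k.startswith("marker:")}
    sel = {}
    if "selection_config" in meta:
        try:
            sel = ast.literal_eval(meta["selection_config"])
        except (ValueError, SyntaxError):
            sel = {}
    return RiskModel(
        marker_ids=[m for m, _ in markers],
        marker_betas=np.array([v for _, v in markers]),
        covariate_betas=covs,
        intercept=intercept,
        center_levels=meta.get("center_levels", "").split(",") if meta.get("center_levels") else [],
        selection_config=sel,
    )
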