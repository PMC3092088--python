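"""Stage II: iterative model-based LD-independence screen.

Stage I candidates are reduced to a mutually independent marker set by
alternating two analysis-of-deviance tests inside one logistic model
(covariates, and the major-locus carrier indicator when conditioning is
on):

1. *seed*: the most significant marker per genomic window at P < 1e-5 is
   entered sequentially, in order of significance; a marker whose
   sequential (type I) p-value fails the retention threshold adds nothing
   beyond the markers already in and is dropped;
2. *expand*: every remaining candidate is tested by a partial (type III)
   test against the accepted model; candidates with residual effect at
   P < 0.001 join;
3. *joint re-test*: the combined set is re-examined by both tests and any
   member failing P < 0.01 in either is removed (two markers in LD cannot
   both stay significant given each other).

Steps 2-3 repeat until no candidate shows a residual effect.  Every
decision is appended to an audit log that replays to the final state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import batched_marker_fits
from .assoc_scan import scan_markers
from .cohort import Cohort, covariate_design
from .glm_core import fit_logistic

__all__ = ["ScreenConfig", "ScreenState", "seed_set", "run_screen"]


@dataclass
class ScreenConfig:
    seed_p: float = 1e-5
    expand_p: float = 1e-3
    retain_p: float = 1e-2
    condition_on_drb1: bool = True
    window_bp: int = 500_000
    max_iterations: int = 25


@dataclass
class ScreenState:
    accepted: list[str]
    candidates: list[str]
    iteration: int
    audit_log: pd.DataFrame
    converged: bool = True

    def __post_init__(self):
        overlap = set(self.accepted) & set(self.candidates)
        if overlap:
            raise ValueError(f"accepted and candidates overlap: {sorted(overlap)}")


def _order_key(tab: pd.DataFrame):
    """Deterministic ordering: p, then (chrom, pos), then id."""
    return tab.sort_values(
        ["p_value", "chrom", "pos", "marker_id"], kind="stable"
    )["marker_id"].tolist()


def seed_set(
    candidates: pd.DataFrame,
    *,
    seed_p: float = 1e-5,
    window_bp: int = 500_000,
) -> list[str]:
    """Best marker per non-overlapping genomic window among P < seed_p.

    ``candidates`` needs columns marker_id, p_value, chrom, pos.  Window
    thinning stands in for the "one top marker per gene" rule; returns
    ids ordered by significance (ties: position, then id).
    """
    sub = candidates[candidates["p_value"] < seed_p].copy()
    if sub.empty:
        return []
    sub["window"] = sub["pos"] // window_bp
    sub = sub.sort_values(["p_value", "pos", "marker_id"], kind="stable")
    best = sub.groupby(["chrom", "window"], sort=False).head(1)
    return _order_key(best)


def _candidate_table(cohort: Cohort, candidates, p_values: pd.Series) -> pd.DataFrame:
    info = cohort.markers.set_index("id")
    rows = []
    for m in candidates:
        rows.append(
            {
                "marker_id": m,
                "p_value": float(p_values[m]),
                "chrom": int(info.loc[m, "chrom"]),
                "pos": int(info.loc[m, "pos"]),
            }
        )
    return pd.DataFrame(rows)


def run_screen(
    cohort: Cohort,
    candidates: list[str],
    config: ScreenConfig = ScreenConfig(),
    *,
    scan: pd.DataFrame | None = None,
) -> ScreenState:
    """Run the iterative sequential/partial independence screen.

    ``candidates`` are Stage I survivors (ids present in the cohort).
    ``scan`` may supply a precomputed conditioned-model scan to order the
    seeds; otherwise one is computed on the candidate set.
    """
    missing = [m for m in candidates if m not in cohort.dosages.columns]
    if missing:
        raise KeyError(f"candidate markers absent from cohort: {missing[:5]}")
    X_cov, cov_names = covariate_design(
        cohort.samples, condition_on_drb1=config.condition_on_drb1
    )
    y = cohort.y
    dcols = cohort.dosages

    if scan is None:
        sub = Cohort(
            dcols[candidates], cohort.samples,
            cohort.markers[cohort.markers["id"].isin(candidates)],
        )
        scan = scan_markers(sub, "conditioned" if config.condition_on_drb1 else "base")
    pvals = scan.set_index("marker_id")["p_value"]
    tab = _candidate_table(cohort, candidates, pvals)

    audit: list[dict] = []

    def log(iteration, marker, kind, stat, p, action):
        audit.append(
            {
                "iteration": iteration,
                "marker": marker,
                "test": kind,
                "statistic": stat,
                "p_value": p,
                "action": action,
            }
        )

    def fit_dev(markers):
        X = np.column_stack([X_cov] + [dcols[m].to_numpy() for m in markers]) \
            if markers else X_cov
        return fit_logistic(X, y, check_rank=False).deviance

    # -- step 1: sequential entry of the window-thinned seeds
    seeds = seed_set(tab, seed_p=config.seed_p, window_bp=config.window_bp)
    accepted: list[str] = []
    dev_prev = fit_dev([])
    for m in seeds:
        dev_new = fit_dev(accepted + [m])
        stat = max(dev_prev - dev_new, 0.0)
        p = float(stats.chi2.sf(stat, 1))
        if p < config.retain_p:
            accepted.append(m)
            dev_prev = dev_new
            log(0, m, "sequential", stat, p, "seeded")
        else:
            log(0, m, "sequential", stat, p, "dropped_seed")

    pool = [m for m in candidates if m not in accepted]
    converged = False
    it = 0
    seen_states: set[tuple] = set()
    for it in range(1, config.max_iterations + 1):
        # -- step 2: partial-test expansion of all remaining candidates
        if not pool:
            converged = True
            break
        X_acc = np.column_stack([X_cov] + [dcols[m].to_numpy() for m in accepted]) \
            if accepted else X_cov
        dev_acc = fit_logistic(X_acc, y, check_rank=False).deviance
        D = dcols[pool].to_numpy(dtype=float)
        _, _, dev_m, _ = batched_marker_fits(X_acc, D, y)
        stat_m = np.maximum(dev_acc - dev_m, 0.0)
        p_m = stats.chi2.sf(stat_m, 1)
        exp_tab = pd.DataFrame(
            {"marker_id": pool, "p_value": p_m}
        ).merge(tab[["marker_id", "chrom", "pos"]], on="marker_id")
        hits = exp_tab[exp_tab["p_value"] < config.expand_p]
        for _, r in exp_tab.iterrows():
            action = "expanded" if r["p_value"] < config.expand_p else "not_expanded"
            if action == "expanded":
                log(it, r["marker_id"], "partial", np.nan, r["p_value"], action)
        if hits.empty:
            converged = True
            break
        new = _order_key(hits)

        # -- step 3: joint re-test of accepted ∪ new by both tests
        combined = accepted + new
        # sequential pass in entry order
        seq_fail = set()
        dev_prev = fit_dev([])
        kept_seq: list[str] = []
        for m in combined:
            dev_new = fit_dev(kept_seq + [m])
            stat = max(dev_prev - dev_new, 0.0)
            p = float(stats.chi2.sf(stat, 1))
            if p >= config.retain_p:
                seq_fail.add(m)
                log(it, m, "sequential", stat, p, "failed_sequential")
            else:
                kept_seq.append(m)
                dev_prev = dev_new
        # partial pass: iterative worst-first prune so that of two markers
        # in mutual LD (both individually non-significant given the other)
        # only one is removed and the survivor is re-tested
        kept = list(kept_seq)
        while kept:
            dev_full = fit_dev(kept)
            worst, worst_stat, worst_p = None, np.nan, -1.0
            for m in kept:
                dev_wo = fit_dev([x for x in kept if x != m])
                stat = max(dev_wo - dev_full, 0.0)
                p = float(stats.chi2.sf(stat, 1))
                if p > worst_p:
                    worst, worst_stat, worst_p = m, stat, p
            if worst_p >= config.retain_p:
                kept.remove(worst)
                log(it, worst, "partial", worst_stat, worst_p, "failed_partial")
            else:
                break
        for m in kept:
            log(it, m, "partial", np.nan, np.nan, "retained")
        accepted = kept
        pool = [m for m in candidates if m not in accepted]

        state_key = tuple(sorted(accepted))
        if state_key in seen_states:
            log(it, "", "cycle", np.nan, np.nan, "cycle_detected")
            converged = False
            break
        seen_states.add(state_key)
    else:
        log(config.max_iterations, "", "cycle", np.nan, np.nan, "max_iterations")

    # -- final audit: every member must pass the partial test jointly
    while len(accepted) > 0:
        dev_full = fit_dev(accepted)
        worst, worst_p = None, -1.0
        for m in accepted:
            dev_wo = fit_dev([x for x in accepted if x != m])
            p = float(stats.chi2.sf(max(dev_wo - dev_full, 0.0), 1))
            if p > worst_p:
                worst, worst_p = m, p
        if worst_p >= config.retain_p:
            accepted.remove(worst)
            log(it, worst, "partial", np.nan, worst_p, "final_prune")
        else:
            break

    return ScreenState(
        accepted=accepted,
        candidates=[m for m in candidates if m not in accepted],
        iteration=it,
        audit_log=pd.DataFrame(
            audit,
            columns=["iteration", "marker", "test", "statistic", "p_value", "action"],
        ),
        converged=converged,
    )
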