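"""Synthetic cohort generation and cohort file I/O.

The generator emulates the statistical structure of an imputed
case-control GWAS panel:

* fractional genotype dosages with a tri-modal distribution peaked at
  0/1/2 and inter-peak mass from imputation uncertainty;
* haplotype-block LD with a controllable within-block correlation;
* one major-effect HLA-like locus tracked by a tag SNP, with a carrier
  frequency around 25% in controls that rises past 50% in cases;
* many weak risk alleles (odds ratios ~1.1-1.6, protective or risk);
* gender imbalance between cases and controls and a multi-center
  stratum structure with center-specific case rates.

Cohorts are written as plain TSV: a samples × markers dosage matrix, a
sample table (sample_id, status, center, gender, drb1_status) and a
marker map (id, chrom, pos, allele1, allele2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, CohortTruth, MARKER_COLUMNS, SAMPLE_COLUMNS

__all__ = [
    "LdBlockSpec",
    "DiseaseModelSpec",
    "simulate_dosages",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "load_preset",
]

#: Default id of the synthetic tag SNP tracking the major HLA locus
#: (named after the field's canonical DRB1*15:01 tag marker).
TAG_MARKER = "rs3135388"


@dataclass
class LdBlockSpec:
    """Haplotype-block layout of the simulated marker panel.

    ``within_block_r`` is the haplotype copy probability of the block
    copula; the resulting pairwise *genotype* correlation within a block
    is approximately ``within_block_r**2`` (exact for equal allele
    frequencies).  Markers in different blocks are independent.
    """

    n_markers_per_block: int = 10
    n_blocks: int = 50
    within_block_r: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0.01 <= low <= high <= 0.5")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must be in [0, 1)")

    @property
    def n_markers(self) -> int:
        return self.n_markers_per_block * self.n_blocks


@dataclass
class DiseaseModelSpec:
    """Generative logistic disease model.

    All effects are odds ratios; the per-sample case probability is
    sigmoid(intercept + center offset + log(gender_or)·female
    + log(major_locus_or)·carrier + Σ log(OR_j)·dosage_j).
    Causal markers are drawn one per LD block so that the planted signals
    are mutually independent; each causal OR magnitude is uniform in
    ``causal_or_range`` and flipped to protective with probability
    ``protective_fraction``.
    """

    intercept: float = -2.0
    major_locus_or: float = 3.4
    major_control_freq: float = 0.25
    n_causal: int = 20
    causal_or_range: tuple[float, float] = (1.1, 1.6)
    gender_or: float = 2.6
    center_effects: dict[str, float] = field(default_factory=lambda: {"C1": 0.0})
    imputation_quality: float = 0.97
    protective_fraction: float = 0.5

    def __post_init__(self):
        if self.major_locus_or <= 0 or self.gender_or <= 0:
            raise ValueError("odds ratios must be positive")
        lo, hi = self.causal_or_range
        if not (0 < lo <= hi):
            raise ValueError("causal_or_range must be positive and ordered")
        if not (0 < self.imputation_quality <= 1):
            raise ValueError("imputation_quality must be in (0, 1]")


def _marker_map(blocks: LdBlockSpec) -> pd.DataFrame:
    """Lay blocks on autosomes: one block per megabase, 5 kb marker spacing."""
    rows = []
    alleles = np.array(["A", "C", "G", "T"])
    for b in range(blocks.n_blocks):
        chrom = (b % 22) + 1
        base = (b // 22 + 1) * 1_000_000
        for j in range(blocks.n_markers_per_block):
            rows.append(
                {
                    "id": f"rsb{b:04d}m{j:02d}",
                    "chrom": chrom,
                    "pos": base + j * 5_000,
                    "allele1": alleles[(b + j) % 4],
                    "allele2": alleles[(b + j + 1) % 4],
                    "block": b,
                }
            )
    return pd.DataFrame(rows)


def _smear(genotypes: np.ndarray, quality: float, rng: np.random.Generator) -> np.ndarray:
    """Blend hard genotypes toward an adjacent class with prob 1 - quality.

    The blend weight is Beta(1.2, 5) — mass near the true class — which
    reproduces a visibly tri-modal fractional-dosage histogram at the
    default quality of 0.97.
    """
    if quality >= 1.0:
        return genotypes.astype(float)
    g = genotypes.astype(float)
    hit = rng.random(g.shape) < (1.0 - quality)
    direction = np.where(g == 0, 1.0, np.where(g == 2, -1.0, rng.choice([-1.0, 1.0], size=g.shape)))
    b = rng.beta(1.2, 5.0, size=g.shape)
    return np.where(hit, g + direction * b, g)


def simulate_dosages(
    blocks: LdBlockSpec,
    n_samples: int,
    seed: int | np.random.Generator,
    *,
    imputation_quality: float = 1.0,
    mafs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate LD-blocked fractional dosages.

    Haplotypes within a block share a latent uniform: each marker copies
    the block latent with probability ``within_block_r`` and draws fresh
    otherwise, then thresholds at its allele frequency.  Marginal allele
    frequencies are exact; pairwise genotype correlation within a block
    is ≈ ``within_block_r**2``.  Returns ``(dosages, marker_map)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = _marker_map(blocks)
    if mafs is None:
        lo, hi = blocks.maf_range
        mafs = rng.uniform(lo, hi, size=blocks.n_markers)
    mafs = np.asarray(mafs, dtype=float)

    L = blocks.n_markers_per_block
    r = blocks.within_block_r
    geno = np.empty((n_samples, blocks.n_markers), dtype=np.int8)
    for b in range(blocks.n_blocks):
        m = mafs[b * L : (b + 1) * L]
        shared = rng.random((n_samples, 2, 1))
        fresh = rng.random((n_samples, 2, L))
        copy = rng.random((n_samples, 2, L)) < r
        u = np.where(copy, shared, fresh)
        geno[:, b * L : (b + 1) * L] = (u < m[None, None, :]).sum(axis=1)

    dosage = _smear(geno, imputation_quality, rng)
    markers = markers.assign(maf=mafs)
    df = pd.DataFrame(
        dosage, columns=markers["id"].tolist(),
        index=pd.Index([f"S{i:06d}" for i in range(n_samples)], name="sample_id"),
    )
    return df, markers


def _tag_marker_column(
    n_samples: int,
    carrier_freq: float,
    quality: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the HLA tag SNP; returns (dosage, true carrier indicator)."""
    p = 1.0 - np.sqrt(1.0 - carrier_freq)  # allele freq giving the carrier freq
    geno = (rng.random((n_samples, 2)) < p).sum(axis=1).astype(np.int8)
    return _smear(geno, quality, rng), (geno >= 1).astype(int)


def simulate_phenotypes(
    dosages: pd.DataFrame,
    model: DiseaseModelSpec,
    seed: int | np.random.Generator,
    *,
    markers: pd.DataFrame | None = None,
    center_probs: dict[str, float] | None = None,
    drb1_carrier: np.ndarray | None = None,
    center_assign: np.ndarray | None = None,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw case/control status from the generative logistic model.

    Causal markers are sampled one per LD block (requiring a marker map
    with a ``block`` column; otherwise uniformly without replacement).
    Returns the sample table and the ground truth (causal ids, log-ORs
    and per-sample liability).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_int = int(rng.integers(2**31)) if not isinstance(seed, int) else seed
    n = len(dosages)

    centers = list(model.center_effects)
    if center_assign is not None:
        center = np.asarray(center_assign, dtype=object)
    else:
        if center_probs is None:
            probs = np.full(len(centers), 1.0 / len(centers))
        else:
            probs = np.array([center_probs[c] for c in centers], dtype=float)
            probs = probs / probs.sum()
        center = rng.choice(np.array(centers, dtype=object), size=n, p=probs)
    female = rng.random(n) < 0.5

    if drb1_carrier is None:
        if TAG_MARKER in dosages.columns:
            drb1_carrier = (np.rint(dosages[TAG_MARKER].to_numpy()) >= 1).astype(int)
        else:
            drb1_carrier = np.zeros(n, dtype=int)

    candidates = [c for c in dosages.columns if c != TAG_MARKER]
    if model.n_causal > len(candidates):
        raise ValueError("n_causal exceeds the number of available markers")
    if markers is not None and "block" in markers.columns:
        blocks = markers.set_index("id")["block"]
        block_ids = sorted(set(blocks[c] for c in candidates))
        if model.n_causal > len(block_ids):
            raise ValueError("n_causal exceeds the number of LD blocks")
        chosen_blocks = rng.choice(block_ids, size=model.n_causal, replace=False)
        causal = []
        for b in chosen_blocks:
            members = [c for c in candidates if blocks[c] == b]
            causal.append(members[int(rng.integers(len(members)))])
    else:
        causal = list(rng.choice(candidates, size=model.n_causal, replace=False))

    lo, hi = model.causal_or_range
    mags = rng.uniform(np.log(lo), np.log(hi), size=model.n_causal)
    signs = np.where(rng.random(model.n_causal) < model.protective_fraction, -1.0, 1.0)
    log_ors = mags * signs

    eta = np.full(n, model.intercept)
    eta += np.array([model.center_effects[c] for c in center])
    eta += np.log(model.gender_or) * female
    eta += np.log(model.major_locus_or) * drb1_carrier
    if causal:
        D = dosages[causal].to_numpy()
        # centre the polygenic term at the mean genotype so the intercept
        # pins baseline prevalence regardless of the signed effect draw
        eta += (D - D.mean(axis=0)) @ log_ors
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(int)

    samples = pd.DataFrame(
        {
            "sample_id": dosages.index,
            "status": y,
            "center": center,
            "gender": np.where(female, "F", "M"),
            "drb1_status": drb1_carrier,
        }
    ).reset_index(drop=True)
    truth = CohortTruth(
        causal_marker_ids=list(causal),
        causal_log_ors=dict(zip(causal, log_ors.tolist())),
        liability=eta,
        seed=seed_int,
    )
    return samples, truth


def simulate_cohort(
    blocks: LdBlockSpec,
    disease: DiseaseModelSpec,
    *,
    n_samples: int | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    seed: int = 0,
    center_probs: dict[str, float] | None = None,
    center_maf_shift: float = 0.0,
    include_tag: bool = True,
    oversample: float = 2.5,
) -> Cohort:
    """End-to-end cohort simulation.

    Either ``n_samples`` (population sampling) or ``n_cases`` and
    ``n_controls`` (case-control ascertainment from an oversampled
    population) must be given.  ``center_maf_shift`` adds center-specific
    allele-frequency offsets (spread ± the given value across centers),
    which together with center case-rate offsets produces the stratification
    confounding that inflates a scan run without the center covariate.
    """
    if (n_samples is None) == (n_cases is None):
        raise ValueError("give either n_samples or (n_cases, n_controls)")
    ascertain = n_samples is None
    if ascertain:
        if n_controls is None:
            raise ValueError("n_controls required with n_cases")
        n_pop = int(np.ceil((n_cases + n_controls) * oversample))
    else:
        n_pop = n_samples

    rng = np.random.default_rng(seed)
    lo, hi = blocks.maf_range
    mafs = rng.uniform(lo, hi, size=blocks.n_markers)

    centers = list(disease.center_effects)
    if center_maf_shift == 0.0:
        dosages, markers = simulate_dosages(
            blocks, n_pop, rng, imputation_quality=disease.imputation_quality, mafs=mafs
        )
        center_assign = None
    else:
        # generate per-center with shifted allele frequencies
        if center_probs is None:
            probs = np.full(len(centers), 1.0 / len(centers))
        else:
            probs = np.array([center_probs[c] for c in centers], dtype=float)
            probs = probs / probs.sum()
        center_assign = rng.choice(np.array(centers, dtype=object), size=n_pop, p=probs)
        offsets = np.linspace(-center_maf_shift, center_maf_shift, len(centers))
        parts = np.empty((n_pop, blocks.n_markers))
        markers = None
        for c, off in zip(centers, offsets):
            idx = np.flatnonzero(center_assign == c)
            if idx.size == 0:
                continue
            m_c = np.clip(mafs + off, 0.01, 0.99)
            d_c, markers = simulate_dosages(
                blocks, idx.size, rng,
                imputation_quality=disease.imputation_quality, mafs=m_c,
            )
            parts[idx] = d_c.to_numpy()
        dosages = pd.DataFrame(
            parts, columns=markers["id"].tolist(),
            index=pd.Index([f"S{i:06d}" for i in range(n_pop)], name="sample_id"),
        )

    carrier = None
    if include_tag:
        tag_dos, carrier = _tag_marker_column(
            n_pop, disease.major_control_freq, disease.imputation_quality, rng
        )
        dosages[TAG_MARKER] = tag_dos
        markers = pd.concat(
            [
                markers,
                pd.DataFrame(
                    [{
                        "id": TAG_MARKER, "chrom": 6, "pos": 32_400_000,
                        "allele1": "C", "allele2": "T", "block": -1,
                        "maf": 1.0 - np.sqrt(1.0 - disease.major_control_freq),
                    }]
                ),
            ],
            ignore_index=True,
        )

    samples, truth = simulate_phenotypes(
        dosages, disease, rng, markers=markers,
        center_probs=center_probs, drb1_carrier=carrier,
        center_assign=center_assign,
    )

    cohort = Cohort(dosages, samples, markers, truth)
    if not ascertain:
        return cohort

    y = samples["status"].to_numpy()
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if cases.size < n_cases or controls.size < n_controls:
        raise ValueError(
            f"population of {n_pop} yielded {cases.size} cases / "
            f"{controls.size} controls; need {n_cases}/{n_controls}. "
            "Adjust the disease-model intercept (or raise `oversample`)."
        )
    keep = np.sort(
        np.concatenate([
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=n_controls, replace=False),
        ])
    )
    return cohort.subset(keep)


# ---------------------------------------------------------------- file I/O

def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write dosages.tsv, samples.tsv and markers.tsv under ``path``.

    Dosages are written in shortest round-trip float representation, so
    ``read_cohort(write_cohort(c))`` reproduces the values bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.dosages.to_csv(path / "dosages.tsv", sep="\t")
    cohort.samples[SAMPLE_COLUMNS].to_csv(path / "samples.tsv", sep="\t", index=False)
    cols = [c for c in MARKER_COLUMNS + ["block", "maf"] if c in cohort.markers.columns]
    cohort.markers[cols].to_csv(path / "markers.tsv", sep="\t", index=False)
    return path


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    try:
        dosages = pd.read_csv(
            path / "dosages.tsv", sep="\t", index_col=0,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed dosage file {path / 'dosages.tsv'}: {exc}") from exc
    arr = dosages.to_numpy()
    try:
        arr = arr.astype(float)
    except (TypeError, ValueError):
        bad = ~dosages.map(np.isreal).to_numpy()
        rows = np.flatnonzero(bad.any(axis=1))
        raise ValueError(
            f"non-numeric dosage at line {rows[0] + 2} of dosages.tsv"
        ) from None
    dosages = pd.DataFrame(arr, index=dosages.index, columns=dosages.columns)
    out_of_range = (arr < 0) | (arr > 2)
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range.any(axis=1))[0]) + 2
        raise ValueError(f"dosage outside [0, 2] at line {line} of dosages.tsv")
    samples = pd.read_csv(path / "samples.tsv", sep="\t", float_precision="round_trip")
    markers = pd.read_csv(path / "markers.tsv", sep="\t", float_precision="round_trip")
    return Cohort(dosages, samples, markers)


def load_preset(name: str = "paper_like") -> dict:
    """Load a named cohort preset (LD spec, disease model, sample sizes)."""
    ref = importlib.resources.files("cumulrisk.data") / f"{name}.yaml"
    with ref.open() as fh:
        raw = yaml.safe_load(fh)
    raw["blocks"] = LdBlockSpec(
        n_markers_per_block=raw["blocks"]["n_markers_per_block"],
        n_blocks=raw["blocks"]["n_blocks"],
        within_block_r=raw["blocks"]["within_block_r"],
        maf_range=tuple(raw["blocks"]["maf_range"]),
    )
    d = raw["disease"]
    raw["disease"] = DiseaseModelSpec(
        intercept=d["intercept"],
        major_locus_or=d["major_locus_or"],
        major_control_freq=d["major_control_freq"],
        n_causal=d["n_causal"],
        causal_or_range=tuple(d["causal_or_range"]),
        gender_or=d["gender_or"],
        center_effects=d["center_effects"],
        imputation_quality=d["imputation_quality"],
        protective_fraction=d.get("protective_fraction", 0.5),
    )
    return raw
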