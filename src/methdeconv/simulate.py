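"""Synthetic data generation: purified-cell studies, mixtures and noise.

Everything the toolkit needs for testing is generated here, emulating the
statistical structure of purified-leukocyte methylation studies:

* CpG baselines are bimodal (mostly near 0 or 1, a minority intermediate),
  as methylation arrays are;
* each cell type owns a set of planted cell-type-specific DMCs with a large
  beta difference against every other type;
* replicate noise and a between-study "lab shift" are Gaussian on the
  M-value scale, matching how array noise behaves;
* mixture weights are Uniform(0,1) draws normalised to the unit simplex and
  mixing is linear in beta space (cell populations combine linearly in
  methylation fraction);
* a synthetic genome assigns every CpG a position, with DNase-hypersensitive
  intervals enriched over planted DMCs of the owning cell type.

A matched EWAS generator builds mixture cohorts with an ordinal phenotype,
optional direct CpG effects and optional cell-composition confounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_EPS,
    BetaMatrix,
    CpGMap,
    DHSCatalog,
    ReferenceMatrix,
    beta_to_m_array,
    m_to_beta_array,
)
from .refbuild import PurifiedDataset

#: Background probability that a non-marker CpG falls in some cell type's DHS.
DHS_BACKGROUND_RATE = 0.1


@dataclass
class SynthConfig:
    """Study-design parameters of the synthetic purified-cell generator.

    Defaults mirror a blood-like design: 7 cell types with 6 replicates
    each, 50 planted markers per type with beta differences of 0.5-0.9,
    replicate noise of 0.15 SD and a cross-study lab shift of 0.3 SD (both
    on the M-value scale, where array noise is approximately Gaussian).
    """

    n_cell_types: int = 7
    n_cpgs: int = 2000
    n_dmcs_per_type: int = 50
    delta_range: tuple[float, float] = (0.5, 0.9)
    replicate_sd: float = 0.15
    n_replicates: int = 6
    study_shift_sd: float = 0.3
    dhs_enrichment: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_cpgs, self.n_dmcs_per_type, self.n_replicates) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.delta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("delta_range must lie inside (0, 1)")
        if self.n_dmcs_per_type * self.n_cell_types > self.n_cpgs:
            raise ValueError(
                "n_dmcs_per_type * n_cell_types exceeds the number of CpGs"
            )


@dataclass
class SynthPurifiedResult:
    """Train/test purified studies plus the planted ground truth and genome."""

    train: PurifiedDataset
    test: PurifiedDataset
    ground_truth: pd.DataFrame  # cpg (index), cell_type, delta, baseline, target_mean
    cpg_map: CpGMap
    dhs: DHSCatalog
    config: SynthConfig


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_simplex_weights(
    n_samples: int, cell_types: Sequence[str], seed: int | np.random.Generator
) -> "MixtureTruth":
    """True mixing weights: C Uniform(0,1) draws per sample, divided by their sum.

    (This is the normalised-uniform recipe, not a flat Dirichlet on the
    simplex; the two differ for C > 2.)
    """
    if n_samples < 1 or len(cell_types) < 1:
        raise ValueError("need n_samples >= 1 and at least one cell type")
    rng = _rng(seed)
    u = rng.uniform(size=(n_samples, len(cell_types)))
    w = u / u.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(
        w,
        index=[f"mix{i + 1}" for i in range(n_samples)],
        columns=list(cell_types),
    )
    return MixtureTruth(frame)


@dataclass
class MixtureTruth:
    """Sample x cell-type matrix of true simulated weights on the unit simplex."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("true weights must be non-negative")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-12:
            raise ValueError("true weight rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def make_mixtures(profiles: ReferenceMatrix, truth: MixtureTruth) -> BetaMatrix:
    """Beta-space linear mixtures of the per-cell-type profiles."""
    if list(profiles.cell_types) != list(truth.cell_types):
        raise ValueError(
            f"cell types of profiles {profiles.cell_types} and truth "
            f"{truth.cell_types} do not match"
        )
    mixed = profiles.values @ truth.values.T
    n_clipped = int(((mixed < 0) | (mixed > 1)).sum())
    if n_clipped:
        import logging

        logging.getLogger(__name__).warning(
            "clipped %d mixture values into [0, 1]", n_clipped
        )
        mixed = np.clip(mixed, 0.0, 1.0)
    return BetaMatrix(
        pd.DataFrame(mixed, index=profiles.cpg_ids, columns=truth.sample_ids)
    )


def add_mspace_noise(
    beta: BetaMatrix,
    sd: float,
    seed: int | np.random.Generator,
    eps: float = DEFAULT_EPS,
) -> BetaMatrix:
    """Add i.i.d. Gaussian noise of standard deviation ``sd`` on the M-value scale.

    Values are clipped into [eps, 1-eps], transformed to M, perturbed, and
    transformed back; ``sd=0`` reproduces the input (up to the clipping
    round trip at the boundaries).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _rng(seed)
    m = beta_to_m_array(beta.values, eps=eps)
    if sd > 0:
        m = m + rng.normal(0.0, sd, size=m.shape)
    noisy = m_to_beta_array(m)
    return BetaMatrix(
        pd.DataFrame(noisy, index=beta.data.index, columns=beta.data.columns)
    )


def _bimodal_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    kind = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    low = rng.uniform(0.02, 0.10, size=n)
    high = rng.uniform(0.90, 0.98, size=n)
    mid = rng.uniform(0.20, 0.80, size=n)
    return np.where(kind == 0, low, np.where(kind == 1, high, mid))


def _replicate_study(
    means: np.ndarray,
    cell_types: list[str],
    cpg_ids: list[str],
    n_replicates: int,
    replicate_sd: float,
    study_tag: str,
    rng: np.random.Generator,
) -> PurifiedDataset:
    m_means = beta_to_m_array(means)
    frames = {}
    labels: dict[str, str] = {}
    for c, cell_type in enumerate(cell_types):
        for r in range(n_replicates):
            sample = f"{study_tag}_{cell_type}_r{r + 1}"
            noise = (
                rng.normal(0.0, replicate_sd, size=m_means.shape[0])
                if replicate_sd > 0
                else 0.0
            )
            frames[sample] = m_to_beta_array(m_means[:, c] + noise)
            labels[sample] = cell_type
    beta = BetaMatrix(pd.DataFrame(frames, index=cpg_ids))
    return PurifiedDataset(beta, labels)


def synth_purified_dataset(config: SynthConfig) -> SynthPurifiedResult:
    """Generate matched train/test purified-cell studies with planted DMCs.

    Each cell type receives ``n_dmcs_per_type`` CpGs whose mean beta differs
    from every other type by a draw from ``delta_range`` (direction chosen
    to stay inside [0.01, 0.99]). The test study shares the underlying
    type means but adds a per-CpG M-space lab shift (``study_shift_sd``)
    common to its replicates, so the two studies are independent in the way
    two labs' datasets are. Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    C, G = config.n_cell_types, config.n_cpgs
    cell_types = [f"CT{c + 1}" for c in range(C)]
    cpg_ids = [f"cg{i:07d}" for i in range(G)]

    baselines = _bimodal_baselines(rng, G)
    means = np.tile(baselines[:, None], (1, C))

    planted = rng.choice(G, size=C * config.n_dmcs_per_type, replace=False)
    gt_rows = []
    lo, hi = config.delta_range
    for c, cell_type in enumerate(cell_types):
        idx = planted[c * config.n_dmcs_per_type : (c + 1) * config.n_dmcs_per_type]
        for g in idx:
            delta = rng.uniform(lo, hi)
            up_ok = baselines[g] + delta <= 0.99
            down_ok = baselines[g] - delta >= 0.01
            if up_ok and down_ok:
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
            elif up_ok:
                sign = 1.0
            else:
                sign = -1.0
            target = baselines[g] + sign * delta
            means[g, c] = target
            gt_rows.append(
                {
                    "cpg": cpg_ids[g],
                    "cell_type": cell_type,
                    "delta": sign * delta,
                    "baseline": baselines[g],
                    "target_mean": target,
                }
            )
    ground_truth = pd.DataFrame(gt_rows).set_index("cpg")

    train = _replicate_study(
        means, cell_types, cpg_ids, config.n_replicates, config.replicate_sd, "train", rng
    )
    shift = (
        rng.normal(0.0, config.study_shift_sd, size=G)
        if config.study_shift_sd > 0
        else np.zeros(G)
    )
    test_means = m_to_beta_array(beta_to_m_array(means) + shift[:, None])
    if config.replicate_sd == 0 and config.study_shift_sd == 0:
        test_means = means  # degenerate-noise case: studies coincide exactly
    test = _replicate_study(
        test_means, cell_types, cpg_ids, config.n_replicates, config.replicate_sd, "test", rng
    )

    positions = 1 + 1000 * np.arange(G)
    cpg_map = CpGMap(
        pd.DataFrame({"chrom": "chr1", "pos": positions}, index=cpg_ids)
    )
    intervals: dict[str, list[tuple[str, int, int]]] = {ct: [] for ct in cell_types}
    planted_of = ground_truth["cell_type"].to_dict()
    for g, cpg in enumerate(cpg_ids):
        pos0 = int(positions[g]) - 1
        iv = ("chr1", max(0, pos0 - 50), pos0 + 50)
        owner = planted_of.get(cpg)
        if owner is not None and rng.uniform() < config.dhs_enrichment:
            intervals[owner].append(iv)
        elif rng.uniform() < DHS_BACKGROUND_RATE:
            intervals[cell_types[rng.integers(C)]].append(iv)
    dhs = DHSCatalog(intervals)

    return SynthPurifiedResult(train, test, ground_truth, cpg_map, dhs, config)


# ---------------------------------------------------------------------------
# EWAS cohorts


@dataclass
class EWASSimResult:
    """A synthetic mixture cohort with phenotype, truth and the matched reference."""

    beta: BetaMatrix
    pheno: pd.DataFrame  # index: sample; column "smoking" in {0, 1, 2}
    fractions_true: MixtureTruth
    reference: ReferenceMatrix
    effect_cpgs: list[str]
    purified: SynthPurifiedResult


def synth_ewas_dataset(
    n_samples: int = 150,
    n_effect_cpgs: int = 20,
    effect_size: float = 0.05,
    confound_strength: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    synth: SynthConfig | None = None,
) -> EWASSimResult:
    """Generate a whole-cohort EWAS dataset from synthetic purified studies.

    Samples are mixtures of the test-study mean profiles with an ordinal
    phenotype (0/1/2 in equal thirds). ``effect_size`` beta units per
    phenotype unit are added to ``n_effect_cpgs`` background CpGs (direct
    effects); ``confound_strength`` shifts the first cell type's true
    fraction with the phenotype, creating composition confounding. A
    reference is built from the *train* study so reference and cohort are
    study-independent.
    """
    from .refbuild import build_reference_pipeline

    rng = np.random.default_rng(seed)
    cfg = synth or SynthConfig(seed=int(rng.integers(2**31 - 1)))
    sim = synth_purified_dataset(cfg)
    reference, _ = build_reference_pipeline(sim.train, mode="fdr")

    cell_types = sim.train.cell_types
    phenotype = np.tile([0, 1, 2], n_samples // 3 + 1)[:n_samples]
    rng.shuffle(phenotype)

    u = rng.uniform(size=(n_samples, len(cell_types)))
    u[:, 0] += confound_strength * phenotype
    w = u / u.sum(axis=1, keepdims=True)
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    truth = MixtureTruth(pd.DataFrame(w, index=sample_ids, columns=cell_types))

    profiles = sim.test.mean_profiles()
    mixed = profiles.values @ w.T

    marker_cpgs = set(reference.cpg_ids) | set(sim.ground_truth.index)
    background = [c for c in profiles.cpg_ids if c not in marker_cpgs]
    effect_cpgs = list(
        rng.choice(background, size=min(n_effect_cpgs, len(background)), replace=False)
    )
    cpg_index = {c: i for i, c in enumerate(profiles.cpg_ids)}
    for cpg in effect_cpgs:
        mixed[cpg_index[cpg], :] += effect_size * phenotype
    mixed = np.clip(mixed, 0.0, 1.0)

    beta = BetaMatrix(pd.DataFrame(mixed, index=profiles.cpg_ids, columns=sample_ids))
    if noise_sd > 0:
        beta = add_mspace_noise(beta, noise_sd, rng)
    pheno = pd.DataFrame({"smoking": phenotype.astype(int)}, index=sample_ids)
    return EWASSimResult(beta, pheno, truth, reference, effect_cpgs, sim)
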