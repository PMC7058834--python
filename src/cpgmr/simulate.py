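"""Synthetic individual-level data under configurable causal DAGs.

Generates genotypes and phenotypes for three traits — CpG methylation (M),
lifetime smoking (S) and lung function (Y) — under a chosen causal structure,
splits individuals into two non-overlapping samples mirroring the two-sample
MR design (a small methylation cohort versus a large GWAS cohort), and emits
per-SNP regression summary statistics plus a ground-truth record.  A separate
generator produces colocalization regions with labelled causal-variant
sharing.

All phenotypes are standardized to unit variance so effect sizes are in SD
units.  With the default ``noise_sd=None`` the residual noise variance is set
analytically from the variance bookkeeping of the linear DAG, so the recorded
true effects are exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .coloc import RegionDataset, enumerate_configurations
from .sumstats import AssociationRecord, LDMatrix

DAGS = ("M_to_Y", "M_to_S_to_Y", "S_to_M_to_Y", "pleiotropy", "null", "confounded")

_TRAIT_META = {
    "M": ("cg_sim", "methylation"),
    "S": ("smoking", "smoking"),
    "Y": ("fev1", "lung_function"),
}
_REGION_TRAITS = ("methylation", "expression", "lung_function")


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-sample design.

    Defaults mirror the real setting at desk scale: a small methylation
    sample (n1=846), a large outcome GWAS (n2=50 000), a few strong cis-mQTL
    instruments (per-SNP r^2 2%-30%), polygenic smoking and lung-function
    instruments with small per-SNP r^2, and effect sizes on the SD scale of
    the reported CpG-FEV1 estimates (total effect -0.1, ~15% of it mediated).
    """

    seed: int = 0
    n_sample1: int = 846
    n_sample2: int = 50_000
    n_instruments_exposure: int = 3
    n_instruments_mediator: int = 20
    n_instruments_outcome: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    dag: str = "M_to_Y"
    theta1: float = 0.1
    theta2: float = -0.15
    theta3: float = -0.085
    r2_exposure_range: tuple[float, float] = (0.029, 0.313)
    r2_mediator_range: tuple[float, float] = (5e-4, 2e-3)
    r2_outcome_range: tuple[float, float] = (5e-4, 2e-3)
    pleiotropy_fraction: float = 0.3
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    confounder_sd: float = 0.1
    noise_sd: float | None = None
    # colocalization-region settings
    n_region_variants: int = 200
    region_ld_rho: float = 0.5
    region_sample_sizes: tuple[int, int, int] = (846, 5000, 20_000)
    region_r2: tuple[float, float, float] = (0.04, 0.04, 0.006)
    region_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.dag not in DAGS:
            raise ValueError(f"unknown dag {self.dag!r}; choose from {DAGS}")
        for rng_ in (self.maf_range, self.region_maf_range):
            if not (0.01 <= rng_[0] <= rng_[1] <= 0.5):
                raise ValueError(f"maf range must lie within [0.01, 0.5]: {rng_}")
        if not -1.0 < self.ld_rho < 1.0 or not -1.0 < self.region_ld_rho < 1.0:
            raise ValueError("AR(1) correlations must lie in (-1, 1)")
        if self.n_sample1 < 4 or self.n_sample2 < 4:
            raise ValueError("samples must have at least 4 individuals")

    @property
    def n_snps(self) -> int:
        return (
            self.n_instruments_exposure
            + self.n_instruments_mediator
            + self.n_instruments_outcome
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthRecord:
    """Ground truth stored alongside every emitted dataset."""

    dag: str
    theta1: float
    theta2: float
    theta3: float
    total: float
    proportion_mediated: float | None
    seed: int
    instrument_effects: dict[str, list[float]] = field(default_factory=dict)
    pleiotropy_alpha: list[float] | None = None
    mafs: list[float] = field(default_factory=list)
    scenario: str | None = None
    causal_indices: dict[str, int | None] | None = None

    def __post_init__(self) -> None:
        expected = self.theta3 + self.theta1 * self.theta2
        if self.total != expected:
            raise ValueError("total must equal theta3 + theta1*theta2 exactly")


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(truth), fh, sort_keys=False)


def read_truth(path: str | Path) -> TruthRecord:
    with open(path) as fh:
        return TruthRecord(**yaml.safe_load(fh))


def _dosages(
    rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """Biallelic dosages in {0,1,2}; AR(1) latent-Gaussian LD within the block."""
    L = len(mafs)
    if rho == 0.0:
        return rng.binomial(2, mafs, size=(n, L)).astype(float)
    thr = stats.norm.ppf(mafs)
    g = np.zeros((n, L))
    scale = np.sqrt(1.0 - rho**2)
    for _ in range(2):
        eps = rng.standard_normal((n, L))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for j in range(1, L):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        g += z < thr
    return g


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, LDMatrix, np.ndarray]:
    """Genotypes for both samples plus the empirical LD matrix.

    Returns dosages of shape (n_sample1 + n_sample2, n_snps), the empirical
    correlation matrix of the dosages, and the generating allele frequencies.
    """
    rng = config.rng() if rng is None else rng
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    g = _dosages(rng, config.n_sample1 + config.n_sample2, mafs, config.ld_rho)
    if config.n_snps == 1:
        rho = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(g, rowvar=False)
        rho = np.nan_to_num(rho, nan=0.0)
        np.fill_diagonal(rho, 1.0)
        rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    snp_ids = tuple(f"rs{j + 1}" for j in range(config.n_snps))
    return g, LDMatrix(snp_ids, rho), mafs


def _gamma_from_r2(r2: np.ndarray, mafs: np.ndarray) -> np.ndarray:
    """Per-allele effect giving each SNP its target variance explained."""
    return np.sqrt(r2 / (2.0 * mafs * (1.0 - mafs)))


class _TraitBuilder:
    """Linear-DAG composer with exact variance bookkeeping.

    Every trait is linear in independent base sources (centered genotypes,
    the shared confounder, per-trait noise), so the coefficients on the base
    sources determine the variance exactly; the own-noise coefficient is
    chosen to make each trait's variance 1.
    """

    def __init__(self, gc: np.ndarray, cov_g: np.ndarray, u: np.ndarray,
                 noise: dict[str, np.ndarray], noise_sd: float | None):
        self.gc = gc
        self.cov_g = cov_g
        self.u = u
        self.noise = noise
        self.noise_sd = noise_sd
        self.coefs: dict[str, dict] = {}
        self.values: dict[str, np.ndarray] = {}

    def build(self, name: str, gcoef: np.ndarray, u_coef: float,
              upstream: Sequence[tuple[float, str]] = ()) -> None:
        g = gcoef.astype(float).copy()
        u_total = float(u_coef)
        eps: dict[str, float] = {}
        for theta, up in upstream:
            parent = self.coefs[up]
            g += theta * parent["g"]
            u_total += theta * parent["u"]
            for key, coef in parent["eps"].items():
                eps[key] = eps.get(key, 0.0) + theta * coef
        explained = float(g @ self.cov_g @ g) + u_total**2 + sum(
            c * c for c in eps.values()
        )
        if self.noise_sd is None:
            if explained >= 1.0:
                raise ValueError(
                    f"trait {name}: explained variance {explained:.3f} >= 1; "
                    "reduce effect sizes or instrument r^2"
                )
            own = float(np.sqrt(1.0 - explained))
        else:
            own = float(self.noise_sd)
        eps[name] = eps.get(name, 0.0) + own
        value = self.gc @ g + u_total * self.u
        for key, coef in eps.items():
            value = value + coef * self.noise[key]
        if self.noise_sd is not None:
            value = (value - value.mean()) / value.std()
        self.coefs[name] = {"g": g, "u": u_total, "eps": eps}
        self.values[name] = value


def simulate_traits(
    genotypes: np.ndarray,
    config: SimConfig,
    mafs: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes M, S, Y under the configured DAG, with ground truth."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n, L = genotypes.shape
    gc = genotypes - 2.0 * mafs
    if config.ld_rho == 0.0:
        cov_g = np.diag(2.0 * mafs * (1.0 - mafs))
    else:
        # population-scale approximation under latent-Gaussian LD
        cov_g = np.cov(genotypes, rowvar=False)

    n_m = config.n_instruments_exposure
    n_s = config.n_instruments_mediator
    idx_m = np.arange(n_m)
    idx_s = np.arange(n_m, n_m + n_s)
    idx_y = np.arange(n_m + n_s, L)

    def _direct(idx: np.ndarray, r2_range: tuple[float, float]) -> np.ndarray:
        coef = np.zeros(L)
        if len(idx) and config.dag != "null":
            r2 = rng.uniform(*r2_range, size=len(idx))
            coef[idx] = _gamma_from_r2(r2, mafs[idx])
        return coef

    g_m = _direct(idx_m, config.r2_exposure_range)
    g_s = _direct(idx_s, config.r2_mediator_range)
    g_y = _direct(idx_y, config.r2_outcome_range)

    cu = 0.0 if config.dag == "null" else config.confounder_sd
    u = rng.standard_normal(n)
    noise = {key: rng.standard_normal(n) for key in ("M", "S", "Y")}
    builder = _TraitBuilder(gc, cov_g, u, noise, config.noise_sd)

    t1, t2, t3 = config.theta1, config.theta2, config.theta3
    alpha = None
    if config.dag in ("M_to_Y", "pleiotropy"):
        t1 = t2 = 0.0
        g_y_full = g_y.copy()
        if config.dag == "pleiotropy":
            k = int(np.ceil(config.pleiotropy_fraction * n_m))
            alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k)
            g_y_full[idx_m[:k]] += alpha
        builder.build("M", g_m, cu)
        builder.build("S", g_s, cu)
        builder.build("Y", g_y_full, cu, upstream=[(t3, "M")])
    elif config.dag == "M_to_S_to_Y":
        builder.build("M", g_m, cu)
        builder.build("S", g_s, cu, upstream=[(t1, "M")])
        builder.build("Y", g_y, cu, upstream=[(t2, "S"), (t3, "M")])
    elif config.dag == "S_to_M_to_Y":
        builder.build("S", g_s, cu)
        builder.build("M", g_m, cu, upstream=[(t1, "S")])
        builder.build("Y", g_y, cu, upstream=[(t2, "M"), (t3, "S")])
    elif config.dag in ("null", "confounded"):
        t1 = t2 = t3 = 0.0
        builder.build("M", g_m, cu)
        builder.build("S", g_s, cu)
        builder.build("Y", g_y, cu)

    phenotypes = pd.DataFrame({k: builder.values[k] for k in ("M", "S", "Y")})
    total = t3 + t1 * t2
    truth = TruthRecord(
        dag=config.dag,
        theta1=t1,
        theta2=t2,
        theta3=t3,
        total=total,
        proportion_mediated=(t1 * t2 / total) if total != 0.0 else None,
        seed=config.seed,
        instrument_effects={
            "M": g_m.tolist(), "S": g_s.tolist(), "Y": g_y.tolist()
        },
        pleiotropy_alpha=None if alpha is None else alpha.tolist(),
        mafs=mafs.tolist(),
    )
    return phenotypes, truth


def association_scan(
    genotypes: np.ndarray,
    y: np.ndarray,
    variant_ids: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
    chromosome: str = "1",
    trait_id: str = "",
    trait_type: str = "",
) -> list[AssociationRecord]:
    """Per-SNP simple linear regression summary statistics for one trait."""
    n, L = genotypes.shape
    if variant_ids is None:
        variant_ids = [f"rs{j + 1}" for j in range(L)]
    if positions is None:
        positions = [1_000_000 + 10_000 * j for j in range(L)]
    gc = genotypes - genotypes.mean(axis=0)
    yc = np.asarray(y, dtype=float) - np.mean(y)
    sxx = np.sum(gc**2, axis=0)
    syy = float(yc @ yc)
    records = []
    for j in range(L):
        if sxx[j] <= 0:
            continue  # monomorphic in this sample
        beta = float(gc[:, j] @ yc / sxx[j])
        s2 = max(syy - beta**2 * sxx[j], 0.0) / (n - 2)
        se = float(np.sqrt(s2 / sxx[j]))
        eaf = float(np.clip(genotypes[:, j].mean() / 2.0, 1e-6, 1 - 1e-6))
        records.append(
            AssociationRecord(
                variant_id=variant_ids[j],
                chromosome=chromosome,
                position=int(positions[j]),
                effect_allele="A",
                other_allele="G",
                eaf=eaf,
                beta=beta,
                se=se,
                n=n,
                trait_id=trait_id,
                trait_type=trait_type,
            )
        )
    return records


def summarize_associations(
    phenotypes: pd.DataFrame,
    genotypes: np.ndarray,
    sample_id: int,
    config: SimConfig,
) -> dict[str, list[AssociationRecord]]:
    """Per-SNP summary statistics within one of the two non-overlapping samples."""
    if sample_id not in (1, 2):
        raise ValueError("sample_id must be 1 or 2")
    rows = (
        slice(0, config.n_sample1)
        if sample_id == 1
        else slice(config.n_sample1, None)
    )
    g = genotypes[rows]
    out: dict[str, list[AssociationRecord]] = {}
    for trait, (trait_id, trait_type) in _TRAIT_META.items():
        out[trait] = association_scan(
            g,
            phenotypes[trait].to_numpy()[rows],
            trait_id=trait_id,
            trait_type=trait_type,
        )
    return out


@dataclass
class SimStudy:
    """One complete synthetic two-sample study."""

    config: SimConfig
    genotypes: np.ndarray
    ld: LDMatrix
    mafs: np.ndarray
    phenotypes: pd.DataFrame
    truth: TruthRecord
    sample1: dict[str, list[AssociationRecord]]
    sample2: dict[str, list[AssociationRecord]]


def simulate_study(config: SimConfig) -> SimStudy:
    """Genotypes, phenotypes and two-sample summary statistics in one call."""
    rng = config.rng()
    genotypes, ld, mafs = simulate_genotypes(config, rng=rng)
    phenotypes, truth = simulate_traits(genotypes, config, mafs, rng=rng)
    return SimStudy(
        config=config,
        genotypes=genotypes,
        ld=ld,
        mafs=mafs,
        phenotypes=phenotypes,
        truth=truth,
        sample1=summarize_associations(phenotypes, genotypes, 1, config),
        sample2=summarize_associations(phenotypes, genotypes, 2, config),
    )


def _region_scan(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    rho: float,
    causal_idx: int | None,
    r2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Summary statistics for one trait in its own independent sample."""
    g = _dosages(rng, n, mafs, rho)
    noise = rng.standard_normal(n)
    if causal_idx is None:
        y = noise
    else:
        maf = mafs[causal_idx]
        lam = float(np.sqrt(r2 / (2.0 * maf * (1.0 - maf))))
        causal = g[:, causal_idx] - 2.0 * maf
        y = lam * causal + np.sqrt(1.0 - r2) * noise
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.maximum(np.sum(gc**2, axis=0), 1e-12)
    beta = gc.T @ yc / sxx
    s2 = np.maximum(float(yc @ yc) - beta**2 * sxx, 0.0) / (n - 2)
    return beta, np.sqrt(s2 / sxx)


def simulate_region(
    config: SimConfig,
    scenario: str,
    rng: np.random.Generator | None = None,
) -> tuple[RegionDataset, TruthRecord]:
    """A colocalization region with causal variants placed per scenario label.

    ``scenario`` is a configuration label over traits a=methylation,
    b=expression, c=lung_function (e.g. ``"abc"``, ``"ac,b"``, ``"null"``);
    traits within one block share a single causal variant, blocks get
    distinct variants, and absent traits have no causal variant.  Summary
    statistics for each trait are computed in independent samples.
    """
    valid = {c.label for c in enumerate_configurations(3)}
    if scenario not in valid:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    nv = config.n_region_variants
    mafs = rng.uniform(*config.region_maf_range, size=nv)
    blocks = [] if scenario == "null" else scenario.split(",")
    causal_variants = rng.choice(nv, size=len(blocks), replace=False)
    causal_by_trait: dict[str, int | None] = {t: None for t in _REGION_TRAITS}
    for block, var in zip(blocks, causal_variants):
        for letter in block:
            causal_by_trait[_REGION_TRAITS["abc".index(letter)]] = int(var)

    betas, ses = [], []
    for t, trait in enumerate(_REGION_TRAITS):
        b, s = _region_scan(
            rng,
            config.region_sample_sizes[t],
            mafs,
            config.region_ld_rho,
            causal_by_trait[trait],
            config.region_r2[t],
        )
        betas.append(b)
        ses.append(s)

    start = 1_000_000
    positions = start + 2_000 * np.arange(nv)
    region = RegionDataset(
        chromosome="1",
        start=start,
        end=int(positions[-1]),
        variant_ids=[f"rs{j + 1}" for j in range(nv)],
        positions=positions,
        maf=mafs,
        betas=np.column_stack(betas),
        ses=np.column_stack(ses),
        n_samples=tuple(config.region_sample_sizes),
        traits=_REGION_TRAITS,
    )
    truth = TruthRecord(
        dag="region",
        theta1=0.0,
        theta2=0.0,
        theta3=0.0,
        total=0.0,
        proportion_mediated=None,
        seed=config.seed,
        mafs=mafs.tolist(),
        scenario=scenario,
        causal_indices=causal_by_trait,
    )
    return region, truth
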