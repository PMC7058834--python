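"""Multiple-trait Bayesian colocalization (up to three traits).

Per variant and trait, evidence for association is a Wakefield approximate
Bayes factor under a normal effect prior.  Sharing hypotheses are the 15
configurations obtained by choosing a subset of the three traits and
partitioning it into blocks, each block driven by one causal variant with
distinct variants across blocks.  Configuration likelihoods sum per-variant
ABF products over all assignments of distinct variants to blocks, weighted
by per-variant priors p1/p2/p3 for blocks of one, two or three traits, and
are normalized into posterior probabilities of association (PPA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    NoTestableGeneError,
    RegionTooSmallError,
    UnsupportedError,
)

TRAIT_LETTERS = "abc"
DEFAULT_PRIORS = (1e-4, 1e-6, 1e-7)
DEFAULT_PRIOR_SD = 0.15
MIN_REGION_VARIANTS = 50
MIN_REGION_MAF = 0.05
PPA_EVIDENCE_THRESHOLD = 0.80


@dataclass(frozen=True)
class Configuration:
    """One sharing configuration: disjoint blocks over a subset of traits."""

    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.blocks:
            if set(block) & seen:
                raise ValueError("configuration blocks must be disjoint")
            seen.update(block)

    @property
    def label(self) -> str:
        return ",".join(self.blocks) if self.blocks else "null"

    def shares(self, letter_a: str, letter_b: str) -> bool:
        return any(letter_a in b and letter_b in b for b in self.blocks)


def _set_partitions(items: tuple[str, ...]):
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        yield ((first,),) + partition
        for i, block in enumerate(partition):
            yield partition[:i] + ((first,) + block,) + partition[i + 1 :]


def enumerate_configurations(n_traits: int) -> list[Configuration]:
    """All sharing configurations for 1-3 traits (counts 2, 5, 15)."""
    if n_traits not in (1, 2, 3):
        raise UnsupportedError(f"n_traits must be 1, 2 or 3, got {n_traits}")
    letters = TRAIT_LETTERS[:n_traits]
    configs = [Configuration(())]
    for size in range(1, n_traits + 1):
        for subset in combinations(letters, size):
            for partition in _set_partitions(subset):
                blocks = tuple(
                    sorted("".join(sorted(block)) for block in partition)
                )
                configs.append(Configuration(blocks))
    # deterministic order: null first, then by number of traits, label
    configs.sort(key=lambda c: (sum(len(b) for b in c.blocks), c.label))
    return configs


def wakefield_log_abf(beta, se, prior_sd_w: float = DEFAULT_PRIOR_SD):
    """log approximate Bayes factor for one association (vectorized).

    With V = se^2, W = prior_sd_w^2 and z = beta/se:
    log ABF = 0.5 log(V/(V+W)) + z^2 W / (2 (V+W)).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd_w <= 0:
        raise ValueError("prior_sd_w must be > 0")
    v = se**2
    w = prior_sd_w**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + 0.5 * z2 * w / (v + w)


def wakefield_abf(beta, se, prior_sd_w: float = DEFAULT_PRIOR_SD):
    return np.exp(wakefield_log_abf(beta, se, prior_sd_w))


@dataclass
class RegionDataset:
    """Per-variant statistics for up to three traits in a genomic window."""

    chromosome: str
    start: int
    end: int
    variant_ids: list[str]
    positions: np.ndarray
    maf: np.ndarray
    betas: np.ndarray  # (n_variants, n_traits)
    ses: np.ndarray
    n_samples: tuple[int, ...]
    traits: tuple[str, ...] = ("methylation", "expression", "lung_function")
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start > 2_000_000:
            raise ValueError("region window must span at most 2 Mb")
        self.positions = np.asarray(self.positions, dtype=int)
        self.maf = np.asarray(self.maf, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        n, k = len(self.variant_ids), len(self.traits)
        if self.betas.shape != (n, k) or self.ses.shape != (n, k):
            raise ValueError("betas/ses must be (n_variants, n_traits)")
        if self.maf.shape != (n,) or self.positions.shape != (n,):
            raise ValueError("maf/positions must match the variant list")
        if len(self.n_samples) != k:
            raise ValueError("one sample size per trait required")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def filtered(self, maf_min: float = MIN_REGION_MAF) -> "RegionDataset":
        """Variants with MAF >= maf_min and complete, positive-SE statistics."""
        keep = (
            (np.minimum(self.maf, 1 - self.maf) >= maf_min)
            & np.all(np.isfinite(self.betas), axis=1)
            & np.all(np.isfinite(self.ses) & (self.ses > 0), axis=1)
        )
        idx = np.flatnonzero(keep)
        return replace(
            self,
            variant_ids=[self.variant_ids[i] for i in idx],
            positions=self.positions[idx],
            maf=self.maf[idx],
            betas=self.betas[idx],
            ses=self.ses[idx],
        )

    def subset_traits(self, trait_idx: Sequence[int]) -> "RegionDataset":
        idx = list(trait_idx)
        return replace(
            self,
            betas=self.betas[:, idx],
            ses=self.ses[:, idx],
            n_samples=tuple(self.n_samples[i] for i in idx),
            traits=tuple(self.traits[i] for i in idx),
        )


@dataclass
class MolocResult:
    posteriors: dict[str, float]
    traits: tuple[str, ...]
    n_variants: int
    best_gene: str | None = None

    @property
    def ppa_three_way(self) -> float:
        return self.posteriors.get("abc", 0.0)

    def ppa_shared(self, trait_a: str, trait_b: str) -> float:
        """Posterior mass on configurations where two traits share a block."""
        la = TRAIT_LETTERS[self.traits.index(trait_a)]
        lb = TRAIT_LETTERS[self.traits.index(trait_b)]
        total = 0.0
        for label, prob in self.posteriors.items():
            if label == "null":
                continue
            if any(la in block and lb in block for block in label.split(",")):
                total += prob
        return total

    @property
    def ppa_meth_fev1(self) -> float:
        return self.ppa_shared("methylation", "lung_function")

    @property
    def best_label(self) -> str:
        return max(self.posteriors, key=self.posteriors.get)


def _distinct_assignment_logsum(block_logs: list[np.ndarray]) -> float:
    """log sum over assignments of distinct variants to blocks of exp-values.

    Each entry of ``block_logs`` is the per-variant log value of one block
    (sum of that block's trait log-ABFs).  Works in a shifted linear space
    with inclusion-exclusion for the distinctness constraint (at most three
    blocks occur for three traits).
    """
    shifts = [float(np.max(l)) for l in block_logs]
    v = [np.exp(l - m) for l, m in zip(block_logs, shifts)]
    if len(v) == 1:
        total = float(np.sum(v[0]))
    elif len(v) == 2:
        total = float(np.sum(v[0]) * np.sum(v[1]) - np.sum(v[0] * v[1]))
    elif len(v) == 3:
        s1, s2, s3 = (float(np.sum(x)) for x in v)
        s12 = float(np.sum(v[0] * v[1]))
        s13 = float(np.sum(v[0] * v[2]))
        s23 = float(np.sum(v[1] * v[2]))
        s123 = float(np.sum(v[0] * v[1] * v[2]))
        total = s1 * s2 * s3 - s12 * s3 - s13 * s2 - s23 * s1 + 2.0 * s123
    else:  # pragma: no cover - capped at 3 traits upstream
        raise UnsupportedError("more than three blocks are not supported")
    return math.log(max(total, 1e-300)) + sum(shifts)


def moloc_posteriors(
    region: RegionDataset,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd: float | Sequence[float] = DEFAULT_PRIOR_SD,
    maf_min: float = MIN_REGION_MAF,
    min_variants: int = MIN_REGION_VARIANTS,
) -> MolocResult:
    """Posterior probability of every sharing configuration for a region.

    ``priors`` are the per-variant prior probabilities that a variant is
    causal for one trait (p1), shared by two traits (p2) or by three (p3).
    The null configuration carries baseline weight 1.  Raises
    :class:`RegionTooSmallError` when fewer than ``min_variants`` variants
    with MAF >= ``maf_min`` and complete statistics remain.
    """
    reg = region.filtered(maf_min)
    if reg.n_variants < min_variants:
        raise RegionTooSmallError(
            f"{reg.n_variants} qualifying variants < required {min_variants}"
        )
    k = len(reg.traits)
    sd = np.broadcast_to(np.asarray(prior_sd, dtype=float), (k,))
    log_abf = np.column_stack(
        [wakefield_log_abf(reg.betas[:, t], reg.ses[:, t], sd[t]) for t in range(k)]
    )
    prior_by_size = {1: priors[0], 2: priors[1], 3: priors[2]}
    letter_index = {TRAIT_LETTERS[t]: t for t in range(k)}

    configs = enumerate_configurations(k)
    log_weights = np.empty(len(configs))
    for i, config in enumerate(configs):
        if not config.blocks:
            log_weights[i] = 0.0
            continue
        block_logs = [
            log_abf[:, [letter_index[c] for c in block]].sum(axis=1)
            for block in config.blocks
        ]
        log_prior = sum(math.log(prior_by_size[len(b)]) for b in config.blocks)
        log_weights[i] = _distinct_assignment_logsum(block_logs) + log_prior
    log_weights -= np.max(log_weights)
    weights = np.exp(log_weights)
    post = weights / weights.sum()
    return MolocResult(
        posteriors={c.label: float(p) for c, p in zip(configs, post)},
        traits=reg.traits,
        n_variants=reg.n_variants,
        best_gene=region.gene,
    )


def best_gene_scan(
    gene_regions: Sequence[RegionDataset], **moloc_kwargs
) -> MolocResult:
    """Run colocalization per candidate gene and keep the highest three-way PPA.

    Each element supplies the shared methylation/lung-function statistics
    together with one gene's expression statistics (genes within 1 Mb of the
    CpG).  Regions failing the variant filter are skipped; if none is
    testable a :class:`NoTestableGeneError` is raised.
    """
    best: MolocResult | None = None
    for region in gene_regions:
        try:
            result = moloc_posteriors(region, **moloc_kwargs)
        except RegionTooSmallError:
            continue
        result.best_gene = region.gene
        if best is None or result.ppa_three_way > best.ppa_three_way:
            best = result
    if best is None:
        raise NoTestableGeneError("every candidate gene region was filtered out")
    return best


def region_to_tsv(region: RegionDataset, path: str | Path) -> None:
    """Write a region as a wide TSV (one beta/se column pair per trait)."""
    frame = pd.DataFrame(
        {
            "variant_id": region.variant_ids,
            "chromosome": region.chromosome,
            "position": region.positions,
            "maf": region.maf,
        }
    )
    for t, trait in enumerate(region.traits):
        frame[f"beta_{trait}"] = region.betas[:, t]
        frame[f"se_{trait}"] = region.ses[:, t]
    with open(path, "w") as fh:
        ns = " ".join(f"n_{t}={n}" for t, n in zip(region.traits, region.n_samples))
        fh.write(f"# window={region.chromosome}:{region.start}-{region.end} {ns}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_region_tsv(
    path: str | Path,
    traits: tuple[str, ...] = ("methylation", "expression", "lung_function"),
    n_samples: tuple[int, ...] | None = None,
    gene: str | None = None,
) -> RegionDataset:
    path = Path(path)
    header_ns: dict[str, int] = {}
    window = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if token.startswith("window="):
                window = token.split("=", 1)[1]
            elif token.startswith("n_") and "=" in token:
                key, value = token[2:].split("=")
                header_ns[key] = int(value)
    frame = pd.read_csv(path, sep="\t", comment="#")
    if n_samples is None:
        n_samples = tuple(header_ns[t] for t in traits)
    positions = frame["position"].to_numpy()
    if window:
        chrom, span = window.split(":")
        start, end = (int(x) for x in span.split("-"))
    else:
        chrom = str(frame["chromosome"].iloc[0])
        start, end = int(positions.min()), int(positions.max())
    return RegionDataset(
        chromosome=chrom,
        start=start,
        end=end,
        variant_ids=frame["variant_id"].astype(str).tolist(),
        positions=positions,
        maf=frame["maf"].to_numpy(),
        betas=frame[[f"beta_{t}" for t in traits]].to_numpy(),
        ses=frame[[f"se_{t}" for t in traits]].to_numpy(),
        n_samples=tuple(n_samples),
        traits=traits,
        gene=gene,
    )


def moloc_result_to_frame(result: MolocResult) -> pd.DataFrame:
    rows = [
        {"configuration": label, "posterior": prob}
        for label, prob in result.posteriors.items()
    ]
    frame = pd.DataFrame(rows)
    frame["ppa_three_way"] = result.ppa_three_way
    if {"methylation", "lung_function"} <= set(result.traits):
        frame["ppa_meth_fev1"] = result.ppa_meth_fev1
    frame["best_gene"] = result.best_gene
    frame["n_variants"] = result.n_variants
    return frame
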