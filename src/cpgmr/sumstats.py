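"""Summary-statistics data model, IO, harmonization and instrument selection.

The atomic unit is one SNP-trait association (:class:`AssociationRecord`):
the per-allele effect ``beta`` with its standard error, alleles, effect-allele
frequency and sample size, as printed in GWAS/mQTL summary tables.  Exposure
and outcome record sets from two non-overlapping studies are merged into a
:class:`HarmonizedSet` whose betas are all expressed per copy of the
*exposure* effect allele — the input every MR estimator in this package
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateSampleError,
    EmptyInputError,
    EmptyOverlapError,
)

VALID_ALLELES = frozenset("ACGT")
TRAIT_TYPES = frozenset({"methylation", "smoking", "lung_function", "expression"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default p-value threshold for mQTL instrument selection
MQTL_P_THRESHOLD = 1e-7
#: default minor-allele-frequency band inside which palindromic SNPs are dropped
PALINDROME_EAF_LIMIT = 0.42


def two_sided_p(z):
    """Two-sided normal-tail p-value of a z statistic (vectorized)."""
    return 2.0 * stats.norm.sf(np.abs(z))


def _round_1sf(x: float) -> float:
    if x <= 0.0:
        return 0.0
    e = math.floor(math.log10(x))
    return round(x / 10.0**e) * 10.0**e


def _p_consistent(p_reported: float, z: float) -> bool:
    # rounding to one significant figure; astronomically small p-values
    # (|z| > 8) are not compared because printed precision is meaningless there
    if abs(z) > 8.0:
        return True
    p_calc = float(two_sided_p(z))
    if _round_1sf(p_reported) == _round_1sf(p_calc):
        return True
    step = 0.5 * 10.0 ** math.floor(math.log10(max(p_calc, 1e-300)))
    return abs(p_reported - p_calc) <= step


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association from a summary-statistics table.

    ``beta`` is the trait change per copy of ``effect_allele`` (SD units for
    the standardized traits handled here); ``pvalue`` is recomputed from
    ``beta/se`` under the normal approximation when absent.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chromosome: str = ""
    position: int = 0
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    trait_id: str = ""
    trait_type: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not (self.se > 0.0 and math.isfinite(self.se)):
            raise ValueError(f"se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must lie in (0, 1), got {self.eaf}")
        if self.n is not None and self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.trait_type and self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.pvalue is None:
            object.__setattr__(self, "pvalue", float(two_sided_p(self.beta / self.se)))
        else:
            if not 0.0 < self.pvalue <= 1.0:
                raise ValueError(f"pvalue must lie in (0, 1], got {self.pvalue}")
            if not _p_consistent(self.pvalue, self.beta / self.se):
                raise ValueError(
                    f"pvalue {self.pvalue:g} inconsistent with |beta/se| = "
                    f"{abs(self.beta / self.se):g} for {self.variant_id}"
                )

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "AssociationRecord":
        """Same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-instrument variance explained and F statistic."""

    variant_id: str
    r_squared: float
    f_stat: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared < 1.0:
            raise ValueError("r_squared must lie in [0, 1)")
        if self.f_stat < 0.0:
            raise ValueError("f_stat must be >= 0")


@dataclass
class LDMatrix:
    """Pairwise genotype correlations for a SNP panel."""

    snps: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.snps = tuple(self.snps)
        self.rho = np.asarray(self.rho, dtype=float)
        k = len(self.snps)
        if self.rho.shape != (k, k):
            raise ValueError("rho dimensions must match the SNP list")
        if not np.allclose(self.rho, self.rho.T, atol=1e-8):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-8):
            raise ValueError("rho must have a unit diagonal")
        if np.any(np.abs(self.rho) > 1.0 + 1e-8):
            raise ValueError("rho entries must lie in [-1, 1]")

    def subset(self, snps: Sequence[str]) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snps)}
        missing = [s for s in snps if s not in index]
        if missing:
            raise ConfigurationError(f"LD matrix missing SNPs: {missing}")
        idx = np.array([index[s] for s in snps])
        return LDMatrix(tuple(snps), self.rho[np.ix_(idx, idx)])


@dataclass
class HarmonizedSet:
    """Exposure/outcome records aligned to the exposure effect allele."""

    snps: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    n_exposure: int | None = None
    n_outcome: int | None = None
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    exposure_records: list[AssociationRecord] = field(default_factory=list)
    outcome_records: list[AssociationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.snps)
        if k < 1:
            raise EmptyOverlapError("harmonized set must retain at least one SNP")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            if getattr(self, name).shape != (k,):
                raise ValueError(f"{name} must have length {k}")

    def __len__(self) -> int:
        return len(self.snps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.snps,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )


class ReadResult(NamedTuple):
    records: list[AssociationRecord]
    rejects: list[tuple[str, str]]


_CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se")


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str = "",
    trait_type: str = "",
) -> ReadResult:
    """Read a tab-separated summary-statistics table.

    ``dialect`` maps canonical column names (``variant_id``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, optionally ``chromosome``, ``position``,
    ``eaf``, ``pvalue``, ``n``) to the file's header names.  Rows whose beta or
    se cannot be parsed are reported as rejects rather than silently dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    colmap = {c: c for c in _CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    for canon in _MANDATORY:
        if colmap[canon] not in frame.columns:
            raise ConfigurationError(
                f"missing mandatory column {colmap[canon]!r} (for {canon!r}) in {path}"
            )

    def _get(row, canon):
        col = colmap[canon]
        if col not in frame.columns:
            return None
        value = row[col]
        return None if pd.isna(value) else value

    records: list[AssociationRecord] = []
    rejects: list[tuple[str, str]] = []
    for _, row in frame.iterrows():
        vid = str(_get(row, "variant_id"))
        parsed: dict[str, float | None] = {}
        bad = None
        for canon in ("beta", "se"):
            try:
                parsed[canon] = float(_get(row, canon))
            except (TypeError, ValueError):
                bad = f"unparseable {canon}"
                break
        if bad is not None:
            rejects.append((vid, bad))
            continue

        def _opt_float(canon):
            raw = _get(row, canon)
            if raw is None:
                return None
            try:
                return float(raw)
            except ValueError:
                return None

        n_raw = _opt_float("n")
        pos_raw = _opt_float("position")
        try:
            records.append(
                AssociationRecord(
                    variant_id=vid,
                    chromosome=str(_get(row, "chromosome") or ""),
                    position=int(pos_raw) if pos_raw is not None else 0,
                    effect_allele=str(_get(row, "effect_allele") or "").upper(),
                    other_allele=str(_get(row, "other_allele") or "").upper(),
                    eaf=_opt_float("eaf"),
                    beta=parsed["beta"],
                    se=parsed["se"],
                    pvalue=_opt_float("pvalue"),
                    n=int(n_raw) if n_raw is not None else None,
                    trait_id=trait_id,
                    trait_type=trait_type,
                )
            )
        except ValueError as exc:
            rejects.append((vid, str(exc)))
    return ReadResult(records, rejects)


def records_to_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": r.variant_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
            "n": r.n,
            "trait_id": r.trait_id,
            "trait_type": r.trait_type,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS) + ["trait_id", "trait_type"])


def write_sumstats(records: Iterable[AssociationRecord], path: str | Path,
                   header_comment: str | None = None) -> None:
    path = Path(path)
    frame = records_to_frame(records)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def select_instruments(
    records: Sequence[AssociationRecord], p_threshold: float = MQTL_P_THRESHOLD
) -> list[AssociationRecord]:
    """Retain associations with p below the mQTL selection threshold (1e-7)."""
    if not records:
        raise EmptyInputError("no records supplied to select_instruments")
    return [r for r in records if r.pvalue < p_threshold]


def instrument_strength(record: AssociationRecord) -> InstrumentStrength:
    """r^2 and single-SNP F from summary statistics.

    Uses the identity r^2 = z^2 / (z^2 + n - 2) for a continuous trait and
    takes the single-SNP F statistic as z^2, so the two are tied by
    F = r^2 (n - 2) / (1 - r^2).
    """
    if record.n is None or record.n < 3:
        raise DegenerateSampleError(
            f"instrument_strength needs n >= 3, got {record.n} for {record.variant_id}"
        )
    z2 = (record.beta / record.se) ** 2
    return InstrumentStrength(
        variant_id=record.variant_id,
        r_squared=z2 / (z2 + record.n - 2),
        f_stat=z2,
    )


def _align_outcome(
    exp: AssociationRecord, out: AssociationRecord
) -> AssociationRecord | None:
    """Re-express the outcome record on the exposure's effect allele.

    Returns None when the allele sets cannot be reconciled (including by
    strand complement).
    """
    pair = (out.effect_allele, out.other_allele)
    if pair == (exp.effect_allele, exp.other_allele):
        return out
    if pair == (exp.other_allele, exp.effect_allele):
        return out.flipped()
    if not exp.is_palindromic():
        comp = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])
        relabel = replace(out, effect_allele=comp[0], other_allele=comp[1])
        if comp == (exp.effect_allele, exp.other_allele):
            return relabel
        if comp == (exp.other_allele, exp.effect_allele):
            return relabel.flipped()
    return None


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_eaf_limit: float = PALINDROME_EAF_LIMIT,
) -> HarmonizedSet:
    """Align outcome records to the exposure effect allele per SNP.

    Swapped allele labels flip the outcome beta sign (and fold the eaf);
    strand-ambiguous A/T and C/G SNPs are kept only when both frequencies sit
    on the same side of 0.5 and outside the ambiguity band
    ``[limit, 1 - limit]``.  Every dropped SNP carries a machine-readable
    reason.
    """
    if not exposure or not outcome:
        raise EmptyInputError("harmonize requires nonempty exposure and outcome sets")
    out_index: dict[str, AssociationRecord] = {}
    for rec in outcome:
        out_index.setdefault(rec.variant_id, rec)
    overlap = [r for r in exposure if r.variant_id in out_index]
    if not overlap:
        raise EmptyOverlapError("no SNPs shared between exposure and outcome")

    kept_exp: list[AssociationRecord] = []
    kept_out: list[AssociationRecord] = []
    exclusions: list[tuple[str, str]] = []
    lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
    for exp in overlap:
        out = _align_outcome(exp, out_index[exp.variant_id])
        if out is None:
            exclusions.append((exp.variant_id, "allele mismatch"))
            continue
        if exp.is_palindromic():
            eafs = (exp.eaf, out.eaf)
            ok = (
                all(e is not None for e in eafs)
                and all(e < lo or e > hi for e in eafs)
                and (eafs[0] - 0.5) * (eafs[1] - 0.5) > 0
            )
            if not ok:
                exclusions.append((exp.variant_id, "palindromic, ambiguous eaf"))
                continue
        kept_exp.append(exp)
        kept_out.append(out)
    if not kept_exp:
        raise EmptyOverlapError("all overlapping SNPs were excluded during harmonization")

    def _median_n(records: list[AssociationRecord]) -> int | None:
        ns = [r.n for r in records if r.n is not None]
        return int(np.median(ns)) if ns else None

    return HarmonizedSet(
        snps=[r.variant_id for r in kept_exp],
        beta_exposure=np.array([r.beta for r in kept_exp]),
        se_exposure=np.array([r.se for r in kept_exp]),
        beta_outcome=np.array([r.beta for r in kept_out]),
        se_outcome=np.array([r.se for r in kept_out]),
        n_exposure=_median_n(kept_exp),
        n_outcome=_median_n(kept_out),
        exclusions=exclusions,
        exposure_records=kept_exp,
        outcome_records=kept_out,
    )


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square whitespace-delimited LD matrix with a header row of IDs."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise EmptyInputError(f"{path} is empty")
    snps = tuple(lines[0].split())
    rho = np.loadtxt(lines[1:])
    rho = np.atleast_2d(rho)
    return LDMatrix(snps, rho)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ld.snps) + "\n")
        for row in ld.rho:
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def write_exclusions(exclusions: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(exclusions, columns=["variant_id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
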