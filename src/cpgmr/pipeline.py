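"""Pipeline stages: discovery MR, replication, bidirectional MR, reporting.

Mirrors the staged design of a molecular-MR study: per-CpG two-sample MR in
a discovery outcome GWAS with Bonferroni control over the CpGs actually
tested, re-estimation of the survivors in an independent replication GWAS
(with direction-concordance summarised as a whole percentage), reciprocal MR
plus Steiger directionality per trait pair, and a consolidated report.
Stratum-specific and negative-control analyses reuse ``run_discovery`` on
stratum-specific summary statistics.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import ivw_fixed, wald_ratios
from .exceptions import EmptyOverlapError, EmptyStageError, WeakInstrumentError
from .sensitivity import steiger_from_harmonized
from .sumstats import (
    AssociationRecord,
    MQTL_P_THRESHOLD,
    harmonize,
    select_instruments,
)


@dataclass
class StageReport:
    stage: str
    tested: int
    threshold: float
    passing: list[str]
    extra: dict = field(default_factory=dict)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests (full precision)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for reported thresholds)."""
    if x == 0.0:
        return 0.0
    return float(f"%.{sig - 1}e" % x)


def percent(k: int, n: int) -> int:
    """Share of k out of n as a whole percentage."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(round(100.0 * k / n))


def _estimate_one(
    instruments: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    se_order: str = "first",
):
    h = harmonize(instruments, outcome)
    return h, ivw_fixed(wald_ratios(h, se_order=se_order))


def run_discovery(
    exposures: Mapping[str, Sequence[AssociationRecord]],
    outcome: Sequence[AssociationRecord],
    alpha: float = 0.05,
    p_instrument: float = MQTL_P_THRESHOLD,
    se_order: str = "first",
    stage_name: str = "discovery",
) -> tuple[StageReport, pd.DataFrame]:
    """Per-CpG two-sample MR with Bonferroni control over CpGs tested.

    CpGs with a single instrument get a Wald ratio; CpGs with several get
    fixed-effects IVW.  The Bonferroni family is the number of CpGs that
    actually produced an estimate, not the manifest size.
    """
    rows = []
    skipped = []
    outcome_label = next((r.trait_id for r in outcome if r.trait_id), "outcome")
    for cpg, records in exposures.items():
        try:
            instruments = select_instruments(list(records), p_instrument)
            if not instruments:
                skipped.append((cpg, "no instruments at threshold"))
                continue
            _, result = _estimate_one(instruments, outcome, se_order)
        except (EmptyOverlapError, WeakInstrumentError) as exc:
            skipped.append((cpg, str(exc)))
            continue
        rows.append(
            {
                "exposure": cpg,
                "outcome": outcome_label,
                "method": result.method,
                "n_snps": result.n_snps,
                "b": result.estimate,
                "se": result.se,
                "pval": result.pvalue,
            }
        )
    if not rows:
        raise EmptyStageError(f"{stage_name}: no testable CpG")
    table = pd.DataFrame(rows)
    threshold = bonferroni_threshold(alpha, len(table))
    table["pass"] = table["pval"] < threshold
    report = StageReport(
        stage=stage_name,
        tested=len(table),
        threshold=threshold,
        passing=table.loc[table["pass"], "exposure"].tolist(),
        extra={"skipped": skipped, "alpha": alpha},
    )
    return report, table


def run_replication(
    discovery_report: StageReport,
    discovery_results: pd.DataFrame,
    exposures: Mapping[str, Sequence[AssociationRecord]],
    replication_outcome: Sequence[AssociationRecord],
    alpha: float = 0.05,
    p_instrument: float = MQTL_P_THRESHOLD,
    se_order: str = "first",
) -> tuple[StageReport, pd.DataFrame]:
    """Re-estimate discovery-passing CpGs in an independent outcome sample.

    Bonferroni correction runs over the passing count; direction concordance
    is the share of re-estimated CpGs whose sign matches discovery, reported
    as a whole percentage.
    """
    passing = discovery_report.passing
    if not passing:
        raise EmptyStageError("replication requires >= 1 discovery-passing CpG")
    discovery_b = discovery_results.set_index("exposure")["b"]
    rows = []
    for cpg in passing:
        try:
            instruments = select_instruments(list(exposures[cpg]), p_instrument)
            _, result = _estimate_one(instruments, replication_outcome, se_order)
        except (KeyError, EmptyOverlapError, WeakInstrumentError):
            continue
        rows.append(
            {
                "exposure": cpg,
                "method": result.method,
                "n_snps": result.n_snps,
                "b": result.estimate,
                "se": result.se,
                "pval": result.pvalue,
                "discovery_b": discovery_b[cpg],
                "concordant": math.copysign(1, result.estimate)
                == math.copysign(1, discovery_b[cpg]),
            }
        )
    if not rows:
        raise EmptyStageError("replication: no CpG could be re-estimated")
    table = pd.DataFrame(rows)
    threshold = bonferroni_threshold(alpha, len(table))
    table["pass"] = table["pval"] < threshold
    concordance = percent(int(table["concordant"].sum()), len(table))
    report = StageReport(
        stage="replication",
        tested=len(table),
        threshold=threshold,
        passing=table.loc[table["pass"], "exposure"].tolist(),
        extra={"direction_concordance_pct": concordance, "alpha": alpha},
    )
    return report, table


def run_bidirectional(
    pairs: Mapping[str, Mapping[str, Sequence[AssociationRecord]]],
    alpha: float = 0.05,
    p_instrument: float = MQTL_P_THRESHOLD,
) -> tuple[StageReport, pd.DataFrame]:
    """Forward and reciprocal MR plus Steiger directionality per trait pair.

    Each pair maps to four record sets: ``fwd_exposure``/``fwd_outcome``
    (exposure instruments looked up in exposure and outcome GWAS) and
    ``rev_exposure``/``rev_outcome`` (outcome instruments, reciprocally).
    Pairs without reverse instruments are skipped with a warning note.
    """
    rows = []
    skipped = []
    for name, data in pairs.items():
        fwd_instr = select_instruments(list(data["fwd_exposure"]), p_instrument)
        h_fwd, fwd = _estimate_one(fwd_instr, data["fwd_outcome"])
        steiger = steiger_from_harmonized(h_fwd)
        row = {
            "pair": name,
            "forward_b": fwd.estimate,
            "forward_se": fwd.se,
            "forward_pval": fwd.pvalue,
            "steiger_direction": steiger.direction,
            "steiger_pval": steiger.pvalue,
        }
        rev_exp = data.get("rev_exposure")
        rev_out = data.get("rev_outcome")
        if not rev_exp or not rev_out:
            skipped.append((name, "missing reverse instruments; reverse MR skipped"))
            row.update(reverse_b=np.nan, reverse_se=np.nan, reverse_pval=np.nan)
        else:
            rev_instr = select_instruments(list(rev_exp), p_instrument)
            _, rev = _estimate_one(rev_instr, rev_out)
            row.update(
                reverse_b=rev.estimate, reverse_se=rev.se, reverse_pval=rev.pvalue
            )
        row["verdict"] = steiger.direction
        rows.append(row)
    if not rows:
        raise EmptyStageError("bidirectional: no testable pair")
    table = pd.DataFrame(rows)
    report = StageReport(
        stage="bidirectional",
        tested=len(table),
        threshold=bonferroni_threshold(alpha, len(table)),
        passing=table.loc[
            table["forward_pval"] < alpha / len(table), "pair"
        ].tolist(),
        extra={"skipped": skipped},
    )
    return report, table


def config_digest(payload) -> str:
    """Short stable hash of a configuration mapping, for report provenance."""
    canonical = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def run_report(
    reports: Sequence[StageReport],
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config_hash: str = "",
) -> Path:
    """Write per-stage TSVs and a human-readable summary; returns summary path.

    Output is deterministic for a fixed set of inputs, so re-running an
    identical configuration reproduces the report byte for byte.
    """
    if not reports:
        raise EmptyStageError("run_report requires at least one completed stage")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# cpgmr analysis report", f"# seed={seed} config={config_hash}", ""]
    for report in reports:
        table = tables.get(report.stage)
        if table is not None:
            table.to_csv(out_dir / f"{report.stage}.tsv", sep="\t", index=False)
        lines.append(f"stage: {report.stage}")
        lines.append(f"  tested: {report.tested}")
        lines.append(f"  threshold: {round_sig(report.threshold, 2):g}")
        lines.append(f"  passing ({len(report.passing)}): {', '.join(report.passing)}")
        for key, value in sorted(report.extra.items()):
            if key == "skipped" and not value:
                continue
            lines.append(f"  {key}: {value}")
        lines.append("")
    summary = out_dir / "summary.txt"
    summary.write_text("\n".join(lines))
    return summary
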