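"""Downstream quantification: snoRNA expression, correlations, pre-rRNA ratios.

Stem-loop qPCR of guide snoRNAs is quantified relative to 5.8S rRNA by
delta-Ct (assay efficiency fixed at 2) and expressed relative to the mean
of proliferating (P) samples, so the P-state mean is 1 by construction.
Northern band intensities are normalized lane-wise to a loading control
(SNORD57 for snoRNA blots) before the same P normalization.  Pre-rRNA
processing is summarized by intermediate ratios (e.g. 30S:41S, which
contrasts processing pathways B and A); P-normalized ratios in the
arrested states are tested with two-tailed one-sample t-tests against an
expected value of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import SiteCatalog
from .design import StudyDesign
from .scoring import RMSScoreTable

__all__ = [
    "CtRecord",
    "TTestResult",
    "RatioResult",
    "CorrelationRecord",
    "DEFAULT_RATIOS",
    "read_ct_table",
    "relative_expression",
    "normalize_northern",
    "one_sample_t",
    "correlate_expression_methylation",
    "processing_ratios",
]

#: pre-rRNA intermediate ratios quantified from northern blots
DEFAULT_RATIOS = (
    ("47S", "28S"),
    ("21S", "47S"),
    ("18S-E", "47S"),
    ("30S", "41S"),
    ("30S", "47S"),
    ("41S", "47S"),
)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference (5.8S rRNA) cycle thresholds."""

    sample_id: str
    target: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"{self.sample_id}/{self.target}: {name} must be positive and finite"
                )


class TTestResult(NamedTuple):
    t: float
    p: float
    df: int


@dataclass
class RatioResult:
    name: str  # e.g. "30S:41S"
    per_sample: pd.Series  # raw ratio per biological sample
    normalized: pd.Series  # P-normalized ratio per biological sample
    state_tests: dict[str, TTestResult]  # state -> one-sample t vs 1 (non-P states)


@dataclass
class CorrelationRecord:
    site: str
    guide: str
    n: int
    pearson_r: float = float("nan")
    spearman_r: float = float("nan")
    status: str = "ok"  # or "insufficient_data"


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "target", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    return [
        CtRecord(str(r["sample"]), str(r["target"]), float(r["ct_target"]),
                 float(r["ct_reference"]))
        for _, r in df.iterrows()
    ]


def _p_samples(design: StudyDesign) -> list[str]:
    bio = design.biological_design()
    p = [s.sample_id for s in bio if s.state == "P"]
    if not p:
        raise ValueError("design contains no P-state samples to normalize against")
    return p


def relative_expression(records: Sequence[CtRecord], design: StudyDesign) -> pd.DataFrame:
    """Delta-Ct relative quantification, normalized so the P-state mean is 1.

    Each sample's linear abundance 2^-dCt (dCt = Ct_target - Ct_reference,
    assay efficiency 2) is divided by the arithmetic mean abundance of the
    P-state samples, so the P-group mean is exactly 1 per target.  Adding a
    constant to both Ct values of a sample cancels in dCt.
    """
    if not records:
        raise ValueError("no Ct records")
    dct: dict[str, dict[str, float]] = {}
    for r in records:
        dct.setdefault(r.target, {})[r.sample_id] = r.ct_target - r.ct_reference
    p_ids = _p_samples(design)
    out: dict[str, dict[str, float]] = {}
    for target, per_sample in dct.items():
        missing_p = [s for s in p_ids if s not in per_sample]
        if missing_p:
            raise ValueError(
                f"target {target}: no Ct record for P sample(s) {missing_p}"
            )
        linear = {s: 2.0 ** (-v) for s, v in per_sample.items()}
        p_mean = float(np.mean([linear[s] for s in p_ids]))
        out[target] = {s: v / p_mean for s, v in linear.items()}
    table = pd.DataFrame(out).T
    # preserve design sample order where possible
    ordered = [s.sample_id for s in design.biological_design() if s.sample_id in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    return table[ordered + extra]


def normalize_northern(
    bands: pd.DataFrame,
    control: str,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Lane-wise normalization to a loading-control band, then (if a design
    is given) normalization of each target to the P-state mean.

    ``bands`` is species/target x lane.  Lanes with a missing or
    non-positive control are excluded with a warning.
    """
    if control not in bands.index:
        raise KeyError(f"control {control!r} not present in the band table")
    ctrl = bands.loc[control]
    bad = [str(c) for c in bands.columns if not (ctrl[c] > 0) or pd.isna(ctrl[c])]
    if bad:
        warnings.warn(f"excluding lane(s) with unusable control signal: {bad}")
    keep = [c for c in bands.columns if str(c) not in bad]
    norm = bands[keep].div(ctrl[keep], axis=1).drop(index=control)
    if design is not None:
        p_ids = [s for s in _p_samples(design) if s in norm.columns]
        if not p_ids:
            raise ValueError("no P-state lanes left after control filtering")
        norm = norm.div(norm[p_ids].mean(axis=1), axis=0)
    return norm


def one_sample_t(values: Sequence[float], expected: float = 1.0) -> TTestResult:
    """Two-tailed one-sample t-test of the mean against ``expected``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("one-sample t-test undefined for zero-variance values")
    df = x.size - 1
    t = (x.mean() - expected) / (sd / np.sqrt(x.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(p), int(df))


def correlate_expression_methylation(
    scores: RMSScoreTable | pd.DataFrame,
    expr: pd.DataFrame,
    catalog: SiteCatalog,
    sites: Iterable[str] | None = None,
) -> list[CorrelationRecord]:
    """Pearson (and Spearman) correlation between each site's methylation
    scores and the expression of its guide snoRNA across shared samples.

    Guide groups such as "SNORD88A/B/C" are single aggregate series.  Sites
    with fewer than 3 paired observations yield an insufficient-data record.
    """
    df = scores.scores if isinstance(scores, RMSScoreTable) else scores
    if sites is None:
        sites = [s.label for s in catalog if s.guide_snoRNAs and s.label in df.index]
    records: list[CorrelationRecord] = []
    for lab in sites:
        site = catalog.get(lab)
        for guide in site.guide_snoRNAs:
            if guide not in expr.index:
                continue
            common = [c for c in df.columns if c in expr.columns]
            pair = pd.DataFrame(
                {"score": df.loc[lab, common], "expr": expr.loc[guide, common]}
            ).dropna()
            if len(pair) < 3:
                records.append(
                    CorrelationRecord(lab, guide, len(pair), status="insufficient_data")
                )
                continue
            r_p = sps.pearsonr(pair["score"], pair["expr"]).statistic
            r_s = sps.spearmanr(pair["score"], pair["expr"]).statistic
            records.append(
                CorrelationRecord(lab, guide, len(pair), float(r_p), float(r_s))
            )
    return records


def processing_ratios(
    bands: pd.DataFrame,
    design: StudyDesign,
    ratios: Sequence[tuple[str, str]] = DEFAULT_RATIOS,
) -> list[RatioResult]:
    """Pre-rRNA intermediate ratios, P-normalized, with one-sample t-tests.

    Normalization is donor-paired when every donor has a P sample (each
    sample's ratio is divided by its donor's P ratio); otherwise the P-state
    mean is used.  Non-P state groups are tested against 1.
    """
    bio = design.biological_design()
    samples = [s for s in bio if s.sample_id in bands.columns]
    if not samples:
        raise ValueError("no design samples found among band table columns")
    donor_p: dict[str, str] = {
        s.donor: s.sample_id for s in samples if s.state == "P"
    }
    paired = all(s.donor in donor_p for s in samples)
    results: list[RatioResult] = []
    for num, den in ratios:
        name = f"{num}:{den}"
        if num not in bands.index or den not in bands.index:
            warnings.warn(f"ratio {name}: species missing from band table, skipped")
            continue
        vals: dict[str, float] = {}
        for s in samples:
            n_v, d_v = bands.loc[num, s.sample_id], bands.loc[den, s.sample_id]
            if pd.isna(n_v) or pd.isna(d_v) or d_v == 0:
                warnings.warn(f"ratio {name}: unusable values for {s.sample_id}, skipped")
                continue
            vals[s.sample_id] = float(n_v / d_v)
        per_sample = pd.Series(vals, name=name)
        normalized = {}
        if paired:
            for s in samples:
                if s.sample_id in vals and donor_p[s.donor] in vals:
                    normalized[s.sample_id] = vals[s.sample_id] / vals[donor_p[s.donor]]
        else:
            p_vals = [vals[s.sample_id] for s in samples
                      if s.state == "P" and s.sample_id in vals]
            if not p_vals:
                warnings.warn(f"ratio {name}: no P samples, skipped")
                continue
            p_mean = float(np.mean(p_vals))
            normalized = {sid: v / p_mean for sid, v in vals.items()}
        normalized = pd.Series(normalized, name=name)
        tests: dict[str, TTestResult] = {}
        for state in design.states:
            if state == "P":
                continue
            group = [
                normalized[s.sample_id]
                for s in samples
                if s.state == state and s.sample_id in normalized.index
            ]
            if len(group) >= 2 and np.std(group, ddof=1) > 0:
                tests[state] = one_sample_t(group, expected=1.0)
        results.append(RatioResult(name, per_sample, normalized, tests))
    return results
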