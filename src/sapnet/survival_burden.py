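"""Per-sample deleterious-SAP burden and two-group prognosis comparison.

The burden of a tumour sample is the sum of the meta-scores of its top-k
(default 30) SAPs.  Samples are split into a high-risk and a low-risk
group around the mean (default) or median burden, and the two survival
curves are compared with a log-rank test plus a single-covariate Cox
proportional-hazards fit on the group indicator (hazard ratio high vs
low).  Ties at exactly the split value go to the low group (strict ">").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test

from .io_formats import FormatError, ScoreVector

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 30


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time in days and observed-event flag."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FormatError(f"{self.sample_id}: negative survival time")
        if self.event not in (0, 1):
            raise FormatError(f"{self.sample_id}: event flag must be 0 or 1")


@dataclass(frozen=True)
class GroupComparison:
    """Result of the high- vs low-burden survival comparison."""

    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    logrank_p: float
    n_high: int
    n_low: int
    split_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "hazard_ratio": self.hazard_ratio,
            "hr_ci_low": self.hr_ci_low,
            "hr_ci_high": self.hr_ci_high,
            "logrank_p": self.logrank_p,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "split_value": self.split_value,
        }


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival TSV with columns sample_id, time_days, event."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = ["sample_id", "time_days", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        SurvivalRecord(row.sample_id, float(row.time_days), int(row.event))
        for row in df.itertuples(index=False)
    ]


def write_survival_table(path: str | Path,
                         records: Sequence[SurvivalRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttime_days\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.time:.3f}\t{r.event}\n")


def sample_burden(
    scores: Sequence[ScoreVector], top_k: int = DEFAULT_TOP_K
) -> dict[str, float]:
    """Per-sample sum of the ``top_k`` largest meta-scores.

    Samples with fewer than ``top_k`` SAPs sum everything they have.
    Ties are immaterial to the sum but the selection is kept deterministic
    by sorting on (meta desc, protein, position).
    """
    if top_k < 1:
        raise FormatError("top_k must be >= 1")
    by_sample: dict[str, list[ScoreVector]] = {}
    for sv in scores:
        if sv.sap.sample_id is None:
            raise FormatError(
                f"{sv.sap.protein_id}:{sv.sap.position}: SAP without a "
                "sample_id in burden computation"
            )
        by_sample.setdefault(sv.sap.sample_id, []).append(sv)
    burdens = {}
    for sample, svs in by_sample.items():
        ordered = sorted(
            svs, key=lambda v: (-v.meta_score, v.sap.protein_id, v.sap.position)
        )
        burdens[sample] = float(sum(v.meta_score for v in ordered[:top_k]))
    return burdens


def stratify(
    burdens: Mapping[str, float], split: str = "mean"
) -> tuple[dict[str, str], float]:
    """Assign each sample to the high or low group around the split statistic.

    ``split`` is "mean" or "median"; high means burden strictly above the
    split value.  All-equal burdens are a degenerate-split error.
    Returns ``(assignments, split_value)``.
    """
    if len(burdens) < 2:
        raise FormatError("stratification needs at least 2 samples")
    values = np.asarray(list(burdens.values()), dtype=float)
    if np.all(values == values[0]):
        raise FormatError("all burdens identical; split is degenerate")
    if split == "mean":
        cut = float(np.mean(values))
    elif split == "median":
        cut = float(np.median(values))
    else:
        raise FormatError(f"unknown split statistic {split!r}")
    groups = {s: ("high" if b > cut else "low") for s, b in burdens.items()}
    return groups, cut


def compare_groups(
    groups: Mapping[str, str],
    survival: Sequence[SurvivalRecord],
    split_value: float | None = None,
) -> GroupComparison:
    """Log-rank test and Cox PH hazard ratio of high- vs low-burden samples.

    Every grouped sample must have a survival record; the converse is not
    required (extra survival records are ignored).
    """
    by_id = {r.sample_id: r for r in survival}
    missing = sorted(s for s in groups if s not in by_id)
    if missing:
        raise FormatError(
            f"no survival record for sample(s): {missing[:10]}"
        )
    n_high = sum(1 for g in groups.values() if g == "high")
    n_low = len(groups) - n_high
    if n_high == 0 or n_low == 0:
        raise FormatError("one stratification group is empty")
    df = pd.DataFrame({
        "time": [by_id[s].time for s in groups],
        "event": [by_id[s].event for s in groups],
        "high": [1 if groups[s] == "high" else 0 for s in groups],
    })
    lr = logrank_test(
        df.loc[df.high == 1, "time"], df.loc[df.high == 0, "time"],
        event_observed_A=df.loc[df.high == 1, "event"],
        event_observed_B=df.loc[df.high == 0, "event"],
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    ci = cph.confidence_intervals_
    ci_low = float(np.exp(ci.iloc[0, 0]))
    ci_high = float(np.exp(ci.iloc[0, 1]))
    return GroupComparison(
        hazard_ratio=hr, hr_ci_low=ci_low, hr_ci_high=ci_high,
        logrank_p=float(lr.p_value), n_high=n_high, n_low=n_low,
        split_value=split_value,
    )
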