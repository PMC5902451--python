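"""Weighted-average meta-score: Condel-style fusion of S, T and I scores.

Each component score is combined into

    WAS = sum_i(S_i * W_i) / sum_i(W_i)

where the weight of a component reflects how surprising its score would be
for a training mutation of the *opposite* class:

* if the component alone calls the mutation deleterious (score >= its
  cutoff), W = 1 - P(neutral training score > observed score);
* otherwise W = 1 - P(deleterious training score > observed score);
* an absent component score gets weight 0 and drops out of the average.

The exceedance probabilities are empirical complementary CDFs over the
per-class training samples — plain counting with strict inequality, no
binning or smoothing, so ties resolve toward the larger weight.

Component-level cutoffs default to the conventions of the scoring scheme:
theta_S = 0.95 (the SIFT 0.05 tolerance cutoff mapped through S = 1-SIFT),
theta_T = 0.9 on the normalized T-score, theta_I = 0.5 (so an interface
hit is a deleterious call).  The meta-score cutoff defaults to 0.9.
All of these are configuration, not constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conservation_score import SiftKey, s_score, sift_for
from .interface_score import i_score
from .io_formats import (
    FormatError,
    InterfaceMap,
    PpiNetwork,
    SapRecord,
    ScoreVector,
)
from .topology_score import (
    TNormalizer,
    fit_t_normalizer,
    normalized_t,
    raw_t_score,
)

COMPONENTS = ("S", "T", "I")

DEFAULT_CUTOFFS = {"S": 0.95, "T": 0.9, "I": 0.5}
DEFAULT_META_CUTOFF = 0.9


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunable parameters of calibration.

    ``youden_t_cutoff=True`` re-derives theta_T from the training data by
    maximizing Youden's J instead of using the 0.9 default.
    """

    cutoffs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )
    meta_cutoff: float = DEFAULT_META_CUTOFF
    youden_t_cutoff: bool = False

    def __post_init__(self) -> None:
        for c, v in self.cutoffs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"cutoff theta_{c} = {v} outside [0, 1]")
        if not (0.0 < self.meta_cutoff < 1.0):
            raise ValueError(f"meta_cutoff {self.meta_cutoff} outside (0, 1)")


@dataclass
class CalibrationModel:
    """Everything learned from labelled training data.

    ``samples[c]["neutral"]`` / ``samples[c]["deleterious"]`` hold the
    sorted per-class training scores of component ``c`` used for the
    empirical exceedance probabilities; ``cutoffs[c]`` is the component
    decision threshold.  ``t_normalizer`` carries the network-wide min-max
    constants so scoring does not need the training network again.
    """

    samples: dict[str, dict[str, np.ndarray]]
    cutoffs: dict[str, float]
    t_normalizer: TNormalizer | None
    meta_cutoff: float = DEFAULT_META_CUTOFF

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "samples": {
                c: {lbl: np.asarray(v, dtype=float).tolist()
                    for lbl, v in by_label.items()}
                for c, by_label in self.samples.items()
            },
            "cutoffs": dict(self.cutoffs),
            "t_normalizer": (
                None if self.t_normalizer is None
                else {"t_min": self.t_normalizer.t_min,
                      "t_max": self.t_normalizer.t_max}
            ),
            "meta_cutoff": self.meta_cutoff,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        doc = json.loads(Path(path).read_text())
        norm = doc["t_normalizer"]
        return cls(
            samples={
                c: {lbl: np.asarray(v, dtype=float)
                    for lbl, v in by_label.items()}
                for c, by_label in doc["samples"].items()
            },
            cutoffs=dict(doc["cutoffs"]),
            t_normalizer=None if norm is None else TNormalizer(**norm),
            meta_cutoff=float(doc["meta_cutoff"]),
        )


def tail_probability(sorted_sample: Sequence[float] | np.ndarray, x: float) -> float:
    """Fraction of sample values *strictly* greater than ``x``.

    An empirical complementary CDF step function; the sample must be
    sorted ascending and nonempty.
    """
    sample = np.asarray(sorted_sample, dtype=float)
    if sample.size == 0:
        raise FormatError("empty sample: tail probability undefined")
    idx = np.searchsorted(sample, x, side="right")
    return float(sample.size - idx) / sample.size


def component_weight(
    score: float | None, component: str, model: CalibrationModel
) -> float:
    """Condel weight of one component score under the calibration model.

    Absent scores weigh 0.  Present scores weigh 1 minus the opposite-class
    exceedance probability: the sharper the score contradicts the opposite
    class, the closer the weight is to 1.
    """
    if score is None:
        return 0.0
    if component not in model.samples:
        raise FormatError(f"model has no training samples for component {component}")
    by_label = model.samples[component]
    if not len(by_label.get("neutral", ())) or not len(by_label.get("deleterious", ())):
        raise FormatError(
            f"component {component}: both class samples are required"
        )
    theta = model.cutoffs[component]
    if score >= theta:
        return 1.0 - tail_probability(by_label["neutral"], score)
    return 1.0 - tail_probability(by_label["deleterious"], score)


def was(components: Mapping[str, tuple[float, float]]) -> tuple[float, bool]:
    """Weighted average score over (score, weight) pairs.

    Returns ``(score, unscorable)``; when every weight is 0 the score is
    defined as 0.0 and the unscorable flag is set, so downstream ranking
    can distinguish "no evidence" from "evidence of neutrality".
    """
    active = []
    for score, weight in components.values():
        if weight < 0:
            raise ValueError("negative component weight")
        if weight > 0:
            active.append((score, weight))
    if not active:
        return 0.0, True
    if len(active) == 1:          # exact single-component identity
        return active[0][0], False
    num = sum(s * w for s, w in active)
    den = sum(w for _, w in active)
    return num / den, False


def _component_columns(
    scored: Iterable[ScoreVector],
) -> dict[str, dict[str, list[float]]]:
    cols: dict[str, dict[str, list[float]]] = {
        c: {"neutral": [], "deleterious": []} for c in COMPONENTS
    }
    for sv in scored:
        lbl = sv.sap.label
        if lbl not in ("neutral", "deleterious"):
            continue
        for c, value in sv.present_scores().items():
            cols[c][lbl].append(value)
    return cols


def calibrate(
    training: Sequence[ScoreVector],
    config: CalibrationConfig | None = None,
    t_normalizer: TNormalizer | None = None,
) -> CalibrationModel:
    """Build a :class:`CalibrationModel` from labelled, component-scored SAPs.

    Both classes must be present.  Per-component per-class score samples
    are stored sorted (so the model is invariant to training-row order);
    cutoffs come from the configuration, with theta_T optionally re-derived
    by Youden's J on the training T-scores.
    """
    config = config or CalibrationConfig()
    labels = {sv.sap.label for sv in training}
    if not {"neutral", "deleterious"} <= labels:
        raise FormatError(
            "calibration requires both deleterious and neutral training SAPs"
        )
    cols = _component_columns(training)
    samples = {
        c: {lbl: np.sort(np.asarray(v, dtype=float))
            for lbl, v in by_label.items()}
        for c, by_label in cols.items()
    }
    cutoffs = dict(DEFAULT_CUTOFFS)
    cutoffs.update(config.cutoffs)
    if config.youden_t_cutoff:
        from .evaluation import youden_threshold

        t_scores = [sv.t_norm for sv in training if sv.t_norm is not None
                    and sv.sap.label in ("neutral", "deleterious")]
        t_labels = [1 if sv.sap.label == "deleterious" else 0
                    for sv in training if sv.t_norm is not None
                    and sv.sap.label in ("neutral", "deleterious")]
        cutoffs["T"] = youden_threshold(t_scores, t_labels)
    return CalibrationModel(
        samples=samples,
        cutoffs=cutoffs,
        t_normalizer=t_normalizer,
        meta_cutoff=config.meta_cutoff,
    )


def compute_components(
    sap: SapRecord,
    network: PpiNetwork | None,
    interfaces: InterfaceMap | None,
    sift_map: Mapping[SiftKey, float] | None,
    t_normalizer: TNormalizer | None,
) -> ScoreVector:
    """Fill the raw component scores of one SAP (no weights or meta yet).

    Any evidence source passed as ``None`` leaves its component absent.
    """
    sv = ScoreVector(sap=sap)
    sv.s_score = s_score(sift_for(sap, sift_map))
    if interfaces is not None:
        sv.i_score = i_score(sap, interfaces)
    if network is not None and t_normalizer is not None:
        sv.t_raw = raw_t_score(network, sap.protein_id)
        sv.t_norm = normalized_t(sv.t_raw, t_normalizer)
    return sv


def component_vectors(
    saps: Sequence[SapRecord],
    network: PpiNetwork,
    interfaces: InterfaceMap | None,
    sift_map: Mapping[SiftKey, float] | None,
) -> tuple[list[ScoreVector], TNormalizer]:
    """Fit the T normalizer on the network and component-score all SAPs."""
    norm = fit_t_normalizer(network)
    return (
        [compute_components(s, network, interfaces, sift_map, norm)
         for s in saps],
        norm,
    )


def finalize_score(sv: ScoreVector, model: CalibrationModel) -> ScoreVector:
    """Attach Condel weights, the meta-score and the predicted class."""
    weights = {
        "S": component_weight(sv.s_score, "S", model),
        "T": component_weight(sv.t_norm, "T", model),
        "I": component_weight(
            None if sv.i_score is None else float(sv.i_score), "I", model
        ),
    }
    sv.w_s, sv.w_t, sv.w_i = weights["S"], weights["T"], weights["I"]
    present = sv.present_scores()
    sv.meta_score, sv.unscorable = was(
        {c: (present[c], weights[c]) for c in present}
    )
    sv.predicted_class = (
        "deleterious" if sv.meta_score >= model.meta_cutoff else "neutral"
    )
    return sv


def score_sap(
    sap: SapRecord,
    network: PpiNetwork | None,
    interfaces: InterfaceMap | None,
    sift_map: Mapping[SiftKey, float] | None,
    model: CalibrationModel,
) -> ScoreVector:
    """Score one SAP end to end: components, weights, meta-score, class."""
    sv = compute_components(sap, network, interfaces, sift_map,
                            model.t_normalizer)
    return finalize_score(sv, model)


def score_saps(
    saps: Sequence[SapRecord],
    network: PpiNetwork | None,
    interfaces: InterfaceMap | None,
    sift_map: Mapping[SiftKey, float] | None,
    model: CalibrationModel,
) -> list[ScoreVector]:
    """Vector convenience wrapper over :func:`score_sap`."""
    return [score_sap(s, network, interfaces, sift_map, model) for s in saps]
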