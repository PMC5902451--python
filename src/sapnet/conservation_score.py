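"""Conservation score (S-score): one minus an external SIFT tolerance.

SIFT assigns each substitution a tolerance probability in [0, 1]; low
values mean the change is rarely seen across homologues.  The S-score
flips the direction so that higher means more deleterious:

    S = 1 - SIFT

SIFT itself is never run here — its output is consumed either from the
``sift_score`` column of the SAP table or from a sidecar TSV keyed by
(protein, position, mutant residue).  When both provide a value for the
same SAP, the sidecar wins and the conflict is logged.  A SAP with no
SIFT output at all keeps S absent, which downstream gives the component a
weight of zero.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .io_formats import FormatError, SapRecord

logger = logging.getLogger(__name__)

SiftKey = tuple[str, int, str]


def s_score(sift: float | None) -> float | None:
    """Map a SIFT tolerance probability to the S-score (1 - SIFT).

    ``None`` passes through as ``None`` (no conservation evidence).
    """
    if sift is None:
        return None
    if not (0.0 <= sift <= 1.0):
        raise FormatError(f"SIFT score {sift} outside [0, 1]")
    return 1.0 - sift


def read_sift_scores(path: str | Path) -> dict[SiftKey, float]:
    """Read a sidecar SIFT table into a (protein, position, mut_aa) lookup.

    Duplicate keys with the same value deduplicate silently; duplicate
    keys with differing values are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"protein_id": str, "mut_aa": str})
    required = ["protein_id", "position", "mut_aa", "sift_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out: dict[SiftKey, float] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        value = float(row.sift_score)
        if not (0.0 <= value <= 1.0):
            raise FormatError(
                f"{path}: row {row_no}: sift_score {value} outside [0, 1]"
            )
        key = (row.protein_id, int(row.position), row.mut_aa)
        if key in out and out[key] != value:
            raise FormatError(
                f"{path}: row {row_no}: conflicting duplicate for {key}: "
                f"{out[key]} vs {value}"
            )
        out[key] = value
    return out


def sift_for(sap: SapRecord, sift_map: dict[SiftKey, float] | None) -> float | None:
    """Resolve the SIFT value for a SAP; the sidecar map beats the record.

    Logs when the two sources disagree.
    """
    from_map = None
    if sift_map is not None:
        from_map = sift_map.get((sap.protein_id, sap.position, sap.mut_aa))
    if from_map is not None:
        if sap.sift_score is not None and sap.sift_score != from_map:
            logger.info(
                "SIFT conflict for %s:%d%s: table %.4f vs sidecar %.4f; "
                "sidecar wins",
                sap.protein_id, sap.position, sap.mut_aa,
                sap.sift_score, from_map,
            )
        return from_map
    return sap.sift_score
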