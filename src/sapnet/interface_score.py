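"""Interface score (I-score): does a SAP sit at an annotated 3D interface?

A substitution at the physical contact surface between two interacting
proteins can disrupt the interaction, so interface membership is treated
as binary deleteriousness evidence: 1 if the mutated position falls inside
any annotated interface range of its protein, else 0.  A protein absent
from the interface annotation scores 0 — absence of structural coverage is
a defined zero, not an error.

Membership is purely positional: the residue identity of the substitution
plays no role, and overlapping or duplicated ranges combine by OR.
"""

from __future__ import annotations

from .io_formats import InterfaceMap, SapRecord


def i_score(sap: SapRecord, interfaces: InterfaceMap) -> int:
    """Return 1 iff ``sap.position`` lies in an interface range of its protein.

    Ranges are 1-based inclusive on both ends.  Returns 0 when the protein
    has no interface annotation at all.
    """
    for rec in interfaces.records_for(sap.protein_id):
        if rec.contains(sap.position):
            return 1
    return 0


def affected_partners(sap: SapRecord, interfaces: InterfaceMap) -> set[str]:
    """Interaction partners whose interface with the protein contains the SAP.

    Empty exactly when :func:`i_score` is 0.  Only ranges annotated on the
    SAP's own side of the pair count; a range on the partner's side says
    nothing about this protein's residues.
    """
    return {
        rec.partner
        for rec in interfaces.records_for(sap.protein_id)
        if rec.contains(sap.position)
    }
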