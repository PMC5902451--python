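"""Readers, writers and domain types for every file the tool touches.

All residue coordinates are 1-based inclusive (protein convention).
Protein accessions are opaque, case-sensitive strings; no identifier
mapping is attempted.

File dialects
-------------
* Edge list: 2-column TSV (``a<TAB>b``) or 3-column SIF
  (``a<TAB>type<TAB>b``; the middle column is ignored).
* Cancer gene list: plain text, one accession per line, ``#`` comments.
* Interface table: TSV with header columns
  ``protein_a  protein_b  protein  start  end`` (one range per row).
* SAP table: TSV with header; required columns ``protein_id position
  wt_aa mut_aa``; optional ``sift_score sample_id label``.
* Score table: TSV written by :func:`write_score_table`, numeric fields
  at 6 decimal places.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

LABELS = ("deleterious", "neutral", "unknown")

#: decimal places used when serializing score tables
SCORE_PRECISION = 6


class FormatError(ValueError):
    """Raised for malformed or invalid input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SapRecord:
    """One candidate single amino acid polymorphism (missense substitution).

    Parameters
    ----------
    protein_id : accession of the mutated protein.
    position : 1-based residue index of the substitution.
    wt_aa, mut_aa : one-letter wild-type / mutant residues (must differ).
    sift_score : externally computed SIFT tolerance probability in [0, 1],
        or ``None`` when no conservation evidence is available.
    sample_id : tumour sample the SAP was observed in, if any.
    label : training label, one of ``deleterious``, ``neutral``, ``unknown``.
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    sift_score: float | None = None
    sample_id: str | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("empty protein_id")
        if self.position < 1:
            raise FormatError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )
        for aa, name in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AMINO_ACIDS:
                raise FormatError(
                    f"{self.protein_id}:{self.position}: {name} {aa!r} is not a "
                    "standard one-letter residue code"
                )
        if self.wt_aa == self.mut_aa:
            raise FormatError(
                f"{self.protein_id}:{self.position}: silent substitution "
                f"{self.wt_aa}->{self.mut_aa}"
            )
        if self.sift_score is not None and not (0.0 <= self.sift_score <= 1.0):
            raise FormatError(
                f"{self.protein_id}:{self.position}: sift_score "
                f"{self.sift_score} outside [0, 1]"
            )
        if self.label not in LABELS:
            raise FormatError(f"unknown label {self.label!r}")

    @property
    def key(self) -> tuple:
        """Identity used for de-duplication."""
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa,
                self.sample_id)


class PpiNetwork:
    """Undirected protein-protein interaction graph with a cancer-node subset.

    Self-loops and duplicate (unordered) edges are rejected by the
    constructor; the file readers drop them silently with a logged count
    before construction.  ``cancer_nodes`` must be a subset of the node set.

    The all-sources unweighted shortest-path (hop count) matrix is computed
    lazily by breadth-first search and cached, since topology scoring needs
    distances from every node.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        cancer_nodes: Iterable[str] = (),
        extra_nodes: Iterable[str] = (),
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(extra_nodes)
        for a, b in edges:
            if a == b:
                raise FormatError(f"self-loop on {a!r}")
            if g.has_edge(a, b):
                raise FormatError(f"duplicate edge {a!r}-{b!r}")
            g.add_edge(a, b)
        self.graph = g
        self.cancer_nodes = frozenset(cancer_nodes)
        missing = self.cancer_nodes - set(g.nodes)
        if missing:
            raise FormatError(
                f"cancer nodes not in network: {sorted(missing)[:5]} ..."
            )
        self._dist: np.ndarray | None = None
        self._index: dict[str, int] | None = None

    # -- basic views --------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def with_cancer_nodes(self, cancer_nodes: Iterable[str]) -> "PpiNetwork":
        """Return a copy of this network with the cancer subset replaced."""
        net = PpiNetwork.__new__(PpiNetwork)
        net.graph = self.graph
        net.cancer_nodes = frozenset(cancer_nodes)
        missing = net.cancer_nodes - set(self.graph.nodes)
        if missing:
            raise FormatError(
                f"cancer nodes not in network: {sorted(missing)[:5]} ..."
            )
        net._dist = self._dist
        net._index = self._index
        return net

    # -- distances ----------------------------------------------------------

    @property
    def node_index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {n: i for i, n in enumerate(sorted(self.graph.nodes))}
        return self._index

    def distance_matrix(self) -> np.ndarray:
        """Hop-count matrix over ``sorted(nodes)``; ``inf`` where unreachable.

        Computed once by breadth-first search (unit edge weights) and cached.
        """
        if self._dist is None:
            order = sorted(self.graph.nodes)
            adj = nx.to_scipy_sparse_array(self.graph, nodelist=order,
                                           format="csr", dtype=np.int8)
            self._dist = _csgraph_shortest_path(
                csr_matrix(adj), method="D", unweighted=True, directed=False
            )
        return self._dist

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass(frozen=True)
class InterfaceRecord:
    """Interface residue ranges of one protein within one interaction pair."""

    protein_a: str
    protein_b: str
    protein: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.protein not in (self.protein_a, self.protein_b):
            raise FormatError(
                f"protein {self.protein!r} is not a member of the pair "
                f"({self.protein_a!r}, {self.protein_b!r})"
            )
        for start, end in self.ranges:
            if start > end:
                raise FormatError(
                    f"inverted range {start}-{end} on {self.protein!r}"
                )
            if start < 1:
                raise FormatError(f"range start {start} < 1 on {self.protein!r}")

    @property
    def partner(self) -> str:
        return self.protein_b if self.protein == self.protein_a else self.protein_a

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.ranges)


class InterfaceMap:
    """Interface annotation: per (unordered pair, protein), residue ranges.

    Lookup by protein is the common access pattern (``records_for``); the
    pair is unordered, so (P, Q) and (Q, P) rows aggregate.
    """

    def __init__(self, records: Iterable[InterfaceRecord] = ()) -> None:
        self._by_protein: dict[str, list[InterfaceRecord]] = {}
        self._records: list[InterfaceRecord] = []
        for rec in records:
            self._records.append(rec)
            self._by_protein.setdefault(rec.protein, []).append(rec)

    @property
    def records(self) -> tuple[InterfaceRecord, ...]:
        return tuple(self._records)

    def records_for(self, protein: str) -> tuple[InterfaceRecord, ...]:
        return tuple(self._by_protein.get(protein, ()))

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class ScoreVector:
    """Per-SAP component scores, Condel weights, meta-score and call.

    ``None`` component scores mean the evidence source is absent for this
    SAP; the corresponding weight is 0 by construction.  ``unscorable`` is
    set when every component weight is 0, to distinguish "no evidence" from
    "evidence of neutrality".
    """

    sap: SapRecord
    s_score: float | None = None
    t_raw: float | None = None
    t_norm: float | None = None
    i_score: int | None = None
    w_s: float = 0.0
    w_t: float = 0.0
    w_i: float = 0.0
    meta_score: float = 0.0
    predicted_class: str = "neutral"
    unscorable: bool = False
    rank: int | None = None

    def present_scores(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.s_score is not None:
            out["S"] = self.s_score
        if self.t_norm is not None:
            out["T"] = self.t_norm
        if self.i_score is not None:
            out["I"] = float(self.i_score)
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lines.append((lineno, line))
    return lines


def read_edge_list(path: str | Path, format: str = "tsv") -> PpiNetwork:
    """Read an undirected edge list (TSV or SIF) into a :class:`PpiNetwork`.

    Self-loops and duplicate (unordered) edges are dropped silently with a
    logged count.  The node set is the union of the endpoint columns; the
    cancer subset is left empty (see :func:`read_cancer_genes`).
    """
    if format not in ("tsv", "sif"):
        raise FormatError(f"unknown edge-list format {format!r}")
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty edge list")
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    nodes: set[str] = set()
    n_self = n_dup = 0
    for lineno, line in lines:
        cols = line.split("\t")
        if len(cols) == 1:
            cols = line.split()
        if len(cols) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >=2 columns")
        if format == "sif" and len(cols) >= 3:
            a, b = cols[0], cols[2]
        else:
            a, b = cols[0], cols[1]
        nodes.update((a, b))
        if a == b:
            n_self += 1
            continue
        key = frozenset((a, b))
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append((a, b))
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    return PpiNetwork(edges, extra_nodes=nodes)


def read_cancer_genes(path: str | Path, network: PpiNetwork) -> PpiNetwork:
    """Attach the cancer-node subset from a one-accession-per-line file.

    Entries absent from the network are counted and logged, not an error;
    an empty resulting subset is an error because the topology score is then
    undefined network-wide.
    """
    entries = {line for _, line in _data_lines(path)}
    in_net = entries & set(network.graph.nodes)
    off = len(entries) - len(in_net)
    if off:
        logger.info("%s: %d cancer gene(s) not present in the network", path, off)
    if not in_net:
        raise FormatError(
            f"{path}: no listed cancer gene is present in the network; "
            "the topology score is undefined"
        )
    return network.with_cancer_nodes(in_net)


def read_interface_table(path: str | Path) -> InterfaceMap:
    """Read interface residue ranges; rows group by (unordered pair, protein).

    Ranges are kept exactly as given (no merging); an inverted range or a
    ``protein`` outside its pair is an error naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["protein_a", "protein_b", "protein", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    grouped: dict[tuple[frozenset, str], list[tuple[int, int]]] = {}
    order: list[tuple[frozenset, str]] = []
    pair_names: dict[frozenset, tuple[str, str]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise FormatError(f"{path}: row {row_no}: non-integer range") from exc
        if row.protein not in (row.protein_a, row.protein_b):
            raise FormatError(
                f"{path}: row {row_no}: protein {row.protein!r} not in pair "
                f"({row.protein_a!r}, {row.protein_b!r})"
            )
        if start > end:
            raise FormatError(
                f"{path}: row {row_no}: inverted range {start}-{end}"
            )
        pair = frozenset((row.protein_a, row.protein_b))
        pair_names.setdefault(pair, (row.protein_a, row.protein_b))
        key = (pair, row.protein)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((start, end))
    records = []
    for pair, protein in order:
        a, b = pair_names[pair]
        records.append(
            InterfaceRecord(a, b, protein, tuple(grouped[(pair, protein)]))
        )
    return InterfaceMap(records)


def read_sap_table(path: str | Path, strict: bool = True) -> list[SapRecord]:
    """Read a SAP candidate table into validated :class:`SapRecord` objects.

    In strict mode (default) any invalid row rejects the whole file with a
    report naming every bad row; in lenient mode invalid rows are dropped
    with a logged count.  Duplicate (protein, position, wt, mut, sample)
    rows collapse to one, logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["protein_id", "position", "wt_aa", "mut_aa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records: list[SapRecord] = []
    seen: set[tuple] = set()
    errors: list[str] = []
    n_dup = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sift = getattr(row, "sift_score", None)
            if sift is not None and not (isinstance(sift, float) and math.isnan(sift)):
                sift = float(sift)
            else:
                sift = None
            sample = getattr(row, "sample_id", None)
            if isinstance(sample, float) and math.isnan(sample):
                sample = None
            label = getattr(row, "label", None)
            if label is None or (isinstance(label, float) and math.isnan(label)):
                label = "unknown"
            rec = SapRecord(
                protein_id=row.protein_id,
                position=int(row.position),
                wt_aa=str(row.wt_aa),
                mut_aa=str(row.mut_aa),
                sift_score=sift,
                sample_id=sample,
                label=label,
            )
        except (FormatError, ValueError) as exc:
            errors.append(f"row {row_no}: {exc}")
            continue
        if rec.key in seen:
            n_dup += 1
            continue
        seen.add(rec.key)
        records.append(rec)
    if errors:
        if strict:
            raise FormatError(
                f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
            )
        logger.warning("%s: dropped %d invalid row(s)", path, len(errors))
    if n_dup:
        logger.info("%s: collapsed %d duplicate row(s)", path, n_dup)
    if not records:
        raise FormatError(f"{path}: no valid SAP records")
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = [
    "protein_id", "position", "wt_aa", "mut_aa",
    "s_score", "t_raw", "t_norm", "i_score",
    "w_s", "w_t", "w_i", "meta_score", "predicted_class", "rank",
]


def _fmt(x: float | int | None) -> str:
    if x is None:
        return "NA"
    if isinstance(x, int):
        return str(x)
    return f"{x:.{SCORE_PRECISION}f}"


def rank_scores(scores: Sequence[ScoreVector]) -> list[ScoreVector]:
    """Sort by meta-score descending; ties broken by (protein_id, position)."""
    ordered = sorted(
        scores,
        key=lambda sv: (-sv.meta_score, sv.sap.protein_id, sv.sap.position),
    )
    for i, sv in enumerate(ordered, start=1):
        sv.rank = i
    return ordered


def write_score_table(path: str | Path, scores: Sequence[ScoreVector]) -> None:
    """Write the ranked score table (TSV, 6-decimal numeric precision).

    Rows are sorted by meta-score descending with deterministic
    (protein_id, position) tie-breaking; rank is 1-based.
    """
    if not scores:
        raise FormatError("refusing to write an empty score table")
    ordered = rank_scores(list(scores))
    with open(path, "w") as fh:
        fh.write("# residue coordinates are 1-based inclusive\n")
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for sv in ordered:
            row = [
                sv.sap.protein_id, str(sv.sap.position), sv.sap.wt_aa,
                sv.sap.mut_aa, _fmt(sv.s_score), _fmt(sv.t_raw),
                _fmt(sv.t_norm),
                "NA" if sv.i_score is None else str(sv.i_score),
                _fmt(sv.w_s), _fmt(sv.w_t), _fmt(sv.w_i),
                _fmt(sv.meta_score), sv.predicted_class, str(sv.rank),
            ]
            fh.write("\t".join(row) + "\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score table back as a DataFrame (round-trip partner)."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                       header=0, names=_SCORE_COLUMNS, skiprows=1)


def write_sap_table(path: str | Path, saps: Sequence[SapRecord]) -> None:
    """Write SAP records as a TSV readable by :func:`read_sap_table`."""
    with open(path, "w") as fh:
        fh.write("# residue coordinates are 1-based inclusive\n")
        fh.write("protein_id\tposition\twt_aa\tmut_aa\tsift_score\t"
                 "sample_id\tlabel\n")
        for s in saps:
            fh.write("\t".join([
                s.protein_id, str(s.position), s.wt_aa, s.mut_aa,
                "NA" if s.sift_score is None else f"{s.sift_score:.{SCORE_PRECISION}f}",
                s.sample_id or "NA",
                s.label,
            ]) + "\n")


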