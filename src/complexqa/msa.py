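"""Complex MSA assembly and alignment-depth measurement.

Per-chain alignments (A3M/FASTA) are combined into an unpaired complex
alignment: each row covers one chain and is padded with gaps equal to the
length of the partner chain, giving a block-diagonal alignment whose rows all
have length lenA + lenB. A residue index shift (default 200) is carried as
metadata for the chain junction, the trick used to signal a chain break to a
single-chain predictor. Rows of putatively co-evolving orthologs concatenated
across both chains can be appended as paired rows.

Alignment depth is summarized as Neff: the number of clusters obtained by
greedy incremental clustering at 62% sequence identity (the CD-HIT convention:
identity = matches / shorter ungapped length, rows visited longest-first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("complexqa")

DEFAULT_RESIDUE_OFFSET = 200
NEFF_IDENTITY_THRESHOLD = 0.62
PREFILTER_MIN_COVERAGE = 50.0  # percent of query columns covered
PREFILTER_MIN_IDENTITY = 20.0  # percent identity to the query over aligned columns

GAP = "-"


class MsaError(ValueError):
    pass


@dataclass
class Alignment:
    """A query-anchored alignment; matrix rows have length ``query_length``.

    ``raw_rows`` keeps A3M lowercase insertion characters; ``rows`` is the
    matrix view with insertions removed.
    """

    rows: list[str]
    labels: list[str]
    raw_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("empty alignment")
        if not self.raw_rows:
            self.raw_rows = list(self.rows)
        q = self.rows[0]
        if GAP in q:
            raise MsaError("query row may not contain gaps")
        for i, r in enumerate(self.rows):
            if len(r) != len(q):
                raise MsaError(f"row {i} length {len(r)} != query length {len(q)}")

    @property
    def query_length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class CombinedMsa:
    """Block-diagonal (plus optional paired) complex alignment for two chains."""

    rows: list[str]
    labels: list[str]
    origin: list[str]  # per-row: 'query', 'chainA', 'chainB' or 'paired'
    len_a: int
    len_b: int
    residue_offset: int = DEFAULT_RESIDUE_OFFSET

    def __post_init__(self) -> None:
        width = self.len_a + self.len_b
        for i, r in enumerate(self.rows):
            if len(r) != width:
                raise MsaError(f"row {i} length {len(r)} != lenA+lenB = {width}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class DepthSummary:
    n_rows: int
    neff: int


def read_a3m(path: str | Path) -> Alignment:
    """Read an A3M/FASTA alignment.

    Lowercase characters are A3M insertions relative to the query: they are
    removed for the matrix view and preserved in the raw rows. '.' gap
    characters are normalized to '-'.
    """
    text = Path(path).read_text()
    labels: list[str] = []
    raw: list[str] = []
    cur: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if labels:
                raw.append("".join(cur))
            labels.append(line[1:].strip() or f"seq{len(labels)}")
            cur = []
        else:
            cur.append(line.replace(".", GAP))
    if labels:
        raw.append("".join(cur))
    if not raw or not raw[0]:
        raise MsaError(f"empty alignment file: {path}")
    rows = ["".join(c for c in r if not c.islower()) for r in raw]
    return Alignment(rows=rows, labels=labels, raw_rows=raw)


def write_a3m(rows: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(labels, rows):
            fh.write(f">{lab}\n{row}\n")


def combine_unpaired(msa_a: Alignment, msa_b: Alignment,
                     residue_offset: int = DEFAULT_RESIDUE_OFFSET) -> CombinedMsa:
    """Build the unpaired complex alignment from two per-chain alignments.

    The query row is the concatenation of both queries; every other chain-A
    row gets lenB trailing gaps and every chain-B row lenA leading gaps.
    """
    la, lb = msa_a.query_length, msa_b.query_length
    rows = [msa_a.rows[0] + msa_b.rows[0]]
    labels = ["query"]
    origin = ["query"]
    for row, lab in zip(msa_a.rows[1:], msa_a.labels[1:]):
        rows.append(row + GAP * lb)
        labels.append(lab)
        origin.append("chainA")
    for row, lab in zip(msa_b.rows[1:], msa_b.labels[1:]):
        rows.append(GAP * la + row)
        labels.append(lab)
        origin.append("chainB")
    return CombinedMsa(rows=rows, labels=labels, origin=origin,
                       len_a=la, len_b=lb, residue_offset=residue_offset)


def add_paired_rows(combined: CombinedMsa,
                    paired: Iterable[tuple[str, str]],
                    labels: Sequence[str] | None = None) -> CombinedMsa:
    """Append rows whose two segments are co-evolving ortholog pairs.

    Paired-only alignments are built by starting from a combined MSA holding
    just the query row.
    """
    rows = list(combined.rows)
    labs = list(combined.labels)
    origin = list(combined.origin)
    for i, (seq_a, seq_b) in enumerate(paired):
        if len(seq_a) != combined.len_a or len(seq_b) != combined.len_b:
            raise MsaError(
                f"paired row {i}: segment lengths ({len(seq_a)}, {len(seq_b)}) "
                f"!= ({combined.len_a}, {combined.len_b})"
            )
        rows.append(seq_a + seq_b)
        labs.append(labels[i] if labels else f"paired{i}")
        origin.append("paired")
    return CombinedMsa(rows=rows, labels=labs, origin=origin,
                       len_a=combined.len_a, len_b=combined.len_b,
                       residue_offset=combined.residue_offset)


def prefilter(aln: Alignment,
              min_coverage: float = PREFILTER_MIN_COVERAGE,
              min_identity: float = PREFILTER_MIN_IDENTITY) -> Alignment:
    """Drop rows below the coverage / identity thresholds (query always kept).

    Coverage is the non-gap fraction over query columns; identity is measured
    against the query over mutually non-gap columns.
    """
    if not (0 <= min_coverage <= 100 and 0 <= min_identity <= 100):
        raise ValueError("thresholds must be percentages in [0, 100]")
    query = aln.rows[0]
    keep = [0]
    for i, row in enumerate(aln.rows[1:], start=1):
        n_cov = sum(1 for c in row if c != GAP)
        coverage = 100.0 * n_cov / len(query)
        aligned = [(q, c) for q, c in zip(query, row) if c != GAP and q != GAP]
        identity = (100.0 * sum(1 for q, c in aligned if q == c) / len(aligned)
                    if aligned else 0.0)
        if coverage >= min_coverage and identity >= min_identity:
            keep.append(i)
    return Alignment(rows=[aln.rows[i] for i in keep],
                     labels=[aln.labels[i] for i in keep],
                     raw_rows=[aln.raw_rows[i] for i in keep])


def _pair_identity(a: str, b: str) -> float:
    """matches / shorter ungapped length, over mutually non-gap columns."""
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    la = sum(1 for x in a if x != GAP)
    lb = sum(1 for x in b if x != GAP)
    shorter = min(la, lb)
    return matches / shorter if shorter else 0.0


def neff(aln: Alignment | Sequence[str],
         identity_threshold: float = NEFF_IDENTITY_THRESHOLD) -> DepthSummary:
    """Alignment depth as a greedy cluster count at the identity threshold.

    Rows are visited in order of decreasing ungapped length; each joins the
    first existing cluster whose representative shares at least the threshold
    identity (matches divided by the shorter ungapped length), otherwise it
    founds a new cluster. Neff is the number of clusters.
    """
    rows = list(aln.rows) if isinstance(aln, Alignment) else list(aln)
    if not rows:
        raise MsaError("empty alignment")
    order = sorted(range(len(rows)),
                   key=lambda i: (-sum(1 for c in rows[i] if c != GAP), i))
    reps: list[str] = []
    for i in order:
        row = rows[i]
        for rep in reps:
            if _pair_identity(row, rep) >= identity_threshold:
                break
        else:
            reps.append(row)
    return DepthSummary(n_rows=len(rows), neff=len(reps))


def depth_report(msa_a: Alignment, msa_b: Alignment,
                 combined: CombinedMsa | None = None,
                 identity_threshold: float = NEFF_IDENTITY_THRESHOLD) -> dict:
    """Per-chain and combined depth summaries as a flat dict (TSV-friendly)."""
    out = {
        "chainA_n_rows": msa_a.n_rows,
        "chainA_neff": neff(msa_a, identity_threshold).neff,
        "chainB_n_rows": msa_b.n_rows,
        "chainB_neff": neff(msa_b, identity_threshold).neff,
    }
    if combined is None:
        combined = combine_unpaired(msa_a, msa_b)
    out["combined_n_rows"] = combined.n_rows
    out["combined_neff"] = neff(combined.rows, identity_threshold).neff
    paired_rows = [r for r, o in zip(combined.rows, combined.origin) if o == "paired"]
    if paired_rows:
        out["paired_n_rows"] = len(paired_rows)
        out["paired_neff"] = neff(paired_rows, identity_threshold).neff
    return out
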