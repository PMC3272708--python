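"""Filtering of precomputed pairwise-alignment hit tables.

Orthologs between the reconstruction's organism and a reference genome are
called as reciprocal best hits (RBH): a pair (q, s) is kept when s is q's
best *passing* hit in the forward search and q is s's best passing hit in
the reverse search. Passing means E-value < 1e-6, percent identity > 30 and
query coverage > 60% (all strict, as printed); best means lowest E-value,
ties broken by higher bitscore, then lexicographic subject id.

Homolog screening against essential-gene databases uses the same E-value
and identity thresholds but no coverage criterion.

Running the alignments themselves is out of scope: tables arrive in
BLAST ``outfmt 6``-style TSV plus a query-length sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd


@dataclass
class HitRecord:
    """One row of a pairwise alignment table."""

    query: str
    subject: str
    e_value: float
    percent_identity: float
    alignment_length: int
    query_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value on hit {self.query}->"
                             f"{self.subject}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent identity {self.percent_identity} out of [0, 100] "
                f"on hit {self.query}->{self.subject}")
        if self.alignment_length <= 0 or self.query_length <= 0:
            raise ValueError(f"non-positive length on hit {self.query}->"
                             f"{self.subject}")

    @property
    def coverage_pct(self) -> float:
        # alignment_length may exceed query_length when gapped; the record
        # is kept and coverage simply computed from the ratio.
        return 100.0 * self.alignment_length / self.query_length


@dataclass
class RbhCriteria:
    """Strict thresholds for a passing hit."""

    max_e: float = 1e-6
    min_identity_pct: float = 30.0
    min_coverage_pct: float = 60.0

    def __post_init__(self) -> None:
        if self.max_e <= 0 or self.min_identity_pct <= 0 \
                or self.min_coverage_pct <= 0:
            raise ValueError("all criteria must be positive")

    def passes(self, hit: HitRecord, use_coverage: bool = True) -> bool:
        ok = (hit.e_value < self.max_e
              and hit.percent_identity > self.min_identity_pct)
        if use_coverage:
            ok = ok and hit.coverage_pct > self.min_coverage_pct
        return ok


def read_hit_table(path: str, query_lengths: Optional[Dict[str, int]] = None
                   ) -> List[HitRecord]:
    """Read a BLAST outfmt-6-style TSV into hit records.

    Columns: qseqid, sseqid, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore (the standard 12). Query lengths
    come from ``query_lengths`` (id -> length) or a 13th ``qlen`` column.
    Malformed rows raise ``ValueError`` with the 1-based line number.
    """
    records: List[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 12:
                    raise ValueError(f"expected >= 12 columns, got "
                                     f"{len(fields)}")
                query, subject = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                if len(fields) >= 13:
                    qlen = int(fields[12])
                elif query_lengths is not None and query in query_lengths:
                    qlen = query_lengths[query]
                else:
                    raise ValueError(f"no query length for {query!r}")
                records.append(HitRecord(
                    query=query, subject=subject, e_value=evalue,
                    percent_identity=pident, alignment_length=length,
                    query_length=qlen, bitscore=bitscore))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed hit row: {exc}") from None
    return records


def write_hit_table(hits: Sequence[HitRecord], path: str) -> None:
    """Write hits as outfmt-6 TSV with a 13th qlen column."""
    rows = []
    for h in hits:
        rows.append((h.query, h.subject, h.percent_identity,
                     h.alignment_length, 0, 0, 1, h.alignment_length, 1,
                     h.alignment_length, h.e_value, h.bitscore,
                     h.query_length))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _best_passing(hits: Iterable[HitRecord], criteria: RbhCriteria
                  ) -> Dict[str, HitRecord]:
    """Best passing hit per query: lowest E, then highest bitscore, then
    lexicographic subject id."""
    best: Dict[str, HitRecord] = {}
    for hit in hits:
        if not criteria.passes(hit):
            continue
        cur = best.get(hit.query)
        if cur is None:
            best[hit.query] = hit
            continue
        key_new = (hit.e_value, -hit.bitscore, hit.subject)
        key_cur = (cur.e_value, -cur.bitscore, cur.subject)
        if key_new < key_cur:
            best[hit.query] = hit
    return best


def filter_rbh(forward: Sequence[HitRecord], reverse: Sequence[HitRecord],
               criteria: Optional[RbhCriteria] = None
               ) -> List[Tuple[str, str]]:
    """Reciprocal best gene pairs (query-of-forward, subject-of-forward).

    Symmetric: swapping the two tables returns the mirrored pairs.
    Tightening any criterion can only shrink the result.
    """
    criteria = criteria or RbhCriteria()
    best_fwd = _best_passing(forward, criteria)
    best_rev = _best_passing(reverse, criteria)
    pairs = []
    for q, hit in best_fwd.items():
        s = hit.subject
        back = best_rev.get(s)
        if back is not None and back.subject == q:
            pairs.append((q, s))
    return sorted(pairs)


def filter_homologs(hits: Sequence[HitRecord], max_e: float = 1e-6,
                    min_identity_pct: float = 30.0) -> List[str]:
    """Queries with at least one passing hit (no coverage criterion).

    This is the screen used against essential-gene databases: a query gene
    counts as having a homolog when any hit has E-value < ``max_e`` and
    identity > ``min_identity_pct``; the result is de-duplicated and sorted.
    """
    kept = {h.query for h in hits
            if h.e_value < max_e and h.percent_identity > min_identity_pct}
    return sorted(kept)
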