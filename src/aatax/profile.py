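"""Taxonomic profiles: per-k unique, non-unique and overall frequencies.

A profile aggregates matched k-mer occurrences per taxon at every k in the
matched range, with three normalisations:

* unique relative frequency h_U — occurrences of k-mers matching only this
  taxon, divided by all uniquely matched occurrences;
* non-unique relative frequency h — each k-mer's occurrence count split
  evenly among the taxa it matched (a k-mer found five times in three taxa
  adds 5/3 to each), divided by all matched occurrences;
* overall relative frequency — the same numerator divided by *all* input
  k-mer occurrences, matched or not, which guards against over-reading a
  sample that is mostly unknown to the index.

h_U and h each sum to 1 over taxa whenever anything matched at that k; the
overall frequencies sum to at most 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .identify import MatchTable
from .index import Index

__all__ = [
    "ProfileRow",
    "profile",
    "ambiguity_value",
    "apply_cutoff",
    "write_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileRow:
    tax_id: int
    name: str
    taxon_line: int
    # per-k maps, k -> value
    unique_count: dict = field(default_factory=dict)
    nonunique_weight: dict = field(default_factory=dict)
    h_unique: dict = field(default_factory=dict)
    h_nonunique: dict = field(default_factory=dict)
    overall: dict = field(default_factory=dict)


def profile(table: MatchTable, index: Index) -> list[ProfileRow]:
    """Aggregate a match table into per-taxon, per-k frequencies.

    Works from the per-prefix match evidence alone, so identification
    scoring may be skipped entirely.  At a k with no matches all
    frequencies are reported as 0 (never NaN).  Rows are ordered by
    descending non-unique frequency at the largest k, ties by tax_id.
    """
    ks = range(table.k_lower, table.k_upper + 1)
    rows: dict[int, ProfileRow] = {}

    def row_for(line: int) -> ProfileRow:
        if line not in rows:
            entry = index.content.entry_at(line)
            rows[line] = ProfileRow(tax_id=entry.tax_id, name=entry.name,
                                    taxon_line=line)
        return rows[line]

    unique_totals: dict[int, int] = {}
    matched_totals: dict[int, int] = {}
    for k in ks:
        per_v = table.prefix_taxa.get(k, {})
        unique_total = 0
        matched_total = 0
        for _v, (taxa, c) in per_v.items():
            matched_total += c
            if len(taxa) == 1:
                unique_total += c
            split = c / len(taxa)
            for t in taxa:
                row = row_for(t)
                row.nonunique_weight[k] = row.nonunique_weight.get(k, 0.0) + split
                if len(taxa) == 1:
                    row.unique_count[k] = row.unique_count.get(k, 0) + c
        unique_totals[k] = unique_total
        matched_totals[k] = matched_total
    for k in ks:
        input_total = table.input_occurrences.get(k, 0)
        for row in rows.values():
            u = row.unique_count.setdefault(k, 0)
            w = row.nonunique_weight.setdefault(k, 0.0)
            row.h_unique[k] = u / unique_totals[k] if unique_totals[k] else 0.0
            row.h_nonunique[k] = w / matched_totals[k] if matched_totals[k] else 0.0
            row.overall[k] = w / input_total if input_total else 0.0
    out = list(rows.values())
    out.sort(key=lambda r: (-r.h_nonunique.get(table.k_upper, 0.0), r.tax_id))
    return out


def ambiguity_value(index: Index) -> float:
    """Degree of k-mer redundancy in the index: (N − D)/N.

    N is the number of entries, D the number of distinct k-mer values; 0
    means no k-mer is shared between taxa, and the value approaches 1 as
    sharing grows.  (The quantity is named after the redundancy diagnostic
    the profile relies on; this particular formula is this package's own.)
    """
    n = len(index)
    if n == 0:
        return 0.0
    return (n - index.distinct_kmer_count()) / n


def apply_cutoff(rows: list[ProfileRow], threshold: float,
                 which: str = "nonunique", k: int | None = None) -> list[ProfileRow]:
    """Drop rows whose selected frequency at k falls below the threshold.

    No renormalisation is applied, so surviving values keep their original
    interpretation.  ``which`` is one of unique / nonunique / overall; ``k``
    defaults to the largest k in the profile.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not rows:
        return rows
    attr = {"unique": "h_unique", "nonunique": "h_nonunique",
            "overall": "overall"}[which]
    if k is None:
        k = max(rows[0].h_nonunique) if rows[0].h_nonunique else None
    kept = [r for r in rows if getattr(r, attr).get(k, 0.0) >= threshold]
    if rows and not kept:
        logger.warning("cutoff %g removed every taxon from the profile", threshold)
    return kept


def write_profile(rows: list[ProfileRow], out_path, k_lower: int, k_upper: int) -> None:
    """TSV profile: one row per taxon, one column group per k."""
    ks = list(range(k_lower, k_upper + 1))
    cols = ["tax_id", "name"]
    for k in ks:
        cols += [f"unique_count_k{k}", f"h_unique_k{k}",
                 f"h_nonunique_k{k}", f"overall_k{k}"]
    with open(Path(out_path), "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fields = [str(r.tax_id), r.name]
            for k in ks:
                fields += [str(r.unique_count.get(k, 0)),
                           f"{r.h_unique.get(k, 0.0):.6g}",
                           f"{r.h_nonunique.get(k, 0.0):.6g}",
                           f"{r.overall.get(k, 0.0):.6g}"]
            fh.write("\t".join(fields) + "\n")
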