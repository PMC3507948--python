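"""Reciprocal-best-hit (RBH) orthology calls from paired hit tables.

Two proteins in different proteomes that find each other as top similarity
hit are operationally orthologous (strict RBH). A relaxed variant accepts
reciprocation anywhere within the top-k hits both ways — useful when a
draft proteome's fragmentary models scramble the hit ranking. A gene
family is called absent from the partner proteome only when every member's
call is absent (this is how a loss, e.g. of a whole photoisomerase family,
is asserted).

Ranking is by descending bitscore (database-size independent), with
ascending e-value and then subject id as tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from gainscan.errors import DomainError, InvariantError
from gainscan.io_formats import HitTable

STRICT = "strict-RBH"
ABSENT = "absent"


def relaxed_status(k: int) -> str:
    return f"relaxed-RBH({k})"


@dataclass(frozen=True)
class OrthologyCall:
    query_id: str
    partner_id: str | None
    status: str  # strict-RBH | relaxed-RBH(k) | absent
    evidence: tuple[tuple[str, str, float, float], ...] = ()

    @property
    def present(self) -> bool:
        return self.status != ABSENT


def top_hits(table: HitTable, query_id: str, k: int = 1) -> list[str]:
    """Up to ``k`` best subjects for a query, self-hits excluded.

    Sort order: bitscore desc, e-value asc, subject id asc. A query absent
    from the table yields an empty list.
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    rows = table.rows
    sub = rows[(rows["query"] == query_id) & (rows["subject"] != query_id)]
    if not len(sub):
        return []
    sub = sub.sort_values(
        by=["bitscore", "evalue", "subject"], ascending=[False, True, True]
    )
    return sub["subject"].head(k).tolist()


def _hit_row(table: HitTable, query: str, subject: str):
    rows = table.rows
    sel = rows[(rows["query"] == query) & (rows["subject"] == subject)]
    if not len(sel):
        return None
    r = sel.iloc[0]
    return (r["query"], r["subject"], float(r["bitscore"]), float(r["evalue"]))


def reciprocal_best(ab: HitTable, ba: HitTable, k: int = 3) -> list[OrthologyCall]:
    """One orthology call per species-A query in ``ab``.

    strict-RBH: rank-1 both ways. relaxed-RBH(k): reciprocation within the
    top k both ways (but not rank-1/rank-1); the best-ranked reciprocating
    subject becomes the partner. absent: no reciprocation at this k.
    Raises on overlapping id spaces between the two species (ids must
    identify the species unambiguously).
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    a_ids = set(ab.query_ids) | set(ba.subject_ids)
    b_ids = set(ba.query_ids) | set(ab.subject_ids)
    collisions = a_ids & b_ids
    if collisions:
        raise InvariantError(
            f"id space collision between species: {sorted(collisions)[:5]}"
        )
    calls = []
    for query in ab.query_ids:
        forward = top_hits(ab, query, k)
        partner = None
        status = ABSENT
        for rank, subject in enumerate(forward):
            back = top_hits(ba, subject, k)
            if query in back:
                partner = subject
                if rank == 0 and back and back[0] == query:
                    status = STRICT
                else:
                    status = relaxed_status(k)
                break
        evidence = ()
        if partner is not None:
            fwd = _hit_row(ab, query, partner)
            rev = _hit_row(ba, partner, query)
            evidence = tuple(r for r in (fwd, rev) if r is not None)
        calls.append(OrthologyCall(query, partner, status, evidence))
    return calls


def family_absent(calls: Iterable[OrthologyCall], family_ids: Iterable[str]) -> bool:
    """True iff every family member's call is absent.

    Members with no call at all (no hits) count as absent.
    """
    family = set(family_ids)
    if not family:
        raise DomainError("family id set must be non-empty")
    by_id = {c.query_id: c for c in calls}
    return all(
        (mid not in by_id) or (not by_id[mid].present) for mid in family
    )


def calls_to_dataframe(calls: Iterable[OrthologyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": c.query_id,
                "partner": c.partner_id or "",
                "status": c.status,
            }
            for c in calls
        ]
    )
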