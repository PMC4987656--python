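"""Detect and stitch split transcript fragments into a modified reference.

A deposited cDNA database can carry one gene copy as two separate entries
(two parts of the same transcript, with or without sequence overlap).  This
module finds such fragment pairs — by suffix/prefix overlap, or by anchoring
both fragments to a full-length homeologous guide copy — merges them, and
rebuilds the reference with the fragments replaced by the stitched records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

from .errors import StitchError
from .records import TranscriptRecord

MIN_OVERLAP_DEFAULT = 20
MIN_IDENTITY_DEFAULT = 0.95
GUIDE_IDENTITY_DEFAULT = 0.90   # fragments align to a ~5%-divergent homeolog
MAX_GUIDE_GAP_DEFAULT = 50


class SplitCandidate(NamedTuple):
    frag_a: str
    frag_b: str
    overlap_nt: int
    score: float        # identities in the aligned region(s)
    guide_id: str | None
    identity: float


@dataclass
class StitchEvent:
    frag_a: str
    frag_b: str
    merged_id: str
    overlap_nt: int
    guide_id: str | None
    junction_pos: int   # 0-based offset in merged sequence where fragment B takes over


def _identity(x: str, y: str) -> tuple[int, float]:
    matches = sum(a == b for a, b in zip(x, y))
    return matches, matches / max(len(x), 1)


def _overlap_candidates(db, min_overlap, min_identity):
    """Suffix/prefix overlap search.

    Candidate generation is seeded on an exact match between the first
    ``min_overlap`` bases of the downstream fragment and the corresponding
    suffix window of the upstream fragment; identity over the full overlap is
    then scored against ``min_identity``.

    Records annotated with different sub-genomes are never paired: homeologs
    are similar enough that a homologous region of the wrong sub-genome copy
    can pass the identity threshold, and sub-genome identity is exactly the
    information used to resolve fragments to one gene copy.
    """
    by_prefix: dict[str, list[TranscriptRecord]] = {}
    for rec in db:
        if rec.length >= min_overlap:
            by_prefix.setdefault(rec.seq[:min_overlap], []).append(rec)
    best: dict[tuple[str, str], SplitCandidate] = {}
    for a in db:
        la = a.length
        for overlap in range(min_overlap, la + 1):
            seed = a.seq[la - overlap : la - overlap + min_overlap]
            for b in by_prefix.get(seed, ()):
                if b.id == a.id or overlap > b.length:
                    continue
                if (
                    a.subgenome != "unknown"
                    and b.subgenome != "unknown"
                    and a.subgenome != b.subgenome
                ):
                    continue
                matches, ident = _identity(a.seq[la - overlap :], b.seq[:overlap])
                if ident < min_identity:
                    continue
                key = (a.id, b.id)
                cand = SplitCandidate(a.id, b.id, overlap, float(matches), None, ident)
                if key not in best or cand.score > best[key].score:
                    best[key] = cand
    return list(best.values())


def _guide_candidates(db, guide_identity, max_gap, min_fragment=30):
    """Anchor same-gene, same-sub-genome fragment pairs on a homeolog guide.

    Both fragments must align (edlib infix alignment) to disjoint, ordered
    intervals of a full-length copy of the same gene from another sub-genome,
    with the gap between intervals at most ``max_gap``.  Accepted joins are
    abutting (overlap 0).
    """
    import edlib

    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in db:
        if rec.gene != "unknown":
            by_gene.setdefault(rec.gene, []).append(rec)
    out = []
    for gene, recs in by_gene.items():
        by_sub: dict[str, list[TranscriptRecord]] = {}
        for rec in recs:
            by_sub.setdefault(rec.subgenome, []).append(rec)
        for sub, frags in by_sub.items():
            if len(frags) < 2:
                continue
            guides = [r for r in recs if r.subgenome != sub]
            for i, a in enumerate(frags):
                for b in frags[i + 1 :]:
                    if min(a.length, b.length) < min_fragment:
                        continue
                    for guide in guides:
                        if guide.length <= max(a.length, b.length):
                            continue
                        hits = []
                        for frag in (a, b):
                            res = edlib.align(frag.seq, guide.seq, mode="HW",
                                              task="locations")
                            if not res["locations"]:
                                hits = None
                                break
                            start, end = res["locations"][0]
                            ident = 1.0 - res["editDistance"] / frag.length
                            hits.append((start, end + 1, ident, frag))
                        if not hits or any(h[2] < guide_identity for h in hits):
                            continue
                        hits.sort(key=lambda h: h[0])
                        (s1, e1, id1, f1), (s2, e2, id2, f2) = hits
                        if e1 <= s2 and s2 - e1 <= max_gap:
                            matches = id1 * f1.length + id2 * f2.length
                            out.append(
                                SplitCandidate(f1.id, f2.id, 0, float(matches),
                                               guide.id, min(id1, id2))
                            )
    return out


def find_split_candidates(
    db: list[TranscriptRecord],
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    min_identity: float = MIN_IDENTITY_DEFAULT,
    use_guides: bool = False,
    guide_identity: float = GUIDE_IDENTITY_DEFAULT,
    max_gap: int = MAX_GUIDE_GAP_DEFAULT,
) -> list[SplitCandidate]:
    """Return accepted fragment pairs, greedily one pair per fragment.

    Candidates are sorted by score (identities) descending, ties broken by
    longer overlap then lexicographic ids; each fragment joins at most one
    accepted pair.  Overlap-free (abutting) joins are only produced by the
    guide-anchored mode, never by suffix/prefix search.
    """
    if not db:
        return []
    cands = _overlap_candidates(db, min_overlap, min_identity)
    if use_guides:
        cands.extend(_guide_candidates(db, guide_identity, max_gap))
    cands.sort(key=lambda c: (-c.score, -c.overlap_nt, c.frag_a, c.frag_b))
    used: set[str] = set()
    accepted = []
    for c in cands:
        if c.frag_a in used or c.frag_b in used:
            continue
        used.update((c.frag_a, c.frag_b))
        accepted.append(c)
    return accepted


def _merged_id(a: TranscriptRecord, b: TranscriptRecord) -> str:
    prefix = ""
    for ca, cb in zip(a.id, b.id):
        if ca != cb:
            break
        prefix += ca
    base = prefix.rstrip("0123456789").rstrip("._-")
    for suffix in ("frag", "part", "fragment"):
        if base.lower().endswith(suffix):
            base = base[: -len(suffix)].rstrip("._-")
    if not base:
        base = a.id
    return base + "_stitched"


def stitch_pair(
    a: TranscriptRecord,
    b: TranscriptRecord,
    overlap_nt: int,
    guide: TranscriptRecord | None = None,
    min_identity: float = MIN_IDENTITY_DEFAULT,
) -> tuple[TranscriptRecord, StitchEvent]:
    """Merge fragment ``b`` onto fragment ``a``.

    The merged sequence is ``a.seq + b.seq[overlap_nt:]``; a positive overlap
    must agree between the two fragments at ``min_identity`` or the join is
    refused.  Abutting joins (overlap 0) require a guide record.
    """
    if overlap_nt < 0:
        raise StitchError("overlap_nt must be >= 0")
    if overlap_nt > min(a.length, b.length):
        raise StitchError(f"overlap {overlap_nt} exceeds fragment length")
    if overlap_nt > 0:
        _, ident = _identity(a.seq[a.length - overlap_nt :], b.seq[:overlap_nt])
        if ident < min_identity:
            raise StitchError(
                f"overlap identity {ident:.3f} below {min_identity} for "
                f"{a.id}+{b.id}"
            )
    elif guide is None:
        raise StitchError(
            f"abutting join {a.id}+{b.id} requires a homeologous guide record"
        )
    merged = replace(
        a,
        id=_merged_id(a, b),
        seq=a.seq + b.seq[overlap_nt:],
    )
    event = StitchEvent(
        frag_a=a.id,
        frag_b=b.id,
        merged_id=merged.id,
        overlap_nt=overlap_nt,
        guide_id=guide.id if guide is not None else None,
        junction_pos=a.length - overlap_nt,
    )
    return merged, event


def build_modified_reference(
    db: list[TranscriptRecord], events: list[StitchEvent]
) -> list[TranscriptRecord]:
    """Replace each event's fragment pair with its stitched record.

    All untouched records pass through unchanged and in input order; the
    merged record takes the position of its first fragment.  The output has
    ``len(db) - len(events)`` records.
    """
    index = {rec.id: rec for rec in db}
    for ev in events:
        for fid in (ev.frag_a, ev.frag_b):
            if fid not in index:
                raise StitchError(f"stitch event references missing id {fid!r}")
    merged_at: dict[str, TranscriptRecord] = {}
    drop: set[str] = set()
    for ev in events:
        a, b = index[ev.frag_a], index[ev.frag_b]
        if ev.overlap_nt > min(a.length, b.length):
            raise StitchError(f"overlap {ev.overlap_nt} exceeds fragment length")
        merged = replace(a, id=ev.merged_id, seq=a.seq + b.seq[ev.overlap_nt:])
        merged_at[ev.frag_a] = merged
        drop.update((ev.frag_a, ev.frag_b))
    out = []
    for rec in db:
        if rec.id in merged_at:
            out.append(merged_at[rec.id])
        elif rec.id not in drop:
            out.append(rec)
    return out


def stitch_candidates(
    db: list[TranscriptRecord],
    candidates: list[SplitCandidate],
    min_identity: float = MIN_IDENTITY_DEFAULT,
) -> tuple[list[TranscriptRecord], list[StitchEvent]]:
    """Stitch every accepted candidate and rebuild the reference."""
    index = {rec.id: rec for rec in db}
    events = []
    for c in candidates:
        guide = index.get(c.guide_id) if c.guide_id else None
        _, event = stitch_pair(index[c.frag_a], index[c.frag_b], c.overlap_nt,
                               guide=guide, min_identity=min_identity)
        events.append(event)
    return build_modified_reference(db, events), events
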