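"""C3/C4 typing of PEPC gene copies from a diagnostic amino-acid residue.

PEPC (phosphoenolpyruvate carboxylase) isoforms differ at a single site that
governs tolerance to feedback inhibition by malate: C3 isoforms carry
arginine (R) there, while C4 isoforms carry one of several substitutions
(S, Q, G or I across known C4 lineages).  The site sits at the 10th position
of a 17-residue window; this module locates that window in translated gene
copies by identity against a packaged library of printed reference windows
and types each copy from the residue found.

Canonical numbering of the site (884 in the maize convention; 885 and 891
for the wheat chromosome-3 and chromosome-5 copies) is carried as metadata
only — matching is purely window-based.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError
from .records import TranscriptRecord

WINDOW_LEN = 17
DIAGNOSTIC_INDEX = 9            # 0-based column of the diagnostic residue
MIN_IDENTITIES_DEFAULT = 11     # out of 17
C4_RESIDUES_DEFAULT = frozenset("SQGI")
CANONICAL_POSITIONS = {"maize": 884, "wheat_chr3": 885, "wheat_chr5": 891}
FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")
_NT_ALPHABET = set("ACGTNacgtn")


@dataclass
class WindowLibrary:
    """Reference set of printed 17-aa diagnostic windows."""

    table: pd.DataFrame                       # table, species, location, window, printed_label
    canonical_positions: dict = field(default_factory=lambda: dict(CANONICAL_POSITIONS))

    def __post_init__(self):
        bad = self.table[self.table["window"].str.len() != WINDOW_LEN]
        if len(bad):
            raise ConfigError(f"non-17-residue windows in library: {bad['window'].tolist()}")

    @property
    def windows(self) -> list[str]:
        """Unique windows in table order."""
        seen, out = set(), []
        for w in self.table["window"]:
            if w not in seen:
                seen.add(w)
                out.append(w)
        return out

    @classmethod
    def packaged(cls) -> "WindowLibrary":
        path = importlib.resources.files("kranzless.data") / "tables_2_3_windows.tsv"
        with importlib.resources.as_file(path) as p:
            table = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
        return cls(table=table)


class WindowHit(NamedTuple):
    window: str       # the protein's own 17-mer at the located position
    offset: int       # 0-based start in the protein
    score: int        # identities to the best library window (out of 17)


@dataclass
class DiagnosticCall:
    seq_id: str
    frame: str                     # +1..+3 / -1..-3 for nucleotide input, "aa" for protein
    window: str | None
    window_offset: int | None
    residue: str                   # single letter or '?'
    klass: str                     # C3 | C4_candidate | unknown
    frame_intact: bool
    match_score: int


class FamilySummary(NamedTuple):
    n_copies: int
    n_C3: int
    n_C4: int
    n_unknown: int


def six_frame_translate(nt_seq: str) -> dict[str, str]:
    """Standard-code translation of all six frames; stops appear as '*'.

    Frames -1..-3 read the reverse complement; trailing partial codons are
    truncated.
    """
    if not nt_seq:
        raise ConfigError("cannot translate an empty sequence")
    seq = Seq(nt_seq.upper())
    rc = seq.reverse_complement()
    out = {}
    for i, frame in enumerate(("+1", "+2", "+3")):
        sub = seq[i:]
        out[frame] = str(sub[: len(sub) - len(sub) % 3].translate())
    for i, frame in enumerate(("-1", "-2", "-3")):
        sub = rc[i:]
        out[frame] = str(sub[: len(sub) - len(sub) % 3].translate())
    return out


def _window_score(window: str, ref: str) -> int:
    # '?' placeholders in printed windows never match
    return sum(a == b and a != "?" and b != "?" for a, b in zip(window, ref))


def locate_diagnostic_window(
    protein: str,
    library: WindowLibrary,
    min_identities: int = MIN_IDENTITIES_DEFAULT,
) -> WindowHit | None:
    """Best-identity placement of any library window within the protein.

    Slides a 17-wide window across the protein and scores identities against
    every library window; returns the best placement when it reaches
    ``min_identities``, ties broken by leftmost offset then library order.
    """
    if not protein:
        raise ConfigError("protein must be non-empty")
    refs = library.windows
    best: WindowHit | None = None
    for offset in range(len(protein) - WINDOW_LEN + 1):
        sub = protein[offset : offset + WINDOW_LEN]
        for ref in refs:
            score = _window_score(sub, ref)
            if best is None or score > best.score:
                best = WindowHit(sub, offset, score)
    if best is None or best.score < min_identities:
        return None
    return best


def classify_residue(residue: str, c4_set: frozenset = C4_RESIDUES_DEFAULT) -> str:
    """'R' is the C3 form; members of ``c4_set`` are C4 candidates."""
    if len(residue) != 1:
        raise ConfigError(f"residue must be a single character, got {residue!r}")
    if residue == "R":
        return "C3"
    if residue in c4_set:
        return "C4_candidate"
    return "unknown"


def is_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq) <= _NT_ALPHABET


def _call_protein(seq_id, protein, frame, library, min_identities, c4_set):
    hit = locate_diagnostic_window(protein, library, min_identities)
    if hit is None:
        return DiagnosticCall(seq_id, frame, None, None, "?", "unknown",
                              frame_intact=False, match_score=0)
    residue = hit.window[DIAGNOSTIC_INDEX]
    intact = "*" not in hit.window
    return DiagnosticCall(seq_id, frame, hit.window, hit.offset, residue,
                          classify_residue(residue, c4_set),
                          frame_intact=intact, match_score=hit.score)


def classify_family(
    sequences: list[TranscriptRecord],
    library: WindowLibrary | None = None,
    min_identities: int = MIN_IDENTITIES_DEFAULT,
    c4_set: frozenset = C4_RESIDUES_DEFAULT,
    alphabet: str = "auto",
) -> tuple[list[DiagnosticCall], FamilySummary]:
    """One diagnostic call per gene copy plus the family summary.

    Nucleotide input is translated in six frames and the best-scoring frame
    is kept; ``frame_intact`` is false when no frame reaches
    ``min_identities`` or the best window spans a stop codon.  Input type is
    auto-detected from the alphabet unless forced via ``alphabet``.
    """
    library = library or WindowLibrary.packaged()
    if alphabet not in ("auto", "nt", "aa"):
        raise ConfigError("alphabet must be 'auto', 'nt' or 'aa'")
    calls = []
    for rec in sequences:
        is_nt = is_nucleotide(rec.seq) if alphabet == "auto" else alphabet == "nt"
        if is_nt:
            frame_calls = [
                _call_protein(rec.id, prot, frame, library, min_identities, c4_set)
                for frame, prot in six_frame_translate(rec.seq).items()
            ]
            call = max(frame_calls, key=lambda c: c.match_score)
        else:
            call = _call_protein(rec.id, rec.seq.upper(), "aa", library,
                                 min_identities, c4_set)
        calls.append(call)
    n_c3 = sum(c.klass == "C3" for c in calls)
    n_c4 = sum(c.klass == "C4_candidate" for c in calls)
    summary = FamilySummary(len(calls), n_c3, n_c4, len(calls) - n_c3 - n_c4)
    return calls, summary


def frame_integrity_check(
    nt_seq: str,
    library: WindowLibrary | None = None,
    min_identities: int = MIN_IDENTITIES_DEFAULT,
) -> tuple[bool, str]:
    """Whether some single reading frame carries a stop-free diagnostic window."""
    library = library or WindowLibrary.packaged()
    notes = []
    for frame, prot in six_frame_translate(nt_seq).items():
        hit = locate_diagnostic_window(prot, library, min_identities)
        if hit is not None and "*" not in hit.window:
            return True, f"intact window in frame {frame} at aa offset {hit.offset}"
        if hit is not None:
            notes.append(f"frame {frame}: window contains a stop")
    return False, "; ".join(notes) or "no frame reaches the identity threshold"


def calls_to_frame(calls: list[DiagnosticCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": c.seq_id, "frame": c.frame, "offset": c.window_offset,
                "window": c.window, "residue": c.residue, "klass": c.klass,
                "score": c.match_score, "frame_intact": c.frame_intact,
            }
            for c in calls
        ]
    )


def reproduce_printed_tables(
    library: WindowLibrary | None = None,
    c4_set: frozenset = C4_RESIDUES_DEFAULT,
) -> pd.DataFrame:
    """Apply the residue rule to every printed window and compare labels.

    Printed labels are normalized ('C4?' counts as a C4 call, a blank label
    as unknown).  The ``divergent`` column flags rows where the rule-based
    call disagrees with the printed label; these are reported, never silently
    reconciled.
    """
    library = library or WindowLibrary.packaged()
    rows = []
    for _, row in library.table.iterrows():
        residue = row["window"][DIAGNOSTIC_INDEX]
        klass = classify_residue(residue, c4_set)
        printed = row["printed_label"].strip().rstrip("?")
        printed_klass = {"C3": "C3", "C4": "C4_candidate", "": "unknown"}.get(
            printed, "unknown"
        )
        rows.append(
            {
                **row,
                "residue": residue,
                "klass": klass,
                "printed_klass": printed_klass,
                "divergent": klass != printed_klass,
            }
        )
    return pd.DataFrame(rows)
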