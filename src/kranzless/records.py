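"""Core transcript record type shared by the generator, stitcher and quantifier."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TranscriptRecord:
    """One reference cDNA entry.

    ``gene``/``subgenome``/``arm`` are annotation fields carried through the
    pipeline; ``subgenome`` is one of the three wheat sub-genome labels
    (A/B/D by default) or ``"unknown"``.
    """

    id: str
    seq: str
    gene: str = "unknown"
    subgenome: str = "unknown"
    arm: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    def header(self) -> str:
        """FASTA header line content (id plus key=value annotation tokens)."""
        tokens = [self.id]
        if self.gene != "unknown":
            tokens.append(f"gene={self.gene}")
        if self.subgenome != "unknown":
            tokens.append(f"subgenome={self.subgenome}")
        if self.arm:
            tokens.append(f"arm={self.arm}")
        return " ".join(tokens)
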