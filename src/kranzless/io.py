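"""FASTA and TSV readers/writers plus the run configuration container.

All tabular interchange is plain TSV; FASTA I/O goes through Biopython with a
thin validation layer that reports line numbers on malformed input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, ParseError
from .records import TranscriptRecord

FASTA_WIDTH = 60


def _parse_annotations(description: str) -> dict:
    out = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            if key in ("gene", "subgenome", "arm"):
                out[key] = value
    return out


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into TranscriptRecords.

    Annotation tokens of the form ``gene=`` / ``subgenome=`` / ``arm=`` in the
    header are recovered; sequence case is preserved.
    """
    path = Path(path)
    # Pre-scan for structural problems so errors carry a line number.
    first_content = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if first_content is None:
                first_content = lineno
                if not stripped.startswith(">"):
                    raise ParseError("expected '>' header as first record", lineno)
            if stripped.startswith(">") and len(stripped) == 1:
                raise ParseError("empty FASTA header", lineno)
    if first_content is None:
        return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_annotations(rec.description)
        records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq), **meta))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.header()[len(r.id):].strip())
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=FASTA_WIDTH)
    writer.write_file(seq_records)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclasses.dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    Stage-specific knobs are grouped in sub-dicts so that the YAML file mirrors
    the pipeline stages; unknown keys are rejected rather than ignored.
    """

    outdir: str = "kranzless_out"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple = ("simulate", "stitch", "quantify", "diffexpr", "classify", "evidence")
    simulate: dict = dataclasses.field(default_factory=dict)
    stitch: dict = dataclasses.field(default_factory=dict)
    quantify: dict = dataclasses.field(default_factory=dict)
    diffexpr: dict = dataclasses.field(default_factory=dict)
    classify: dict = dataclasses.field(default_factory=dict)
    evidence: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw = {**raw, "stages": tuple(raw["stages"])}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d
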