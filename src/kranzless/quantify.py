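"""RPKM quantification with the pair=2 / singleton=1 counting convention.

Mapped read pairs contribute two units and mapped singletons one unit; RPKM
is computed from those units against per-sample library totals, aggregated to
gene x sub-genome (with the A+B+D sum as the homeolog-combined expression
level), and contrasted between tissues as fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class CountMatrix:
    """Transcript x sample pair and singleton counts plus sample metadata."""

    pair_counts: pd.DataFrame
    singleton_counts: pd.DataFrame
    sample_meta: pd.DataFrame          # indexed by sample_id: genotype, tissue, stage
    lengths: pd.Series | None = None   # nt per transcript (optional until RPKM)

    def __post_init__(self):
        if not self.pair_counts.index.equals(self.singleton_counts.index):
            raise ConfigError("pair and singleton matrices disagree on transcripts")
        if not self.pair_counts.columns.equals(self.singleton_counts.columns):
            raise ConfigError("pair and singleton matrices disagree on samples")
        missing = set(self.pair_counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ConfigError(f"samples without metadata: {sorted(missing)}")
        if (self.pair_counts.values < 0).any() or (self.singleton_counts.values < 0).any():
            raise ConfigError("counts must be non-negative")

    @property
    def transcripts(self) -> list[str]:
        return list(self.pair_counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.pair_counts.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: transcript_id, sample_id, pair_count, singleton_count."""
        pairs = self.pair_counts.stack()
        singles = self.singleton_counts.stack()
        df = pd.DataFrame({"pair_count": pairs, "singleton_count": singles})
        df.index.names = ["transcript_id", "sample_id"]
        return df.reset_index()

    @classmethod
    def from_long(cls, df: pd.DataFrame, sample_meta: pd.DataFrame,
                  lengths: pd.Series | None = None) -> "CountMatrix":
        pairs = df.pivot(index="transcript_id", columns="sample_id", values="pair_count")
        singles = df.pivot(index="transcript_id", columns="sample_id",
                           values="singleton_count")
        return cls(pair_counts=pairs, singleton_counts=singles,
                   sample_meta=sample_meta, lengths=lengths)


@dataclass
class RpkmMatrix:
    values: pd.DataFrame               # transcript x sample, RPKM units
    lengths: pd.Series                 # nt per transcript
    library_units: pd.Series           # per-sample total mapped read units

    def __post_init__(self):
        if not np.isfinite(self.values.values).all():
            raise ConfigError("RPKM values must be finite")
        if (self.library_units <= 0).any():
            bad = self.library_units[self.library_units <= 0].index.tolist()
            raise ConfigError(f"non-positive library units for samples: {bad}")


@dataclass
class ExpressionContrast:
    """Tissue-contrast fold change for one gene (or gene copy)."""

    gene: str
    numerator_tissue: str
    denominator_tissue: str
    mean_num: float
    mean_den: float
    fold: float                        # raw ratio (nan when undefined)
    fold_rounded: int | None           # half-away-from-zero integer
    direction: str                     # up | down | flat
    undefined: bool = False


def read_units(cm: CountMatrix) -> pd.DataFrame:
    """Unit matrix: two per mapped pair, one per mapped singleton."""
    if (cm.pair_counts.values < 0).any() or (cm.singleton_counts.values < 0).any():
        raise ConfigError("counts must be non-negative")
    return 2 * cm.pair_counts + cm.singleton_counts


def compute_rpkm(
    units: pd.DataFrame,
    lengths: pd.Series,
    library_units: pd.Series | None = None,
) -> RpkmMatrix:
    """RPKM[t, s] = 1e9 * units[t, s] / (length[t] * library_units[s]).

    Library totals default to per-sample column sums of the unit matrix over
    the whole reference (not a gene subset).
    """
    lengths = lengths.reindex(units.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ConfigError(f"no length for transcripts: {missing[:5]}")
    if (lengths <= 0).any():
        raise ConfigError("transcript lengths must be > 0")
    if library_units is None:
        library_units = units.sum(axis=0)
    library_units = library_units.reindex(units.columns)
    zero = library_units[(library_units <= 0) | library_units.isna()].index.tolist()
    if zero:
        raise ConfigError(f"zero or missing library units for samples: {zero}")
    values = 1e9 * units.div(lengths, axis=0).div(library_units, axis=1)
    return RpkmMatrix(values=values, lengths=lengths, library_units=library_units)


@dataclass
class SubgenomeTable:
    """Per-sample gene x sub-genome RPKM sums with the A+B+D combined level."""

    per_copy: pd.DataFrame             # rows (gene, subgenome), columns samples
    abd_sum: pd.DataFrame              # rows gene, columns samples
    unknown_subgenome: list = field(default_factory=list)

    def tissue_means(self, sample_meta: pd.DataFrame) -> pd.DataFrame:
        """Mean of the combined A+B+D level across genotypes within tissue."""
        tissues = sample_meta.loc[self.abd_sum.columns, "tissue"]
        return self.abd_sum.T.groupby(tissues.values).mean().T


def subgenome_aggregate(rpkm: RpkmMatrix, annotation: pd.DataFrame) -> SubgenomeTable:
    """Sum transcript RPKM to gene x sub-genome and to the A+B+D total.

    ``annotation`` maps transcript_id to gene and subgenome.  Transcripts with
    unknown sub-genome are excluded from the combined sum and listed in
    ``unknown_subgenome``.
    """
    ann = annotation.set_index("transcript_id") if "transcript_id" in annotation else annotation
    ann = ann.reindex(rpkm.values.index)
    genes = ann["gene"].fillna("unknown")
    subs = ann["subgenome"].fillna("unknown")
    per_copy = rpkm.values.groupby([genes, subs]).sum()
    per_copy.index.names = ["gene", "subgenome"]
    known = subs != "unknown"
    abd = rpkm.values[known.values].groupby(genes[known.values].values).sum()
    abd.index.name = "gene"
    unknown = rpkm.values.index[~known.values].tolist()
    return SubgenomeTable(per_copy=per_copy, abd_sum=abd, unknown_subgenome=unknown)


def round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def fold_change(
    mean_num: float,
    mean_den: float,
    floor: float = 0.0,
    gene: str = "",
    numerator_tissue: str = "",
    denominator_tissue: str = "",
    direction_threshold: float = 2.0,
) -> ExpressionContrast:
    """Fold change between two tissue means with an optional denominator floor.

    With the default floor of 0 a zero denominator is a hard error; when both
    means fall below a positive floor the contrast is flagged undefined and
    reported flat.
    """
    if mean_num < 0 or mean_den < 0:
        raise ConfigError("means must be non-negative")
    if mean_num <= floor and mean_den <= floor:
        return ExpressionContrast(gene, numerator_tissue, denominator_tissue,
                                  mean_num, mean_den, float("nan"), None,
                                  "flat", undefined=True)
    if mean_den <= 0 and floor <= 0:
        raise ConfigError(
            f"zero denominator mean for {gene or 'contrast'}; pass a positive floor"
        )
    fold = mean_num / max(mean_den, floor)
    if fold >= direction_threshold:
        direction = "up"
    elif fold <= 1.0 / direction_threshold:
        direction = "down"
    else:
        direction = "flat"
    return ExpressionContrast(gene, numerator_tissue, denominator_tissue,
                              mean_num, mean_den, fold, round_half_away(fold),
                              direction)


@dataclass
class RelativeContrast:
    rounded_product: int | None
    raw_product: float
    undefined: bool = False


def relative_contrast(a: ExpressionContrast, b: ExpressionContrast) -> RelativeContrast:
    """Combined contrast of two genes: product of the integer-rounded folds.

    The raw product of the unrounded ratios is reported alongside.
    """
    if a.undefined or b.undefined:
        return RelativeContrast(None, float("nan"), undefined=True)
    return RelativeContrast(a.fold_rounded * b.fold_rounded, a.fold * b.fold)
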