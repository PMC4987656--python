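"""Synthetic hexaploid-like transcriptomes with known ground truth.

The generator emulates the structure of a bread-wheat grain RNA-Seq study:
a three-sub-genome (A/B/D) transcriptome of homeologous gene copies, a small
number of transcripts deposited as two fragments of one gene copy, negative
binomial read-unit counts across many genotypes with grain-specific
up-regulation of a designated C4-pathway gene set, and PEPC protein families
carrying known diagnostic residues.  Every emitted dataset comes with the
truth needed to score downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .records import TranscriptRecord

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_C4_GENES = ("ppc", "aat", "mdh", "me2", "gpt", "ppdk")
DEFAULT_C4_RESIDUES = frozenset("SQGI")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic transcriptome.

    Defaults mirror the study design being emulated: 31 genotypes, grain
    sampled at two post-anthesis stages plus a seedling-stage leaf tissue,
    and the six NAD-ME-pathway genes up-regulated in grain.
    """

    n_genes: int = 100
    subgenomes: tuple = ("A", "B", "D")
    n_genotypes: int = 31
    tissues: tuple = ("grain_14dpa", "grain_30dpa", "leaf_Z10")
    transcript_length_range: tuple = (500, 2000)
    base_expression_mean: float = 50.0
    nb_dispersion: float = 0.1
    c4_gene_set: tuple = DEFAULT_C4_GENES
    grain_up_fold: float = 8.0
    unique_gene_set: tuple = ()          # genes silent outside grain tissues
    singleton_fraction: float = 0.1
    n_split_transcripts: int = 10
    homeolog_divergence: float = 0.05    # expected pairwise difference between homeologs
    expression_sigma: float = 0.5        # lognormal spread of per-transcript baselines
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.subgenomes:
            raise ConfigError("subgenomes must be non-empty")
        if self.n_genotypes < 1:
            raise ConfigError("n_genotypes must be >= 1")
        if not self.tissues:
            raise ConfigError("tissues must be non-empty")
        lo, hi = self.transcript_length_range
        if lo < 50 or hi < lo:
            raise ConfigError("transcript_length_range must satisfy 50 <= lo <= hi")
        if self.base_expression_mean <= 0:
            raise ConfigError("base_expression_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.grain_up_fold < 1:
            raise ConfigError("grain_up_fold must be >= 1")
        if not 0 <= self.singleton_fraction <= 1:
            raise ConfigError("singleton_fraction must be in [0, 1]")
        if self.n_split_transcripts % 2 != 0 or self.n_split_transcripts < 0:
            raise ConfigError("n_split_transcripts must be a non-negative even count")
        if not 0 <= self.homeolog_divergence < 0.2:
            raise ConfigError("homeolog_divergence must be in [0, 0.2)")
        unknown = set(self.unique_gene_set) - set(self.c4_gene_set)
        if unknown:
            raise ConfigError(f"unique_gene_set not within c4_gene_set: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    split_pairs: list = field(default_factory=list)       # (frag_a, frag_b, parent_id)
    de_transcripts: set = field(default_factory=set)      # truly up in grain
    unique_transcripts: set = field(default_factory=set)  # expressed only in grain
    residue_truth: dict = field(default_factory=dict)     # protein id -> "C3" | "C4"
    parent_records: dict = field(default_factory=dict)    # parent id -> TranscriptRecord


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _NT.take(codes).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    # shift by 1..3 so a touched site always changes base
    out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def simulate_reference(config: SimConfig) -> tuple[list[TranscriptRecord], SimTruth]:
    """Emit ``n_genes x |subgenomes|`` homeologous transcripts plus truth.

    Each gene has one ancestral sequence; each sub-genome copy is an
    independently mutated descendant, so homeologs differ by about
    ``homeolog_divergence`` pairwise.  The first genes take the names in
    ``c4_gene_set``; their copies are the designated grain-up transcripts.
    """
    config.validate()
    if len(config.c4_gene_set) > config.n_genes:
        raise ConfigError("c4_gene_set larger than n_genes")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    per_copy_rate = config.homeolog_divergence / 2.0
    records: list[TranscriptRecord] = []
    truth = SimTruth()
    for g in range(config.n_genes):
        gene = (
            config.c4_gene_set[g]
            if g < len(config.c4_gene_set)
            else f"g{g + 1:05d}"
        )
        arm = f"{rng.integers(1, 8)}{'L' if rng.random() < 0.5 else 'S'}"
        ancestor = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for sub in config.subgenomes:
            copy = _mutate(rng, ancestor, per_copy_rate)
            rec = TranscriptRecord(
                id=f"{gene}_{sub}", seq=_to_str(copy),
                gene=gene, subgenome=sub, arm=arm,
            )
            records.append(rec)
            if gene in config.c4_gene_set:
                truth.de_transcripts.add(rec.id)
            if gene in config.unique_gene_set:
                truth.unique_transcripts.add(rec.id)
    return records, truth


def split_transcripts(
    records: list[TranscriptRecord],
    n_split: int,
    overlap_nt: int,
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[list[TranscriptRecord], SimTruth]:
    """Replace ``n_split // 2`` records by two fragments each.

    ``n_split`` counts the resulting fragment transcripts (so 10 fragments
    arise from 5 parents).  With ``overlap_nt == 0`` the fragments abut; with
    a positive overlap the tail of the first fragment repeats the head of the
    second, and re-joining (dropping the duplicated overlap once)
    reconstructs the parent exactly.
    """
    if n_split % 2 != 0:
        raise ConfigError("n_split must be even (fragments come in pairs)")
    n_parents = n_split // 2
    if n_parents > len(records):
        raise ConfigError("n_split/2 exceeds number of records")
    if overlap_nt < 0:
        raise ConfigError("overlap_nt must be >= 0")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SimTruth()
    chosen = sorted(rng.choice(len(records), size=n_parents, replace=False).tolist())
    chosen_set = set(chosen)
    out: list[TranscriptRecord] = []
    for idx, rec in enumerate(records):
        if idx not in chosen_set:
            out.append(rec)
            continue
        L = rec.length
        if overlap_nt >= L:
            raise ConfigError(
                f"overlap_nt={overlap_nt} not smaller than parent length {L} ({rec.id})"
            )
        cut_lo = max(overlap_nt + 1, L // 3)
        cut_hi = max(cut_lo + 1, 2 * L // 3)
        cut = int(rng.integers(cut_lo, cut_hi))
        frag_a = replace(rec, id=f"{rec.id}.frag1", seq=rec.seq[:cut])
        frag_b = replace(rec, id=f"{rec.id}.frag2", seq=rec.seq[cut - overlap_nt:])
        out.extend([frag_a, frag_b])
        truth.split_pairs.append((frag_a.id, frag_b.id, rec.id))
        truth.parent_records[rec.id] = rec
        # fragment ids replace the parent wherever the parent was listed
        for bag in (truth.de_transcripts, truth.unique_transcripts):
            if rec.id in bag:
                bag.discard(rec.id)
                bag.update((frag_a.id, frag_b.id))
    return out, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = m + dispersion * m^2 (Poisson as d -> 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(records, config: SimConfig, truth: SimTruth, seed: int):
    """Draw pair/singleton count layers for every transcript x sample.

    The expected unit count is ``base_expression_mean`` scaled by transcript
    length (per kb), a per-transcript lognormal baseline, and the tissue
    effect: ``grain_up_fold`` on grain-up transcripts in grain tissues, zero
    outside grain for grain-unique transcripts.  Pairs (two units each) and
    singletons are two independent negative binomial layers whose expected
    unit share matches ``singleton_fraction``.
    """
    from .quantify import CountMatrix  # local import to avoid a cycle
    import pandas as pd

    if not records:
        raise ConfigError("records must be non-empty")
    config.validate()
    rng = np.random.default_rng(seed)
    ids = [r.id for r in records]
    lengths = np.array([r.length for r in records], dtype=float)
    baseline = (
        config.base_expression_mean
        * (lengths / 1000.0)
        * np.exp(rng.normal(0.0, config.expression_sigma, size=len(records)))
    )
    de = np.array([r.id in truth.de_transcripts for r in records])
    uniq = np.array([r.id in truth.unique_transcripts for r in records])

    samples, meta_rows = [], []
    pair_cols, single_cols = [], []
    for tissue in config.tissues:
        grain = tissue.startswith("grain")
        mu = baseline.copy()
        if grain:
            mu[de] *= config.grain_up_fold
        else:
            mu[uniq] = 0.0
        stage = tissue.split("_", 1)[1] if "_" in tissue else tissue
        for g in range(config.n_genotypes):
            genotype = f"G{g + 1:03d}"
            sample = f"{genotype}_{tissue}"
            samples.append(sample)
            meta_rows.append({"sample_id": sample, "genotype": genotype,
                              "tissue": tissue, "stage": stage})
            pair_cols.append(_nb_draw(rng, mu * (1 - config.singleton_fraction) / 2.0,
                                      config.nb_dispersion))
            single_cols.append(_nb_draw(rng, mu * config.singleton_fraction,
                                        config.nb_dispersion))
    pair_counts = pd.DataFrame(np.column_stack(pair_cols), index=ids, columns=samples)
    singleton_counts = pd.DataFrame(np.column_stack(single_cols), index=ids, columns=samples)
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(pair_counts=pair_counts, singleton_counts=singleton_counts,
                       sample_meta=sample_meta,
                       lengths=pd.Series(lengths, index=ids))


def simulate_two_group(
    n_transcripts: int,
    n_per_group: int,
    seed: int,
    mean: float = 50.0,
    dispersion: float = 0.1,
    fold: float = 8.0,
    frac_up_a: float = 0.0,
    frac_up_b: float = 0.0,
    frac_unique_a: float = 0.0,
    frac_unique_b: float = 0.0,
    sigma: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-group unit-count matrices with planted effects, for test design.

    Transcripts are assigned, in order, to up-in-A, up-in-B, unique-to-A and
    unique-to-B blocks by the given fractions; the remainder is null.  Returns
    ``(units_a, units_b, truth)`` where truth maps each block name to the set
    of row indices.
    """
    fracs = (frac_up_a, frac_up_b, frac_unique_a, frac_unique_b)
    if sum(fracs) > 1:
        raise ConfigError("planted fractions exceed 1")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n_transcripts)) for f in fracs]
    bounds = np.cumsum([0] + counts)
    names = ("up_a", "up_b", "unique_a", "unique_b")
    truth = {
        name: set(range(bounds[i], bounds[i + 1])) for i, name in enumerate(names)
    }
    truth["null"] = set(range(bounds[-1], n_transcripts))
    baseline = mean * np.exp(rng.normal(0.0, sigma, size=n_transcripts))
    mu_a, mu_b = baseline.copy(), baseline.copy()
    idx = lambda name: sorted(truth[name])  # noqa: E731
    mu_a[idx("up_a")] *= fold
    mu_b[idx("up_b")] *= fold
    mu_b[idx("unique_a")] = 0.0
    mu_a[idx("unique_b")] = 0.0
    units_a = _nb_draw(rng, np.repeat(mu_a[:, None], n_per_group, axis=1), dispersion)
    units_b = _nb_draw(rng, np.repeat(mu_b[:, None], n_per_group, axis=1), dispersion)
    return units_a, units_b, truth


@dataclass
class PepcTruth:
    """Truth for a simulated PEPC protein family."""

    residue_truth: dict      # protein id -> "C3" | "C4"
    embeddings: dict         # protein id -> (offset, 17-aa window)


def simulate_pepc_family(
    family_spec: list[tuple],
    seed: int,
    windows: list[str] | None = None,
    c4_set: frozenset = DEFAULT_C4_RESIDUES,
    flank_range: tuple = (60, 120),
) -> tuple[list[TranscriptRecord], PepcTruth]:
    """Generate protein copies each carrying one embedded diagnostic window.

    ``family_spec`` is a list of ``(taxon, n_copies, residues)`` where
    ``residues`` gives the diagnostic letter of each copy ('R' for the C3
    form, or a letter from ``c4_set``).  The window is drawn from the packaged
    printed-window set with the 10th position overwritten by the requested
    residue, then buried in random flanking sequence.
    """
    from .residue_classifier import WindowLibrary

    if windows is None:
        windows = [w for w in WindowLibrary.packaged().windows if "?" not in w]
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    truth = PepcTruth(residue_truth={}, embeddings={})
    for taxon, n_copies, residues in family_spec:
        residues = list(residues)
        if len(residues) != n_copies:
            raise ConfigError(
                f"{taxon}: {n_copies} copies but {len(residues)} residues given"
            )
        for i, res in enumerate(residues, start=1):
            if len(res) != 1 or (res != "R" and res not in c4_set):
                raise ConfigError(f"{taxon}: unknown diagnostic residue {res!r}")
            base = windows[int(rng.integers(0, len(windows)))]
            window = base[:9] + res + base[10:]
            left = "".join(rng.choice(list(_AA20), int(rng.integers(*flank_range))))
            right = "".join(rng.choice(list(_AA20), int(rng.integers(*flank_range))))
            pid = f"{taxon}_ppc{i}"
            records.append(TranscriptRecord(id=pid, seq=left + window + right,
                                            gene="ppc"))
            truth.residue_truth[pid] = "C3" if res == "R" else "C4"
            truth.embeddings[pid] = (len(left), window)
    return records, truth


def reverse_translate(protein: str, seed: int) -> str:
    """Random-codon nucleotide sequence translating back to ``protein``."""
    from Bio.Data.CodonTable import standard_dna_table

    back: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        back.setdefault(aa, []).append(codon)
    back["*"] = list(standard_dna_table.stop_codons)
    rng = np.random.default_rng(seed)
    try:
        return "".join(
            sorted(back[aa])[int(rng.integers(0, len(back[aa])))] for aa in protein
        )
    except KeyError as exc:
        raise ConfigError(f"cannot reverse-translate residue {exc}") from exc
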