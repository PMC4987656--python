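"""The generator must emit the advertised structure and honour its own truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kranzless import synthetic_data as sd
from kranzless.errors import ConfigError
from kranzless.quantify import read_units


def test_reference_shape_and_gene_naming():
    cfg = sd.SimConfig(n_genes=6, seed=3)
    records, truth = sd.simulate_reference(cfg)
    assert len(records) == 6 * 3  # one copy per gene per sub-genome
    assert {r.gene for r in records} == set(sd.DEFAULT_C4_GENES)
    assert truth.de_transcripts == {r.id for r in records}
    # homeologs of one gene stay >= 90% identical by construction
    by_gene = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r.seq)
    for seqs in by_gene.values():
        ident = np.mean([a == b for a, b in zip(seqs[0], seqs[1])])
        assert ident >= 0.90


def test_reference_determinism():
    cfg = sd.SimConfig(n_genes=10, seed=42)
    recs1, _ = sd.simulate_reference(cfg)
    recs2, _ = sd.simulate_reference(cfg)
    assert [(r.id, r.seq) for r in recs1] == [(r.id, r.seq) for r in recs2]


@pytest.mark.parametrize("bad,field", [
    (dict(n_genes=0), "n_genes"),
    (dict(grain_up_fold=0.5), "grain_up_fold"),
    (dict(singleton_fraction=1.5), "singleton_fraction"),
    (dict(n_split_transcripts=3), "n_split_transcripts"),
])
def test_invalid_config_names_field(bad, field):
    with pytest.raises(ConfigError, match=field):
        sd.SimConfig(**bad).validate()


@pytest.mark.parametrize("overlap", [0, 1, 20, 50])
def test_split_reconstruction_byte_exact(overlap):
    cfg = sd.SimConfig(n_genes=100, seed=5)
    records, _ = sd.simulate_reference(cfg)
    split, truth = sd.split_transcripts(records, 10, overlap, seed=6)
    assert len(truth.split_pairs) == 5
    assert len(split) == len(records) + 5
    by_id = {r.id: r for r in split}
    for fa, fb, parent in truth.split_pairs:
        a, b = by_id[fa], by_id[fb]
        assert a.seq + b.seq[overlap:] == truth.parent_records[parent].seq
        assert a.length + b.length == truth.parent_records[parent].length + overlap


def test_split_rejects_oversized_overlap():
    cfg = sd.SimConfig(n_genes=8, transcript_length_range=(50, 60), seed=7)
    records, _ = sd.simulate_reference(cfg)
    with pytest.raises(ConfigError, match="overlap"):
        sd.split_transcripts(records, 4, 500, seed=8)


def test_counts_deterministic_and_layered(small_sim):
    cfg, _, split, truth = small_sim
    cm1 = sd.simulate_counts(split, cfg, truth, seed=9)
    cm2 = sd.simulate_counts(split, cfg, truth, seed=9)
    pd.testing.assert_frame_equal(cm1.pair_counts, cm2.pair_counts)
    pd.testing.assert_frame_equal(cm1.singleton_counts, cm2.singleton_counts)
    units = read_units(cm1)
    # singleton unit share tracks the configured fraction
    share = cm1.singleton_counts.values.sum() / units.values.sum()
    assert abs(share - cfg.singleton_fraction) < 0.05


def test_poisson_limit_variance_to_mean():
    cfg = sd.SimConfig(n_genes=60, n_genotypes=40, nb_dispersion=1e-12,
                       tissues=("leaf_Z10",), seed=10)
    records, truth = sd.simulate_reference(cfg)
    cm = sd.simulate_counts(records, cfg, truth, seed=11)
    for layer in (cm.pair_counts.values, cm.singleton_counts.values):
        ratio = layer.var(axis=1, ddof=1) / np.maximum(layer.mean(axis=1), 1e-9)
        assert abs(np.median(ratio) - 1.0) < 0.2


def test_null_fold_gives_no_systematic_difference():
    """With grain_up_fold=1 grain and leaf means differ only by noise."""
    nonsig = []
    for rep in range(10):
        cfg = sd.SimConfig(n_genes=40, n_genotypes=8, grain_up_fold=1.0,
                           tissues=("grain_14dpa", "leaf_Z10"), seed=100 + rep)
        records, truth = sd.simulate_reference(cfg)
        cm = sd.simulate_counts(records, cfg, truth, seed=200 + rep)
        units = read_units(cm)
        grain = cm.sample_meta.index[cm.sample_meta.tissue == "grain_14dpa"]
        leaf = cm.sample_meta.index[cm.sample_meta.tissue == "leaf_Z10"]
        p = stats.ttest_ind(units[grain], units[leaf], axis=1,
                            equal_var=False).pvalue
        nonsig.append(np.mean(p > 0.01))
    assert np.mean(nonsig) >= 0.97


def test_grain_fold_converges_to_configured_value():
    cfg = sd.SimConfig(n_genes=30, n_genotypes=30, grain_up_fold=8.0,
                       nb_dispersion=0.1, tissues=("grain_14dpa", "leaf_Z10"),
                       seed=13)
    records, truth = sd.simulate_reference(cfg)
    cm = sd.simulate_counts(records, cfg, truth, seed=14)
    units = read_units(cm)
    grain = cm.sample_meta.index[cm.sample_meta.tissue == "grain_14dpa"]
    leaf = cm.sample_meta.index[cm.sample_meta.tissue == "leaf_Z10"]
    de = sorted(truth.de_transcripts)
    ratio = (units.loc[de, grain].values.mean(axis=1)
             / units.loc[de, leaf].values.mean(axis=1))
    assert abs(ratio.mean() - 8.0) / 8.0 < 0.10


def test_two_group_generator_plants_requested_blocks():
    ua, ub, truth = sd.simulate_two_group(100, 5, seed=1, frac_up_a=0.1,
                                          frac_unique_b=0.1)
    assert ua.shape == (100, 5)
    assert len(truth["up_a"]) == 10 and len(truth["unique_b"]) == 10
    assert (ua[sorted(truth["unique_b"])] == 0).all()


def test_pepc_family_truth_and_embedding():
    fam, truth = sd.simulate_pepc_family(
        [("toyTaxon", 5, ["R", "R", "R", "R", "S"])], seed=21
    )
    classes = list(truth.residue_truth.values())
    assert classes.count("C3") == 4 and classes.count("C4") == 1
    for rec in fam:
        offset, window = truth.embeddings[rec.id]
        assert rec.seq[offset : offset + 17] == window
        # requested residue sits at the 10th window position
        assert window[9] in "RS"


def test_pepc_family_rejects_unknown_residue():
    with pytest.raises(ConfigError, match="residue"):
        sd.simulate_pepc_family([("toy", 1, ["Z"])], seed=1)


def test_reverse_translate_round_trip():
    from Bio.Seq import Seq

    protein = "MAGDPYLKQRLRLRESY"
    nt = sd.reverse_translate(protein, seed=3)
    assert str(Seq(nt).translate()) == protein
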