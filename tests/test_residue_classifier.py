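"""Six-frame translation, window location and C3/C4 residue typing."""

import numpy as np
import pytest

from kranzless import residue_classifier as rc
from kranzless import synthetic_data as sd
from kranzless.errors import ConfigError
from kranzless.records import TranscriptRecord

# independent codon table for the translation oracle
_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = str.maketrans("ACGT", "TGCA")


def _oracle_translate(nt, frame):
    if frame < 0:
        nt = nt.translate(_COMP)[::-1]
    sub = nt[abs(frame) - 1:]
    return "".join(_CODONS[sub[i:i + 3]] for i in range(0, len(sub) - len(sub) % 3, 3))


def test_six_frame_basics():
    frames = rc.six_frame_translate("ATGGCT")
    assert frames["+1"] == "MA"
    assert rc.six_frame_translate("TAA")["+1"] == "*"
    with pytest.raises(ConfigError, match="empty"):
        rc.six_frame_translate("")


def test_six_frame_matches_oracle_on_random_sequence():
    rng = np.random.default_rng(8)
    nt = "".join(rng.choice(list("ACGT"), 300))
    frames = rc.six_frame_translate(nt)
    for sign in (1, -1):
        for k in (1, 2, 3):
            assert frames[f"{'+' if sign > 0 else '-'}{k}"] == _oracle_translate(nt, sign * k)


def test_locate_exact_printed_window(library):
    protein = "MMMMM" + "LEGDPYLKQRLRLRESY" + "KKKKK"
    hit = rc.locate_diagnostic_window(protein, library)
    assert hit.window == "LEGDPYLKQRLRLRESY"
    assert hit.offset == 5
    assert hit.score == 17


def test_locate_returns_none_below_threshold(library):
    assert rc.locate_diagnostic_window("X" * 40, library) is None


def _oracle_scan(protein, windows):
    best = None
    for off in range(len(protein) - 17 + 1):
        sub = protein[off:off + 17]
        for ref in windows:
            s = sum(a == b and a != "?" for a, b in zip(sub, ref))
            if best is None or s > best[2]:
                best = (sub, off, s)
    return best


def test_locator_equals_exhaustive_scan_oracle(library):
    fam, truth = sd.simulate_pepc_family(
        [("oracleTaxon", 10, ["R", "S", "G", "Q", "I", "R", "R", "S", "R", "G"])],
        seed=31,
    )
    for rec in fam:
        hit = rc.locate_diagnostic_window(rec.seq, library)
        window, offset, score = _oracle_scan(rec.seq, library.windows)
        assert (hit.window, hit.offset, hit.score) == (window, offset, score)
        assert hit.offset == truth.embeddings[rec.id][0]


@pytest.mark.parametrize("residue,klass", [
    ("R", "C3"), ("S", "C4_candidate"), ("Q", "C4_candidate"),
    ("G", "C4_candidate"), ("I", "C4_candidate"), ("?", "unknown"),
    ("A", "unknown"),
])
def test_classify_residue_rule(residue, klass):
    assert rc.classify_residue(residue) == klass


def test_classify_residue_rejects_multichar():
    with pytest.raises(ConfigError, match="single"):
        rc.classify_residue("RS")


def test_classify_family_on_printed_species_rows(library):
    def family(species):
        rows = library.table[library.table["species"] == species]
        return [TranscriptRecord(id=f"{species}_{i}", seq=w)
                for i, w in enumerate(rows["window"])]

    _, hordeum = rc.classify_family(family("Hordeum vulgare"), library)
    assert hordeum == (5, 4, 1, 0)
    _, brachy = rc.classify_family(family("Brachypodium distachyon"), library)
    assert brachy == (5, 5, 0, 0)
    _, zea = rc.classify_family(family("Zea mays"), library)
    assert zea == (4, 3, 1, 0)


def test_classification_round_trip_on_synthetic_family(library):
    fam, truth = sd.simulate_pepc_family(
        [("toyTaxon", 5, ["R", "R", "R", "R", "S"])], seed=21
    )
    calls, summary = rc.classify_family(fam, library)
    assert summary == (5, 4, 1, 0)
    for call in calls:
        want = truth.residue_truth[call.seq_id]
        assert call.klass == {"C3": "C3", "C4": "C4_candidate"}[want]


def test_classify_family_translates_nucleotide_input(library):
    fam, truth = sd.simulate_pepc_family([("ntTaxon", 2, ["R", "G"])], seed=5)
    nt_records = [
        TranscriptRecord(id=r.id, seq=sd.reverse_translate(r.seq, seed=9))
        for r in fam
    ]
    calls, summary = rc.classify_family(nt_records, library)
    assert summary.n_C3 == 1 and summary.n_C4 == 1
    assert all(c.frame in ("+1", "+2", "+3", "-1", "-2", "-3") for c in calls)


def test_frame_integrity_detects_shifts_and_stops(library):
    fam, truth = sd.simulate_pepc_family([("fsTaxon", 1, ["S"])], seed=6)
    protein = fam[0].seq
    nt = sd.reverse_translate(protein, seed=7)
    intact, note = rc.frame_integrity_check(nt, library)
    assert intact and "+1" in note
    # a 1-nt deletion upstream shifts the window into another frame;
    # the copy is still recoverable but flagged as frameshifted
    shifted = nt[1:]
    intact2, note2 = rc.frame_integrity_check(shifted, library)
    assert intact2 and "+1" not in note2
    # a stop codon inside the window breaks every frame
    offset, window = truth.embeddings[fam[0].id]
    broken = protein[: offset + 3] + "*" * 11 + protein[offset + 14:]
    nt_broken = sd.reverse_translate(broken, seed=8)
    intact3, _ = rc.frame_integrity_check(nt_broken, library)
    assert not intact3


def test_printed_tables_reproduced_with_single_divergence(library):
    report = rc.reproduce_printed_tables(library)
    divergent = report[report["divergent"]]
    assert len(divergent) == 1
    row = divergent.iloc[0]
    assert row["species"] == "Setaria italica"
    assert row["window"] == "LESDPGLQQQLMLRDSY"
    assert row["klass"] == "C4_candidate" and row["printed_klass"] == "C3"
    blanks = report[report["printed_label"].str.strip() == ""]
    assert (blanks["klass"] == "unknown").all()
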