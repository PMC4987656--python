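"""Type PEPC gene copies as C3 or C4-candidate from the diagnostic residue.

Applies the window rule (R at the 10th position of the 17-residue diagnostic
window = C3; S/Q/G/I = C4 candidate) to every printed reference window, then
round-trips a synthetic Triticeae-like family (four C3 copies plus one
C4-candidate) through six-frame translation and window location.
"""

from _common import RESULTS, run_stages
from kranzless.io import write_tsv
from kranzless.residue_classifier import WindowLibrary, reproduce_printed_tables


def main():
    library = WindowLibrary.packaged()
    report = reproduce_printed_tables(library)
    agree = int((~report["divergent"]).sum())
    print(f"printed windows classified: {len(report)} "
          f"({agree} agree with the printed label)")
    for _, row in report[report["divergent"]].iterrows():
        print(f"  divergence flagged: {row['species']} {row['window']} "
              f"(rule: {row['klass']}, printed: {row['printed_klass']})")
    c4 = report[(report["table"] == "3") & (report["printed_klass"] == "C4_candidate")]
    print(f"distinct C4-diagnostic residues: {sorted(set(c4['residue']))}")
    write_tsv(report, RESULTS / "ppc_window_report.tsv")

    state = run_stages("classify")
    s = state.ppc_summary
    print(f"\nsynthetic family round-trip: {s.n_copies} copies -> "
          f"{s.n_C3} C3, {s.n_C4} C4-candidate, {s.n_unknown} unknown")
    print(f"calls table: {RESULTS / 'pipeline' / 'ppc_calls.tsv'}")


if __name__ == "__main__":
    main()
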