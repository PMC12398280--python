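"""Independent naive string editor: re-applies a truth table to a reference.

Deliberately implemented differently from the package (descending-order
slice editing driven only by the emitted truth-table columns) so it can
serve as an oracle for round-trip reconstruction tests.
"""

import pandas as pd

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _row_edits(row, ref: str):
    """(position, cut_length, replacement) triples for one truth row."""
    t = row["vtype"]
    s, e = int(row["ref_start"]), int(row["ref_end"])
    if t in ("DEL", "SMALL_DEL"):
        return [(s, e - s, "")]
    if t in ("INS", "SMALL_INS"):
        return [(s, 0, str(row["payload"]))]
    if t == "INV":
        return [(s, e - s, _rc(ref[s:e]))]
    if t == "DUP":
        seg = ref[s:e]
        copy = _rc(seg) if str(row["inverted"]) in ("1", "True") else seg
        dest = int(row["dest"])
        return [(dest, 0, copy * (int(row["copies"]) - 1))]
    if t == "TRA_BAL":
        b1, b2 = int(row["region_b_start"]), int(row["region_b_end"])
        return [(s, e - s, ref[b1:b2]), (b1, b2 - b1, ref[s:e])]
    if t == "TRA_UNBAL":
        b1, b2 = int(row["region_b_start"]), int(row["region_b_end"])
        if str(row["copy_b"]) == "1":  # B copied, not moved
            return [(s, e - s, ref[b1:b2])]
        return [(s, e - s, ref[b1:b2]), (b1, b2 - b1, "")]
    if t == "SNP":
        return [(s, 1, str(row["payload"]))]
    raise ValueError(f"unknown truth-table type {t}")


def rebuild_donors(truth_path, ref: str, ploidy: int) -> list[str]:
    """Rebuild every donor haplotype from the truth table alone."""
    df = pd.read_csv(truth_path, sep="\t", dtype=str)
    donors = []
    for hap in range(ploidy):
        edits = []
        for _, row in df.iterrows():
            gt = row["genotype"].split("|")
            if gt[hap] != "1":
                continue
            edits.extend(_row_edits(row, ref))
        seq = ref
        # descending application; at equal positions apply the wider cut
        # first so a point-insertion at a breakpoint lands before (and is
        # never swallowed by) a replacement starting there
        for pos, cut, repl in sorted(edits, key=lambda x: (x[0], x[1]), reverse=True):
            seq = seq[:pos] + repl + seq[pos + cut :]
        donors.append(seq)
    return donors
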