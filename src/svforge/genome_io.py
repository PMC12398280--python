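"""Reading references and empirical variant tables; writing simulation output.

Conventions
-----------
* Internal coordinates are 0-based half-open; BED input is 0-based
  half-open; VCF output is 1-based.
* The donor FASTA holds one record per haplotype.
* The truth table is tab-separated, one row per *simple* event (composite
  events are expanded into their components, linked by ``event_id`` and the
  ``csv_type``/``csv_index`` columns).  Coordinates in the truth table are
  0-based half-open so a naive string editor can re-apply it directly.
* The VCF is version 4.3 with symbolic structural ALT alleles
  (``<DEL>``, ``<INS>``, ``<INV>``, ``<DUP>``, ``<TRA>``), ``SVTYPE`` /
  ``SVLEN`` / ``END`` INFO keys, the full inserted allele in ``INSSEQ``,
  and ``CSV-TYPE`` / ``CSV-INDEX`` annotating composite components.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core_model import VariantRecord
from .variant_constructors import CoordinateMap

logger = logging.getLogger("svforge")

_VALID_BASES = set("ACGTN")
#: IUPAC ambiguity codes are accepted on input and normalised to N.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")

KNOWN_BED_TYPES = {"DEL", "INS", "INV", "DUP", "TRA", "SNP"}

EXACT_COLUMNS = [
    "position", "vtype", "length",
    "region_b_start", "region_b_end",
    "source_start", "source_end", "dest", "csv_group",
]


class FastaFormatError(ValueError):
    pass


class BedRowError(ValueError):
    pass


class ExactTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSequence:
    """A named base string over {A,C,G,T,N} of length ``G``."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid residues in {self.name}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)


def read_fasta(path) -> list[ReferenceSequence]:
    """Read a (multi-record) FASTA file, uppercasing and validating residues.

    IUPAC ambiguity codes are normalised to ``N``; residues outside the
    IUPAC alphabet raise :class:`FastaFormatError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[ReferenceSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        residues = set(seq)
        non_iupac = residues - _VALID_BASES - _IUPAC_AMBIGUOUS
        if non_iupac:
            raise FastaFormatError(
                f"record {rec.id!r}: non-IUPAC residues {sorted(non_iupac)}"
            )
        ambiguous = residues & _IUPAC_AMBIGUOUS
        if ambiguous:
            logger.warning(
                "record %s: normalising ambiguity codes %s to N",
                rec.id, sorted(ambiguous),
            )
            seq = re.sub(f"[{''.join(sorted(ambiguous))}]", "N", seq)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} is empty")
        out.append(ReferenceSequence(name=rec.id, bases=seq))
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Empirical observations (BED-like cohort tables)
# ---------------------------------------------------------------------------

@dataclass
class VariantObservation:
    """One empirical variant: sample tag, location, type and length.

    For insertions ``end == start`` (point of insertion) and ``length`` is
    the inserted-allele length (5th BED column when present).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    vtype: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("observation length must be >= 1")
        if self.vtype != "INS" and self.start >= self.end:
            raise ValueError("interval observation requires start < end")


def read_bed_variants(
    paths: Sequence, sample_ids: Sequence[str], strict: bool = True
) -> list[VariantObservation]:
    """Read BED-like variant tables (one file per sample).

    Expected columns: chrom, start, end, type[, length].  Coordinates are
    0-based half-open.  Insertions take their length from the 5th column
    when present (else ``end - start``) and are stored as point events.
    With ``strict=False`` unknown type tokens are dropped (with a logged
    count) instead of raising.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("one sample id per input file is required")
    out: list[VariantObservation] = []
    dropped = 0
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str
        )
        if df.shape[1] < 4:
            raise BedRowError(f"{path}: expected at least 4 columns")
        for i, row in enumerate(df.itertuples(index=False), start=1):
            vtype = str(row[3]).upper()
            if vtype not in KNOWN_BED_TYPES:
                if strict:
                    raise BedRowError(f"{path} line {i}: unknown type {vtype!r}")
                dropped += 1
                continue
            try:
                start, end = int(row[1]), int(row[2])
            except ValueError as exc:
                raise BedRowError(f"{path} line {i}: {exc}") from exc
            if vtype == "INS":
                length = None
                if len(row) > 4 and not pd.isna(row[4]):
                    length = int(row[4])
                if length is None:
                    length = end - start
                obs_end = start
            else:
                if start >= end:
                    raise BedRowError(
                        f"{path} line {i}: start {start} >= end {end}"
                    )
                length = end - start
                obs_end = end
            try:
                out.append(
                    VariantObservation(
                        sample_id=sid, chrom=str(row[0]), start=start,
                        end=obs_end, vtype=vtype, length=length,
                    )
                )
            except ValueError as exc:
                raise BedRowError(f"{path} line {i}: {exc}") from exc
    if dropped:
        logger.info("dropped %d observations with unsupported type tokens", dropped)
    return out


def read_bed_regions(path) -> list[tuple[int, int]]:
    """Plain interval BED (e.g. tandem-repeat regions): chrom, start, end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ivs = [(int(r[1]), int(r[2])) for r in df.itertuples(index=False)]
    for a, b in ivs:
        if a >= b:
            raise BedRowError(f"{path}: empty region [{a},{b})")
    return sorted(ivs)


# ---------------------------------------------------------------------------
# Exact-mode tables
# ---------------------------------------------------------------------------

@dataclass
class ExactVariantRow:
    """One row of an exact-mode table (1-based ``position``)."""

    position: int
    vtype: str
    length: int
    region_b_start: int | None = None
    region_b_end: int | None = None
    source_start: int | None = None
    source_end: int | None = None
    dest: int | None = None
    csv_group: str | None = None


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "."):
        return None
    return int(float(value))


def read_exact_table(path) -> list[ExactVariantRow]:
    """Parse a tab-separated exact-mode table.

    Recognised columns are listed in :data:`EXACT_COLUMNS`; unknown extra
    columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    extra = [c for c in df.columns if c not in EXACT_COLUMNS]
    if extra:
        logger.warning("exact table %s: ignoring unknown columns %s", path, extra)
    rows: list[ExactVariantRow] = []
    for r in df.to_dict("records"):
        rows.append(
            ExactVariantRow(
                position=int(r["position"]),
                vtype=str(r["vtype"]).upper(),
                length=int(r["length"]),
                region_b_start=_opt_int(r.get("region_b_start")),
                region_b_end=_opt_int(r.get("region_b_end")),
                source_start=_opt_int(r.get("source_start")),
                source_end=_opt_int(r.get("source_end")),
                dest=_opt_int(r.get("dest")),
                csv_group=(
                    None
                    if r.get("csv_group") is None
                    or (isinstance(r.get("csv_group"), float) and np.isnan(r["csv_group"]))
                    else str(r["csv_group"])
                ),
            )
        )
    return rows


def write_exact_table(rows: Sequence[ExactVariantRow], path) -> None:
    df = pd.DataFrame(
        [
            {
                "position": r.position,
                "vtype": r.vtype,
                "length": r.length,
                "region_b_start": r.region_b_start,
                "region_b_end": r.region_b_end,
                "source_start": r.source_start,
                "source_end": r.source_end,
                "dest": r.dest,
                "csv_group": r.csv_group,
            }
            for r in rows
        ],
        columns=EXACT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, na_rep=".")


_EXACT_TYPES = {
    "DEL", "INS", "INV", "DUP", "TRA", "TRA_BAL", "TRA_UNBAL",
    "SMALL_DEL", "SMALL_INS", "SNP",
}


def validate_exact_table(
    rows: Sequence[ExactVariantRow], reference: ReferenceSequence
) -> list[ExactVariantRow]:
    """Field-completion, coordinate-range and type-consistency checks.

    Balanced translocations must carry both exchanged regions; duplications
    must carry the source and destination positions.  Raises
    :class:`ExactTableError` naming the first offending row.
    """
    G = reference.length
    for i, row in enumerate(rows, start=1):
        where = f"exact table row {i} ({row.vtype} at {row.position})"
        if row.vtype not in _EXACT_TYPES:
            raise ExactTableError(f"{where}: unknown variant type")
        if not 1 <= row.position <= G:
            raise ExactTableError(
                f"{where}: position outside reference of length {G}"
            )
        if row.length < 1:
            raise ExactTableError(f"{where}: length must be >= 1")
        if row.vtype in ("TRA", "TRA_BAL"):
            if row.region_b_start is None or row.region_b_end is None:
                raise ExactTableError(f"{where}: missing exchanged region")
            if not 1 <= row.region_b_start < row.region_b_end <= G:
                raise ExactTableError(f"{where}: exchanged region out of range")
        if row.vtype == "DUP":
            if row.source_start is None or row.source_end is None:
                raise ExactTableError(f"{where}: missing source region")
            if row.dest is None:
                raise ExactTableError(f"{where}: missing destination")
            if not 1 <= row.source_start < row.source_end <= G:
                raise ExactTableError(f"{where}: source region out of range")
            if not 1 <= row.dest <= G:
                raise ExactTableError(f"{where}: destination out of range")
        span_end = row.position - 1 + (
            row.length if row.vtype in ("DEL", "INV", "SMALL_DEL") else 1
        )
        if span_end > G:
            raise ExactTableError(f"{where}: event extends past the reference")
    return list(rows)


# ---------------------------------------------------------------------------
# Population-VCF filtering
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(
    r"^\s*(?P<field>[\w.-]+)\s*(?P<op>>=|<=|==|>|<|≥|≤)\s*"
    r"(?P<value>[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\s*$"
)

_OPS = {
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    "≥": lambda a, b: a >= b,
    "≤": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
}


@dataclass
class PopulationFilterExpression:
    """AND-conjunction of ``KEY OP NUMBER`` clauses on VCF INFO fields."""

    clauses: list[tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def parse(cls, text: str) -> "PopulationFilterExpression":
        parts = re.split(r"\s+(?:AND|and)\s+|\s*&\s*", text.strip())
        clauses = []
        for part in parts:
            if not part.strip():
                continue
            m = _CLAUSE_RE.match(part)
            if not m:
                raise ValueError(f"cannot parse filter clause {part!r}")
            clauses.append((m["field"], m["op"], float(m["value"])))
        if not clauses:
            raise ValueError("empty filter expression")
        return cls(clauses=clauses)

    def fields(self) -> list[str]:
        return [f for f, _, _ in self.clauses]

    def evaluate(self, info: dict) -> bool:
        for key, op, threshold in self.clauses:
            value = info.get(key)
            if value is None:
                return False
            if isinstance(value, (tuple, list)):
                value = value[0]
            try:
                value = float(value)
            except (TypeError, ValueError):
                return False
            if not _OPS[op](value, threshold):
                return False
        return True


def filter_population_vcf(
    vcf_path, expression: PopulationFilterExpression | str
) -> list[ExactVariantRow]:
    """Select SV records satisfying all filter clauses, as exact-mode rows.

    Every clause field must be declared in the VCF header INFO section.
    Among mutually overlapping survivors, the first by coordinate is kept
    and the rest dropped, so the result is directly usable by exact mode.
    """
    import pysam

    if isinstance(expression, str):
        expression = PopulationFilterExpression.parse(expression)
    vcf = pysam.VariantFile(str(vcf_path))
    declared = set(vcf.header.info.keys())
    missing = [f for f in expression.fields() if f not in declared]
    if missing:
        raise ValueError(f"INFO fields not declared in VCF header: {missing}")

    survivors: list[tuple[int, int, ExactVariantRow]] = []
    for rec in vcf:
        info = dict(rec.info)
        if not expression.evaluate(info):
            continue
        svtype = info.get("SVTYPE")
        if svtype is None:
            continue
        svtype = str(svtype).upper()
        svlen = info.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        end = rec.stop  # half-open 0-based end from END or ref allele
        start0 = rec.start
        if svlen is not None:
            length = abs(int(svlen))
        else:
            length = max(1, end - start0)
        span = (start0, start0 + 1) if svtype == "INS" else (start0, max(end, start0 + 1))
        survivors.append(
            (
                span[0],
                span[1],
                ExactVariantRow(position=start0 + 1, vtype=svtype, length=length),
            )
        )
    survivors.sort(key=lambda t: (t[0], t[1]))
    kept: list[ExactVariantRow] = []
    last_end = -1
    for s, e, row in survivors:
        if s < last_end:
            continue
        kept.append(row)
        last_end = e
    return kept


# ---------------------------------------------------------------------------
# Output emission: donor FASTA, truth table, VCF 4.3
# ---------------------------------------------------------------------------

TRUTH_FIXED_COLUMNS = [
    "id", "event_id", "csv_type", "csv_index", "vtype",
    "ref_start", "ref_end", "length", "payload",
    "region_b_start", "region_b_end", "dest", "copies", "inverted", "copy_b",
    "genotype",
]


def _truth_rows(
    variants: Sequence[VariantRecord], cmap: CoordinateMap, ploidy: int
) -> pd.DataFrame:
    rows = []
    for rec in variants:
        for sub in rec.simple_records():
            row = {
                "id": sub.id,
                "event_id": rec.id,
                "csv_type": sub.csv_type or ".",
                "csv_index": sub.csv_index if sub.csv_index is not None else ".",
                "vtype": sub.vtype,
                "ref_start": sub.start,
                "ref_end": sub.end,
                "length": sub.length,
                "payload": sub.payload or ".",
                "region_b_start": sub.region_b[0] if sub.region_b else ".",
                "region_b_end": sub.region_b[1] if sub.region_b else ".",
                "dest": sub.dest if sub.dest is not None else ".",
                "copies": sub.copies if sub.vtype == "DUP" else ".",
                "inverted": int(sub.inverted) if sub.vtype == "DUP" else ".",
                "copy_b": int(sub.copy_b) if sub.vtype == "TRA_UNBAL" else ".",
                "genotype": "|".join(
                    "1" if h in (rec.genotype or ()) else "0" for h in range(ploidy)
                ),
            }
            for h in range(ploidy):
                span = cmap.lookup(h, sub.id) if h < len(cmap.positions) else None
                row[f"donor_start_hap{h + 1}"] = span[0] if span else "."
                row[f"donor_end_hap{h + 1}"] = span[1] if span else "."
            rows.append(row)
    cols = TRUTH_FIXED_COLUMNS + [
        f"donor_{w}_hap{h + 1}" for h in range(ploidy) for w in ("start", "end")
    ]
    return pd.DataFrame(rows, columns=cols)


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Difference in length between REF and ALT alleles">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Full inserted allele sequence">',
    '##INFO=<ID=DEST,Number=1,Type=Integer,Description="1-based insertion point of duplicated copies">',
    '##INFO=<ID=COPIES,Number=1,Type=Integer,Description="Total copy number of the duplicated segment">',
    '##INFO=<ID=INVCOPY,Number=0,Type=Flag,Description="Duplicated copy is inverted">',
    '##INFO=<ID=REGIONB,Number=2,Type=Integer,Description="1-based start and end of the second translocation region">',
    '##INFO=<ID=BALANCED,Number=0,Type=Flag,Description="Balanced translocation">',
    '##INFO=<ID=CSV-TYPE,Number=1,Type=String,Description="Complex SV template identifier">',
    '##INFO=<ID=CSV-INDEX,Number=1,Type=Integer,Description="Component index within the complex SV">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=INV,Description="Inversion">',
    '##ALT=<ID=DUP,Description="Duplication">',
    '##ALT=<ID=TRA,Description="Intrachromosomal translocation">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _vcf_record(
    sub: VariantRecord, parent: VariantRecord, bases: str, chrom: str, ploidy: int
) -> str:
    s, e = sub.start, sub.end
    info: list[str] = []
    gt = "|".join("1" if h in (parent.genotype or ()) else "0" for h in range(ploidy))

    def anchor(pos0: int) -> tuple[int, str]:
        """1-based POS of the base before pos0 plus that base (left anchor)."""
        if pos0 > 0:
            return pos0, bases[pos0 - 1]
        return 1, bases[0]

    t = sub.vtype
    if t == "SNP":
        pos, ref, alt = s + 1, bases[s], sub.payload
    elif t == "SMALL_DEL":
        if s > 0:
            pos, ref, alt = s, bases[s - 1 : e], bases[s - 1]
        else:  # right-anchored fallback at the sequence start
            pos, ref, alt = 1, bases[s : e + 1], bases[e]
    elif t == "SMALL_INS":
        pos, a = anchor(s)
        ref = a
        alt = (a + sub.payload) if s > 0 else (sub.payload + a)
    else:
        pos, ref = anchor(s)
        alt = f"<{ {'TRA_BAL': 'TRA', 'TRA_UNBAL': 'TRA'}.get(t, t) }>"
        info.append(f"SVTYPE={ {'TRA_BAL': 'TRA', 'TRA_UNBAL': 'TRA'}.get(t, t) }")
        if t == "DEL":
            info += [f"SVLEN={-sub.length}", f"END={e}"]
        elif t == "INS":
            info += [f"SVLEN={sub.length}", f"END={pos}", f"INSSEQ={sub.payload}"]
        elif t == "INV":
            info += [f"SVLEN={sub.length}", f"END={e}"]
        elif t == "DUP":
            extra = sub.length * (sub.copies - 1)
            info += [f"SVLEN={extra}", f"END={e}"]
            if sub.dest is not None:
                info.append(f"DEST={sub.dest + 1}")
            info.append(f"COPIES={sub.copies}")
            if sub.inverted:
                info.append("INVCOPY")
        elif t == "TRA_BAL":
            b1, b2 = sub.region_b
            info += [f"SVLEN=0", f"END={e}", f"REGIONB={b1 + 1},{b2}", "BALANCED"]
        elif t == "TRA_UNBAL":
            b1, b2 = sub.region_b
            net = (b2 - b1) - sub.length if sub.copy_b else -sub.length
            info += [f"SVLEN={net}", f"END={e}", f"REGIONB={b1 + 1},{b2}"]
    if t in ("SNP", "SMALL_DEL", "SMALL_INS"):
        info.append(f"SVTYPE={t}")
        if t == "SMALL_DEL":
            info.append(f"SVLEN={-sub.length}")
        elif t == "SMALL_INS":
            info.append(f"SVLEN={sub.length}")
    if sub.csv_type:
        info.append(f"CSV-TYPE={sub.csv_type}")
        info.append(f"CSV-INDEX={sub.csv_index}")
    info_str = ";".join(info) if info else "."
    vid = f"sv{parent.id}" if sub is parent else f"sv{parent.id}.{sub.csv_index}"
    return "\t".join(
        [chrom, str(pos), vid, ref, alt, ".", "PASS", info_str, "GT", gt]
    )


def write_vcf(
    reference: ReferenceSequence,
    variants: Sequence[VariantRecord],
    path,
    ploidy: int = 2,
    sample_name: str = "SIMULATED",
) -> None:
    """Write all simulated variants as a VCF 4.3 file (sorted by position)."""
    lines = ["##fileformat=VCFv4.3"]
    lines.append(f"##contig=<ID={reference.name},length={reference.length}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name
    )
    body: list[tuple[int, str]] = []
    for rec in variants:
        for sub in rec.simple_records():
            line = _vcf_record(sub, rec, reference.bases, reference.name, ploidy)
            body.append((int(line.split("\t")[1]), line))
    body.sort(key=lambda t: t[0])
    lines.extend(line for _, line in body)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def emit_outputs(
    reference: ReferenceSequence,
    variants: Sequence[VariantRecord],
    donors: Sequence[str],
    cmap: CoordinateMap,
    out_prefix,
) -> dict:
    """Write donor FASTA, truth table and VCF; returns the paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ploidy = len(donors)
    for rec in variants:
        for sub in rec.simple_records():
            for h in range(ploidy):
                if (
                    rec.genotype is not None
                    and h in rec.genotype
                    and cmap.lookup(h, sub.id) is None
                ):
                    raise RuntimeError(
                        f"variant {sub.id} lacks donor coordinates on haplotype {h}"
                    )
    fasta_path = out_prefix.with_suffix(".donor.fasta")
    write_fasta(
        (
            (f"{reference.name}_hap{h + 1}", donor)
            for h, donor in enumerate(donors)
        ),
        fasta_path,
    )
    truth_path = out_prefix.with_suffix(".truth.tsv")
    _truth_rows(variants, cmap, ploidy).to_csv(truth_path, sep="\t", index=False)
    vcf_path = out_prefix.with_suffix(".vcf")
    write_vcf(reference, variants, vcf_path, ploidy=ploidy)
    return {"fasta": fasta_path, "truth": truth_path, "vcf": vcf_path}
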