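"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally; the 1-based VCF convention
is converted at this boundary and nowhere else.  Insertion position ``pos``
is the reference base *before which* the sequence is inserted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from ._dna import normalize_counted

log = logging.getLogger(__name__)

REPEAT_CLASSES = (
    "LINE",
    "LTR",
    "SVA",
    "SINE",
    "Simple repeat",
    "Low complexity",
    "Other TE",
    "Unique",
)

TE_FAMILIES = ("L1", "Alu", "SVA", "ERV", "Other", "cDNA", "reference")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class InsertionCall:
    """One structural-variant record carrying an inserted sequence.

    ``pos`` is 0-based: the insertion lies between reference bases
    ``pos - 1`` and ``pos``.  ``seq`` is empty exactly when ``sv_type`` is
    ``DEL``; a deletion instead carries its 0-based half-open ``del_span``.
    """

    id: str
    sample_id: str
    chrom: str
    pos: int
    sv_type: str  # "INS" | "DEL"
    seq: str = ""
    del_span: Optional[tuple[int, int]] = None
    read_support: int = 0
    supporting_read_ids: list[str] = field(default_factory=list)
    strand: str = "unknown"  # "+" | "-" | "unknown"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for call {self.id}")
        if self.sv_type == "INS" and not self.seq:
            raise ValueError(f"INS call {self.id} has empty sequence")
        if self.sv_type == "DEL" and self.del_span is None:
            raise ValueError(f"DEL call {self.id} has no span")


@dataclass
class IntervalTrack:
    """A named set of genomic intervals (0-based half-open)."""

    name: str
    records: list[tuple]  # (chrom, start, end, label, value-or-None)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r[0], r[1], r[2]))

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees; data = (label, value, index)."""
        out: dict[str, IntervalTree] = {}
        for i, (chrom, start, end, label, value) in enumerate(self.records):
            out.setdefault(chrom, IntervalTree()).addi(start, end, (label, value, i))
        return out

    def overlapping(self, chrom: str, pos: int) -> list[tuple]:
        tree = self.trees().get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree[pos])]


@dataclass
class LibraryEntry:
    name: str
    sequence: str
    family: str
    exons: Optional[list[tuple[int, int]]] = None  # cDNA exon spans on the entry

    @property
    def canonical_length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceLibrary:
    """TE consensus / cDNA / reference sequences keyed by name."""

    entries: dict[str, LibraryEntry]

    def __getitem__(self, name: str) -> LibraryEntry:
        return self.entries[name]

    def by_family(self, *families: str) -> list[LibraryEntry]:
        return [e for e in self.entries.values() if e.family in families]


@dataclass
class KnownTeTable:
    """Known TE polymorphisms: (chrom, 0-based pos, te_type)."""

    records: list[tuple[str, int, str]]


# ---------------------------------------------------------------------------
# repeat-class collapse


def _load_class_map() -> list[tuple[str, str]]:
    text = resources.files("tprt_detect").joinpath("data/repeat_classes.tsv").read_text()
    rules = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        pattern, cls = line.split("\t")
        rules.append((pattern.lower(), cls))
    return rules


_CLASS_RULES: Optional[list[tuple[str, str]]] = None


def collapse_repeat_class(label: str) -> str:
    """Collapse a RepeatMasker-style repeat name to the 8-class scheme."""
    global _CLASS_RULES
    if _CLASS_RULES is None:
        _CLASS_RULES = _load_class_map()
    low = label.lower()
    for pattern, cls in _CLASS_RULES:
        if low.startswith(pattern):
            return cls
    return "Other TE"


def infer_family(name: str) -> str:
    """TE family from a library entry name (header token heuristics)."""
    low = name.lower()
    if low.startswith(("l1", "line")):
        return "L1"
    if low.startswith("alu"):
        return "Alu"
    if low.startswith("sva"):
        return "SVA"
    if low.startswith(("erv", "herv", "ltr")):
        return "ERV"
    return "Other"


# ---------------------------------------------------------------------------
# readers


def read_insertion_vcf(path: str | Path, sample_id: str) -> list[InsertionCall]:
    """Read Sniffles-dialect INS/DEL records into :class:`InsertionCall`.

    INS sequence is accepted either as a literal ALT allele or from a
    ``SEQ`` info field next to a symbolic ``<INS>`` ALT.  Records of unknown
    SV type, and INS records with no recoverable sequence, are skipped with
    a logged warning.
    """
    calls: list[InsertionCall] = []
    skipped_unknown = 0
    skipped_noseq = 0

    def info_get(rec, *keys, default=None):
        # pysam raises on keys absent from the header; tolerate any dialect
        for key in keys:
            try:
                value = rec.info.get(key)
            except (KeyError, ValueError):
                continue
            if value is not None:
                return value
        return default

    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf, start=1):
            try:
                svtype = info_get(rec, "SVTYPE")
                if svtype is None:
                    alt = rec.alts[0] if rec.alts else ""
                    svtype = "DEL" if len(rec.ref) > len(alt) else "INS"
                if svtype not in ("INS", "DEL"):
                    skipped_unknown += 1
                    continue
                support = int(info_get(rec, "RE", "SUPPORT", default=0) or 0)
                rnames = info_get(rec, "RNAMES", default=())
                if isinstance(rnames, str):
                    rnames = tuple(rnames.split(","))
                strand = info_get(rec, "STRAND", "STRANDS", default="unknown")
                if isinstance(strand, tuple):
                    strand = strand[0]
                if strand not in ("+", "-"):
                    strand = "unknown"
                pos = rec.pos - 1  # 1-based VCF -> 0-based
                if svtype == "INS":
                    alt = rec.alts[0] if rec.alts else ""
                    if alt.startswith("<"):
                        seq = info_get(rec, "SEQ", default="")
                    else:
                        # Sniffles writes REF base + inserted sequence or the
                        # plain inserted sequence; strip a shared leading base.
                        seq = alt[len(rec.ref):] if alt.startswith(rec.ref) else alt
                    if not seq:
                        skipped_noseq += 1
                        log.warning("INS record %s at line %d has no sequence; skipped", rec.id, i)
                        continue
                    # VCF anchors the insertion after POS's base
                    calls.append(
                        InsertionCall(
                            id=rec.id or f"{sample_id}_{i}",
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=pos + 1 if (rec.alts and rec.alts[0].startswith(rec.ref)) else pos,
                            sv_type="INS",
                            seq=normalize_counted(seq)[0],
                            read_support=support,
                            supporting_read_ids=list(rnames),
                            strand=strand,
                        )
                    )
                else:
                    end = rec.stop  # pysam: 0-based exclusive end from END
                    calls.append(
                        InsertionCall(
                            id=rec.id or f"{sample_id}_{i}",
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=pos,
                            sv_type="DEL",
                            del_span=(pos, end),
                            read_support=support,
                            supporting_read_ids=list(rnames),
                            strand=strand,
                        )
                    )
            except (KeyError, IndexError, TypeError) as exc:
                raise VcfParseError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    if skipped_unknown:
        log.info("skipped %d records of unknown SV type", skipped_unknown)
    return calls


def read_interval_tracks(path: str | Path, kind: str = "bed") -> IntervalTrack:
    """Read a BED3+/BED6 or bedGraph file into an :class:`IntervalTrack`.

    ``kind``:
      * ``"bed"`` — label from column 4 when present;
      * ``"repeats"`` — RepeatMasker-style BED; labels collapsed to the
        8-class scheme (Unique is computed downstream as the complement);
      * ``"bedgraph"`` — column 4 is a numeric value.
    Records with ``start >= end`` are rejected and counted.
    """
    path = Path(path)
    records: list[tuple] = []
    rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                rejected += 1
                continue
            label, value = "", None
            if kind == "bedgraph":
                value = float(parts[3])
            elif len(parts) > 3:
                label = parts[3]
                if kind == "repeats":
                    label = collapse_repeat_class(label)
            records.append((chrom, start, end, label, value))
    if rejected:
        log.info("rejected %d malformed intervals in %s", rejected, path)
    return IntervalTrack(name=path.stem, records=records)


def read_sequence_libraries(
    *paths: str | Path,
    families: Optional[Mapping[str, str]] = None,
) -> SequenceLibrary:
    """Read one or more FASTA files into a :class:`SequenceLibrary`.

    Family is taken from ``families`` (name -> family) when given, else
    inferred from the header.  A header token ``exons=a-b,c-d`` records cDNA
    exon spans.  Duplicate names are an error; non-ACGTN characters become N.
    """
    entries: dict[str, LibraryEntry] = {}
    replaced_total = 0
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in entries:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            seq, replaced = normalize_counted(str(rec.seq))
            replaced_total += replaced
            exons = None
            for token in rec.description.split():
                if token.startswith("exons="):
                    exons = [
                        (int(a), int(b))
                        for a, b in (span.split("-") for span in token[6:].split(","))
                    ]
            family = (families or {}).get(rec.id) or (
                "cDNA" if exons is not None else infer_family(rec.id)
            )
            entries[rec.id] = LibraryEntry(rec.id, seq, family, exons)
    if replaced_total:
        log.info("replaced %d non-ACGTN characters with N", replaced_total)
    return SequenceLibrary(entries=entries)


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Reference genome as chrom -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_known_te_table(path: str | Path) -> KnownTeTable:
    """TSV with columns chrom, pos (0-based), te_type."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "pos", "te_type"], header=0)
    return KnownTeTable(records=[(r.chrom, int(r.pos), r.te_type) for r in df.itertuples()])


# ---------------------------------------------------------------------------
# writers


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tprt-detect
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End of DEL (1-based inclusive)">
##INFO=<ID=RE,Number=1,Type=Integer,Description="Read support">
##INFO=<ID=RNAMES,Number=.,Type=String,Description="Supporting read names">
##INFO=<ID=STRAND,Number=1,Type=String,Description="Strand">
##INFO=<ID=TE_FAMILY,Number=1,Type=String,Description="Annotated TE family">
##INFO=<ID=HALLMARKS,Number=1,Type=Integer,Description="TPRT hallmark count">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_insertion_vcf(
    calls: Sequence[InsertionCall],
    path: str | Path,
    ref: Optional[Mapping[str, str]] = None,
    info_extra: Optional[Mapping[str, Mapping[str, object]]] = None,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write calls in the Sniffles-like dialect consumed by this package.

    Deterministic: records are sorted by (chrom, pos, id).  INS ALT carries
    the literal inserted sequence.  ``info_extra`` maps call id to extra
    INFO key/values (annotation fields).
    """
    lines = ["##fileformat=VCFv4.2", "##source=tprt-detect"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(VCF_HEADER.splitlines()[2:])
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.id)):
        info = [f"SVTYPE={call.sv_type}", f"RE={call.read_support}"]
        if call.supporting_read_ids:
            info.append("RNAMES=" + ",".join(call.supporting_read_ids))
        if call.strand in "+-":
            info.append(f"STRAND={call.strand}")
        if call.sv_type == "INS":
            if ref is not None and call.pos > 0:
                # standard anchored form: POS is the base before the insertion
                anchor = ref[call.chrom][call.pos - 1]
                pos1, ref_field, alt = call.pos, anchor, anchor + call.seq
            else:
                # unanchored dialect: insertion precedes the POS base
                pos1, ref_field, alt = call.pos + 1, "N", call.seq
        else:
            start, end = call.del_span
            pos1 = start + 1
            ref_field, alt = "N", "<DEL>"
            info.append(f"END={end}")
        for k, v in (info_extra or {}).get(call.id, {}).items():
            info.append(f"{k}={v}")
        lines.append(
            "\t".join(
                [call.chrom, str(pos1), call.id, ref_field, alt, ".", "PASS",
                 ";".join(info)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, sort_by: Optional[list[str]] = None) -> None:
    if sort_by and len(df):
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def write_outputs(
    outdir: str | Path,
    calls: Sequence[InsertionCall],
    annotation: Optional[pd.DataFrame] = None,
    inversion: Optional[pd.DataFrame] = None,
    cohort: Optional[pd.DataFrame] = None,
    support: Optional[pd.DataFrame] = None,
    ref: Optional[Mapping[str, str]] = None,
    header_meta: Optional[Mapping[str, object]] = None,
) -> dict[str, Path]:
    """Write deterministic, sorted TSV tables plus an annotated VCF.

    Rerunning on identical inputs is byte-identical.  Returns the paths
    written, keyed by table name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    info_extra = {}
    if annotation is not None and len(annotation):
        for row in annotation.itertuples():
            info_extra[row.call_id] = {
                "TE_FAMILY": row.te_family,
                "HALLMARKS": row.hallmark_count,
            }
    vcf_path = outdir / "calls.vcf"
    write_insertion_vcf(calls, vcf_path, ref=ref, info_extra=info_extra)
    written["vcf"] = vcf_path

    tables = {
        "annotation": (annotation, ["call_id"]),
        "inversion": (inversion, ["call_id"]),
        "cohort": (cohort, ["chrom", "pos", "locus_id"]),
        "support": (support, ["locus_id"] if support is not None and "locus_id" in support else None),
    }
    for name, (df, sort_by) in tables.items():
        if df is None:
            continue
        path = outdir / f"{name}.tsv"
        if header_meta:
            with open(path, "w") as fh:
                for k, v in header_meta.items():
                    fh.write(f"# {k}={v}\n")
            df_sorted = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True) if sort_by and len(df) else df
            df_sorted.to_csv(path, sep="\t", index=False, mode="a", lineterminator="\n", float_format="%.6g")
        else:
            _write_tsv(df, path, sort_by)
        written[name] = path
    return written


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Plain FASTA writer used by the simulator (deterministic layout)."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
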