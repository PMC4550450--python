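"""Reading barcode records, NUMT screening, translation, BIN representatives.

COI barcodes are protein-coding mitochondrial sequences, so nuclear
pseudogene copies (NUMTs) betray themselves through in-frame stop codons
or frameshifts.  Records are screened by translating all three reading
frames under the invertebrate mitochondrial code and requiring a
stop-free frame; one representative per BIN (the longest sequence with
fewest ambiguous bases) is then selected for downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

#: NCBI translation table for invertebrate mitochondria.
INVERTEBRATE_MITO_CODE = 5

METADATA_COLUMNS = ("record_id", "bin_id", "order", "family", "genus", "source")


class RecordError(ValueError):
    """Malformed or inconsistent input records."""


@dataclass
class SequenceRecord:
    """One barcode record with its taxonomy and provenance."""

    record_id: str
    bin_id: str
    order: str
    family: str
    genus: str
    nt_seq: str
    source: str = "voucher"  # 'voucher' or 'mined'
    n_ambiguous: int = field(init=False)

    def __post_init__(self):
        if len(self.nt_seq) < 1:
            raise RecordError(f"{self.record_id}: empty sequence")
        if self.source not in ("voucher", "mined"):
            raise RecordError(
                f"{self.record_id}: source must be 'voucher' or 'mined', "
                f"got {self.source!r}")
        self.nt_seq = self.nt_seq.upper()
        self.n_ambiguous = sum(c not in "ACGT" for c in self.nt_seq)


@dataclass(frozen=True)
class QCResult:
    record_id: str
    chosen_frame: int
    stop_codons: int
    n_codons: int
    passes: bool


def read_records(fasta_path: Path | str, metadata_path: Path | str) -> list[SequenceRecord]:
    """Read a nucleotide FASTA plus its tab-delimited metadata table.

    Every FASTA id must have a metadata row; duplicates are an error.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise RecordError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise RecordError(f"duplicate record_id in metadata: {dups}")
    meta = meta.set_index("record_id")

    records, seen = [], set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise RecordError(f"duplicate record_id in FASTA: {rid}")
        seen.add(rid)
        if rid not in meta.index:
            raise RecordError(f"FASTA record {rid!r} has no metadata row")
        row = meta.loc[rid]
        records.append(SequenceRecord(
            record_id=rid, bin_id=row["bin_id"], order=row["order"],
            family=row["family"], genus=row["genus"],
            nt_seq=str(entry.seq), source=row["source"] or "voucher"))
    return records


def _codon_tables(code: int):
    table = CodonTable.unambiguous_dna_by_id[code]
    return table.forward_table, set(table.stop_codons)


def _frame_codons(seq: str, frame: int) -> list[str]:
    usable = len(seq) - frame
    usable -= usable % 3
    return [seq[i:i + 3] for i in range(frame, frame + usable, 3)]


def screen_numt(record: SequenceRecord, code: int = INVERTEBRATE_MITO_CODE,
                min_codons: int = 150) -> QCResult:
    """Choose the reading frame with fewest stop codons and flag NUMT-like records.

    A record passes when its best frame is stop-free and long enough
    (>= ``min_codons`` complete codons).  Failing records are flagged,
    not deleted.
    """
    _, stops = _codon_tables(code)
    best_frame, best_stops, best_len = 0, None, 0
    for frame in (0, 1, 2):
        codons = _frame_codons(record.nt_seq, frame)
        n_stop = sum(c in stops for c in codons)
        if best_stops is None or n_stop < best_stops:
            best_frame, best_stops, best_len = frame, n_stop, len(codons)
    passes = best_stops == 0 and best_len >= min_codons
    return QCResult(record.record_id, best_frame, best_stops, best_len, passes)


def translate(record: SequenceRecord | str, frame: int = 0,
              code: int = INVERTEBRATE_MITO_CODE,
              on_stop: str = "raise") -> str:
    """Translate a nucleotide sequence in the given frame.

    Codons containing any non-ACGT symbol become ``X``; a trailing
    partial codon is dropped.  An internal stop codon raises (it should
    have been caught by :func:`screen_numt`) unless ``on_stop='mask'``,
    in which case it becomes ``X``.
    """
    seq = record.nt_seq if isinstance(record, SequenceRecord) else record.upper()
    fwd, stops = _codon_tables(code)
    out = []
    for codon in _frame_codons(seq, frame):
        if any(c not in "ACGT" for c in codon):
            out.append("X")
        elif codon in stops:
            if on_stop == "mask":
                out.append("X")
            else:
                rid = record.record_id if isinstance(record, SequenceRecord) else "<seq>"
                raise RecordError(f"{rid}: internal stop codon in frame {frame}")
        else:
            out.append(fwd[codon])
    return "".join(out)


def select_representatives(records: list[SequenceRecord],
                           qc: dict[str, QCResult] | None = None,
                           code: int = INVERTEBRATE_MITO_CODE,
                           min_codons: int = 150) -> dict[str, str]:
    """Pick one QC-passing record per BIN: longest, then fewest Ns, then id.

    Returns a mapping ``bin_id -> record_id``.  BINs with no passing
    record are dropped with a warning.  The result is independent of the
    input ordering.
    """
    if qc is None:
        qc = {r.record_id: screen_numt(r, code=code, min_codons=min_codons)
              for r in records}
    by_bin: dict[str, list[SequenceRecord]] = {}
    for r in records:
        if not r.bin_id:
            raise RecordError(f"{r.record_id}: missing bin_id")
        by_bin.setdefault(r.bin_id, []).append(r)

    chosen: dict[str, str] = {}
    for bin_id in sorted(by_bin):
        passing = [r for r in by_bin[bin_id] if qc[r.record_id].passes]
        if not passing:
            warnings.warn(f"BIN {bin_id}: no QC-passing record; dropped",
                          stacklevel=2)
            continue
        best = min(passing,
                   key=lambda r: (-len(r.nt_seq), r.n_ambiguous, r.record_id))
        chosen[bin_id] = best.record_id
    return chosen


def write_qc_report(qc: dict[str, QCResult], path: Path | str) -> None:
    df = pd.DataFrame(
        [(q.record_id, q.chosen_frame, q.stop_codons, q.n_codons, q.passes)
         for q in qc.values()],
        columns=["record_id", "chosen_frame", "stop_codons", "n_codons", "passes"])
    df.to_csv(path, sep="\t", index=False)


def write_representatives(reps: dict[str, str], path: Path | str) -> None:
    pd.DataFrame(sorted(reps.items()), columns=["bin_id", "record_id"]).to_csv(
        path, sep="\t", index=False)


def read_representatives(path: Path | str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["bin_id"], df["record_id"]))
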