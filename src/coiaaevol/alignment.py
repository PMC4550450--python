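"""Reference-guided alignment into the 219-site consensus coordinate frame.

Instead of a progressive multiple alignment, every protein is aligned
pairwise (global Needleman-Wunsch with affine gaps) against a class-wide
consensus.  COI barcode proteins are near-fixed length, so this keeps
indel coordinates deterministic: consensus sites are numbered 1..N and
never renumbered; insertions relative to the consensus are recorded as
"after site s".

The consensus is bootstrapped: a seed consensus is the column majority
over all full-frame (219-residue) sequences, then alignment and
consensus construction are iterated so gap placements are judged
against a consensus the whole sample agrees on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .dayhoff import AMINO_ACIDS, AA_INDEX, SubstitutionModel, load_dayhoff_model


class UnalignableError(ValueError):
    """Alignment score fell below the configured floor."""


@dataclass(frozen=True)
class AlignedProtein:
    """One protein expressed in consensus coordinates.

    ``columns`` has exactly one character per consensus site ('-' for a
    deletion relative to the consensus); ``insertions`` are extra
    residues that follow a consensus site (``after_site`` is 1-based;
    0 means before site 1).
    """

    record_id: str
    columns: str
    insertions: tuple[tuple[int, str], ...] = ()
    score: float | None = None

    @property
    def n_gap_columns(self) -> int:
        return self.columns.count("-")

    def sequence(self) -> str:
        """Reconstruct the original (unaligned) protein string."""
        ins = dict(self.insertions)
        out = [ins.get(0, "")]
        for site, res in enumerate(self.columns, start=1):
            if res != "-":
                out.append(res)
            out.append(ins.get(site, ""))
        return "".join(out)


@dataclass
class ConsensusProfile:
    """Per-site majority residue and residue counts over an alignment."""

    residues: str
    counts: np.ndarray  # (n_sites, 20) counts of standard residues

    @property
    def n_sites(self) -> int:
        return len(self.residues)

    @property
    def site_frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)


def build_consensus(rows: list[AlignedProtein]) -> ConsensusProfile:
    """Majority residue per column among non-gap residues; ties go to the
    alphabetically first residue; all-gap columns stay '-'."""
    if not rows:
        raise ValueError("cannot build a consensus from zero rows")
    n_sites = len(rows[0].columns)
    for r in rows:
        if len(r.columns) != n_sites:
            raise ValueError(
                f"{r.record_id}: {len(r.columns)} columns, expected {n_sites}")
    counts = np.zeros((n_sites, 20), dtype=int)
    for r in rows:
        for i, res in enumerate(r.columns):
            j = AA_INDEX.get(res)
            if j is not None:
                counts[i, j] += 1
    residues = []
    for i in range(n_sites):
        if counts[i].sum() == 0:
            residues.append("-")
        else:
            # argmax returns the first maximum => alphabetical tie-break
            residues.append(AMINO_ACIDS[int(np.argmax(counts[i]))])
    return ConsensusProfile("".join(residues), counts)


_ALIGN_ALPHABET = AMINO_ACIDS + "X"


def _make_aligner(model: SubstitutionModel, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    scores = model.log_odds_matrix(2.5)
    mat = substitution_matrices.Array(alphabet=_ALIGN_ALPHABET, dims=2)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[a, b] = scores[i, j]
    # X (ambiguous) is scored neutrally against everything
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_to_reference(protein: str, reference: ConsensusProfile,
                       model: SubstitutionModel | None = None,
                       gap_open: float = 10.0, gap_extend: float = 1.0,
                       score_floor: float = 0.0,
                       record_id: str = "",
                       _aligner: Align.PairwiseAligner | None = None) -> AlignedProtein:
    """Globally align ``protein`` to the consensus and express it in
    consensus coordinates.

    Scores are half-bit log-odds from the substitution model at 250 PAM
    with affine gap penalties (a gap of length L costs
    ``gap_open + L * gap_extend``).  Raises :class:`UnalignableError`
    when the optimal score is below ``score_floor``.
    """
    if model is None:
        model = load_dayhoff_model()
    aligner = _aligner if _aligner is not None else _make_aligner(
        model, gap_open, gap_extend)
    target = reference.residues.replace("-", "X")
    aln = aligner.align(target, protein)[0]
    if aln.score < score_floor:
        raise UnalignableError(
            f"{record_id or protein[:12]}: score {aln.score:.1f} below floor "
            f"{score_floor:.1f}")

    n_sites = reference.n_sites
    columns = ["-"] * n_sites
    insertions: list[tuple[int, str]] = []
    t_prev = q_prev = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        if q0 > q_prev:  # residues not matched to any consensus site
            insertions.append((t_prev, protein[q_prev:q0]))
        for k in range(t1 - t0):
            columns[t0 + k] = protein[q0 + k]
        t_prev, q_prev = t1, q1
    if q_prev < len(protein):
        insertions.append((t_prev, protein[q_prev:]))
    return AlignedProtein(record_id, "".join(columns), tuple(insertions),
                          score=float(aln.score))


def align_rows(proteins: dict[str, str], reference: ConsensusProfile,
               model: SubstitutionModel | None = None,
               gap_open: float = 10.0, gap_extend: float = 1.0,
               score_floor: float = 0.0) -> tuple[list[AlignedProtein], list[str]]:
    """Align many proteins against one reference; returns (rows, skipped ids)."""
    if model is None:
        model = load_dayhoff_model()
    aligner = _make_aligner(model, gap_open, gap_extend)
    rows, skipped = [], []
    for rid in sorted(proteins):
        try:
            rows.append(align_to_reference(
                proteins[rid], reference, model, gap_open, gap_extend,
                score_floor, record_id=rid, _aligner=aligner))
        except UnalignableError:
            skipped.append(rid)
    return rows, skipped


STANDARD_BARCODE_SITES = 219


def build_reference_frame(proteins: dict[str, str],
                          model: SubstitutionModel | None = None,
                          frame_length: int | None = STANDARD_BARCODE_SITES,
                          n_passes: int = 2,
                          **align_kwargs):
    """Bootstrapped consensus construction.

    The seed consensus is the column majority over all full-frame
    sequences (length ``frame_length``, the 219 sites of a standard
    barcode; the modal length is used when ``frame_length`` is None or
    unrepresented) — no alignment needed.  Each subsequent pass aligns
    every sequence to the current consensus and rebuilds it from the
    aligned rows; two alignment passes make gap placements robust to
    noise in the seed majority.  Anchoring at the full frame keeps
    coordinates stable even when deletion-bearing lineages dominate the
    sample.

    Returns ``(consensus, rows, skipped_ids)``.
    """
    if not proteins:
        raise ValueError("no proteins to align")
    lengths = Counter(len(p) for p in proteins.values())
    if frame_length is not None and lengths.get(frame_length, 0) >= 2:
        modal_len = frame_length
    else:
        modal_len = lengths.most_common(1)[0][0]
    seed_rows = [AlignedProtein(rid, p) for rid, p in sorted(proteins.items())
                 if len(p) == modal_len]
    consensus = build_consensus(seed_rows)
    rows, skipped = [], []
    for _ in range(max(1, n_passes)):
        rows, skipped = align_rows(proteins, consensus, model, **align_kwargs)
        consensus = build_consensus(rows)
    return consensus, rows, skipped


# ---------------------------------------------------------------------------
# aligned-FASTA IO (expanded coordinates: insertion columns are added so
# every row has the same width; consensus sites keep their order)

def _insertion_layout(rows: list[AlignedProtein]) -> dict[int, int]:
    width: dict[int, int] = {}
    for r in rows:
        for site, res in r.insertions:
            width[site] = max(width.get(site, 0), len(res))
    return width


def write_alignment_fasta(rows: list[AlignedProtein], path: Path | str) -> None:
    width = _insertion_layout(rows)
    with open(path, "w") as fh:
        for r in rows:
            ins = dict(r.insertions)
            parts = [ins.get(0, "").ljust(width.get(0, 0), "-")]
            for site, res in enumerate(r.columns, start=1):
                parts.append(res)
                if site in width:
                    parts.append(ins.get(site, "").ljust(width[site], "-"))
            fh.write(f">{r.record_id}\n{''.join(parts)}\n")


def read_alignment_fasta(path: Path | str) -> dict[str, str]:
    """Read an aligned protein FASTA as plain gapped strings."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_consensus_fasta(consensus: ConsensusProfile, path: Path | str,
                          name: str = "consensus") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{consensus.residues}\n")
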