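"""Pairwise local target-template alignments and per-alignment statistics.

Implements the coverage, identity and similarity measures used throughout
the analysis:

* target sequence coverage      q      = 100 * N_ali / N_tot
* interface coverage            q_int  = 100 * N_int_ali / N_int_tot
* domain coverage               q_dom  = q restricted to a user-supplied domain
* alignment identity/similarity a_iden = 100 * N_iden / L_ali,
                                a_sim  = 100 * N_pos  / L_ali
* interface identity/similarity i_iden, i_sim — the same ratios restricted to
  columns whose target residue belongs to the binding site

where L_ali counts target residues in the alignment plus gap columns in the
aligned target string, N_iden counts identical aligned pairs and N_pos counts
aligned pairs with a strictly positive substitution-matrix score.

A local alignment is classified *full interface coverage* (FIC) when at most
``tolerance`` (default 1) target interface residues fall outside it.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Collection, Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Blast import NCBIXML

from .errors import AlignmentError, ParameterError

__all__ = [
    "PairwiseLocalAlignment", "AlignmentMetrics", "load_matrix",
    "target_coverage", "interface_coverage", "classify_fic",
    "alignment_identity_similarity", "interface_identity_similarity",
    "domain_coverage", "compute_metrics", "filter_pool", "subset_by_qmax",
    "parse_blast_xml", "read_alignments_tsv", "write_alignments_tsv",
    "read_fasta_lengths",
]

GAP = "-"
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_FIC_TOLERANCE = 1

TSV_COLUMNS = [
    "target_id", "template_id", "e_value",
    "target_start", "target_end", "template_start", "template_end",
    "target_aln", "template_aln",
    "target_full_length", "template_full_length",
]


def load_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix (BLOSUM62 by default)."""
    return substitution_matrices.load(name)


@dataclass(frozen=True)
class PairwiseLocalAlignment:
    """One local alignment of a target sequence against a template."""

    target_id: str
    template_id: str
    e_value: float
    target_aln: str
    template_aln: str
    target_start: int
    target_end: int
    template_start: int
    template_end: int
    target_full_length: int
    template_full_length: int

    def __post_init__(self):
        if len(self.target_aln) != len(self.template_aln):
            raise AlignmentError(
                f"{self.target_id}/{self.template_id}: aligned strings differ "
                f"in length ({len(self.target_aln)} vs {len(self.template_aln)})"
            )
        if any(t == GAP and m == GAP
               for t, m in zip(self.target_aln, self.template_aln)):
            raise AlignmentError(
                f"{self.target_id}/{self.template_id}: column with gaps on both sides"
            )
        n_t = sum(c != GAP for c in self.target_aln)
        if n_t != self.target_end - self.target_start + 1:
            raise AlignmentError(
                f"{self.target_id}/{self.template_id}: target span "
                f"{self.target_start}-{self.target_end} inconsistent with "
                f"{n_t} non-gap target characters"
            )
        n_m = sum(c != GAP for c in self.template_aln)
        if n_m != self.template_end - self.template_start + 1:
            raise AlignmentError(
                f"{self.target_id}/{self.template_id}: template span "
                f"{self.template_start}-{self.template_end} inconsistent with "
                f"{n_m} non-gap template characters"
            )

    @property
    def n_ali(self) -> int:
        """Number of target residues in the alignment."""
        return self.target_end - self.target_start + 1

    @property
    def l_ali(self) -> int:
        """Alignment length: target residues plus target-side gap columns."""
        return len(self.target_aln)

    def target_positions(self) -> range:
        """Target sequence positions covered by the alignment (1-based)."""
        return range(self.target_start, self.target_end + 1)

    def columns_with_target_positions(self):
        """Yield (column_index, target_position_or_None, t_char, m_char)."""
        pos = self.target_start
        for k, (t, m) in enumerate(zip(self.target_aln, self.template_aln)):
            if t == GAP:
                yield k, None, t, m
            else:
                yield k, pos, t, m
                pos += 1


@dataclass
class AlignmentMetrics:
    """All per-alignment statistics for one local alignment."""

    target_id: str
    template_id: str
    e_value: float
    q: float
    q_int: float | None
    q_dom: float | None
    a_iden: float
    a_sim: float
    i_iden: float | None
    i_sim: float | None
    is_fic: bool | None
    missing_interface_count: int | None


def target_coverage(aln: PairwiseLocalAlignment) -> float:
    """Percent of the full target sequence present in the alignment."""
    if aln.target_full_length <= 0:
        raise AlignmentError(f"{aln.target_id}: target full length must be positive")
    if aln.n_ali > aln.target_full_length:
        raise AlignmentError(
            f"{aln.target_id}: alignment covers {aln.n_ali} residues but the "
            f"full sequence has only {aln.target_full_length}"
        )
    return 100.0 * aln.n_ali / aln.target_full_length


def interface_coverage(
    aln: PairwiseLocalAlignment, interface_positions: Collection[int]
) -> tuple[float, int]:
    """Percent of target interface residues inside the alignment, and the
    number of interface residues missing from it."""
    n_int_tot = len(set(interface_positions))
    if n_int_tot == 0:
        raise AlignmentError(
            f"{aln.target_id}: empty interface; complex should have been "
            "excluded upstream"
        )
    n_int_ali = sum(
        1 for p in set(interface_positions)
        if aln.target_start <= p <= aln.target_end
    )
    return 100.0 * n_int_ali / n_int_tot, n_int_tot - n_int_ali


def classify_fic(missing_interface_count: int,
                 tolerance: int = DEFAULT_FIC_TOLERANCE) -> bool:
    """Full-interface-coverage test: at most ``tolerance`` residues missing."""
    if missing_interface_count < 0:
        raise ParameterError("missing interface count cannot be negative")
    return missing_interface_count <= tolerance


def _pair_is_identical(t: str, m: str) -> bool:
    return t == m and t in STANDARD_AA


def _pair_is_positive(t: str, m: str, matrix) -> bool:
    # unknown residues are conservatively never positive
    if t == GAP or m == GAP or t not in STANDARD_AA or m not in STANDARD_AA:
        return False
    return matrix[t][m] > 0


def _check_alphabet(aln: PairwiseLocalAlignment) -> None:
    allowed = STANDARD_AA | {GAP, "X"}
    for k, (t, m) in enumerate(zip(aln.target_aln, aln.template_aln)):
        if t not in allowed or m not in allowed:
            raise AlignmentError(
                f"{aln.target_id}/{aln.template_id}: unexpected character "
                f"at column {k}: {t!r}/{m!r}"
            )


def alignment_identity_similarity(
    aln: PairwiseLocalAlignment, matrix=None
) -> tuple[float, float]:
    """(a_iden, a_sim): identical / positive pairs over the alignment length."""
    matrix = matrix if matrix is not None else load_matrix()
    _check_alphabet(aln)
    n_iden = sum(_pair_is_identical(t, m)
                 for t, m in zip(aln.target_aln, aln.template_aln))
    n_pos = sum(_pair_is_positive(t, m, matrix)
                for t, m in zip(aln.target_aln, aln.template_aln))
    l_ali = aln.l_ali
    return 100.0 * n_iden / l_ali, 100.0 * n_pos / l_ali


def interface_identity_similarity(
    aln: PairwiseLocalAlignment,
    interface_positions: Collection[int],
    matrix=None,
) -> tuple[float, float]:
    """(i_iden, i_sim): identity/similarity over interface columns only.

    The denominator is the number of target interface residues present in the
    alignment; defined only when that number is positive (in the analysis it
    is computed for FIC alignments only).
    """
    matrix = matrix if matrix is not None else load_matrix()
    _check_alphabet(aln)
    members = set(interface_positions)
    n_int_ali = n_iden = n_pos = 0
    for _, pos, t, m in aln.columns_with_target_positions():
        if pos is None or pos not in members:
            continue
        n_int_ali += 1
        if _pair_is_identical(t, m):
            n_iden += 1
        if _pair_is_positive(t, m, matrix):
            n_pos += 1
    if n_int_ali == 0:
        raise AlignmentError(
            f"{aln.target_id}/{aln.template_id}: no interface residues inside "
            "the alignment; interface identity undefined"
        )
    return 100.0 * n_iden / n_int_ali, 100.0 * n_pos / n_int_ali


def domain_coverage(
    aln: PairwiseLocalAlignment, domain_positions: Collection[int]
) -> float:
    """Coverage of a user-supplied domain (same form as target coverage)."""
    members = set(domain_positions)
    if not members:
        raise AlignmentError(f"{aln.target_id}: empty domain range")
    inside = sum(1 for p in members if aln.target_start <= p <= aln.target_end)
    return 100.0 * inside / len(members)


def compute_metrics(
    aln: PairwiseLocalAlignment,
    interface_positions: Collection[int] | None = None,
    matrix=None,
    domain_positions: Collection[int] | None = None,
    fic_tolerance: int = DEFAULT_FIC_TOLERANCE,
) -> AlignmentMetrics:
    """Compute every per-alignment statistic in one pass.

    Interface identity/similarity are reported only for FIC alignments with
    at least one interface residue inside the alignment; otherwise they are
    None (the analysis restricts those measures to FIC alignments).
    """
    matrix = matrix if matrix is not None else load_matrix()
    q = target_coverage(aln)
    a_iden, a_sim = alignment_identity_similarity(aln, matrix)
    q_int = i_iden = i_sim = None
    is_fic = missing = None
    if interface_positions is not None:
        q_int, missing = interface_coverage(aln, interface_positions)
        is_fic = classify_fic(missing, fic_tolerance)
        n_inside = len(set(interface_positions)) - missing
        if is_fic and n_inside > 0:
            i_iden, i_sim = interface_identity_similarity(
                aln, interface_positions, matrix
            )
    q_dom = (domain_coverage(aln, domain_positions)
             if domain_positions is not None else None)
    return AlignmentMetrics(
        target_id=aln.target_id, template_id=aln.template_id,
        e_value=aln.e_value, q=q, q_int=q_int, q_dom=q_dom,
        a_iden=a_iden, a_sim=a_sim, i_iden=i_iden, i_sim=i_sim,
        is_fic=is_fic, missing_interface_count=missing,
    )


# ---------------------------------------------------------------------------
# pool filtering


def _target_template_difference(aln: PairwiseLocalAlignment) -> int:
    """Operational target/template difference: substituted aligned positions
    plus unaligned residues on both sides."""
    substituted = sum(
        1 for t, m in zip(aln.target_aln, aln.template_aln)
        if t != GAP and m != GAP and t != m
    )
    unaligned_target = aln.target_full_length - aln.n_ali
    n_template = aln.template_end - aln.template_start + 1
    unaligned_template = aln.template_full_length - n_template
    return substituted + unaligned_target + unaligned_template


def filter_pool(
    alignments: Iterable[PairwiseLocalAlignment],
    e_threshold: float = 1.0,
    min_difference: int = 10,
) -> tuple[list[PairwiseLocalAlignment],
           list[tuple[PairwiseLocalAlignment, str]]]:
    """Apply the pool filters: drop statistically insignificant alignments
    (e-value strictly greater than ``e_threshold``) and near-identical
    target/template pairs (difference below ``min_difference`` residues).

    Returns (kept, excluded) with each exclusion tagged by its rule.
    """
    kept: list[PairwiseLocalAlignment] = []
    excluded: list[tuple[PairwiseLocalAlignment, str]] = []
    for aln in alignments:
        if aln.e_value > e_threshold:
            excluded.append((aln, "evalue"))
        elif _target_template_difference(aln) < min_difference:
            excluded.append((aln, "near-identical"))
        else:
            kept.append(aln)
    return kept, excluded


def subset_by_qmax(
    alignments: Sequence[PairwiseLocalAlignment], q_max: float
) -> list[PairwiseLocalAlignment]:
    """Alignments whose target sequence coverage does not exceed q_max."""
    if not (0 < q_max <= 100):
        raise ParameterError(f"q_max must be in (0, 100], got {q_max}")
    return [a for a in alignments if target_coverage(a) <= q_max]


# ---------------------------------------------------------------------------
# input/output


def parse_blast_xml(
    path, target_full_lengths: Mapping[str, int] | None = None
) -> list[PairwiseLocalAlignment]:
    """Parse BLAST XML output into one record per HSP.

    The full target length is taken from ``target_full_lengths`` when given
    (keyed by the first token of the query definition), otherwise from the
    query length stored in the XML.
    """
    records: list[PairwiseLocalAlignment] = []
    with open(path) as fh:
        # consume the parser fully before validating, so the expat stream is
        # never abandoned mid-file
        parsed = list(NCBIXML.parse(fh))
    for rec in parsed:
        target_id = (rec.query or "").split()[0]
        if target_full_lengths is not None:
            if target_id not in target_full_lengths:
                raise AlignmentError(
                    f"no full length supplied for target {target_id!r}"
                )
            full_len = int(target_full_lengths[target_id])
        else:
            full_len = int(rec.query_length)
        for hit in rec.alignments:
            template_id = (hit.hit_def or hit.hit_id or "").split()[0]
            for hsp in hit.hsps:
                records.append(PairwiseLocalAlignment(
                    target_id=target_id,
                    template_id=template_id,
                    e_value=float(hsp.expect),
                    target_aln=hsp.query,
                    template_aln=hsp.sbjct,
                    target_start=int(hsp.query_start),
                    target_end=int(hsp.query_end),
                    template_start=int(hsp.sbjct_start),
                    template_end=int(hsp.sbjct_end),
                    target_full_length=full_len,
                    template_full_length=int(hit.length),
                ))
    return records


def read_alignments_tsv(path) -> list[PairwiseLocalAlignment]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise AlignmentError(f"alignment TSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(PairwiseLocalAlignment(
                    target_id=row["target_id"],
                    template_id=row["template_id"],
                    e_value=float(row["e_value"]),
                    target_aln=row["target_aln"],
                    template_aln=row["template_aln"],
                    target_start=int(row["target_start"]),
                    target_end=int(row["target_end"]),
                    template_start=int(row["template_start"]),
                    template_end=int(row["template_end"]),
                    target_full_length=int(row["target_full_length"]),
                    template_full_length=int(row["template_full_length"]),
                ))
            except (KeyError, ValueError) as exc:
                raise AlignmentError(f"bad alignment record at line {i}: {exc}") from exc
    return records


def write_alignments_tsv(alignments: Iterable[PairwiseLocalAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for a in alignments:
            w.writerow([
                a.target_id, a.template_id, repr(a.e_value),
                a.target_start, a.target_end, a.template_start, a.template_end,
                a.target_aln, a.template_aln,
                a.target_full_length, a.template_full_length,
            ])


def read_fasta_lengths(path) -> dict[str, int]:
    """Full sequence lengths from a FASTA file, keyed by record id."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
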