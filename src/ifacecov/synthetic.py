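"""Synthetic structures, models and alignment pools with known ground truth.

Everything here is deliberately independent of the analysis modules: the
interface ground truth is computed by a brute-force all-atom-pair scan (not
the KD-tree implementation), and alignment pools carry planted labels that
the analysis modules are expected to recover exactly.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignments import GAP, PairwiseLocalAlignment
from .errors import ParameterError
from .interface import InterfaceMap, VdwTable
from .structure import AtomRecord, Chain, ComplexStructure, Residue

__all__ = [
    "SyntheticComplexSpec", "PlantedCurve", "PooledAlignment",
    "make_complex", "make_model", "make_alignment_pool",
    "brute_force_interface", "write_pool_blast_xml", "write_pool_ground_truth",
]

# 19 standard residues with identical heavy-atom layout (GLY lacks CB)
_RESIDUE_NAMES = (
    "ALA ARG ASN ASP CYS GLN GLU HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)
_ONE_LETTER = "ARNDCQEHILKMFPSTWYV"

_HELIX_RISE = 1.5          # Angstrom per residue along the axis
_HELIX_RADIUS = 2.3        # CA radius of an ideal alpha helix
_HELIX_TWIST = math.radians(100.0)

# local heavy-atom offsets relative to the CA trace frame (arbitrary but rigid)
_ATOM_OFFSETS = {
    "N": (-0.8, 0.9, -0.6),
    "C": (0.9, 0.7, 0.5),
    "O": (1.1, 1.6, 0.9),
    "CB": (0.4, -1.4, 0.3),
}
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class SyntheticComplexSpec:
    """Recipe for a two-chain synthetic complex with a contact patch.

    ``contact_size`` is the minimum number of interface residues required on
    each chain under the default distance criterion.
    """

    chain_lengths: tuple[int, int] = (30, 30)
    contact_size: int = 5
    geometry: str = "two-helix"
    seed: int = 0

    def __post_init__(self):
        if len(self.chain_lengths) != 2 or min(self.chain_lengths) < 5:
            raise ParameterError("chain lengths must be two values >= 5")
        if not (1 <= self.contact_size <= min(self.chain_lengths)):
            raise ParameterError(
                f"contact_size must be in [1, {min(self.chain_lengths)}]"
            )
        if self.geometry not in ("two-helix", "random-walk"):
            raise ParameterError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class PlantedCurve:
    """Ground-truth FIC probability per identity bin (5%-wide over [0,100])."""

    bin_edges: tuple[float, ...] = tuple(float(x) for x in range(0, 105, 5))
    p_fic: tuple[float, ...] = tuple([0.5] * 20)

    def __post_init__(self):
        edges = self.bin_edges
        if len(edges) != len(self.p_fic) + 1:
            raise ParameterError("need len(bin_edges) == len(p_fic) + 1")
        if edges[0] != 0.0 or edges[-1] != 100.0:
            raise ParameterError("bins must cover [0, 100]")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ParameterError("bin edges must be strictly increasing")
        if any(not (0.0 <= p <= 1.0) for p in self.p_fic):
            raise ParameterError("all p_fic must be in [0, 1]")

    @classmethod
    def constant(cls, p: float) -> "PlantedCurve":
        return cls(p_fic=tuple([p] * 20))

    @property
    def n_bins(self) -> int:
        return len(self.p_fic)


@dataclass
class PooledAlignment:
    """One generated alignment plus its planted ground truth."""

    alignment: PairwiseLocalAlignment
    interface_positions: frozenset[int]
    planted_bin: int
    planted_p: float
    is_fic: bool
    missing_interface_count: int


# ---------------------------------------------------------------------------
# structures


def _ca_trace_helix(n: int, phase: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    theta = i * _HELIX_TWIST + phase
    return np.column_stack([
        _HELIX_RADIUS * np.cos(theta),
        _HELIX_RADIUS * np.sin(theta),
        _HELIX_RISE * i,
    ])


def _ca_trace_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """A stiff random walk with 3.8 A steps (no physical realism intended)."""
    step = 3.8
    direction = np.array([0.0, 0.0, 1.0])
    coords = [np.zeros(3)]
    for _ in range(n - 1):
        perturb = rng.normal(scale=0.45, size=3)
        direction = direction + perturb
        direction /= np.linalg.norm(direction)
        coords.append(coords[-1] + step * direction)
    return np.asarray(coords)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector ``a`` onto unit vector ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _perpendicular(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= axis * np.dot(v, axis)
    return v / np.linalg.norm(v)


def _build_chain(chain_id: str, ca: np.ndarray, names: Sequence[str]) -> Chain:
    residues = []
    for i, name in enumerate(names):
        base = ca[i]
        atoms = [AtomRecord(chain_id, i + 1, "", name, "CA", "C", tuple(base))]
        for aname, off in _ATOM_OFFSETS.items():
            atoms.append(AtomRecord(chain_id, i + 1, "", name, aname,
                                    _ATOM_ELEMENTS[aname], tuple(base + np.asarray(off))))
        residues.append(Residue(i + 1, "", name, atoms))
    return Chain(chain_id, residues)


def brute_force_interface(
    complex_structure: ComplexStructure, vdw: VdwTable | None = None
) -> tuple[InterfaceMap, set[tuple[tuple[int, str], tuple[int, str]]]]:
    """All-pairs O(N^2) interface assignment; the oracle for the KD-tree path.

    Returns the interface map and the full set of residue pairs in contact.
    """
    vdw = vdw or VdwTable()
    chain_a, chain_b = complex_structure.chains

    def arrays(chain):
        xyz, rad, ridx = [], [], []
        for i, res in enumerate(chain.residues):
            for a in res.atoms:
                xyz.append(a.position)
                rad.append(vdw.radius(a.element))
                ridx.append(i)
        return (np.asarray(xyz, float), np.asarray(rad, float),
                np.asarray(ridx, int))

    xa, ra, ia = arrays(chain_a)
    xb, rb, ib = arrays(chain_b)
    # every atom pair, no spatial pruning: strict inequality on the threshold
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    thr = ra[:, None] + rb[None, :] + vdw.water_diameter
    contact = d < thr
    pairs: set[tuple[tuple[int, str], tuple[int, str]]] = set()
    in_a: set[tuple[int, str]] = set()
    in_b: set[tuple[int, str]] = set()
    for i, j in zip(*np.nonzero(contact)):
        ra_id = chain_a.residues[ia[i]].res_id
        rb_id = chain_b.residues[ib[j]].res_id
        pairs.add((ra_id, rb_id))
        in_a.add(ra_id)
        in_b.add(rb_id)
    imap = InterfaceMap(complex_structure.id, {
        chain_a.chain_id: tuple(sorted(in_a)),
        chain_b.chain_id: tuple(sorted(in_b)),
    })
    return imap, pairs


def _contact_count(complex_structure: ComplexStructure, vdw: VdwTable) -> int:
    imap, _ = brute_force_interface(complex_structure, vdw)
    a, b = complex_structure.chain_ids
    return min(len(imap.residues[a]), len(imap.residues[b]))


def make_complex(
    spec: SyntheticComplexSpec, vdw: VdwTable | None = None
) -> tuple[ComplexStructure, InterfaceMap]:
    """Generate a two-chain complex whose interface (under the default
    distance criterion) has at least ``contact_size`` residues per chain.

    The returned ground-truth interface map comes from the brute-force
    all-pairs oracle, not from the production interface code.
    """
    vdw = vdw or VdwTable()
    rng = np.random.default_rng(spec.seed)
    na, nb = spec.chain_lengths
    names_a = [_RESIDUE_NAMES[i] for i in rng.integers(0, len(_RESIDUE_NAMES), na)]
    names_b = [_RESIDUE_NAMES[i] for i in rng.integers(0, len(_RESIDUE_NAMES), nb)]

    if spec.geometry == "two-helix":
        ca_a = _ca_trace_helix(na)
        ca_b0 = _ca_trace_helix(nb, phase=math.pi)
        shift_dir = np.array([1.0, 0.0, 0.0])
        start, stop, step = 18.0, 0.0, 0.25
    else:
        ca_a = _ca_trace_walk(na, rng)
        ca_b0 = _ca_trace_walk(nb, rng)
        # align the walks' principal axes so that shrinking the lateral
        # separation grows the contact patch along their shared length
        axis_a = _principal_axis(ca_a)
        axis_b = _principal_axis(ca_b0)
        R_align = _rotation_between(axis_b, axis_a)
        ca_b0 = (ca_b0 - ca_b0.mean(axis=0)) @ R_align.T + ca_a.mean(axis=0)
        shift_dir = _perpendicular(axis_a, rng)
        start, stop, step = 80.0, 0.0, 0.5

    # slide chain B toward A until the requested contact patch size is reached
    sep = start
    chosen = None
    while sep >= stop:
        cplx = ComplexStructure(
            f"synth{spec.seed}",
            (_build_chain("A", ca_a, names_a),
             _build_chain("B", ca_b0 + sep * shift_dir, names_b)),
        )
        if _contact_count(cplx, vdw) >= spec.contact_size:
            chosen = cplx
            break
        sep -= step
    if chosen is None:
        raise ParameterError(
            f"contact_size={spec.contact_size} infeasible for geometry "
            f"{spec.geometry!r} with chain lengths {spec.chain_lengths}"
        )
    imap, _ = brute_force_interface(chosen, vdw)
    return chosen, imap


def make_model(
    native: ComplexStructure,
    chain_id: str,
    noise_sigma: float,
    keep_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> Chain:
    """A perturbed, possibly truncated copy of one native chain.

    Residues with numbers inside ``keep_range`` (inclusive; default: all) are
    retained with their numbering, and every coordinate receives i.i.d.
    Gaussian noise of standard deviation ``noise_sigma``.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    chain = native.chain(chain_id)
    if keep_range is None:
        kept = list(chain.residues)
    else:
        lo, hi = keep_range
        kept = [r for r in chain.residues if lo <= r.number <= hi]
    if not kept:
        raise ParameterError(f"keep_range {keep_range} selects no residues")
    rng = np.random.default_rng(seed)
    residues = []
    for r in kept:
        atoms = []
        for a in r.atoms:
            noise = rng.normal(scale=noise_sigma, size=3) if noise_sigma > 0 \
                else np.zeros(3)
            atoms.append(AtomRecord(a.chain_id, a.residue_number,
                                    a.insertion_code, a.residue_name,
                                    a.atom_name, a.element,
                                    tuple(a.xyz + noise)))
        residues.append(Residue(r.number, r.insertion_code, r.name, atoms))
    return Chain(chain_id, residues)


# ---------------------------------------------------------------------------
# alignment pools


def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [_ONE_LETTER[i] for i in rng.integers(0, len(_ONE_LETTER), n)]


def _substitute(rng: np.random.Generator, c: str) -> str:
    choices = [a for a in _ONE_LETTER if a != c]
    return choices[int(rng.integers(0, len(choices)))]


def _pick_n_iden(lo: float, hi: float, l_ali: int, n_cols: int) -> int | None:
    """Smallest N_iden with lo <= 100*N_iden/l_ali < hi and N_iden <= n_cols."""
    first = math.ceil(lo * l_ali / 100.0)
    # the closed top bin [95, 100] admits equality at 100%
    last_excl = l_ali + 1 if hi >= 100.0 else math.ceil(hi * l_ali / 100.0)
    for n in range(first, last_excl):
        if 0 <= n <= n_cols:
            return n
    return None


def make_alignment_pool(
    curve: PlantedCurve,
    n: int,
    interface_sizes: Sequence[int] = (4, 6, 8, 10, 12),
    coverage_range: tuple[float, float] = (0.25, 0.9),
    seed: int = 0,
    target_length_range: tuple[int, int] = (80, 200),
    gap_fraction: float = 0.0,
    bins: Sequence[int] | None = None,
) -> list[PooledAlignment]:
    """Generate ``n`` alignments whose recomputed identity lands in a planted
    bin and whose FIC status is drawn Bernoulli(p_fic of that bin).

    Interface residues are placed inside/outside the aligned window so that
    the FIC label (one-missing-residue tolerance) is exact by construction.
    ``bins`` restricts generation to a subset of bin indices (default: all).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if min(interface_sizes) < 2:
        raise ParameterError("interface sizes must be >= 2 so that a non-FIC "
                             "label (>= 2 missing residues) is realisable")
    lo_cov, hi_cov = coverage_range
    if not (0 < lo_cov <= hi_cov <= 1):
        raise ParameterError("coverage_range must satisfy 0 < lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    bin_pool = list(bins) if bins is not None else list(range(curve.n_bins))
    out: list[PooledAlignment] = []
    for i in range(n):
        k = bin_pool[int(rng.integers(0, len(bin_pool)))]
        p = curve.p_fic[k]
        lo, hi = curve.bin_edges[k], curve.bin_edges[k + 1]
        n_tot = int(rng.integers(target_length_range[0],
                                 target_length_range[1] + 1))
        n_ali = int(round(n_tot * rng.uniform(lo_cov, hi_cov)))
        n_ali = max(2, min(n_ali, n_tot))
        m = int(interface_sizes[int(rng.integers(0, len(interface_sizes)))])
        if n_ali < m - 1:
            raise ParameterError(
                f"coverage too small to contain the interface: window of "
                f"{n_ali} residues cannot hold {m - 1} interface residues"
            )
        fic = bool(rng.random() < p)
        outside_capacity = n_tot - n_ali
        if fic:
            missing = int(rng.integers(0, 2)) if outside_capacity >= 1 else 0
            if n_ali < m - missing:
                missing = m - n_ali  # fall back to the tolerated single miss
        else:
            if outside_capacity < 2 or m < 2:
                raise ParameterError(
                    "cannot realise a non-FIC alignment: fewer than 2 target "
                    "positions fall outside the aligned window"
                )
            missing = int(rng.integers(2, min(m, outside_capacity) + 1))

        start = int(rng.integers(1, n_tot - n_ali + 2))
        end = start + n_ali - 1
        window = np.arange(start, end + 1)
        complement = np.concatenate([np.arange(1, start),
                                     np.arange(end + 1, n_tot + 1)])
        inside = rng.choice(window, size=m - missing, replace=False)
        outside = (rng.choice(complement, size=missing, replace=False)
                   if missing else np.array([], dtype=int))
        interface = frozenset(int(x) for x in np.concatenate([inside, outside]))

        # aligned strings: target-side gap columns dilute identity only
        n_gap = int(round(gap_fraction * n_ali))
        l_ali = n_ali + n_gap
        n_iden = _pick_n_iden(lo, hi, l_ali, n_ali)
        if n_iden is None:
            n_gap = 0
            l_ali = n_ali
            n_iden = _pick_n_iden(lo, hi, l_ali, n_ali)
        if n_iden is None:
            raise ParameterError(
                f"identity bin [{lo}, {hi}) unreachable with an alignment of "
                f"{n_ali} residues; widen coverage or target length"
            )
        t_res = _random_sequence(rng, n_ali)
        m_res = list(t_res)
        iden_cols = set(rng.choice(n_ali, size=n_iden, replace=False).tolist())
        for j in range(n_ali):
            if j not in iden_cols:
                m_res[j] = _substitute(rng, t_res[j])
        t_cols, m_cols = list(t_res), list(m_res)
        if n_gap:
            for pos in sorted(rng.integers(0, len(t_cols) + 1, n_gap).tolist(),
                              reverse=True):
                t_cols.insert(pos, GAP)
                m_cols.insert(pos, _ONE_LETTER[int(rng.integers(0, 19))])
        template_start = int(rng.integers(1, 51))
        n_template = sum(c != GAP for c in m_cols)
        template_end = template_start + n_template - 1
        aln = PairwiseLocalAlignment(
            target_id=f"T{i:05d}",
            template_id=f"H{i:05d}",
            e_value=float(10.0 ** (-rng.uniform(0.0, 30.0))),
            target_aln="".join(t_cols),
            template_aln="".join(m_cols),
            target_start=start,
            target_end=end,
            template_start=template_start,
            template_end=template_end,
            target_full_length=n_tot,
            template_full_length=template_end + int(rng.integers(20, 80)),
        )
        out.append(PooledAlignment(aln, interface, k, p, fic, missing))
    return out


# ---------------------------------------------------------------------------
# pool serialisation


def write_pool_ground_truth(pool: Sequence[PooledAlignment], path) -> None:
    """Planted labels as TSV: target, bin, p, FIC flag, interface positions."""
    with open(path, "w") as fh:
        fh.write("target_id\tplanted_bin\tplanted_p\tis_fic\t"
                 "missing_interface_count\tinterface_positions\n")
        for rec in pool:
            fh.write("\t".join([
                rec.alignment.target_id, str(rec.planted_bin),
                repr(rec.planted_p), str(int(rec.is_fic)),
                str(rec.missing_interface_count),
                ",".join(str(p) for p in sorted(rec.interface_positions)),
            ]) + "\n")


_XML_HEADER = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
<BlastOutput>
<BlastOutput_program>blastp</BlastOutput_program>
<BlastOutput_version>BLASTP 2.2.18 [synthetic]</BlastOutput_version>
<BlastOutput_reference>none</BlastOutput_reference>
<BlastOutput_db>synthetic</BlastOutput_db>
<BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
<BlastOutput_query-def>{first_query}</BlastOutput_query-def>
<BlastOutput_query-len>{first_len}</BlastOutput_query-len>
<BlastOutput_param><Parameters>
<Parameters_matrix>BLOSUM62</Parameters_matrix>
<Parameters_expect>10</Parameters_expect>
<Parameters_gap-open>11</Parameters_gap-open>
<Parameters_gap-extend>1</Parameters_gap-extend>
</Parameters></BlastOutput_param>
<BlastOutput_iterations>
"""

_XML_STAT = """<Iteration_stat><Statistics>
<Statistics_db-num>1</Statistics_db-num>
<Statistics_db-len>1000</Statistics_db-len>
<Statistics_hsp-len>0</Statistics_hsp-len>
<Statistics_eff-space>100000</Statistics_eff-space>
<Statistics_kappa>0.041</Statistics_kappa>
<Statistics_lambda>0.267</Statistics_lambda>
<Statistics_entropy>0.14</Statistics_entropy>
</Statistics></Iteration_stat>
"""


def write_pool_blast_xml(alignments: Sequence[PairwiseLocalAlignment], path) -> None:
    """Write alignments as minimal BLAST XML, one iteration per target."""
    if not alignments:
        raise ParameterError("cannot write an empty pool")
    by_target: dict[str, list[PairwiseLocalAlignment]] = {}
    for a in alignments:
        by_target.setdefault(a.target_id, []).append(a)
    first = alignments[0]
    parts = [_XML_HEADER.format(first_query=first.target_id,
                                first_len=first.target_full_length)]
    for it, (tid, group) in enumerate(by_target.items(), start=1):
        parts.append(f"<Iteration>\n<Iteration_iter-num>{it}</Iteration_iter-num>\n"
                     f"<Iteration_query-ID>Query_{it}</Iteration_query-ID>\n"
                     f"<Iteration_query-def>{tid}</Iteration_query-def>\n"
                     f"<Iteration_query-len>{group[0].target_full_length}"
                     f"</Iteration_query-len>\n<Iteration_hits>\n")
        for hn, a in enumerate(group, start=1):
            midline = "".join(
                t if (t == m and t != GAP) else " "
                for t, m in zip(a.target_aln, a.template_aln)
            )
            parts.append(
                f"<Hit>\n<Hit_num>{hn}</Hit_num>\n"
                f"<Hit_id>{a.template_id}</Hit_id>\n"
                f"<Hit_def>{a.template_id}</Hit_def>\n"
                f"<Hit_accession>{a.template_id}</Hit_accession>\n"
                f"<Hit_len>{a.template_full_length}</Hit_len>\n"
                f"<Hit_hsps>\n<Hsp>\n<Hsp_num>1</Hsp_num>\n"
                f"<Hsp_bit-score>50.0</Hsp_bit-score>\n"
                f"<Hsp_score>100</Hsp_score>\n"
                f"<Hsp_evalue>{a.e_value!r}</Hsp_evalue>\n"
                f"<Hsp_query-from>{a.target_start}</Hsp_query-from>\n"
                f"<Hsp_query-to>{a.target_end}</Hsp_query-to>\n"
                f"<Hsp_hit-from>{a.template_start}</Hsp_hit-from>\n"
                f"<Hsp_hit-to>{a.template_end}</Hsp_hit-to>\n"
                f"<Hsp_identity>0</Hsp_identity>\n"
                f"<Hsp_positive>0</Hsp_positive>\n"
                f"<Hsp_gaps>0</Hsp_gaps>\n"
                f"<Hsp_align-len>{a.l_ali}</Hsp_align-len>\n"
                f"<Hsp_qseq>{a.target_aln}</Hsp_qseq>\n"
                f"<Hsp_hseq>{a.template_aln}</Hsp_hseq>\n"
                f"<Hsp_midline>{midline}</Hsp_midline>\n"
                f"</Hsp>\n</Hit_hsps>\n</Hit>\n"
            )
        parts.append("</Iteration_hits>\n" + _XML_STAT + "</Iteration>\n")
    parts.append("</BlastOutput_iterations>\n</BlastOutput>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
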