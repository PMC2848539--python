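"""Model quality: Kabsch superposition, interface RMSD and model ranking.

Quality classes for partial models, by interface RMSD over C-alpha atoms of
the binding-site residues after rigid superposition:

* good        rmsd <= 5.0 A   (boundary inclusive)
* acceptable  5.0 < rmsd <= 10.0 A
* incorrect   rmsd > 10.0 A
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ParameterError, StructureError
from .structure import Chain

__all__ = [
    "ModelStructure", "SuperpositionResult", "ModelQualityRecord",
    "kabsch", "superimpose", "interface_rmsd", "classify_quality",
    "select_top_model", "select_best_model",
    "GOOD_THRESHOLD", "ACCEPTABLE_THRESHOLD",
]

GOOD_THRESHOLD = 5.0
ACCEPTABLE_THRESHOLD = 10.0

Scope = Literal["all", "interface"]


@dataclass
class ModelStructure:
    """A (partial) structural model of one chain of a target complex."""

    target_id: str
    chain_id: str
    chain: Chain
    template_id: str | None = None
    provenance: object | None = None  # the alignment the model was built from

    def __post_init__(self):
        if len(self.chain) == 0:
            raise StructureError(f"model for {self.target_id} has no residues")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3 proper rotation
    translation: np.ndarray    # 3-vector; model -> native is R @ x + t
    matched_residue_count: int
    rmsd_all_matched: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ModelQualityRecord:
    target_id: str
    template_id: str
    interface_rmsd: float
    quality_class: str
    a_iden: float
    e_value: float
    is_top: bool = False
    is_best: bool = False


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (R, t) such that ``moving @ R.T + t`` minimises the RMSD to
    ``fixed``; R is constrained to a proper rotation (det = +1).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ParameterError("coordinate arrays must both be (n, 3)")
    if moving.shape[0] < 3:
        raise ParameterError("need at least 3 matched points for superposition")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:
        raise ParameterError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return R, t


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _matched_ca(native_chain: Chain, model_chain: Chain):
    """Residues shared by number between native and model that have CA in both."""
    model_by_id = {r.res_id: r for r in model_chain.residues}
    matched = []
    for nres in native_chain.residues:
        mres = model_by_id.get(nres.res_id)
        if mres is None:
            continue
        nca, mca = nres.ca, mres.ca
        if nca is not None and mca is not None:
            matched.append((nres.res_id, nca.xyz, mca.xyz))
    return matched


def superimpose(
    native_chain: Chain,
    model: ModelStructure,
    scope: Scope = "all",
    interface_res_ids: Sequence[tuple[int, str]] | None = None,
) -> SuperpositionResult:
    """Superimpose a model chain onto the native chain over shared CA atoms.

    ``scope='all'`` fits over every shared residue; ``scope='interface'``
    restricts the fit to the supplied interface residues.
    """
    matched = _matched_ca(native_chain, model.chain)
    if scope == "interface":
        if interface_res_ids is None:
            raise ParameterError("interface scope requires interface residue ids")
        wanted = set(interface_res_ids)
        matched = [m for m in matched if m[0] in wanted]
    if len(matched) < 3:
        raise ParameterError(
            f"only {len(matched)} shared CA atoms between native and model; "
            "need at least 3"
        )
    native_xyz = np.array([m[1] for m in matched])
    model_xyz = np.array([m[2] for m in matched])
    R, t = kabsch(model_xyz, native_xyz)
    rmsd = _rmsd(model_xyz @ R.T + t, native_xyz)
    return SuperpositionResult(R, t, len(matched), rmsd)


def interface_rmsd(
    native_chain: Chain,
    model: ModelStructure,
    interface_res_ids: Sequence[tuple[int, str]],
    scope: Scope = "all",
) -> float:
    """RMSD over CA atoms of the interface residues after superposition.

    The superposition is computed over ``scope`` (all shared CA or interface
    CA only); the RMSD itself is always over interface CA atoms.
    """
    if not interface_res_ids:
        raise ParameterError("empty interface residue list")
    sup = superimpose(native_chain, model, scope=scope,
                      interface_res_ids=interface_res_ids)
    model_by_id = {r.res_id: r for r in model.chain.residues}
    native_by_id = {r.res_id: r for r in native_chain.residues}
    missing = []
    native_xyz, model_xyz = [], []
    for rid in interface_res_ids:
        nres = native_by_id.get(rid)
        mres = model_by_id.get(rid)
        if nres is None or nres.ca is None:
            missing.append(("native", rid))
            continue
        if mres is None or mres.ca is None:
            missing.append(("model", rid))
            continue
        native_xyz.append(nres.ca.xyz)
        model_xyz.append(mres.ca.xyz)
    if missing:
        raise StructureError(
            f"interface residues without CA: {missing[:10]}"
        )
    return _rmsd(sup.apply(np.array(model_xyz)), np.array(native_xyz))


def classify_quality(rmsd: float) -> str:
    """Partition [0, inf) into good / acceptable / incorrect."""
    if rmsd < 0 or not np.isfinite(rmsd):
        raise ParameterError(f"interface RMSD must be finite and >= 0, got {rmsd}")
    if rmsd <= GOOD_THRESHOLD:
        return "good"
    if rmsd <= ACCEPTABLE_THRESHOLD:
        return "acceptable"
    return "incorrect"


def select_top_model(records: Iterable[ModelQualityRecord]) -> ModelQualityRecord:
    """The model built from the alignment with the highest identity.

    Ties are broken by lower e-value, then lexicographic template id, so the
    selection is deterministic.
    """
    records = list(records)
    if not records:
        raise ParameterError("no candidate models")
    top = min(records, key=lambda r: (-r.a_iden, r.e_value, r.template_id))
    top.is_top = True
    return top


def select_best_model(records: Iterable[ModelQualityRecord]) -> ModelQualityRecord:
    """The model with the lowest interface RMSD (ties: template id)."""
    records = list(records)
    if not records:
        raise ParameterError("no candidate models")
    best = min(records, key=lambda r: (r.interface_rmsd, r.template_id))
    best.is_best = True
    return best
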