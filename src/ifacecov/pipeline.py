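"""Pipeline orchestration: interfaces -> per-alignment metrics -> pool
statistics, with a JSON + TSV report bundle.

The link between alignments and interfaces is the target identifier
convention ``<complex_id>_<chain_id>`` (last underscore separates the chain).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .alignments import (
    PairwiseLocalAlignment, compute_metrics, filter_pool, load_matrix,
    parse_blast_xml, read_alignments_tsv, subset_by_qmax, target_coverage,
    DEFAULT_FIC_TOLERANCE,
)
from .errors import PipelineError
from .interface import read_interface_tsv
from .stats import (count_fic_by_complex, fic_probability, fit_curve,
                    histogram, metrics_to_frame)

log = logging.getLogger("ifacecov")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "split_target_id"]

DEFAULT_QMAX = (40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)


def split_target_id(target_id: str) -> tuple[str, str]:
    """Split '<complex_id>_<chain>' on the last underscore."""
    if "_" not in target_id:
        return target_id, ""
    cid, _, chain = target_id.rpartition("_")
    return cid, chain


@dataclass
class PipelineConfig:
    alignments: str
    interfaces: str
    output_dir: str
    complexes: str | None = None          # optional complex list file
    class_labels: str | None = None       # optional TSV: complex_id, class
    matrix_name: str = "BLOSUM62"
    fic_tolerance: int = DEFAULT_FIC_TOLERANCE
    q_max_values: Sequence[float] = DEFAULT_QMAX
    bin_width: float = 5.0
    fit_degree: int = 3
    e_threshold: float = 1.0
    min_difference: int = 10
    seed: int = 0

    def validate(self):
        for name in ("alignments", "interfaces"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", f"{name} path does not exist: {p}")
        if self.bin_width <= 0 or self.fit_degree < 0 or self.fic_tolerance < 0:
            raise PipelineError("config", "numeric parameter out of range")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


@dataclass
class RunReport:
    version: str
    config: dict
    pool_size_input: int = 0
    pool_size_kept: int = 0
    excluded_by_rule: dict = field(default_factory=dict)
    fic_fraction: float | None = None
    fic_counts: dict = field(default_factory=dict)
    q_max_pool_sizes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_alignments(path: str) -> list[PairwiseLocalAlignment]:
    if str(path).endswith(".xml"):
        return parse_blast_xml(path)
    return read_alignments_tsv(path)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run filtering, metrics and pool statistics; write all intermediates."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__,
                       config={k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(config).items()})

    try:
        pool = _load_alignments(config.alignments)
    except Exception as exc:
        raise PipelineError("load-alignments", str(exc)) from exc
    report.pool_size_input = len(pool)
    log.info("load-alignments: %d records", len(pool))

    kept, excluded = filter_pool(pool, e_threshold=config.e_threshold,
                                 min_difference=config.min_difference)
    report.pool_size_kept = len(kept)
    for _, reason in excluded:
        report.excluded_by_rule[reason] = report.excluded_by_rule.get(reason, 0) + 1
    assert len(kept) + len(excluded) == len(pool)
    log.info("filter: kept %d, excluded %s", len(kept), report.excluded_by_rule)

    try:
        interfaces = read_interface_tsv(config.interfaces)
    except Exception as exc:
        raise PipelineError("load-interfaces", str(exc)) from exc

    matrix = load_matrix(config.matrix_name)
    metrics = []
    for aln in kept:
        key = split_target_id(aln.target_id)
        positions = interfaces.get(key)
        try:
            metrics.append(compute_metrics(
                aln, interface_positions=positions, matrix=matrix,
                fic_tolerance=config.fic_tolerance))
        except Exception as exc:
            raise PipelineError(
                "metrics", f"{aln.target_id}/{aln.template_id}: {exc}") from exc
    frame = metrics_to_frame(metrics)
    if not frame.empty:
        frame.insert(0, "complex_id",
                     [split_target_id(t)[0] for t in frame["target_id"]])
        frame.insert(1, "chain",
                     [split_target_id(t)[1] for t in frame["target_id"]])
    metrics_path = out_dir / "metrics.tsv"
    frame.to_csv(metrics_path, sep="\t", index=False)
    report.outputs["metrics"] = str(metrics_path)
    if not frame.empty and frame["is_fic"].notna().any():
        known = frame["is_fic"].dropna()
        report.fic_fraction = float(known.astype(bool).mean()) if len(known) else None

    # per-q_max histograms and probability curves
    q_values = {a.target_id + "/" + a.template_id: target_coverage(a) for a in kept}
    for q_max in config.q_max_values:
        sub_ids = {a.target_id + "/" + a.template_id
                   for a in subset_by_qmax(kept, q_max)}
        if frame.empty:
            report.q_max_pool_sizes[str(q_max)] = 0
            continue
        mask = (frame["target_id"] + "/" + frame["template_id"]).isin(sub_ids)
        sub = frame[mask]
        report.q_max_pool_sizes[str(q_max)] = int(len(sub))
        tag = f"qmax{int(q_max)}"
        for metric in ("a_iden", "a_sim", "i_iden", "i_sim"):
            if sub[metric].notna().sum() == 0:
                continue
            hist = histogram(sub, metric, bin_width=config.bin_width)
            hist.to_frame().to_csv(out_dir / f"hist_{metric}_{tag}.tsv",
                                   sep="\t", index=False)
        for metric in ("a_iden", "a_sim"):
            if sub.empty or sub["is_fic"].notna().sum() == 0:
                continue
            curve = fic_probability(sub, metric, window=config.bin_width)
            n_occupied = int(curve.defined().sum())
            if n_occupied >= config.fit_degree + 1:
                curve = fit_curve(curve, degree=config.fit_degree)
                with open(out_dir / f"fit_{metric}_{tag}.json", "w") as fh:
                    json.dump({
                        "metric": metric, "q_max": q_max,
                        "degree": curve.fit_degree,
                        "coefficients_ascending": list(curve.fit_coefficients),
                        "weighted_rss": curve.fit_rss,
                    }, fh, indent=2)
            curve.to_frame().to_csv(out_dir / f"ficprob_{metric}_{tag}.tsv",
                                    sep="\t", index=False)

    # per-complex FIC summary (needs a complex inventory)
    if config.complexes:
        from .dataset import load_complex_list
        try:
            inventory = {code + ca + cb: (ca, cb)
                         for code, ca, cb in load_complex_list(config.complexes)}
        except Exception as exc:
            raise PipelineError("load-complexes", str(exc)) from exc
        labels = None
        if config.class_labels:
            lab = pd.read_csv(config.class_labels, sep="\t")
            labels = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
        with_iface = frame[frame["is_fic"].notna()] if not frame.empty else frame
        known_ids = set(inventory)
        if not with_iface.empty:
            with_iface = with_iface[with_iface["complex_id"].isin(known_ids)]
        _, totals = count_fic_by_complex(with_iface, inventory, labels)
        report.fic_counts = totals

    report_path = out_dir / "report.json"
    report.to_json(report_path)
    report.outputs["report"] = str(report_path)
    return report
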