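"""Pool-level statistics: metric histograms, per-complex FIC summaries, and
the binned FIC probability curve with its polynomial fit.

The probability that a local alignment contains the full binding site (FIC)
is estimated per 5%-wide identity (or similarity) bin as
N_FIC(bin) / N_all(bin); bins with no alignments are undefined, not zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignmentMetrics
from .errors import ParameterError

__all__ = [
    "MetricHistogram", "FICProbabilityCurve", "ComplexFICSummary",
    "metrics_to_frame", "histogram", "fic_probability", "fit_curve",
    "count_fic_by_complex",
]

METRIC_COLUMNS = ("q", "q_int", "q_dom", "a_iden", "a_sim", "i_iden", "i_sim")


def metrics_to_frame(metrics: Iterable[AlignmentMetrics]) -> pd.DataFrame:
    """Tabulate AlignmentMetrics records (one row per alignment)."""
    rows = []
    for m in metrics:
        rows.append({
            "target_id": m.target_id, "template_id": m.template_id,
            "e_value": m.e_value, "q": m.q, "q_int": m.q_int, "q_dom": m.q_dom,
            "a_iden": m.a_iden, "a_sim": m.a_sim,
            "i_iden": m.i_iden, "i_sim": m.i_sim,
            "is_fic": m.is_fic,
            "missing_interface_count": m.missing_interface_count,
        })
    return pd.DataFrame(rows)


def _fic_mask(series: pd.Series) -> np.ndarray:
    """Boolean FIC mask; missing values (no interface known) count as False."""
    return series.astype("boolean").fillna(False).to_numpy(dtype=bool)


def _bin_index(values: np.ndarray, bin_width: float, n_bins: int) -> np.ndarray:
    # left-closed right-open bins; the last bin is closed at 100
    idx = np.floor(values / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class MetricHistogram:
    metric_name: str
    bin_edges: np.ndarray          # length n_bins + 1
    counts_all: np.ndarray
    counts_fic: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:],
            "count_all": self.counts_all, "count_fic": self.counts_fic,
            "fraction_all": self.counts_all / max(self.counts_all.sum(), 1),
            "fraction_fic": self.counts_fic / max(self.counts_fic.sum(), 1),
        })


def histogram(
    frame: pd.DataFrame, metric_name: str, bin_width: float = 5.0
) -> MetricHistogram:
    """Histogram a percentage-valued metric into bins of ``bin_width`` over
    [0, 100], with a parallel count restricted to FIC alignments."""
    if metric_name not in frame.columns:
        raise ParameterError(f"unknown metric {metric_name!r}; "
                             f"available: {sorted(frame.columns)}")
    values = frame[metric_name].dropna().to_numpy(dtype=float)
    if values.size and (values.min() < 0 or values.max() > 100):
        raise ParameterError(f"{metric_name} values outside [0, 100]")
    n_bins = int(round(100.0 / bin_width))
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts_all = np.zeros(n_bins, dtype=int)
    counts_fic = np.zeros(n_bins, dtype=int)
    sub = frame.dropna(subset=[metric_name])
    idx = _bin_index(sub[metric_name].to_numpy(dtype=float), bin_width, n_bins)
    np.add.at(counts_all, idx, 1)
    if "is_fic" in sub.columns:
        fic_mask = _fic_mask(sub["is_fic"])
        np.add.at(counts_fic, idx[fic_mask], 1)
    return MetricHistogram(metric_name, edges, counts_all, counts_fic)


@dataclass
class FICProbabilityCurve:
    """Binned probability that an alignment has full interface coverage,
    as a function of one alignment metric."""

    metric_name: str
    bin_centers: np.ndarray
    probability: np.ndarray        # NaN where no alignments fall in the bin
    n_all: np.ndarray
    n_fic: np.ndarray
    fit_coefficients: np.ndarray | None = None   # ascending powers
    fit_degree: int | None = None
    fit_rss: float | None = None

    def defined(self) -> np.ndarray:
        return self.n_all > 0

    def evaluate_fit(self, x: np.ndarray) -> np.ndarray:
        if self.fit_coefficients is None:
            raise ParameterError("curve has no fitted polynomial")
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.fit_coefficients)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers, "n_all": self.n_all,
            "n_fic": self.n_fic, "probability": self.probability,
        })


def fic_probability(
    frame: pd.DataFrame, metric_name: str, window: float = 5.0
) -> FICProbabilityCurve:
    """Estimate the FIC probability per metric bin of width ``window``."""
    if frame.empty:
        raise ParameterError("empty metrics table")
    hist = histogram(frame, metric_name, bin_width=window)
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(hist.counts_all > 0,
                        hist.counts_fic / np.maximum(hist.counts_all, 1),
                        np.nan)
    return FICProbabilityCurve(
        metric_name=metric_name,
        bin_centers=hist.bin_centers,
        probability=prob,
        n_all=hist.counts_all,
        n_fic=hist.counts_fic,
    )


def fit_curve(curve: FICProbabilityCurve, degree: int = 3) -> FICProbabilityCurve:
    """Weighted least-squares polynomial fit of probability vs bin center.

    Each occupied bin is weighted by its alignment count n_all (empty bins are
    excluded, not imputed). Returns a copy of the curve with coefficients
    (ascending powers), degree and the weighted residual sum of squares.
    """
    mask = curve.defined()
    x = curve.bin_centers[mask]
    y = curve.probability[mask]
    w = curve.n_all[mask].astype(float)
    if x.size < degree + 1:
        raise ParameterError(
            f"need at least {degree + 1} occupied bins for a degree-{degree} "
            f"fit, have {x.size}"
        )
    # numpy weights multiply residuals before squaring -> sqrt gives n_all weighting
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree, w=np.sqrt(w))
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    rss = float(np.sum(w * resid ** 2))
    return FICProbabilityCurve(
        metric_name=curve.metric_name, bin_centers=curve.bin_centers,
        probability=curve.probability, n_all=curve.n_all, n_fic=curve.n_fic,
        fit_coefficients=coeffs, fit_degree=degree, fit_rss=rss,
    )


@dataclass
class ComplexFICSummary:
    complex_id: str
    fic_counts: dict[str, int]     # chain -> number of FIC alignments
    functional_class: str | None = None

    @property
    def fic_both(self) -> bool:
        return len(self.fic_counts) == 2 and all(v > 0 for v in self.fic_counts.values())

    @property
    def fic_one(self) -> bool:
        return sum(v > 0 for v in self.fic_counts.values()) == 1

    @property
    def fic_none(self) -> bool:
        return not (self.fic_both or self.fic_one)


def count_fic_by_complex(
    frame: pd.DataFrame,
    complexes: Mapping[str, tuple[str, str]],
    class_labels: Mapping[str, str] | None = None,
) -> tuple[list[ComplexFICSummary], dict]:
    """Classify each complex by whether FIC alignments exist for both, one or
    none of its chains.

    ``frame`` must carry ``complex_id``, ``chain`` and ``is_fic`` columns;
    ``complexes`` maps each complex id to its two chain ids (complexes with no
    alignments at all are classified fic_none). Totals are also aggregated per
    functional class when ``class_labels`` is given.
    """
    required = {"complex_id", "chain", "is_fic"}
    if not frame.empty and not required <= set(frame.columns):
        raise ParameterError(f"metrics table must have columns {sorted(required)}")
    if not frame.empty:
        unknown = set(frame["complex_id"]) - set(complexes)
        if unknown:
            raise ParameterError(
                f"alignments reference unknown complexes: {sorted(unknown)[:5]}"
            )
    summaries = []
    totals = {"both": 0, "one": 0, "none": 0, "by_class": {}}
    for cid, chain_pair in complexes.items():
        counts = {c: 0 for c in chain_pair}
        if not frame.empty:
            sub = frame[frame["complex_id"] == cid]
            for chain in chain_pair:
                counts[chain] = int(
                    _fic_mask(sub[sub["chain"] == chain]["is_fic"]).sum()
                )
        label = class_labels.get(cid) if class_labels else None
        s = ComplexFICSummary(cid, counts, functional_class=label)
        summaries.append(s)
        key = "both" if s.fic_both else ("one" if s.fic_one else "none")
        totals[key] += 1
        if label is not None:
            cls = totals["by_class"].setdefault(
                label, {"both": 0, "one": 0, "none": 0})
            cls[key] += 1
    return summaries, totals
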