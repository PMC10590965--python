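"""Sensitivity / specificity scoring and tau-grid ROC scanning.

Truth is binary: a read is a true positive when it comes from the aOral
source; Skin and SedimentSoil collapse into the negative class.
Sensitivity is the fraction of true aOral reads retained (== TPR);
specificity is the fraction of non-aOral reads removed (FPR == 1 −
specificity); retainment is the fraction of all input reads kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassifierConfig, ReadAnnotation, TwoPassReadClassifier
from .fastx import ReadRecord
from .kmers import KmerConfig

__all__ = ["EvalMetrics", "score", "retainment", "roc_scan", "DEFAULT_TAU_GRID"]

DEFAULT_TAU_GRID = tuple(round(0.1 * i, 1) for i in range(1, 10))

POSITIVE_LABEL = "aOral"


@dataclass(frozen=True)
class EvalMetrics:
    sensitivity: float
    specificity: float
    tpr: float
    fpr: float
    retainment: float
    n_reads: int
    n_retained: int

    def as_percent_row(self) -> str:
        return (
            f"sensitivity {self.sensitivity * 100:.2f}%  "
            f"specificity {self.specificity * 100:.2f}%  "
            f"retainment {self.retainment * 100:.2f}%"
        )


def _truth_map(truth: pd.DataFrame | Mapping[str, str]) -> dict[str, str]:
    if isinstance(truth, pd.DataFrame):
        return dict(zip(truth["read_id"], truth["label"]))
    return dict(truth)


def score(
    retained_ids: Iterable[str], truth: pd.DataFrame | Mapping[str, str]
) -> EvalMetrics:
    """Confusion-matrix metrics for a retained-read set against truth.

    Raises ``KeyError`` naming any retained id absent from the truth
    table.
    """
    tmap = _truth_map(truth)
    retained = set(retained_ids)
    for rid in retained:
        if rid not in tmap:
            raise KeyError(f"retained read id {rid!r} is not present in the truth table")
    n_pos = sum(1 for lb in tmap.values() if lb == POSITIVE_LABEL)
    n_neg = len(tmap) - n_pos
    tp = sum(1 for rid in retained if tmap[rid] == POSITIVE_LABEL)
    fp = len(retained) - tp
    sens = tp / n_pos if n_pos else 0.0
    fpr = fp / n_neg if n_neg else 0.0
    spec = 1.0 - fpr
    return EvalMetrics(
        sensitivity=sens,
        specificity=spec,
        tpr=sens,
        fpr=fpr,
        retainment=retainment(len(tmap), len(retained)),
        n_reads=len(tmap),
        n_retained=len(retained),
    )


def retainment(n_in: int, n_out: int) -> float:
    """Fraction of input reads kept after decontamination."""
    if n_in <= 0:
        raise ValueError("n_in must be positive")
    if not (0 <= n_out <= n_in):
        raise ValueError(f"n_out must be in [0, {n_in}], got {n_out}")
    return n_out / n_in


def roc_scan(
    reads: Sequence[ReadRecord],
    membership,
    truth: pd.DataFrame | Mapping[str, str],
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    kcfg: KmerConfig | None = None,
) -> pd.DataFrame:
    """TPR/FPR across a tau grid, plus the one-pass baseline row.

    Pass 1 is tau-independent, so the anchor computation runs once and
    Pass 2 is re-thresholded per tau — exactly equivalent to a full run
    at each tau. The final row (mode ``one_pass``, tau NaN) retains the
    Pass-1 anchors directly.
    """
    if not tau_grid:
        raise ValueError("tau_grid must be nonempty")
    for t in tau_grid:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"tau {t} outside [0, 1]")
    kcfg = kcfg or KmerConfig(k=membership.k)
    est = TwoPassReadClassifier(k=kcfg.k, tau=0.0, mode="two_pass").fit(membership)
    annotations = est.annotate(reads)
    rows = []
    for tau in tau_grid:
        retained_ids = [
            a.seq_id for a in annotations if a.anchor_proportion >= tau
        ]
        m = score(retained_ids, truth)
        rows.append(
            {
                "mode": "two_pass",
                "tau": tau,
                "tpr": m.tpr,
                "fpr": m.fpr,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "retainment": m.retainment,
            }
        )
    one_pass_ids = [a.seq_id for a in annotations if a.is_consecutive_match_found]
    m = score(one_pass_ids, truth)
    rows.append(
        {
            "mode": "one_pass",
            "tau": float("nan"),
            "tpr": m.tpr,
            "fpr": m.fpr,
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "retainment": m.retainment,
        }
    )
    return pd.DataFrame(rows)


def plot_roc(roc: pd.DataFrame, path: str | Path) -> None:
    """Optional ROC figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    two = roc[roc["mode"] == "two_pass"].sort_values("fpr")
    one = roc[roc["mode"] == "one_pass"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(two["fpr"], two["tpr"], "o-", label="two-pass (tau grid)")
    for _, row in two.iterrows():
        ax.annotate(f"{row['tau']:.1f}", (row["fpr"], row["tpr"]), fontsize=7)
    if not one.empty:
        ax.plot(one["fpr"], one["tpr"], "s", color="tab:blue", label="one pass")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
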