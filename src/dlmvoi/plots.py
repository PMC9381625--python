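"""Optional plot artifacts: empirical ROC curves and the diameter sweep.

All statistics elsewhere use the empirical ROC; plotting is presentation
only and never feeds back into any computed number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import EvalResult

__all__ = ["plot_roc", "plot_diameter_sweep"]


def plot_roc(results: Sequence[EvalResult], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        ax.plot(r.roc_fpr, r.roc_tpr,
                label=f"{r.model_id} (AUC {r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_diameter_sweep(results: Sequence[EvalResult], path: str | Path) -> None:
    """AUC with 95% CI per candidate VOI diameter."""
    rs = sorted(results, key=lambda r: r.diameter_mm or 0)
    d = [r.diameter_mm for r in rs]
    auc = [r.auc for r in rs]
    lo = [r.auc - r.ci_low for r in rs]
    hi = [r.ci_high - r.auc for r in rs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(d, auc, yerr=[lo, hi], fmt="o-", capsize=3)
    ax.set_xlabel("initial VOI diameter (mm)")
    ax.set_ylabel("test AUC")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
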