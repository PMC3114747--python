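"""Three-class balanced-accuracy scoring and simulation experiments.

With no decision threshold to sweep, the ROC of a fixed classifier reduces
to its operative point, where the area equals the balanced accuracy
``(TP/P + TN/N) / 2``.  For the three-state calling task the score is the
unweighted mean of the per-class balanced accuracies of gain, loss and
normal, each computed one-vs-rest.  An absent class (P = 0 or N = 0)
contributes 1 by convention, so aberration-free data correctly called
all-normal scores a perfect 1.0.

:func:`run_mixture_experiment` drives the simulator across a grid of
stromal fractions, scoring one or more callers against the ground truth
over seeded replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import StateCallTrack, classify_three_state
from .errors import ValidationError
from .simulate import STATES, MixtureSpec, TruthTrack, simulate_dataset

__all__ = ["ThreeClassTally", "auc_roc_three_class", "run_mixture_experiment"]


@dataclass(frozen=True)
class ThreeClassTally:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    p: int
    tn: int
    n: int

    @property
    def balanced_accuracy(self) -> float:
        sens = self.tp / self.p if self.p > 0 else 1.0
        spec = self.tn / self.n if self.n > 0 else 1.0
        return 0.5 * (sens + spec)


def _states(track) -> np.ndarray:
    if isinstance(track, (StateCallTrack, TruthTrack)):
        return track.state
    return np.asarray(track)


def tally_class(calls, truth, label: str) -> ThreeClassTally:
    """One-vs-rest tally of a call track against truth for one class."""
    c = _states(calls)
    t = _states(truth)
    if c.shape != t.shape:
        raise ValidationError("calls and truth must cover the same loci")
    pos = t == label
    called = c == label
    return ThreeClassTally(
        tp=int(np.sum(pos & called)),
        p=int(np.sum(pos)),
        tn=int(np.sum(~pos & ~called)),
        n=int(np.sum(~pos)),
    )


def auc_roc_three_class(calls, truth) -> float:
    """Mean one-vs-rest balanced accuracy over gain, loss and normal."""
    return float(
        np.mean([tally_class(calls, truth, label).balanced_accuracy for label in STATES])
    )


def run_mixture_experiment(
    alphas: Sequence[float],
    n_reps: int = 200,
    n_subclones: int = 1,
    callers: Mapping[str, Callable] | None = None,
    seed: int = 0,
    n_loci: int = 10_000,
    snr: float = 30.0,
    het_prob: float = 0.095,
) -> pd.DataFrame:
    """Score callers across stromal fractions on independent simulations.

    Each caller maps a locus profile to a state track (a
    ``StateCallTrack`` or a plain state array), letting external tools'
    call files be scored through a thin adapter.  A caller that raises is
    recorded as a failed cell and the run continues.

    Returns a tidy frame with one row per (alpha, caller): columns
    ``alpha``, ``caller``, ``mean_auc``, ``sd_auc``, ``n_ok``, ``n_failed``.
    Replicate seeds are derived deterministically from ``seed``.
    """
    if callers is None:
        callers = {"m_measure": lambda profile: classify_three_state(profile)}
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(alphas) * n_reps
    ) % (2**31)
    rows = []
    for i, alpha in enumerate(alphas):
        scores: dict[str, list[float]] = {name: [] for name in callers}
        failures: dict[str, int] = {name: 0 for name in callers}
        for rep in range(n_reps):
            spec = MixtureSpec(
                alpha=float(alpha),
                n_subclones=n_subclones,
                snr=snr,
                n_loci=n_loci,
                het_prob=het_prob,
                seed=int(child_seeds[i * n_reps + rep]),
            )
            profile, truth = simulate_dataset(spec)
            for name, caller in callers.items():
                try:
                    calls = caller(profile)
                    scores[name].append(auc_roc_three_class(calls, truth))
                except Exception:
                    failures[name] += 1
        for name in callers:
            ok = scores[name]
            rows.append(
                {
                    "alpha": float(alpha),
                    "caller": name,
                    "mean_auc": float(np.mean(ok)) if ok else float("nan"),
                    "sd_auc": float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0,
                    "n_ok": len(ok),
                    "n_failed": failures[name],
                }
            )
    return pd.DataFrame(rows)
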