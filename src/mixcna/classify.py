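"""M-measure of allelic imbalance and three-state CNA classification.

Exact integer copy numbers cannot be recovered from the aggregate signal of
a heterogeneous sample, so calling is reduced to three states — gain, loss,
normal — of the dominant aberrant component.  Two sources of evidence are
combined per SNP:

* the **M-measure**, a windowed score of allelic imbalance.  A per-SNP
  imbalance function ``f(beta) = |sin(2*pi*beta)|`` vanishes at the
  B-allele-frequency values of a normal sample (0 at homozygotes, 0.5 at
  balanced heterozygotes, 1 at homozygotes) and rises steeply in between;
  it is averaged over the informative (heterozygous-band) SNPs of a
  symmetric window of ``window`` SNPs.  Homozygous SNPs carry no imbalance
  information, so SNPs with ``beta`` within ``hom_beta_margin`` of 0 or 1
  are excluded from the average — otherwise a realistic ~9.5% germline
  heterozygosity would dilute the score below any usable cutoff.

* a windowed one-sided test for **depressed total DNA** (mean ``log_r``
  significantly below 0).  This rescues hemizygous deletions carried by
  the majority of cells, where the B-allele bands collapse onto 0/1 and
  the M-measure is blind.

A SNP flagged aberrant by either source is labeled loss or gain by the sign
of its windowed mean ``log_r``; flagged SNPs whose mean ``log_r`` sits
within ``logr_tolerance`` of 0 revert to normal (copy-neutral imbalance is
not a copy-number event).  The same (m, log_r) evidence can also be decoded
with a three-state Viterbi algorithm (:func:`viterbi_3smm`) whose
transition and emission parameters may be fit from a known truth track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .errors import ValidationError
from .signals import LocusProfile
from .simulate import STATES, TruthTrack

__all__ = [
    "ClassifierConfig",
    "MMeasureTrack",
    "StateCallTrack",
    "HmmParams",
    "m_measure",
    "classify_three_state",
    "viterbi_3smm",
    "fit_hmm_from_truth",
    "viterbi_decode",
]


def default_imbalance(beta: np.ndarray) -> np.ndarray:
    """|sin(2*pi*beta)|: zero at beta in {0, 0.5, 1}, maximal at 0.25/0.75."""
    return np.abs(np.sin(2.0 * np.pi * beta))


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the three-state classifier.

    window:
        Number of flanking SNPs pooled around each SNP (``window // 2`` on
        each side); windows shrink symmetrically at the ends.
    m_cutoff:
        M-measure threshold above which a SNP is flagged aberrant.
    logr_alpha:
        Significance level of the one-sided depressed-``log_r`` test.
    logr_tolerance:
        Half-width of the ``log_r`` band around 0 treated as carrying no
        total-DNA evidence; flagged SNPs inside the band stay normal.
    hom_beta_margin:
        SNPs with ``min(beta, 1-beta)`` at or below this margin are treated
        as homozygous and excluded from the M-measure average.
    rho_floor:
        ``rho`` values below this floor are clamped before taking logs so
        homozygous-deletion loci yield a large finite negative ``log_r``.
    imbalance_fn:
        Per-SNP imbalance function f(beta); injectable so alternative
        members of the measure family can be swapped in.
    """

    window: int = 20
    m_cutoff: float = 0.1
    logr_alpha: float = 0.01
    logr_tolerance: float = 0.02
    hom_beta_margin: float = 0.1
    rho_floor: float = 1.0 / 64.0
    imbalance_fn: Callable[[np.ndarray], np.ndarray] = field(
        default=default_imbalance, compare=False
    )

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be >= 1")
        if not 0.0 < self.m_cutoff < 1.0:
            raise ValidationError("m_cutoff must lie in (0, 1)")
        if not 0.0 < self.logr_alpha < 1.0:
            raise ValidationError("logr_alpha must lie in (0, 1)")
        if self.logr_tolerance < 0:
            raise ValidationError("logr_tolerance must be non-negative")
        if not 0.0 <= self.hom_beta_margin < 0.5:
            raise ValidationError("hom_beta_margin must lie in [0, 0.5)")


@dataclass(frozen=True)
class MMeasureTrack:
    """Per-SNP M-measure values (non-negative)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if np.any(m < -1e-12):
            raise ValidationError("M-measure must be non-negative")
        object.__setattr__(self, "m", m)


@dataclass(frozen=True)
class StateCallTrack:
    """Per-SNP three-state calls with the evidence that produced them."""

    state: np.ndarray
    m: MMeasureTrack
    logr_mean: np.ndarray

    def __post_init__(self) -> None:
        state = np.asarray(self.state)
        bad = set(np.unique(state)) - set(STATES)
        if bad:
            raise ValidationError(f"unknown call states: {sorted(bad)}")
        object.__setattr__(self, "state", state)

    @property
    def n_loci(self) -> int:
        return int(self.state.size)


def _windowed_sums(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding sums and element counts over a symmetric window of W SNPs."""
    half = window // 2
    kernel = np.ones(2 * half + 1)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums, counts


def m_measure(profile: LocusProfile, config: ClassifierConfig | None = None) -> MMeasureTrack:
    """Windowed allelic-imbalance score per SNP.

    The imbalance function is averaged over the informative SNPs of each
    window; a window with no informative SNP scores 0 (no evidence).
    """
    config = config or ClassifierConfig()
    if profile.n_loci == 0:
        raise ValidationError("profile is empty")
    if config.window > profile.n_loci:
        raise ValidationError("window exceeds the number of loci")
    beta = profile.beta
    informative = np.minimum(beta, 1.0 - beta) > config.hom_beta_margin
    f = np.where(informative, config.imbalance_fn(beta), 0.0)
    sums, _ = _windowed_sums(f, config.window)
    n_inf, _ = _windowed_sums(informative.astype(float), config.window)
    m = np.zeros(profile.n_loci)
    np.divide(sums, n_inf, out=m, where=n_inf > 0)
    return MMeasureTrack(m=np.maximum(m, 0.0))


def _logr_evidence(
    profile: LocusProfile, config: ClassifierConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean log_r and the one-sided depressed-rho z statistic.

    The per-SNP noise scale is estimated robustly from the global median
    absolute deviation of log_r, so aberrant segments inflate it little.
    """
    log_r = np.where(
        np.isfinite(profile.log_r),
        profile.log_r,
        np.log2(np.maximum(profile.rho, config.rho_floor)),
    )
    sums, counts = _windowed_sums(log_r, config.window)
    mean = sums / counts
    med = np.median(log_r)
    sigma = 1.4826 * np.median(np.abs(log_r - med))
    sigma = max(sigma, 1e-9)
    z = mean * np.sqrt(counts) / sigma
    return mean, z


def classify_three_state(
    profile: LocusProfile, config: ClassifierConfig | None = None
) -> StateCallTrack:
    """Call gain / loss / normal per SNP from M-measure and log_r evidence."""
    config = config or ClassifierConfig()
    track = m_measure(profile, config)
    logr_mean, z = _logr_evidence(profile, config)
    z_crit = stats.norm.ppf(config.logr_alpha)
    aberrant = (track.m > config.m_cutoff) | (z < z_crit)
    state = np.full(profile.n_loci, "normal", dtype="<U6")
    state[aberrant & (logr_mean < -config.logr_tolerance)] = "loss"
    state[aberrant & (logr_mean > config.logr_tolerance)] = "gain"
    return StateCallTrack(state=state, m=track, logr_mean=logr_mean)


# --------------------------------------------------------------------------
# Three-state Viterbi decoding (3SMM)

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class HmmParams:
    """Three-state HMM over per-SNP (m, windowed mean log_r) observations.

    States are ordered (normal, loss, gain).  Emissions are independent
    Gaussians per state on the two observation channels; ``means`` and
    ``sds`` have shape (3, 2).
    """

    transition: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    start: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))
    config: ClassifierConfig = field(default_factory=ClassifierConfig, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (3, 3) or np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1) > 1e-8):
            raise ValidationError("transition must be a 3x3 row-stochastic matrix")
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if means.shape != (3, 2) or sds.shape != (3, 2):
            raise ValidationError("means and sds must have shape (3, 2)")
        if np.any(sds <= 0):
            raise ValidationError("emission standard deviations must be positive")
        start = np.asarray(self.start, dtype=float)
        if start.shape != (3,) or np.any(start < 0) or abs(start.sum() - 1) > 1e-8:
            raise ValidationError("start must be a length-3 probability vector")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        object.__setattr__(self, "start", start)


def viterbi_decode(
    log_start: np.ndarray, log_trans: np.ndarray, log_emit: np.ndarray
) -> np.ndarray:
    """Maximum-a-posteriori state path of a discrete-state HMM.

    ``log_emit`` has shape (T, K).  Ties are broken toward the
    lowest-index state at every step, so with the (normal, loss, gain)
    ordering ambiguous stretches decode as normal.
    """
    n_obs, n_states = log_emit.shape
    score = log_start + log_emit[0]
    back = np.zeros((n_obs, n_states), dtype=int)
    for t in range(1, n_obs):
        cand = score[:, None] + log_trans
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(n_states)] + log_emit[t]
    path = np.zeros(n_obs, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(n_obs - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _observations(profile: LocusProfile, config: ClassifierConfig) -> np.ndarray:
    m = m_measure(profile, config).m
    logr_mean, _ = _logr_evidence(profile, config)
    return np.column_stack([m, logr_mean])


def viterbi_3smm(profile: LocusProfile, params: HmmParams) -> StateCallTrack:
    """Decode the three-state MAP path over (m, log_r) observations."""
    obs = _observations(profile, params.config)
    log_emit = np.zeros((obs.shape[0], 3))
    for k in range(3):
        log_emit[:, k] = stats.norm.logpdf(
            obs, loc=params.means[k], scale=params.sds[k]
        ).sum(axis=1)
    with np.errstate(divide="ignore"):
        path = viterbi_decode(
            np.log(params.start), np.log(params.transition), log_emit
        )
    state = np.array(STATES, dtype="<U6")[path]
    return StateCallTrack(
        state=state, m=MMeasureTrack(m=obs[:, 0]), logr_mean=obs[:, 1]
    )


def fit_hmm_from_truth(
    profile: LocusProfile,
    truth: TruthTrack,
    config: ClassifierConfig | None = None,
    sd_floor: float = 1e-3,
) -> HmmParams:
    """Estimate HMM parameters from a known per-locus truth track.

    Transitions come from add-one-smoothed state bigram counts; emissions
    are per-state Gaussians fit on the (m, log_r) observations of loci with
    that true label.  Every state must occur in the truth.
    """
    config = config or ClassifierConfig()
    if truth.n_loci != profile.n_loci:
        raise ValidationError("truth and profile must cover the same loci")
    codes = np.array([_STATE_INDEX[s] for s in truth.state])
    present = set(codes.tolist())
    missing = [s for s, i in _STATE_INDEX.items() if i not in present]
    if missing:
        raise ValidationError(
            f"states {missing} absent from truth; supply default parameters instead"
        )
    counts = np.ones((3, 3))  # add-one smoothing
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    transition = counts / counts.sum(axis=1, keepdims=True)
    obs = _observations(profile, config)
    means = np.zeros((3, 2))
    sds = np.zeros((3, 2))
    for k in range(3):
        sel = obs[codes == k]
        means[k] = sel.mean(axis=0)
        sds[k] = np.maximum(sel.std(axis=0), sd_floor)
    start = np.bincount(codes, minlength=3).astype(float)
    start /= start.sum()
    return HmmParams(transition=transition, means=means, sds=sds, start=start, config=config)
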