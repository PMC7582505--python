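"""Session-level scoring and longitudinal statistics.

Per-trial network scores are averaged within each (participant, session)
pair; session means are then compared with the clinical FMA scores through

* mean absolute error (FMA points),
* Pearson correlation,
* a one-sample TOST equivalence test on the paired differences
  (predicted − true) against the asymmetric interval (−5, +6.6) FMA points —
  the published FMA test-retest agreement band, applied asymmetrically
  as reported — reporting p = max of the two one-sided p-values,
* standard paired and Welch two-sample t-tests.

The cross-participant protocol retrains on a pool verified to exclude every
trial of the target participant; any overlap raises ``LeakageError``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import LabeledDataset
from .models import TrainedModel, build_model, train_model


class LeakageError(RuntimeError):
    """Target-participant trials were found in a training pool."""


@dataclass(frozen=True)
class SessionScore:
    participant_id: str
    session_id: str
    predicted: float          # mean of the session's per-trial scores
    n_trials: int
    fma_true: float

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("a session must contribute at least one trial")


@dataclass(frozen=True)
class EquivalenceSpec:
    lower_bound: float = -5.0
    upper_bound: float = 6.6
    alpha: float = 0.05

    def __post_init__(self):
        if not self.lower_bound < 0 < self.upper_bound:
            raise ValueError("equivalence interval must straddle zero")


@dataclass(frozen=True)
class TostResult:
    p: float
    p_lower: float
    p_upper: float
    t_lower: float
    t_upper: float
    df: int
    zero_variance: bool = False


@dataclass(frozen=True)
class TTestResult:
    paired_p: float
    unpaired_p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.paired_p, self.unpaired_p))


@dataclass
class EquivalenceReport:
    mae: float
    pearson_r: float
    tost_p: float
    ttest_paired_p: float
    ttest_unpaired_p: float
    differences: np.ndarray           # per-session predicted − true
    sessions: list[SessionScore]
    spec: EquivalenceSpec
    degenerate_ttest: bool = False

    def __post_init__(self):
        if self.mae < 0:
            raise ValueError("mae must be non-negative")

    @property
    def equivalent(self) -> bool:
        return self.tost_p < self.spec.alpha

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "tost_p": self.tost_p,
            "ttest_paired_p": self.ttest_paired_p,
            "ttest_unpaired_p": self.ttest_unpaired_p,
            "equivalent": bool(self.equivalent),
            "differences": [float(d) for d in self.differences],
            "spec": asdict(self.spec),
            "sessions": [asdict(s) for s in self.sessions],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> str:
        lines = [f"{'participant':<12}{'session':<12}{'predicted':>10}"
                 f"{'FMA':>7}{'diff':>8}{'trials':>8}"]
        for s in self.sessions:
            lines.append(f"{s.participant_id:<12}{s.session_id:<12}"
                         f"{s.predicted:>10.2f}{s.fma_true:>7.1f}"
                         f"{s.predicted - s.fma_true:>8.2f}{s.n_trials:>8d}")
        lines.append(f"MAE = {self.mae:.3f} FMA points | r = "
                     f"{self.pearson_r:.3f} | TOST p = {self.tost_p:.4g} | "
                     f"paired t p = {self.ttest_paired_p:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# aggregation and metrics
# ---------------------------------------------------------------------------

def aggregate_sessions(trial_scores, index: pd.DataFrame
                       ) -> list[SessionScore]:
    """One SessionScore per (participant, session): the mean over its trials.

    ``index`` needs columns participant_id, session_id, fma_ue aligned with
    ``trial_scores``.
    """
    trial_scores = np.asarray(trial_scores, dtype=float)
    if len(trial_scores) != len(index):
        raise ValueError("scores and index must be aligned")
    if len(trial_scores) == 0:
        raise ValueError("no trials to aggregate")
    df = index.copy()
    df["score"] = trial_scores
    out = []
    for (pid, sid), grp in df.groupby(["participant_id", "session_id"],
                                      sort=True):
        truth = grp["fma_ue"].unique()
        if len(truth) != 1:
            raise ValueError(f"conflicting FMA labels in session {pid}/{sid}")
        out.append(SessionScore(str(pid), str(sid),
                                float(grp["score"].mean()), len(grp),
                                float(truth[0])))
    return out


def mae(sessions: list[SessionScore]) -> float:
    if not sessions:
        raise ValueError("need at least one session")
    return float(np.mean([abs(s.predicted - s.fma_true) for s in sessions]))


def pearson(predicted, true) -> float:
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if len(predicted) < 2:
        raise ValueError("need at least two points")
    if predicted.std() == 0 or true.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(predicted, true).statistic)


def tost(differences, spec: EquivalenceSpec = EquivalenceSpec()
         ) -> TostResult:
    """One-sample TOST on paired differences against (lower, upper).

    Two one-sided t-tests: H0a mean <= lower vs H1a mean > lower, and
    H0b mean >= upper vs H1b mean < upper; reported p is the larger of the
    two one-sided p-values.  With zero sample variance the limiting p is 0
    when the mean lies strictly inside the interval and 1 otherwise.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("TOST needs at least two differences")
    m = d.mean()
    s = d.std(ddof=1)
    df = n - 1
    if s == 0.0:
        inside = spec.lower_bound < m < spec.upper_bound
        p = 0.0 if inside else 1.0
        return TostResult(p, p, p, np.inf * np.sign(m - spec.lower_bound),
                          np.inf * np.sign(m - spec.upper_bound), df,
                          zero_variance=True)
    se = s / np.sqrt(n)
    t_lower = (m - spec.lower_bound) / se
    t_upper = (m - spec.upper_bound) / se
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    return TostResult(max(p_lower, p_upper), p_lower, p_upper,
                      float(t_lower), float(t_upper), df)


def ttests(predicted_sessions, true_sessions) -> TTestResult:
    """Two-sided paired and Welch two-sample t-tests on session scores.

    Identical vectors give a zero-variance paired test; that degenerate case
    is reported as p = 1 with the ``degenerate`` flag set.
    """
    a = np.asarray(predicted_sessions, dtype=float)
    b = np.asarray(true_sessions, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired t-test needs equal-length vectors")
    if len(a) < 2:
        raise ValueError("need at least two sessions")
    if np.std(a - b, ddof=1) == 0.0:
        paired_p, degenerate = 1.0, True
    else:
        paired_p = float(stats.ttest_rel(a, b).pvalue)
        degenerate = False
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        unpaired_p, degenerate = 1.0, True
    else:
        with warnings.catch_warnings():
            # one constant vector (e.g. an unchanging clinical score) trips
            # scipy's catastrophic-cancellation warning; Welch still applies
            warnings.simplefilter("ignore", RuntimeWarning)
            unpaired_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return TTestResult(paired_p, unpaired_p, degenerate)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def _report(model: TrainedModel, dataset: LabeledDataset,
            spec: EquivalenceSpec) -> EquivalenceReport:
    scores = model.predict(dataset.features)
    sessions = aggregate_sessions(scores, dataset.index_frame())
    pred = np.array([s.predicted for s in sessions])
    true = np.array([s.fma_true for s in sessions])
    diffs = pred - true
    try:
        r = pearson(pred, true)
    except ValueError:
        r = float("nan")
    tost_res = tost(diffs, spec)
    tt = ttests(pred, true)
    return EquivalenceReport(
        mae=mae(sessions), pearson_r=r, tost_p=tost_res.p,
        ttest_paired_p=tt.paired_p, ttest_unpaired_p=tt.unpaired_p,
        differences=diffs, sessions=sessions, spec=spec,
        degenerate_ttest=tt.degenerate)


def within_participant_eval(model: TrainedModel, dataset: LabeledDataset,
                            spec: EquivalenceSpec = EquivalenceSpec()
                            ) -> EquivalenceReport:
    """Score longitudinal sessions with a model whose training pool may
    have included the participant's earlier data."""
    if len(dataset) == 0:
        raise ValueError("no longitudinal trials to evaluate")
    return _report(model, dataset, spec)


def cross_participant_eval(pool: LabeledDataset, target: LabeledDataset,
                           target_participant: str, config, seed: int,
                           spec: EquivalenceSpec = EquivalenceSpec(),
                           tune_budget: int = 0, learning_rate: float = 1e-3,
                           ) -> EquivalenceReport:
    """Leave-one-subject-out evaluation.

    The target participant's trials are removed from the pool, the removal
    is verified (participant ids and trial ids), the model is retrained
    (optionally retuned) on the reduced pool and evaluated on the target's
    longitudinal sessions.
    """
    if target_participant not in set(target.participants):
        raise ValueError(
            f"target {target_participant!r} absent from longitudinal data")
    train_pool = pool.exclude_participant(target_participant)
    verify_no_leakage(train_pool, target, target_participant)

    if tune_budget > 0:
        from .tune import cnn_search_space, optimize, resnet_search_space
        # hold out a fifth of the pool participants' trials for validation
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(train_pool))
        n_val = max(1, len(idx) // 5)
        space = (cnn_search_space()
                 if config.__class__.__name__ == "CnnConfig"
                 else resnet_search_space())
        result = optimize(space, train_pool.subset(idx[n_val:]),
                          train_pool.subset(idx[:n_val]), tune_budget,
                          seed=seed, learning_rate=learning_rate)
        config = result.best_config
    trained = train_model(build_model(config), train_pool, seed,
                          learning_rate=learning_rate)
    return _report(trained, target, spec)


def plot_sessions(report: EquivalenceReport, path):
    """Predicted vs clinical score per session (SVG/PNG by extension).

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    true = [s.fma_true for s in report.sessions]
    pred = [s.predicted for s in report.sessions]
    ax.scatter(true, pred, zorder=3)
    lo = min(min(true), min(pred)) - 2
    hi = max(max(true), max(pred)) + 2
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8, zorder=1)
    ax.fill_between([lo, hi],
                    [lo + report.spec.lower_bound, hi + report.spec.lower_bound],
                    [lo + report.spec.upper_bound, hi + report.spec.upper_bound],
                    alpha=0.15, color="tab:blue", zorder=2,
                    label="equivalence band")
    ax.set_xlabel("clinical FMA score")
    ax.set_ylabel("EEG-predicted score (session mean)")
    ax.set_title(f"MAE {report.mae:.2f} | TOST p {report.tost_p:.3g}")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def verify_no_leakage(train_pool: LabeledDataset, target: LabeledDataset,
                      target_participant: str):
    """Hard guarantee that no target trial can reach the training set."""
    if target_participant in set(train_pool.participants):
        raise LeakageError(
            f"trials of {target_participant!r} present in the training pool")
    overlap = set(train_pool.trial_ids) & set(target.trial_ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} target trials found in the training pool "
            f"(e.g. {sorted(overlap)[:3]})")
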