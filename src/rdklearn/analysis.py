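"""Learning-rate and transfer analysis of per-session direction-range thresholds.

Each (participant, session, location, component) cell of the trial log is
fit with the Weibull psychometric function and summarized by its DRT.
Learning rates are the slopes of ordinary least-squares fits of DRT on
training day, per participant; group learning rates are the means of
participant slopes with between-participant standard errors.  Retention and
transfer are the changes in DRT from the last training day to the cue-free
post-test at the trained and untrained locations, with bootstrap confidence
intervals over participants.

Horizontal-component rates are computed for every group but carry a caveat
flag for cued (AV) training, where the suprathreshold auditory cue pins
horizontal performance at ceiling and a learning rate is not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .psychometric import aggregate, fit_weibull

__all__ = [
    "LearningFit",
    "fit_sessions",
    "learning_rate",
    "LearningRateModel",
    "participant_slopes",
    "group_marginal_slope",
    "retention_and_transfer",
]

COMPONENTS = ("vertical", "horizontal", "combined")

#: Chance level per component judgment; the combined 4AFC judgment uses 0.25.
GAMMA_BY_COMPONENT = {"vertical": 0.5, "horizontal": 0.5, "combined": 0.25}


@dataclass
class LearningFit:
    """OLS fit of DRT against training day for one participant/component."""

    slope_deg_per_day: float
    intercept_deg: float
    slope_se: float
    n_sessions: int
    n_dropped: int = 0  # non-converged sessions excluded

    def __post_init__(self) -> None:
        if self.n_sessions < 2:
            raise ValueError("a learning fit needs at least 2 sessions")


class LearningRateModel(BaseEstimator):
    """Scikit-learn style OLS of threshold on training day.

    ``fit(X, y)`` takes X = day (n_samples,) or (n_samples, 1) and
    y = DRT (deg); exposes ``slope_``, ``intercept_``, ``slope_se_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape or len(x) < 2:
            raise ValueError("need >= 2 (day, DRT) pairs of equal length")
        xbar, ybar = x.mean(), y.mean()
        sxx = np.sum((x - xbar) ** 2)
        if sxx == 0:
            raise ValueError("days are all identical")
        self.slope_ = float(np.sum((x - xbar) * (y - ybar)) / sxx)
        self.intercept_ = float(ybar - self.slope_ * xbar)
        resid = y - (self.intercept_ + self.slope_ * x)
        dof = len(x) - 2
        self.slope_se_ = (
            float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
        )
        self.n_ = len(x)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_sessions(
    trials: pd.DataFrame,
    lapse: float = 0.05,
    components: tuple = COMPONENTS,
    drt_ceiling: float = 360.0,
) -> pd.DataFrame:
    """Per-session Weibull fits: one row per (participant, session, location,
    component), with columns alpha, beta, drt_deg, loglik, converged.

    Training sessions are keyed by day; post-test rows get
    ``session = "posttest"`` and their location.  Practice rows are skipped
    (too few trials to fit); the titration block is fit as session
    ``"titration"``.

    Direction range is physically bounded by the full circle, so reported
    thresholds saturate at ``drt_ceiling`` (360 deg): when performance never
    declines over the tested levels — e.g. the cue-driven horizontal
    component during AV training — the MLE threshold is unbounded and the
    session is reported at ceiling.
    """
    rows = []
    usable = trials[trials["phase"].isin(["titration", "training", "posttest"])]
    for (pid, group, phase, day, loc), df in usable.groupby(
        ["participant_id", "group", "phase", "session_day", "location"], sort=True
    ):
        session = {"titration": "titration", "posttest": "posttest"}.get(
            phase, str(int(day))
        )
        for comp in components:
            gamma = GAMMA_BY_COMPONENT[comp]
            fit = fit_weibull(aggregate(df, comp), gamma=gamma, lapse=lapse)
            rows.append(
                dict(
                    participant_id=pid,
                    group=group,
                    phase=phase,
                    session=session,
                    session_day=int(day),
                    location=loc,
                    component=comp,
                    alpha=fit.alpha,
                    beta=fit.beta,
                    drt_deg=(
                        min(fit.drt_deg, drt_ceiling) if fit.converged else np.nan
                    ),
                    loglik=fit.loglik,
                    converged=fit.converged,
                    cued=bool(df["cue_present"].any()) and comp == "horizontal",
                )
            )
    return pd.DataFrame(rows)


def learning_rate(session_drts: pd.DataFrame) -> LearningFit:
    """Slope of a linear fit to one participant's training DRTs over days.

    Input: rows of the session-summary frame for a single participant and
    component (training phase).  Non-converged sessions are dropped and
    counted in ``n_dropped``.
    """
    df = session_drts[session_drts["phase"] == "training"]
    dropped = int((~df["converged"].astype(bool)).sum())
    df = df[df["converged"].astype(bool)]
    if len(df) < 2:
        raise ValueError("need >= 2 converged training sessions for a slope")
    model = LearningRateModel().fit(
        df["session_day"].to_numpy(float), df["drt_deg"].to_numpy(float)
    )
    return LearningFit(
        model.slope_, model.intercept_, model.slope_se_, model.n_, dropped
    )


def participant_slopes(
    summary: pd.DataFrame, component: str = "vertical"
) -> pd.DataFrame:
    """Per-participant learning slopes for one component (training phase)."""
    rows = []
    df = summary[
        (summary["component"] == component) & (summary["phase"] == "training")
    ]
    for (pid, group), sub in df.groupby(["participant_id", "group"], sort=True):
        try:
            fit = learning_rate(sub)
        except ValueError:
            continue
        rows.append(
            dict(
                participant_id=pid,
                group=group,
                component=component,
                slope_deg_per_day=fit.slope_deg_per_day,
                intercept_deg=fit.intercept_deg,
                slope_se=fit.slope_se,
                n_sessions=fit.n_sessions,
                n_dropped=fit.n_dropped,
                cued=bool(sub["cued"].any()),
            )
        )
    return pd.DataFrame(rows)


def group_marginal_slope(
    summary: pd.DataFrame,
    component: str = "vertical",
    method: str = "per-participant",
) -> pd.DataFrame:
    """Group learning rates: mean slope with between-participant SE.

    ``method="per-participant"`` (default) fits a slope per participant and
    averages; ``method="mean-then-fit"`` averages DRT across participants per
    day first and fits one line per group (its SE is then the OLS slope SE).
    Single-participant groups get ``slope_se = NaN``.  The ``cued`` flag
    marks group/component cells where training was cue-driven (AV
    horizontal), whose rate should not be interpreted as visual learning.
    """
    if method == "per-participant":
        slopes = participant_slopes(summary, component)
        rows = []
        for group, sub in slopes.groupby("group", sort=True):
            n = len(sub)
            rows.append(
                dict(
                    group=group,
                    component=component,
                    slope_deg_per_day=float(sub["slope_deg_per_day"].mean()),
                    slope_se=(
                        float(sub["slope_deg_per_day"].std(ddof=1) / np.sqrt(n))
                        if n > 1
                        else np.nan
                    ),
                    n_participants=n,
                    cued=bool(sub["cued"].any()),
                )
            )
        return pd.DataFrame(rows)
    if method == "mean-then-fit":
        df = summary[
            (summary["component"] == component)
            & (summary["phase"] == "training")
            & summary["converged"].astype(bool)
        ]
        rows = []
        for group, sub in df.groupby("group", sort=True):
            mean_drt = sub.groupby("session_day")["drt_deg"].mean()
            model = LearningRateModel().fit(
                mean_drt.index.to_numpy(float), mean_drt.to_numpy(float)
            )
            rows.append(
                dict(
                    group=group,
                    component=component,
                    slope_deg_per_day=model.slope_,
                    slope_se=model.slope_se_,
                    n_participants=sub["participant_id"].nunique(),
                    cued=bool(sub["cued"].any()),
                )
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown method {method!r}")


def retention_and_transfer(
    summary: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Change in DRT from the last training day to the post-test, per group
    and component, at the trained and untrained locations.

    Delta = DRT(post-test, location) - DRT(last training day) per
    participant; rows report the group mean delta with a seeded bootstrap
    95% CI over participants (B = ``n_boot``).
    """
    rng = np.random.default_rng(seed)
    train = summary[
        (summary["phase"] == "training") & summary["converged"].astype(bool)
    ]
    last_day = train.groupby("participant_id")["session_day"].transform("max")
    final = train[train["session_day"] == last_day].set_index(
        ["participant_id", "component"]
    )["drt_deg"]
    post = summary[
        (summary["phase"] == "posttest") & summary["converged"].astype(bool)
    ]
    rows = []
    for (group, comp, loc), sub in post.groupby(
        ["group", "component", "location"], sort=True
    ):
        deltas = []
        for _, row in sub.iterrows():
            key = (row["participant_id"], comp)
            if key in final.index:
                deltas.append(row["drt_deg"] - final.loc[key])
        deltas = np.asarray(deltas, dtype=float)
        if len(deltas) == 0:
            continue
        boots = rng.choice(deltas, size=(n_boot, len(deltas)), replace=True).mean(
            axis=1
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            dict(
                group=group,
                component=comp,
                location=loc,
                mean_delta_deg=float(deltas.mean()),
                ci_lo=float(lo),
                ci_hi=float(hi),
                n_participants=len(deltas),
            )
        )
    return pd.DataFrame(rows)
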