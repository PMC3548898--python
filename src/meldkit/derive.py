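"""Derive albumin-extended score models from a cohort.

The derivation pipeline mirrors how sodium was originally grafted onto MELD:
fit a proportional-hazards model for 90-day waiting-list mortality with the
base score, the clamped albumin deficit, and their interaction as covariates,
then divide the albumin coefficients by the base-score coefficient so that
points stay on the base-score scale (the base score keeps its published
coefficients; only the albumin terms are new).  The result is a
:class:`~meldkit.scores.ScoreModel` directly usable for integer scoring.

Cox fitting uses Efron's tie-handling (many tied event days at day
resolution).  Candidates with hyperalbuminemia (albumin > 5.0 g/dL) are
excluded from model fitting — albumin infusion in severely ill patients makes
the high tail uninformative about synthetic function — but never at scoring
time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import outcomes_at_horizon
from .scores import SCORE_CEIL, SCORE_FLOOR, ClampPolicy, ScoreModel, base_linear_frame

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "HazardFit",
    "split_cohort",
    "fit_hazards",
    "derive_extension",
    "predict_risk",
    "score_risk_model",
    "HYPERALBUMINEMIA_GDL",
]

HYPERALBUMINEMIA_GDL = 5.0


@dataclass(frozen=True)
class SplitSpec:
    """Random derivation/validation split specification."""

    fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"derivation fraction must be in (0, 1), got {self.fraction}")


@dataclass
class HazardFit:
    """A fitted proportional-hazards model plus the pieces risk prediction needs."""

    coefficients: pd.Series
    standard_errors: pd.Series
    baseline_survival_horizon: float  # S0 at the horizon, covariates at zero
    n_events: int
    horizon: float
    ties: str = "efron"
    converged: bool = True
    ridged: bool = False  # a tiny ridge was needed (near-singular information)
    log_likelihood: float = float("nan")
    max_observed_time: float = float("nan")
    model_: CoxPHFitter | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival_horizon <= 1.0:
            raise ValueError("baseline survival must be in (0, 1]")


def split_cohort(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly split a cohort into (derivation, validation) frames.

    Disjoint, exhaustive, and reproducible under the spec's seed.
    """
    spec = spec or SplitSpec()
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(cohort))
    n_der = int(round(spec.fraction * len(cohort)))
    der_idx = np.sort(perm[:n_der])
    val_idx = np.sort(perm[n_der:])
    return (
        cohort.iloc[der_idx].reset_index(drop=True),
        cohort.iloc[val_idx].reset_index(drop=True),
    )


def _prepare_fit_frame(
    cohort: pd.DataFrame,
    covariates: pd.DataFrame | list[str],
    horizon: float,
    too_sick_as_death: bool,
    exclude_hyperalbuminemia: bool,
) -> pd.DataFrame:
    if isinstance(covariates, list):
        X = cohort[covariates].astype(float)
    else:
        X = covariates.astype(float)
        if len(X) != len(cohort):
            raise ValueError("covariate frame length does not match cohort")
    oh = outcomes_at_horizon(cohort, horizon, too_sick_as_death)
    df = X.copy()
    df["time"] = oh["time"].to_numpy()
    df["event"] = oh["event"].to_numpy()
    if exclude_hyperalbuminemia and "alb_gdl" in cohort.columns:
        keep = ~(cohort["alb_gdl"].to_numpy(float) > HYPERALBUMINEMIA_GDL)
        df = df[keep]
    df = df[np.isfinite(df.drop(columns=["event"]).to_numpy(float)).all(axis=1)]
    df = df[df["time"] > 0]
    return df


def fit_hazards(
    cohort: pd.DataFrame,
    covariates: pd.DataFrame | list[str],
    horizon: float = 90.0,
    too_sick_as_death: bool = True,
    exclude_hyperalbuminemia: bool = True,
    penalizer: float = 0.0,
) -> HazardFit:
    """Fit a Cox model for mortality by ``horizon`` on the given covariates.

    ``covariates`` is a list of cohort column names or a ready design frame
    aligned to the cohort.  Efron's method handles tied event days.  Requires
    at least two events.  Near-singular designs (e.g. a constant covariate)
    are refit with a tiny ridge and flagged ``ridged``; non-convergence raises
    with lifelines' diagnostic trail attached.
    """
    df = _prepare_fit_frame(cohort, covariates, horizon, too_sick_as_death,
                            exclude_hyperalbuminemia)
    n_events = int(df["event"].sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit hazards, found {n_events}")

    # constant columns carry no information and make the information matrix
    # singular; report them with a zero coefficient and an infinite SE
    cov_cols = [c for c in df.columns if c not in ("time", "event")]
    constant = [c for c in cov_cols if df[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant covariate(s) from Cox fit: %s", constant)
        df = df.drop(columns=constant)

    def _fit(pen: float, step: float | None = None) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=pen)
        opts = {"step_size": step} if step else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # low-variance / convergence chatter
            cph.fit(df, duration_col="time", event_col="event", fit_options=opts)
        return cph

    ridged = False
    try:
        cph = _fit(penalizer)
    except (ConvergenceError, np.linalg.LinAlgError) as first_err:
        # near-singular information or an overshooting Newton step: damp the
        # step first, then add a tiny ridge
        logger.warning("Cox fit did not converge (%s); retrying damped", first_err)
        try:
            cph = _fit(penalizer, step=0.1)
        except (ConvergenceError, np.linalg.LinAlgError):
            cph = _fit(max(penalizer, 1e-6), step=0.1)
            ridged = True

    zeros = pd.DataFrame(
        np.zeros((1, len(cph.params_))), columns=cph.params_.index
    )
    s0 = float(cph.predict_survival_function(zeros, times=[horizon]).iloc[0, 0])
    coefs = cph.params_.copy()
    ses = cph.standard_errors_.copy()
    for c in constant:
        coefs[c] = 0.0
        ses[c] = np.inf
    coefs = coefs.reindex(cov_cols)
    ses = ses.reindex(cov_cols)
    return HazardFit(
        coefficients=coefs,
        standard_errors=ses,
        baseline_survival_horizon=s0,
        n_events=n_events,
        horizon=horizon,
        ties="efron",
        converged=True,
        ridged=ridged,
        log_likelihood=float(cph.log_likelihood_),
        max_observed_time=float(df["time"].max()),
        model_=cph,
    )


def derive_extension(
    derivation: pd.DataFrame,
    base: str = "meldna",
    horizon: float = 90.0,
    name: str | None = None,
    too_sick_as_death: bool = True,
) -> tuple[ScoreModel, HazardFit]:
    """Derive an albumin-extended ScoreModel from a derivation cohort.

    Fits ``base score + albumin deficit + interaction`` and rescales by the
    base-score coefficient so the derived points sit on the base-score scale:

        albumin_coeff     = beta_deficit / beta_base
        interaction_coeff = beta_interaction / beta_base

    The albumin deficit is ``4.0 - clamp(albumin, 1, 4)``, so a candidate at
    the upper clamp gains no points.  An albumin coefficient with unexpected
    sign (higher albumin raising the score) triggers a warning but the model
    is still emitted.
    """
    if base not in ("meld", "meldna"):
        raise ValueError(f"base must be 'meld' or 'meldna', got {base!r}")
    clamp = ClampPolicy()
    _, lin = base_linear_frame(derivation, base, clamp)
    b = np.clip(lin, SCORE_FLOOR, SCORE_CEIL)
    lo, hi = clamp.albumin_bounds
    g = hi - np.clip(derivation["alb_gdl"].to_numpy(float), lo, hi)
    # the interaction column is centered (g x (b - 30)) purely for numerical
    # conditioning — g and g*b are nearly collinear — and mapped back to the
    # uncentered parameterization afterwards; 30 sits where deaths concentrate
    center = 30.0
    X = pd.DataFrame(
        {"base": b, "alb_deficit": g, "deficit_x_base_c": g * (b - center)},
        index=derivation.index,
    )
    fit = fit_hazards(derivation, X, horizon, too_sick_as_death,
                      exclude_hyperalbuminemia=True)
    beta = fit.coefficients
    if beta["base"] <= 0:
        raise ValueError(
            "base-score coefficient is non-positive; cannot rescale to base points"
        )
    alb_coeff = float((beta["alb_deficit"] - center * beta["deficit_x_base_c"]) / beta["base"])
    int_coeff = float(beta["deficit_x_base_c"] / beta["base"])
    if alb_coeff < 0:
        warnings.warn(
            "derived albumin coefficient has unexpected sign (higher albumin "
            "raises the score); emitting the model anyway",
            stacklevel=2,
        )
    if name is None:
        name = "5vmeld_derived" if base == "meldna" else "meld_albumin_derived"
    model = ScoreModel(
        name=name,
        base=base,
        albumin_coeff=alb_coeff,
        interaction_coeff=int_coeff,
        clamp=clamp,
        rounding="half_up",
    )
    return model, fit


def predict_risk(
    fit: HazardFit, design: pd.DataFrame, horizon: float | None = None
) -> np.ndarray:
    """Predicted probability of death by the horizon for each design row.

    ``risk = 1 - S0(horizon) ** exp(linear predictor)``; monotone in the
    linear predictor.  Raises when the horizon lies beyond the fitted model's
    observed follow-up support.
    """
    horizon = fit.horizon if horizon is None else horizon
    if np.isfinite(fit.max_observed_time) and horizon > fit.max_observed_time:
        raise ValueError(
            f"horizon {horizon} beyond observed follow-up support "
            f"({fit.max_observed_time})"
        )
    cols = list(fit.coefficients.index)
    X = design[cols].to_numpy(float)
    lp = X @ fit.coefficients.to_numpy(float)
    if horizon == fit.horizon:
        s0 = fit.baseline_survival_horizon
    else:
        zeros = pd.DataFrame(np.zeros((1, len(cols))), columns=cols)
        s0 = float(fit.model_.predict_survival_function(zeros, times=[horizon]).iloc[0, 0])
    risk = 1.0 - s0 ** np.exp(lp)
    return np.clip(risk, 0.0, 1.0)


def score_risk_model(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float = 90.0,
) -> tuple[HazardFit, np.ndarray]:
    """Fit a one-covariate Cox model on an integer score; return per-subject risk.

    This is the standard route from a score to an absolute 90-day mortality
    probability: candidates with equal scores get equal risks, and risk is
    monotone in the score.
    """
    cohort = pd.DataFrame(
        {
            "score": np.asarray(scores, float),
            "followup_days": np.asarray(times, float),
            "outcome": np.where(np.asarray(events, bool), "death", "administrative_censor"),
        }
    )
    X = cohort[["score"]]
    fit = fit_hazards(cohort, X, horizon, exclude_hyperalbuminemia=False)
    risks = predict_risk(fit, X)
    return fit, risks
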