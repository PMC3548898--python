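"""Integer liver-allocation scores: MELD, MELDNa, MELD-albumin, and 5vMELD.

All four scores map listing laboratory values to an integer on the 6-40
allocation scale.  MELD is the classic three-variable score

    MELD = 10 * (0.957 ln(creatinine) + 0.378 ln(bilirubin)
                 + 1.120 ln(INR) + 0.643)

computed on clamped labs (floor 1.0 for bilirubin/creatinine/INR; creatinine
capped at 4.0 mg/dL, and set to 4.0 for patients on dialysis), rounded to the
nearest integer and constrained to [6, 40].  MELDNa adjusts MELD for serum
sodium (clamped to [125, 140] mmol/L):

    MELDNa = MELD - Na - 0.025 * MELD * (140 - Na) + 140

and is truncated toward zero rather than rounded, which is the convention that
reproduces the published worked examples (21.25 -> 21, 33.75 -> 33).

The albumin extensions add points for hypoalbuminemia with an attenuating
interaction: with g = 4.0 - clamp(albumin, 1.0, 4.0) in g/dL,

    extended = base + g * (albumin_coeff + interaction_coeff * base)

where ``base`` is the *unrounded* value of the base score (MELD for
MELD-albumin, MELDNa for 5vMELD).  The result is rounded half-up and
constrained to [6, 40].  Coefficients are configuration, loadable from a YAML
file or produced by :mod:`meldkit.derive` from cohort data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "LabPanel",
    "ClampPolicy",
    "ScoreModel",
    "ScoreValue",
    "clamp_labs",
    "meld",
    "meldna",
    "apply_albumin_extension",
    "score_cohort",
    "load_models",
    "save_models",
    "default_models",
]

SCORE_FLOOR = 6
SCORE_CEIL = 40


class MissingDataError(ValueError):
    """A lab required by the requested score is absent."""


class InvalidLabError(ValueError):
    """A lab value is non-positive or non-numeric."""


class CoefficientsUnsetError(ValueError):
    """Extension coefficients were never configured."""


@dataclass(frozen=True)
class LabPanel:
    """One candidate's listing laboratory values, in raw (unclamped) units.

    bilirubin, creatinine in mg/dL; INR dimensionless; sodium in mmol/L
    (``None`` when not measured); albumin in g/dL; ``on_dialysis`` true when
    the candidate had >= 2 dialysis sessions in the prior week.
    """

    bilirubin: float
    creatinine: float
    inr: float
    albumin: float
    sodium: float | None = None
    on_dialysis: bool = False

    def __post_init__(self) -> None:
        for name in ("bilirubin", "creatinine", "inr", "albumin"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InvalidLabError(f"{name} must be a positive number, got {v!r}")
        if self.sodium is not None and (
            not math.isfinite(self.sodium) or self.sodium <= 0
        ):
            raise InvalidLabError(f"sodium must be positive or None, got {self.sodium!r}")


@dataclass(frozen=True)
class ClampPolicy:
    """Lab clamping bounds applied before score evaluation."""

    lab_floor: float = 1.0
    creatinine_cap: float = 4.0
    sodium_bounds: tuple[float, float] = (125.0, 140.0)
    albumin_bounds: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.sodium_bounds, self.albumin_bounds):
            if not lo < hi:
                raise ValueError(f"bounds must be ordered low < high, got ({lo}, {hi})")


Rounding = Literal["half_up", "truncate"]


def _round(x: float, policy: Rounding) -> int:
    if policy == "half_up":
        return int(math.floor(x + 0.5))
    if policy == "truncate":
        return int(x)  # scores are positive; int() truncates toward zero
    raise ValueError(f"unknown rounding policy {policy!r}")


def _constrain(score: int) -> int:
    return min(max(score, SCORE_FLOOR), SCORE_CEIL)


@dataclass(frozen=True)
class ScoreValue:
    """An integer score plus the unrounded linear value behind it."""

    model_name: str
    score: int
    linear: float

    def __post_init__(self) -> None:
        if not SCORE_FLOOR <= self.score <= SCORE_CEIL:
            raise ValueError(f"score {self.score} outside [{SCORE_FLOOR}, {SCORE_CEIL}]")

    @property
    def linear_constrained(self) -> float:
        """Unrounded value clipped to the allocation scale; feeds extensions."""
        return min(max(self.linear, float(SCORE_FLOOR)), float(SCORE_CEIL))


@dataclass(frozen=True)
class ScoreModel:
    """A named scoring rule: base score plus optional albumin extension.

    ``albumin_coeff`` is points per g/dL of albumin deficit below the upper
    clamp; ``interaction_coeff`` is points per (g/dL deficit x base point).
    ``None`` coefficients mean "not configured" (distinct from an explicit 0).
    """

    name: str
    base: Literal["meld", "meldna"] | None = None
    albumin_coeff: float | None = None
    interaction_coeff: float | None = None
    clamp: ClampPolicy = field(default_factory=ClampPolicy)
    rounding: Rounding = "half_up"

    @property
    def is_extension(self) -> bool:
        return self.base is not None and self.name not in ("meld", "meldna")


def clamp_labs(labs: LabPanel, policy: ClampPolicy | None = None) -> LabPanel:
    """Apply the standard clamping rules; idempotent.

    Bilirubin/creatinine/INR are floored at ``lab_floor``; creatinine is capped
    at ``creatinine_cap`` and forced to the cap on dialysis; sodium and albumin
    are clamped to their bound pairs (sodium only when present).
    """
    policy = policy or ClampPolicy()
    creat = max(labs.creatinine, policy.lab_floor)
    creat = policy.creatinine_cap if labs.on_dialysis else min(creat, policy.creatinine_cap)
    sodium = labs.sodium
    if sodium is not None:
        sodium = min(max(sodium, policy.sodium_bounds[0]), policy.sodium_bounds[1])
    return replace(
        labs,
        bilirubin=max(labs.bilirubin, policy.lab_floor),
        creatinine=creat,
        inr=max(labs.inr, policy.lab_floor),
        sodium=sodium,
        albumin=min(max(labs.albumin, policy.albumin_bounds[0]), policy.albumin_bounds[1]),
    )


def meld_linear(labs: LabPanel, policy: ClampPolicy | None = None) -> float:
    """Unrounded MELD value on clamped labs."""
    c = clamp_labs(labs, policy)
    return 10.0 * (
        0.957 * math.log(c.creatinine)
        + 0.378 * math.log(c.bilirubin)
        + 1.120 * math.log(c.inr)
        + 0.643
    )


def meld(labs: LabPanel, policy: ClampPolicy | None = None) -> ScoreValue:
    """Classic three-variable MELD, rounded half-up, constrained to [6, 40]."""
    lin = meld_linear(labs, policy)
    return ScoreValue("meld", _constrain(_round(lin, "half_up")), lin)


def meldna(
    meld_score: int,
    sodium: float | None,
    policy: ClampPolicy | None = None,
    rounding: Rounding = "truncate",
) -> ScoreValue:
    """Sodium-adjusted MELD from an integer MELD score.

    Equals the MELD score when sodium >= 140 mmol/L (the adjustment vanishes).
    Raises :class:`MissingDataError` when sodium is absent; the caller decides
    whether to fall back to MELD.
    """
    if sodium is None or (isinstance(sodium, float) and math.isnan(sodium)):
        raise MissingDataError("sodium is required for MELDNa")
    if not SCORE_FLOOR <= meld_score <= SCORE_CEIL:
        raise ValueError(f"meld_score {meld_score} outside [{SCORE_FLOOR}, {SCORE_CEIL}]")
    policy = policy or ClampPolicy()
    na = min(max(float(sodium), policy.sodium_bounds[0]), policy.sodium_bounds[1])
    lin = meld_score - na - 0.025 * meld_score * (140.0 - na) + 140.0
    return ScoreValue("meldna", _constrain(_round(lin, rounding)), lin)


def apply_albumin_extension(base: ScoreValue, albumin: float, model: ScoreModel) -> ScoreValue:
    """Extend a base score with albumin and albumin x base interaction points.

    The extension operates on the base's unrounded (clamped-to-scale) value;
    the albumin deficit g = upper_clamp - clamp(albumin) multiplies
    ``albumin_coeff + interaction_coeff * base``.  A model with both
    coefficients exactly zero is the identity on the base score.
    """
    if model.albumin_coeff is None or model.interaction_coeff is None:
        raise CoefficientsUnsetError(
            f"model {model.name!r} has unset albumin/interaction coefficients; "
            "supply a populated coefficient file or derive one with "
            "meldkit.derive.derive_extension"
        )
    if albumin is None or not math.isfinite(albumin) or albumin <= 0:
        raise InvalidLabError(f"albumin must be a positive number, got {albumin!r}")
    if model.albumin_coeff == 0.0 and model.interaction_coeff == 0.0:
        return base  # null extension: identity by definition
    lo, hi = model.clamp.albumin_bounds
    g = hi - min(max(albumin, lo), hi)
    b = base.linear_constrained
    lin = b + g * (model.albumin_coeff + model.interaction_coeff * b)
    return ScoreValue(model.name, _constrain(_round(lin, model.rounding)), lin)


# ---------------------------------------------------------------------------
# vectorized scoring (cohort-scale)


def _meld_linear_arr(bili, creat, inr, dialysis, policy: ClampPolicy | None = None) -> np.ndarray:
    """Vectorized unrounded MELD on clamped labs."""
    policy = policy or ClampPolicy()
    b = np.maximum(np.asarray(bili, float), policy.lab_floor)
    c = np.minimum(np.maximum(np.asarray(creat, float), policy.lab_floor), policy.creatinine_cap)
    c = np.where(np.asarray(dialysis, bool), policy.creatinine_cap, c)
    i = np.maximum(np.asarray(inr, float), policy.lab_floor)
    return 10.0 * (0.957 * np.log(c) + 0.378 * np.log(b) + 1.120 * np.log(i) + 0.643)


def _round_arr(x: np.ndarray, policy: Rounding) -> np.ndarray:
    if policy == "half_up":
        return np.floor(x + 0.5)
    if policy == "truncate":
        return np.trunc(x)
    raise ValueError(f"unknown rounding policy {policy!r}")


def base_linear_frame(
    cohort: pd.DataFrame, base: str, policy: ClampPolicy | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (integer score, unrounded linear) for a base score.

    ``base`` is ``"meld"`` or ``"meldna"``.  The MELDNa linear value is built
    from the *integer* MELD score, mirroring the published formula; candidates
    with missing sodium get NaN under ``"meldna"``.
    """
    policy = policy or ClampPolicy()
    mlin = _meld_linear_arr(
        cohort["bili_mgdl"], cohort["creat_mgdl"], cohort["inr"],
        cohort.get("dialysis", pd.Series(False, index=cohort.index)), policy,
    )
    mint = np.clip(_round_arr(mlin, "half_up"), SCORE_FLOOR, SCORE_CEIL)
    if base == "meld":
        return mint.astype(int), mlin
    if base == "meldna":
        na = cohort["na_mmoll"].to_numpy(float)
        na_c = np.clip(na, *policy.sodium_bounds)
        lin = mint - na_c - 0.025 * mint * (140.0 - na_c) + 140.0
        score = np.clip(_round_arr(lin, "truncate"), SCORE_FLOOR, SCORE_CEIL)
        score = np.where(np.isnan(lin), np.nan, score)
        return score, lin
    raise ValueError(f"unknown base score {base!r}")


def score_frame(cohort: pd.DataFrame, model: ScoreModel) -> pd.DataFrame:
    """Vectorized scores for every row; NaN score where inputs are missing.

    Returns a frame with columns ``score`` and ``linear`` on the cohort index.
    Rows with invalid (non-positive) required labs or missing sodium (for
    sodium-based models) carry NaN; :func:`score_cohort` turns those into an
    exclusion ledger.
    """
    name = model.name.lower().replace("-", "_")
    policy = model.clamp
    base_name = "meldna" if name == "meldna" or model.base == "meldna" else "meld"

    valid = np.ones(len(cohort), bool)
    for c in ("bili_mgdl", "creat_mgdl", "inr", "alb_gdl"):
        v = cohort[c].to_numpy(float)
        valid &= np.isfinite(v) & (v > 0)
    safe = pd.DataFrame(
        {
            "bili_mgdl": np.where(valid, cohort["bili_mgdl"], 1.0),
            "creat_mgdl": np.where(valid, cohort["creat_mgdl"], 1.0),
            "inr": np.where(valid, cohort["inr"], 1.0),
            "na_mmoll": cohort["na_mmoll"].to_numpy(float)
            if "na_mmoll" in cohort.columns
            else np.full(len(cohort), np.nan),
            "dialysis": cohort.get("dialysis", pd.Series(False, index=cohort.index))
            .fillna(False)
            .astype(bool)
            .to_numpy(),
        },
        index=cohort.index,
    )
    with np.errstate(invalid="ignore"):
        score, lin = base_linear_frame(safe, base_name, policy)
    if name in ("meld", "meldna") or not model.is_extension:
        out_score, out_lin = score, lin
    else:
        if model.albumin_coeff is None or model.interaction_coeff is None:
            raise CoefficientsUnsetError(
                f"model {model.name!r} has unset albumin/interaction coefficients"
            )
        alb = cohort["alb_gdl"].to_numpy(float)
        lo, hi = policy.albumin_bounds
        g = hi - np.clip(alb, lo, hi)
        b = np.clip(lin, SCORE_FLOOR, SCORE_CEIL)
        if model.albumin_coeff == 0.0 and model.interaction_coeff == 0.0:
            out_score, out_lin = score, lin  # null extension: identity on base
        else:
            ext = b + g * (model.albumin_coeff + model.interaction_coeff * b)
            out_score = np.clip(_round_arr(ext, model.rounding), SCORE_FLOOR, SCORE_CEIL)
            out_lin = ext
    out_score = np.where(valid, out_score, np.nan)
    out_lin = np.where(valid, out_lin, np.nan)
    return pd.DataFrame({"score": out_score, "linear": out_lin}, index=cohort.index)


def _score_one(labs: LabPanel, model: ScoreModel) -> ScoreValue:
    """Score a single lab panel under ``model`` (resolving the base chain)."""
    name = model.name.lower().replace("-", "_")
    if name == "meld" or (model.base is None and not model.is_extension):
        sv = meld(labs, model.clamp)
        return replace(sv, model_name=model.name) if model.name != "meld" else sv
    if name == "meldna":
        m = meld(labs, model.clamp)
        return meldna(m.score, labs.sodium, model.clamp, model.rounding)
    # albumin extension over meld or meldna base
    m = meld(labs, model.clamp)
    if model.base == "meldna":
        base = meldna(m.score, labs.sodium, model.clamp)
    else:
        base = m
    return apply_albumin_extension(base, labs.albumin, model)


def score_cohort(
    cohort: pd.DataFrame, model: ScoreModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every candidate in a cohort frame under one model.

    Returns ``(scored, exclusions)``: ``scored`` has columns ``id``, ``score``,
    ``linear``; ``exclusions`` lists dropped candidates with a reason
    (mirroring the registry practice of excluding candidates with missing
    labs).  Deterministic: scoring the same cohort twice gives identical
    output.
    """
    if len(cohort) == 0:
        logger.warning("score_cohort called on an empty cohort")
        empty = pd.DataFrame(columns=["id", "score", "linear"])
        return empty, pd.DataFrame(columns=["id", "reason"])

    sf = score_frame(cohort, model)
    ok = sf["score"].notna().to_numpy()

    # attribute a reason to each dropped candidate
    reasons = pd.Series("", index=cohort.index, dtype=object)
    needs_na = model.name.lower().replace("-", "_") == "meldna" or model.base == "meldna"
    if needs_na:
        na = (
            cohort["na_mmoll"].isna()
            if "na_mmoll" in cohort.columns
            else pd.Series(True, index=cohort.index)
        )
        reasons[~ok & na.to_numpy()] = "sodium is required for this model"
    reasons[~ok & (reasons == "")] = "invalid labs (non-positive or non-numeric)"

    scored = pd.DataFrame(
        {
            "id": cohort.loc[ok, "id"].values,
            "score": sf.loc[ok, "score"].astype(int).values,
            "linear": sf.loc[ok, "linear"].values,
        }
    )
    exclusions = pd.DataFrame(
        {"id": cohort.loc[~ok, "id"].values, "reason": reasons[~ok].values}
    )
    dropped = exclusions
    if len(dropped):
        logger.info("score_cohort: %d candidates excluded", len(dropped))
    return scored, exclusions


# ---------------------------------------------------------------------------
# Coefficient configuration files


def _model_from_dict(name: str, d: dict) -> ScoreModel:
    clamp_d = d.get("clamp", {})
    clamp = ClampPolicy(
        lab_floor=clamp_d.get("lab_floor", 1.0),
        creatinine_cap=clamp_d.get("creatinine_cap", 4.0),
        sodium_bounds=tuple(clamp_d.get("sodium_bounds", (125.0, 140.0))),
        albumin_bounds=tuple(clamp_d.get("albumin_bounds", (1.0, 4.0))),
    )
    return ScoreModel(
        name=name,
        base=d.get("base"),
        albumin_coeff=d.get("albumin_coeff"),
        interaction_coeff=d.get("interaction_coeff"),
        clamp=clamp,
        rounding=d.get("rounding", "half_up"),
    )


def load_models(path) -> dict[str, ScoreModel]:
    """Read a coefficient configuration file (YAML) into ScoreModels."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "models" not in doc:
        raise ValueError(f"{path}: expected a top-level 'models' mapping")
    return {name: _model_from_dict(name, d or {}) for name, d in doc["models"].items()}


def save_models(models: dict[str, ScoreModel], path) -> None:
    """Write ScoreModels to a coefficient file; inverse of :func:`load_models`."""
    doc: dict = {"models": {}}
    for name, m in models.items():
        doc["models"][name] = {
            "base": m.base,
            "albumin_coeff": m.albumin_coeff,
            "interaction_coeff": m.interaction_coeff,
            "rounding": m.rounding,
            "clamp": {
                "lab_floor": m.clamp.lab_floor,
                "creatinine_cap": m.clamp.creatinine_cap,
                "sodium_bounds": list(m.clamp.sodium_bounds),
                "albumin_bounds": list(m.clamp.albumin_bounds),
            },
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_models() -> dict[str, ScoreModel]:
    """The shipped reference models (MELD, MELDNa, MELD-albumin, 5vMELD)."""
    ref = resources.files("meldkit.data").joinpath("reference_models.yaml")
    with resources.as_file(ref) as p:
        return load_models(p)
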