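"""Risk reclassification tables, net reclassification improvement, calibration.

Two models' predicted 90-day mortality risks are cross-classified into ordered
strata (default 0-<5%, 5-<10%, 10-<20%, >=20%; half-open on the right, so a
risk of exactly 5% belongs to the 5-<10% stratum).  Each cell tracks persons,
deaths and survivors at the horizon (persons censored inside the window belong
to neither count), a Kaplan-Meier observed mortality using all cell members,
and the mean predicted risk under each model.

The net reclassification improvement (NRI) sums, over decedents, the net
fraction moved to a *higher* stratum by the new model, and over survivors the
net fraction moved *lower*; its asymptotic standard error follows the
summed-binomial construction.  The reclassification calibration statistic is a
Hosmer-Lemeshow-type chi-square restricted to reclassified (off-diagonal)
cells with at least ``min_cell`` members, referred to a chi-square with
(cells - 2) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskStrata",
    "ReclassTable",
    "NRIResult",
    "build_table",
    "nri",
    "nri_from_strata",
    "reclass_calibration",
    "correctly_reclassified",
]


@dataclass(frozen=True)
class RiskStrata:
    """Ordered predicted-risk cut points in percent, covering [0, 100]."""

    cuts: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 100.0)

    def __post_init__(self) -> None:
        c = self.cuts
        if len(c) < 3 or any(a >= b for a, b in zip(c, c[1:])):
            raise ValueError("cuts must be strictly increasing with >= 2 strata")
        if c[0] != 0.0 or c[-1] != 100.0:
            raise ValueError("strata must cover [0, 100] percent")

    @property
    def n(self) -> int:
        return len(self.cuts) - 1

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.cuts, self.cuts[1:]):
            out.append(f">={lo:g}%" if hi == 100.0 else f"{lo:g}% to <{hi:g}%")
        return out

    def assign(self, risks: np.ndarray) -> np.ndarray:
        """Stratum index per risk (risks as probabilities in [0, 1])."""
        r = np.asarray(risks, float)
        if np.any(~np.isfinite(r)) or np.any(r < 0) or np.any(r > 1):
            raise ValueError("risks must be finite probabilities in [0, 1]")
        pct = r * 100.0
        idx = np.searchsorted(np.asarray(self.cuts[1:-1]), pct, side="right")
        return idx.astype(int)


@dataclass
class ReclassTable:
    """Cross-classification of two models' risk strata with outcome counts."""

    persons: np.ndarray  # (k, k) int, rows = model-A stratum, cols = model-B
    deaths: np.ndarray  # deaths by horizon, censored-in-window excluded
    survivors: np.ndarray  # alive at horizon
    km: np.ndarray  # KM observed mortality per cell (NaN where unavailable)
    mean_risk_a: np.ndarray
    mean_risk_b: np.ndarray
    strata: RiskStrata = field(default_factory=RiskStrata)
    min_cell: int = 20
    horizon: float = 90.0

    def __post_init__(self) -> None:
        k = self.strata.n
        for m in (self.persons, self.deaths, self.survivors, self.km,
                  self.mean_risk_a, self.mean_risk_b):
            if m.shape != (k, k):
                raise ValueError(f"matrix shape {m.shape} != ({k}, {k})")
        if np.any(self.deaths + self.survivors > self.persons):
            raise ValueError("deaths + survivors exceed persons in some cell")

    @classmethod
    def from_counts(
        cls,
        persons,
        deaths,
        survivors,
        strata: RiskStrata | None = None,
        min_cell: int = 20,
        mean_risk_a=None,
        mean_risk_b=None,
    ) -> "ReclassTable":
        """Build a table from printed per-cell counts (no per-person data).

        Observed mortality falls back to deaths / (deaths + survivors); mean
        predicted risks are NaN unless supplied.
        """
        persons = np.asarray(persons, dtype=int)
        deaths = np.asarray(deaths, dtype=int)
        survivors = np.asarray(survivors, dtype=int)
        strata = strata or RiskStrata()
        with np.errstate(invalid="ignore", divide="ignore"):
            km = np.where(
                deaths + survivors > 0, deaths / np.maximum(deaths + survivors, 1), np.nan
            )
        nan = np.full_like(km, np.nan)
        return cls(
            persons=persons,
            deaths=deaths,
            survivors=survivors,
            km=km,
            mean_risk_a=np.asarray(mean_risk_a, float) if mean_risk_a is not None else nan.copy(),
            mean_risk_b=np.asarray(mean_risk_b, float) if mean_risk_b is not None else nan.copy(),
            strata=strata,
            min_cell=min_cell,
        )

    @property
    def n_persons(self) -> int:
        return int(self.persons.sum())

    def qualifying(self) -> np.ndarray:
        """Boolean mask of cells meeting the minimum-size rule."""
        return self.persons >= self.min_cell

    def reclassified_persons(self) -> int:
        """Off-diagonal persons in qualifying cells (the headline reclassified count)."""
        off = ~np.eye(self.strata.n, dtype=bool)
        return int(self.persons[off & self.qualifying()].sum())

    def as_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell with every per-cell quantity."""
        k = self.strata.n
        rows = []
        for i in range(k):
            for j in range(k):
                rows.append(
                    {
                        "stratum_a": self.strata.labels[i],
                        "stratum_b": self.strata.labels[j],
                        "persons": int(self.persons[i, j]),
                        "deaths": int(self.deaths[i, j]),
                        "survivors": int(self.survivors[i, j]),
                        "observed_mortality": self.km[i, j],
                        "mean_risk_a": self.mean_risk_a[i, j],
                        "mean_risk_b": self.mean_risk_b[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class NRIResult:
    """Net reclassification improvement with asymptotic inference."""

    event_improvement: float  # (up - down) / deaths
    nonevent_improvement: float  # (down - up) / survivors
    nri: float
    se: float
    ci: tuple[float, float]
    p: float
    n_events: int
    n_nonevents: int


def build_table(
    risk_a,
    risk_b,
    times,
    events,
    horizon: float = 90.0,
    strata: RiskStrata | None = None,
    min_cell: int = 20,
) -> ReclassTable:
    """Cross-classify per-person risks from two models into a ReclassTable.

    ``times``/``events`` are raw follow-up: deaths within the horizon count as
    deaths, persons followed to the horizon without an event as survivors, and
    persons censored inside the window contribute to ``persons`` and the KM
    estimate only.
    """
    from .evaluate import km_mortality

    ra = np.asarray(risk_a, float)
    rb = np.asarray(risk_b, float)
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if not (len(ra) == len(rb) == len(t) == len(e)):
        raise ValueError("risk_a, risk_b, times, events must have equal length")
    strata = strata or RiskStrata()
    ia = strata.assign(ra)
    ib = strata.assign(rb)
    k = strata.n

    death = e & (t <= horizon)
    survivor = ~death & (t >= horizon)

    persons = np.zeros((k, k), dtype=int)
    deaths = np.zeros((k, k), dtype=int)
    survivors = np.zeros((k, k), dtype=int)
    km = np.full((k, k), np.nan)
    mra = np.full((k, k), np.nan)
    mrb = np.full((k, k), np.nan)
    np.add.at(persons, (ia, ib), 1)
    np.add.at(deaths, (ia, ib), death.astype(int))
    np.add.at(survivors, (ia, ib), survivor.astype(int))
    for i in range(k):
        for j in range(k):
            cell = (ia == i) & (ib == j)
            if not cell.any():
                continue
            mra[i, j] = ra[cell].mean()
            mrb[i, j] = rb[cell].mean()
            ct = np.minimum(t[cell], horizon)
            ce = death[cell]
            km[i, j] = km_mortality(ct, ce, horizon) if ce.any() else 0.0
    return ReclassTable(
        persons=persons,
        deaths=deaths,
        survivors=survivors,
        km=km,
        mean_risk_a=mra,
        mean_risk_b=mrb,
        strata=strata,
        min_cell=min_cell,
        horizon=horizon,
    )


def _up_down(matrix: np.ndarray) -> tuple[int, int]:
    up = int(np.triu(matrix, k=1).sum())
    down = int(np.tril(matrix, k=-1).sum())
    return up, down


def nri(table: ReclassTable, min_cell: int | None = None) -> NRIResult:
    """Net reclassification improvement of model B over model A.

    By default every cell counts (matching the published convention, where the
    minimum-cell rule applies to the headline reclassified-person count but
    not the NRI numerators).  Pass ``min_cell`` to restrict to large cells.
    """
    deaths = table.deaths.copy()
    survivors = table.survivors.copy()
    if min_cell is not None:
        small = table.persons < min_cell
        deaths[small] = 0
        survivors[small] = 0
    n_e = int(deaths.sum())
    n_ne = int(survivors.sum())
    if n_e == 0:
        raise ValueError("no deaths counted: event-side improvement undefined")
    if n_ne == 0:
        raise ValueError("no survivors counted: non-event-side improvement undefined")
    up_e, down_e = _up_down(deaths)
    up_ne, down_ne = _up_down(survivors)
    ev = (up_e - down_e) / n_e
    nev = (down_ne - up_ne) / n_ne
    total = ev + nev
    # summed-binomial asymptotic variance (movement fractions per outcome arm)
    var_e = ((up_e + down_e) / n_e - ev**2) / n_e
    var_ne = ((up_ne + down_ne) / n_ne - nev**2) / n_ne
    se = float(np.sqrt(var_e + var_ne))
    if se == 0:
        p = 1.0 if total == 0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(total) / se))
    return NRIResult(
        event_improvement=float(ev),
        nonevent_improvement=float(nev),
        nri=float(total),
        se=se,
        ci=(total - 1.96 * se, total + 1.96 * se),
        p=p,
        n_events=n_e,
        n_nonevents=n_ne,
    )


def nri_from_strata(strata_a, strata_b, events, strata: RiskStrata | None = None) -> NRIResult:
    """NRI from per-person stratum indices and event indicators."""
    strata = strata or RiskStrata()
    ia = np.asarray(strata_a, int)
    ib = np.asarray(strata_b, int)
    e = np.asarray(events, bool)
    k = strata.n
    deaths = np.zeros((k, k), dtype=int)
    survivors = np.zeros((k, k), dtype=int)
    np.add.at(deaths, (ia[e], ib[e]), 1)
    np.add.at(survivors, (ia[~e], ib[~e]), 1)
    table = ReclassTable.from_counts(deaths + survivors, deaths, survivors,
                                     strata=strata, min_cell=0)
    return nri(table)


def reclass_calibration(table: ReclassTable, model: str = "a") -> tuple[float, int, float]:
    """Hosmer-Lemeshow-type calibration over reclassified cells for one model.

    Over off-diagonal cells with at least ``table.min_cell`` persons, sums
    ``(observed - expected)^2 / (expected * (1 - mean risk))`` where expected
    deaths are ``persons * mean predicted risk`` under the model being tested
    and observed deaths come from the cell's KM mortality (falling back to the
    raw death count when no KM estimate exists).  Returns
    ``(statistic, dof, p)`` with a chi-square reference on (cells - 2) dof.
    """
    if model not in ("a", "b"):
        raise ValueError("model must be 'a' or 'b'")
    pred = table.mean_risk_a if model == "a" else table.mean_risk_b
    off = ~np.eye(table.strata.n, dtype=bool)
    use = off & table.qualifying() & np.isfinite(pred)
    cells = int(use.sum())
    if cells < 3:
        raise ValueError(
            f"only {cells} qualifying reclassified cells; need >= 3 for calibration"
        )
    persons = table.persons[use].astype(float)
    p_hat = pred[use]
    observed = np.where(
        np.isfinite(table.km[use]), table.km[use] * persons, table.deaths[use]
    )
    expected = persons * p_hat
    denom = expected * (1.0 - p_hat)
    if np.any(denom <= 0):
        raise ValueError("degenerate cell (expected deaths or survivors = 0)")
    statistic = float(np.sum((observed - expected) ** 2 / denom))
    dof = cells - 2
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, dof, p


def correctly_reclassified(table: ReclassTable) -> tuple[int, float]:
    """Persons in reclassified cells whose observed mortality sits closer to
    the destination model's mean prediction than the source model's.

    Returns (count, fraction of reclassified persons).  Cells lacking a KM
    estimate or a mean prediction are skipped.
    """
    off = ~np.eye(table.strata.n, dtype=bool)
    use = off & table.qualifying()
    total = int(table.persons[use].sum())
    if total == 0:
        return 0, float("nan")
    good = use & np.isfinite(table.km) & np.isfinite(table.mean_risk_a) & np.isfinite(table.mean_risk_b)
    closer = np.abs(table.km - table.mean_risk_b) < np.abs(table.km - table.mean_risk_a)
    count = int(table.persons[good & closer].sum())
    return count, count / total
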