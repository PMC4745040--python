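"""Parametric bootstrap and the Monte-Carlo likelihood oracle.

The bootstrap simulates datasets under a generating parameter set, refits
the model to each, and summarises bias and precision of the estimates.

The Monte-Carlo oracle estimates the probability (or binned density) of a
single-colonist observation pattern directly from forward simulations; it is
the independent cross-check of the master-equation likelihood used
throughout the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from island_assembly.island_data import ValidationError
from island_assembly.inference import ModelSpec, fit_model
from island_assembly.likelihood_core import (
    DEFAULT_OPTIONS,
    LikelihoodOptions,
    ParameterSet,
)
from island_assembly.simulator import simulate_island, simulate_lineage

__all__ = [
    "BootstrapReport",
    "RecordPattern",
    "OracleEstimate",
    "bootstrap",
    "mc_likelihood_oracle",
]


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapReport:
    """Replicate-level estimates plus per-parameter summaries.

    ``estimates`` has one row per successfully refitted replicate; derived
    net-diversification columns (``netdiv:<class>`` = lambda_c - mu) are
    appended.  ``reliable`` is False when more than 20% of replicates failed
    to refit.
    """

    model: ModelSpec
    generating_params: Mapping[str, ParameterSet]
    generating_values: Mapping[str, float]
    n_datasets: int
    estimates: pd.DataFrame
    failures: list[str]
    medians: Mapping[str, float]
    intervals: Mapping[str, tuple[float, float]]
    bias: Mapping[str, float]
    reliable: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, med in self.medians.items():
            lo, hi = self.intervals[name]
            rows.append(
                {
                    "parameter": name,
                    "true": self.generating_values.get(name, math.nan),
                    "median": med,
                    "q2.5": lo,
                    "q97.5": hi,
                    "bias": self.bias.get(name, math.nan),
                }
            )
        return pd.DataFrame(rows)


def _generating_slot_values(
    model: ModelSpec, params: Mapping[str, ParameterSet]
) -> dict[str, float]:
    values: dict[str, float] = {}
    for slot in model.free_parameters():
        if ":" in slot:
            p, cls = slot.split(":", 1)
        else:
            p, cls = slot, model.classes[0]
        values[slot] = getattr(params[cls], p)
    for cls in model.classes:
        values[f"netdiv:{cls}"] = params[cls].lambda_c - params[cls].mu
    return values


def bootstrap(
    model: ModelSpec,
    generating_params: Mapping[str, ParameterSet],
    M: int,
    class_fractions: Mapping[str, float],
    island_age: float,
    n_datasets: int,
    n_starts: int = 10,
    seed: int | None = None,
    options: LikelihoodOptions = DEFAULT_OPTIONS,
    **fit_kwargs,
) -> BootstrapReport:
    """Simulate ``n_datasets`` islands under ``generating_params`` and refit.

    Replicates use independent child seeds of ``seed``, so the report is
    invariant to execution order.  Refit failures are recorded; if more
    than 20% fail the report is flagged unreliable.
    """
    if n_datasets < 1:
        raise ValidationError("n_datasets must be >= 1")
    root = np.random.SeedSequence(seed)
    sim_seeds, fit_seeds = root.spawn(2)
    sim_children = sim_seeds.spawn(n_datasets)
    fit_children = fit_seeds.spawn(n_datasets)
    rows = []
    failures: list[str] = []
    for i in range(n_datasets):
        outcome = simulate_island(
            generating_params,
            M,
            class_fractions,
            island_age,
            seed=np.random.default_rng(sim_children[i]),
            keep_events=False,
        )
        try:
            fit = fit_model(
                outcome.dataset,
                model,
                n_starts=n_starts,
                seed=int(fit_children[i].generate_state(1)[0] % (2**31)),
                options=options,
                **fit_kwargs,
            )
        except (RuntimeError, ArithmeticError, ValidationError) as exc:
            failures.append(f"replicate {i}: {exc}")
            continue
        row = {"replicate": i, "loglik": fit.loglik, "converged": fit.converged}
        row.update(fit.estimates)
        by_class = fit.params_by_class()
        for cls in model.classes:
            row[f"netdiv:{cls}"] = by_class[cls].lambda_c - by_class[cls].mu
        rows.append(row)
    est = pd.DataFrame(rows)
    true_values = _generating_slot_values(model, generating_params)
    medians: dict[str, float] = {}
    intervals: dict[str, tuple[float, float]] = {}
    bias: dict[str, float] = {}
    if len(est):
        for name in true_values:
            if name not in est.columns:
                continue
            col = est[name].to_numpy(dtype=float)
            medians[name] = float(np.median(col))
            intervals[name] = (
                float(np.percentile(col, 2.5)),
                float(np.percentile(col, 97.5)),
            )
            bias[name] = medians[name] - true_values[name]
    return BootstrapReport(
        model=model,
        generating_params=dict(generating_params),
        generating_values=true_values,
        n_datasets=n_datasets,
        estimates=est,
        failures=failures,
        medians=medians,
        intervals=intervals,
        bias=bias,
        reliable=len(failures) <= 0.2 * n_datasets,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo likelihood oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecordPattern:
    """A single-colonist observation pattern for the oracle.

    ``status`` follows the five data-entry types.  ``n_missing`` restricts
    the number of extant descendants outside the phylogeny.  For timed
    patterns, ``colonisation_bin``/``branching_bin`` are ``(old, young)``
    age intervals (My before present) the colonisation and the first
    branching time must fall into; ``n_clade`` restricts the number of
    species in the phylogeny (statuses 4-5).
    """

    status: int
    n_missing: int = 0
    colonisation_bin: tuple[float, float] | None = None
    branching_bin: tuple[float, float] | None = None
    n_clade: int | None = None
    max_age: float | None = None  # status 2: upper bound on colonisation age


@dataclass(frozen=True)
class OracleEstimate:
    estimate: float  # probability, or density for timed patterns
    se: float
    n_matching: int
    n_sims: int
    wide_interval: bool  # True when nothing matched

    def agrees_with(self, value: float, n_se: float = 3.0, slack: float = 0.0) -> bool:
        return abs(value - self.estimate) <= n_se * self.se + slack


def _bin_contains(bin_: tuple[float, float], age: float) -> bool:
    old, young = max(bin_), min(bin_)
    return young <= age < old


def _pattern_matches(pattern: RecordPattern, rec, island_age: float) -> bool:
    if pattern.status == 2:
        # present, non-diverged, colonisation age below the bound
        if rec is None or rec.status != 3 or rec.n_missing != pattern.n_missing:
            return False
        bound = pattern.max_age if pattern.max_age is not None else island_age
        return rec.colonisation_time < bound
    if rec is None:
        return pattern.status == 1
    if pattern.status == 1 or rec.status != pattern.status:
        return False
    if rec.n_missing != pattern.n_missing:
        return False
    if pattern.n_clade is not None and rec.n_in_phylogeny != pattern.n_clade:
        return False
    if pattern.colonisation_bin is not None and not _bin_contains(
        pattern.colonisation_bin, rec.colonisation_time
    ):
        return False
    if pattern.branching_bin is not None:
        if not rec.branching_times:
            return False
        if not _bin_contains(pattern.branching_bin, rec.branching_times[0]):
            return False
    return True


def mc_likelihood_oracle(
    pattern: RecordPattern,
    params: ParameterSet,
    island_age: float,
    n_sims: int,
    seed: int | None = None,
) -> OracleEstimate:
    """Estimate the probability/density of ``pattern`` by forward simulation.

    Counts simulations of a single mainland species whose present-day record
    matches ``pattern``; binned time patterns are converted to densities by
    dividing by the bin widths.  The standard error is binomial (delta
    method for densities).
    """
    if pattern.status not in (1, 2, 3, 4, 5):
        raise ValidationError(f"unknown pattern status {pattern.status}")
    rng = np.random.default_rng(seed)
    g0 = params.gamma
    n_hit = 0
    # vectorised first-arrival screen: lineages arriving after the island's
    # lifespan match exactly the empty pattern
    arrivals = (
        rng.exponential(1.0 / g0, size=n_sims)
        if g0 > 0
        else np.full(n_sims, np.inf)
    )
    colonised = arrivals < island_age
    if pattern.status == 1:
        pass  # empty lineages counted below
    for first in arrivals[colonised]:
        out = simulate_lineage(params, island_age, rng, first_arrival=float(first))
        rec = (
            out.to_record("x", "c", island_age) if out.events else None
        )
        if _pattern_matches(pattern, rec, island_age):
            n_hit += 1
    if pattern.status == 1:
        n_hit += int(n_sims - colonised.sum())
    p_hat = n_hit / n_sims
    se_p = math.sqrt(max(p_hat * (1.0 - p_hat), 1e-300) / n_sims)
    width = 1.0
    for b in (pattern.colonisation_bin, pattern.branching_bin):
        if b is not None:
            width *= abs(b[0] - b[1])
    return OracleEstimate(
        estimate=p_hat / width,
        se=se_p / width,
        n_matching=n_hit,
        n_sims=n_sims,
        wide_interval=(n_hit == 0),
    )
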