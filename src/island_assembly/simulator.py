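"""Forward stochastic simulation of island community assembly.

Each mainland species colonises and diversifies independently, so an island
simulation is a collection of independent per-lineage Gillespie simulations.
Events per lineage, with ``n`` the number of extant island species descended
from (or identical to) the focal mainland species:

* immigration at rate ``gamma_n``: founds a non-endemic population, or, if a
  non-diverged population is already present, replaces it and resets its
  colonisation time;
* anagenesis at rate ``lambda_a`` (non-endemic population only): the
  population becomes an endemic species, its colonisation time freezes;
* cladogenesis at per-species rate ``lambda_c_n``: a species splits into two
  endemic daughters (the splitting species becomes an internal node);
* extinction at per-species rate ``mu``.

Times are simulated forward from island birth and reported as ages before
present.  Present-day survivors are converted to colonist records with the
most-recent-immigration convention for colonisation times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from island_assembly.island_data import ColonistRecord, IslandDataset, ValidationError
from island_assembly.likelihood_core import ParameterSet, dd_rate

__all__ = [
    "LineageOutcome",
    "SimulationOutcome",
    "SummaryStatistics",
    "EnsembleResult",
    "simulate_lineage",
    "simulate_island",
    "simulate_ensemble",
    "summarise",
    "colonisation_age_distribution",
    "single_colonisation_predicate",
]


@dataclass
class _Species:
    """A species (or internal node) in the per-lineage genealogy."""

    sid: int
    parent: int  # -1 for an immigration founder
    birth: float  # forward time of creation (split or immigration)
    root: int  # founding immigration event id
    endemic: bool
    alive: bool = True


@dataclass
class LineageOutcome:
    """Result of simulating one mainland species over the island lifespan."""

    events: list[tuple[float, str, int]] = field(default_factory=list)
    species: list[_Species] = field(default_factory=list)
    splits: list[tuple[float, int, int, int]] = field(default_factory=list)
    root_col_time: dict[int, float] = field(default_factory=dict)
    pop: int = -1  # index of the live non-endemic population, -1 if absent

    # -- present-day summaries ------------------------------------------

    def alive_ids(self) -> list[int]:
        return [s.sid for s in self.species if s.alive]

    @property
    def n_alive(self) -> int:
        return sum(1 for s in self.species if s.alive)

    def n_alive_endemic(self) -> int:
        return sum(1 for s in self.species if s.alive and s.endemic)

    def pop_alive(self) -> bool:
        return self.pop >= 0 and self.species[self.pop].alive

    def _subtree_has_alive(self) -> dict[int, bool]:
        has = {s.sid: s.alive for s in self.species}
        for s in reversed(self.species):  # children always created after parents
            if s.parent >= 0 and has[s.sid]:
                has[s.parent] = True
        return has

    def reconstructed_branching_times(self, root: int, island_age: float) -> list[float]:
        """Ages of splits with extant descendants on both sides, oldest first."""
        has = self._subtree_has_alive()
        ages = [
            island_age - t
            for (t, _parent, c1, c2) in self.splits
            if self.species[c1].root == root and has[c1] and has[c2]
        ]
        ages.sort(reverse=True)
        return ages

    def to_record(self, label: str, lineage_class: str, island_age: float) -> ColonistRecord | None:
        """Present-day colonist record, or ``None`` if nothing survived.

        The record's phylogeny is the endemic clade descending from the
        oldest colonisation with surviving endemic species; survivors of any
        later colonisation (other than the non-diverged immigrant
        population, which sets status 5) are counted as missing species.
        """
        alive = [s for s in self.species if s.alive]
        if not alive:
            return None
        pop_alive = self.pop_alive()
        endemic_roots = sorted(
            {s.root for s in alive if s.endemic},
            key=lambda r: self.root_col_time[r],
        )
        if not endemic_roots:
            # a lone non-endemic population: colonisation time known exactly
            pop = self.species[self.pop]
            return ColonistRecord(
                label=label,
                status=3,
                lineage_class=lineage_class,
                colonisation_time=island_age - self.root_col_time[pop.root],
                n_missing=0,
            )
        main = endemic_roots[0]
        in_main = [s for s in alive if s.root == main]
        n_missing = len(alive) - len(in_main) - (1 if pop_alive else 0)
        return ColonistRecord(
            label=label,
            status=5 if pop_alive else 4,
            lineage_class=lineage_class,
            colonisation_time=island_age - self.root_col_time[main],
            branching_times=tuple(
                self.reconstructed_branching_times(main, island_age)
            ),
            n_missing=n_missing,
        )

    def diversity_at(self, grid: np.ndarray) -> np.ndarray:
        """Species counts at forward times ``grid`` replayed from the event log."""
        counts = np.zeros(len(grid), dtype=int)
        deltas = {"immigration_new": 1, "cladogenesis": 1, "extinction": -1}
        times = []
        steps = []
        for (t, kind, _sid) in self.events:
            d = deltas.get(kind, 0)
            if d:
                times.append(t)
                steps.append(d)
        if not times:
            return counts
        cum = np.cumsum(steps)
        idx = np.searchsorted(times, grid, side="right")
        counts = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0)
        return counts


def simulate_lineage(
    params: ParameterSet,
    island_age: float,
    rng: np.random.Generator,
    first_arrival: float | None = None,
) -> LineageOutcome:
    """Exact Gillespie simulation of one mainland species.

    ``first_arrival`` optionally supplies a pre-drawn time of the first
    immigration (an Exp(gamma) variate), letting callers skip lineages that
    never colonise without touching the per-lineage RNG stream.
    """
    g0 = dd_rate(params.gamma, 0, params.K_prime)
    out = LineageOutcome()
    if first_arrival is None:
        if g0 <= 0:
            return out
        first_arrival = rng.exponential(1.0 / g0)
    t = first_arrival
    if t >= island_age:
        return out
    species = out.species
    alive: list[int] = []  # indices of live species, for O(1) uniform choice

    def add_species(parent: int, birth: float, root: int, endemic: bool) -> int:
        sid = len(species)
        species.append(_Species(sid, parent, birth, root, endemic))
        alive.append(sid)
        return sid

    def kill(sid: int) -> None:
        species[sid].alive = False
        alive.remove(sid)

    n_roots = 0
    out.root_col_time[n_roots] = t
    out.pop = add_species(-1, t, n_roots, endemic=False)
    out.events.append((t, "immigration_new", out.pop))
    n_roots += 1

    mu, la = params.mu, params.lambda_a
    while True:
        n = len(alive)
        g_n = dd_rate(params.gamma, n, params.K_prime)
        lc_n = dd_rate(params.lambda_c, n, params.K_prime)
        pop_here = out.pop >= 0 and species[out.pop].alive
        total = g_n + n * (mu + lc_n) + (la if pop_here else 0.0)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= island_age:
            break
        u = rng.random() * total
        if u < g_n:
            # immigration: replacement if a non-diverged population is present
            if pop_here:
                pop = species[out.pop]
                pop.birth = t
                out.root_col_time[pop.root] = t
                out.events.append((t, "immigration_replace", out.pop))
            else:
                out.root_col_time[n_roots] = t
                out.pop = add_species(-1, t, n_roots, endemic=False)
                out.events.append((t, "immigration_new", out.pop))
                n_roots += 1
            continue
        u -= g_n
        if pop_here and u < la:
            species[out.pop].endemic = True
            out.events.append((t, "anagenesis", out.pop))
            out.pop = -1
            continue
        if pop_here:
            u -= la
        idx = min(int(u / (mu + lc_n)), n - 1)
        sid = alive[idx]
        if u - idx * (mu + lc_n) < mu:
            kill(sid)
            out.events.append((t, "extinction", sid))
            if sid == out.pop:
                out.pop = -1
        else:
            sp = species[sid]
            kill(sid)
            c1 = add_species(sid, t, sp.root, endemic=True)
            c2 = add_species(sid, t, sp.root, endemic=True)
            out.splits.append((t, sid, c1, c2))
            out.events.append((t, "cladogenesis", sid))
            if sid == out.pop:
                out.pop = -1
    return out


# ---------------------------------------------------------------------------
# island-level simulation
# ---------------------------------------------------------------------------


def _class_counts(class_fractions: Mapping[str, float], M: int) -> dict[str, int]:
    """Integer mainland pool sizes by largest-remainder apportionment."""
    shares = {c: f * M for c, f in class_fractions.items()}
    counts = {c: int(math.floor(s)) for c, s in shares.items()}
    short = M - sum(counts.values())
    for c in sorted(shares, key=lambda c: shares[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


@dataclass
class SimulationOutcome:
    """One simulated island: event log, survivors, diversity trajectory."""

    island_age: float
    M: int
    class_fractions: dict[str, float]
    records: list[tuple[str, ColonistRecord]]  # (class, record) per survivor
    events: list[tuple[float, str, str, int, int]]  # (t, kind, class, lineage, sid)
    dtt_grid: np.ndarray
    dtt: np.ndarray
    dtt_by_class: dict[str, np.ndarray]
    n_colonised_by_class: dict[str, int]

    @property
    def dataset(self) -> IslandDataset:
        return IslandDataset(
            island_age=self.island_age,
            M=self.M,
            class_fractions=self.class_fractions,
            colonists=tuple(rec for (_cls, rec) in self.records),
        )


def simulate_island(
    params_by_class: Mapping[str, ParameterSet],
    M: int,
    class_fractions: Mapping[str, float],
    island_age: float,
    seed: int | np.random.Generator,
    dtt_points: int = 201,
    keep_events: bool = True,
) -> SimulationOutcome:
    """Simulate a whole island: ``M`` independent mainland species.

    Lineages that never colonise are skipped via a vectorised first-arrival
    draw, which leaves the outcome identical to simulating every lineage.
    """
    if island_age <= 0:
        raise ValidationError("island_age must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = _class_counts(class_fractions, M)
    grid = np.linspace(0.0, island_age, dtt_points)
    dtt = np.zeros(dtt_points, dtype=int)
    dtt_by_class = {c: np.zeros(dtt_points, dtype=int) for c in class_fractions}
    records: list[tuple[str, ColonistRecord]] = []
    events: list[tuple[float, str, str, int, int]] = []
    n_colonised = {c: 0 for c in class_fractions}
    for cls in class_fractions:
        ps = params_by_class[cls]
        m_c = counts[cls]
        g0 = dd_rate(ps.gamma, 0, ps.K_prime)
        if g0 <= 0 or m_c == 0:
            continue
        arrivals = rng.exponential(1.0 / g0, size=m_c)
        for i in np.flatnonzero(arrivals < island_age):
            out = simulate_lineage(ps, island_age, rng, first_arrival=float(arrivals[i]))
            if not out.events:
                continue
            n_colonised[cls] += 1
            d = out.diversity_at(grid)
            dtt += d
            dtt_by_class[cls] += d
            rec = out.to_record(f"{cls}:{i}", cls, island_age)
            if rec is not None:
                records.append((cls, rec))
            if keep_events:
                events.extend((t, kind, cls, int(i), sid) for (t, kind, sid) in out.events)
    events.sort(key=lambda e: e[0])
    return SimulationOutcome(
        island_age=island_age,
        M=M,
        class_fractions=dict(class_fractions),
        records=records,
        events=events,
        dtt_grid=grid,
        dtt=dtt,
        dtt_by_class=dtt_by_class,
        n_colonised_by_class=n_colonised,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStatistics:
    """Present-day counts used for goodness-of-fit comparison."""

    total_species: int
    species_by_class: dict[str, int]
    n_colonisations: int
    n_endemic_clades: int
    n_nonendemic_lineages: int
    n_anagenetic_species: int

    def to_dict(self) -> dict:
        return {
            "total_species": self.total_species,
            "species_by_class": dict(self.species_by_class),
            "n_colonisations": self.n_colonisations,
            "n_endemic_clades": self.n_endemic_clades,
            "n_nonendemic_lineages": self.n_nonendemic_lineages,
            "n_anagenetic_species": self.n_anagenetic_species,
        }


def summarise(outcome: SimulationOutcome) -> SummaryStatistics:
    """Deterministic present-day summary of a simulated island.

    An "anagenetic species" is a status-4 record with a single endemic
    species and no in-situ branching; an "endemic clade" is any record with
    at least one endemic species.
    """
    total = 0
    by_class = {c: 0 for c in outcome.class_fractions}
    n_endemic_clades = 0
    n_nonendemic = 0
    n_anagenetic = 0
    for cls, rec in outcome.records:
        total += rec.n_species
        by_class[cls] += rec.n_species
        if rec.status in (4, 5):
            n_endemic_clades += 1
            if rec.status == 4 and not rec.branching_times and rec.n_missing == 0:
                n_anagenetic += 1
        if rec.status in (2, 3, 5):
            n_nonendemic += 1
    return SummaryStatistics(
        total_species=total,
        species_by_class=by_class,
        n_colonisations=len(outcome.records),
        n_endemic_clades=n_endemic_clades,
        n_nonendemic_lineages=n_nonendemic,
        n_anagenetic_species=n_anagenetic,
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    outcomes: list[SimulationOutcome]
    dtt_grid: np.ndarray
    dtt_median: np.ndarray
    dtt_bands: dict[float, np.ndarray]
    n_attempted: int

    @property
    def acceptance_rate(self) -> float:
        return len(self.outcomes) / self.n_attempted if self.n_attempted else 0.0


def single_colonisation_predicate(
    lineage_class: str, surviving: bool = True
) -> Callable[[SimulationOutcome], bool]:
    """Predicate: exactly one colonisation of ``lineage_class``.

    With ``surviving`` (default) the colonisation must have extant
    descendants at the present; otherwise exactly one colonisation must
    have occurred over the island's history.
    """

    def predicate(outcome: SimulationOutcome) -> bool:
        if surviving:
            return sum(1 for c, _r in outcome.records if c == lineage_class) == 1
        return outcome.n_colonised_by_class.get(lineage_class, 0) == 1

    return predicate


def simulate_ensemble(
    params_by_class: Mapping[str, ParameterSet],
    M: int,
    class_fractions: Mapping[str, float],
    island_age: float,
    n_replicates: int,
    seed: int,
    condition: Callable[[SimulationOutcome], bool] | None = None,
    percentiles: Sequence[float] = (2.5, 75.0),
    dtt_points: int = 201,
    max_attempts: int | None = None,
    keep_events: bool = False,
) -> EnsembleResult:
    """Simulate replicate islands, rejection-sampling on ``condition``.

    Returns the accepted outcomes plus pointwise median and percentile
    bands of the diversity-through-time trajectory.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if max_attempts is None:
        max_attempts = 200 * n_replicates
    rng = np.random.default_rng(seed)
    outcomes: list[SimulationOutcome] = []
    attempts = 0
    while len(outcomes) < n_replicates:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"conditioning predicate accepted {len(outcomes)}/{attempts} "
                f"simulations; empirical acceptance rate "
                f"{len(outcomes) / max(attempts, 1):.2e} too low"
            )
        attempts += 1
        outcome = simulate_island(
            params_by_class,
            M,
            class_fractions,
            island_age,
            rng,
            dtt_points=dtt_points,
            keep_events=keep_events,
        )
        if condition is None or condition(outcome):
            outcomes.append(outcome)
    dtt_matrix = np.vstack([o.dtt for o in outcomes])
    return EnsembleResult(
        outcomes=outcomes,
        dtt_grid=outcomes[0].dtt_grid,
        dtt_median=np.median(dtt_matrix, axis=0),
        dtt_bands={p: np.percentile(dtt_matrix, p, axis=0) for p in percentiles},
        n_attempted=attempts,
    )


def colonisation_age_distribution(
    ensemble: EnsembleResult | Sequence[SimulationOutcome],
    lineage_class: str,
    percentiles: Sequence[float] = (2.5, 97.5),
) -> dict:
    """Colonisation-age summary of present, not-yet-speciated lineages.

    Collects, across the ensemble, the colonisation ages (most-recent
    immigration convention) of status-3 records of ``lineage_class`` --
    lineages on the island at the present that have not produced any
    endemic species -- and returns their median and percentiles.
    """
    outcomes = ensemble.outcomes if isinstance(ensemble, EnsembleResult) else ensemble
    ages = [
        rec.colonisation_time
        for o in outcomes
        for cls, rec in o.records
        if cls == lineage_class and rec.status == 3
    ]
    if not ages:
        return {"n": 0, "empty": True, "median": math.nan, "percentiles": {}}
    arr = np.asarray(ages)
    return {
        "n": len(arr),
        "empty": False,
        "median": float(np.median(arr)),
        "percentiles": {p: float(np.percentile(arr, p)) for p in percentiles},
    }
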