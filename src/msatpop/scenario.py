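"""Declarative divergence-scenario grammar with priors.

A scenario is a backward-time description of population history: sampled
demes with effective-size parameters, MERGE events (a source deme's lineages
move into a target deme) and SIZE_CHANGE events, at event times given by
named parameters with order constraints (e.g. t0 < t2 < t3). Every parameter
carries a prior (log-uniform, uniform or truncated log-normal) and draws
violating the order constraints are rejected and redrawn.

The shipped `scenario13` configuration encodes the best-supported Aegean
history: central-western merges into north-western at t2 (Holocene), the
north-western and north-eastern demes merge into the northern deme at t3
(Pleistocene) which then takes the ancestral size Na, and t0 is a recent
effective-size change on the central-western deme (its biological role is
unresolved; it is kept so the parameter vector matches the published table).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm


class ScenarioError(ValueError):
    """Raised on an invalid scenario configuration."""


@dataclass
class PriorSpec:
    """Marginal prior for one scenario parameter."""

    name: str
    shape: str  # 'log-uniform' | 'uniform' | 'truncated-log-normal'
    low: float
    high: float
    meanlog: float | None = None
    sdlog: float | None = None

    SHAPES = ("log-uniform", "uniform", "truncated-log-normal")

    def __post_init__(self):
        if self.shape not in self.SHAPES:
            raise ScenarioError(f"{self.name}: unknown prior shape {self.shape!r}")
        if not (0 < self.low < self.high):
            raise ScenarioError(f"{self.name}: need 0 < low < high")
        if self.shape == "truncated-log-normal" and (
            self.meanlog is None or self.sdlog is None
        ):
            raise ScenarioError(f"{self.name}: log-normal needs meanlog and sdlog")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.shape == "uniform":
            return rng.uniform(self.low, self.high, n)
        if self.shape == "log-uniform":
            return np.exp(rng.uniform(np.log(self.low), np.log(self.high), n))
        a = (np.log(self.low) - self.meanlog) / self.sdlog
        b = (np.log(self.high) - self.meanlog) / self.sdlog
        z = truncnorm.rvs(a, b, size=n, random_state=rng)
        return np.exp(self.meanlog + self.sdlog * z)


@dataclass
class Event:
    kind: str  # 'merge' | 'size_change'
    time: str  # parameter name
    source: str | None = None  # merge: deme that disappears (backward)
    target: str | None = None  # merge: deme receiving the lineages
    deme: str | None = None  # size_change
    size: str | None = None  # size_change: parameter name of new size


@dataclass
class DemographicScenario:
    """Population-split tree with sizes, event times and priors."""

    name: str
    demes: list[str]
    sizes: dict[str, str]  # deme -> size parameter name
    priors: dict[str, PriorSpec]
    events: list[Event]
    constraints: list[tuple[str, str]] = field(default_factory=list)  # (lo, hi)
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------

    def _time_order(self) -> dict[str, int]:
        """Total order of event-time symbols from the constraint DAG."""
        symbols = sorted({ev.time for ev in self.events})
        edges = [(a, b) for a, b in self.constraints if a in symbols and b in symbols]
        order: list[str] = []
        remaining = set(symbols)
        while remaining:
            free = sorted(
                s for s in remaining if not any(b == s and a in remaining for a, b in edges)
            )
            if not free:
                raise ScenarioError("cyclic time constraints among events")
            if len(free) > 1 and len(remaining) > 1:
                # more than one minimal symbol: order ambiguous unless they
                # are never both used by merges (size changes can tie)
                merge_syms = {ev.time for ev in self.events if ev.kind == "merge"}
                amb = [s for s in free if s in merge_syms]
                if len(amb) > 1:
                    raise ScenarioError(
                        f"merge event times not totally ordered: {amb}"
                    )
            order.append(free[0])
            remaining.discard(free[0])
        return {s: i for i, s in enumerate(order)}

    def sorted_events(self) -> list[Event]:
        """Events sorted by time-symbol rank, file order breaking ties."""
        rank = self._time_order()
        indexed = sorted(enumerate(self.events), key=lambda t: (rank[t[1].time], t[0]))
        return [ev for _, ev in indexed]

    def validate(self) -> None:
        if len(self.demes) != len(set(self.demes)):
            raise ScenarioError("duplicate deme names")
        for d in self.demes:
            if d not in self.sizes:
                raise ScenarioError(f"deme {d} has no size parameter")
        refs = set(self.sizes.values()) | {ev.time for ev in self.events}
        for ev in self.events:
            if ev.kind == "size_change":
                refs.add(ev.size)
        missing = sorted(r for r in refs if r not in self.priors)
        if missing:
            raise ScenarioError(f"parameters without priors: {missing}")
        for a, b in self.constraints:
            for s in (a, b):
                if s not in self.priors:
                    raise ScenarioError(f"constraint references unknown parameter {s}")
        # sweep backward in time: merges must leave exactly one deme
        active = set(self.demes)
        for ev in self.sorted_events():
            if ev.kind == "merge":
                for d in (ev.source, ev.target):
                    if d not in self.demes:
                        raise ScenarioError(f"merge references unknown deme {d}")
                    if d not in active:
                        raise ScenarioError(
                            f"merge at {ev.time} uses inactive deme {d}"
                        )
                if ev.source == ev.target:
                    raise ScenarioError("merge source equals target")
                active.discard(ev.source)
            else:
                if ev.deme not in self.demes:
                    raise ScenarioError(f"size change on unknown deme {ev.deme}")
                if ev.deme not in active:
                    raise ScenarioError(
                        f"size change at {ev.time} on inactive deme {ev.deme}"
                    )
        if len(active) != 1:
            raise ScenarioError(
                f"after all merges {len(active)} demes remain active: {sorted(active)}"
            )

    @property
    def parameter_names(self) -> list[str]:
        return list(self.priors)

    # -- prior sampling -----------------------------------------------------

    def satisfies_constraints(self, draws: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(draws), dtype=bool)
        for a, b in self.constraints:
            ok &= draws[a].to_numpy() < draws[b].to_numpy()
        return ok

    def sample_priors(self, n_draws: int, seed=None, rng=None) -> pd.DataFrame:
        """n_draws joint prior draws honouring order constraints (rejection)."""
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        out = []
        got = 0
        while got < n_draws:
            batch = max(n_draws - got, 1000)
            draws = pd.DataFrame(
                {p: spec.sample(batch, rng) for p, spec in self.priors.items()}
            )
            draws = draws[self.satisfies_constraints(draws)]
            if len(draws):
                out.append(draws)
                got += len(draws)
        return pd.concat(out, ignore_index=True).iloc[:n_draws].reset_index(drop=True)

    # -- msprime bridge -----------------------------------------------------

    def to_demography(self, params: dict[str, float]):
        """Build an msprime.Demography for one parameter draw."""
        import msprime

        dem = msprime.Demography()
        for d in self.demes:
            dem.add_population(name=d, initial_size=float(params[self.sizes[d]]))
        evs = []
        for ev in self.sorted_events():
            t = float(params[ev.time])
            if ev.kind == "merge":
                evs.append(("merge", t, ev))
            else:
                evs.append(("size", t, ev))
        evs.sort(key=lambda x: x[1])
        for kind, t, ev in evs:
            if kind == "merge":
                dem.add_mass_migration(
                    time=t, source=ev.source, dest=ev.target, proportion=1.0
                )
            else:
                dem.add_population_parameters_change(
                    time=t, population=ev.deme, initial_size=float(params[ev.size])
                )
        dem.sort_events()
        return dem


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_CONSTRAINT_RE = re.compile(r"^\s*(\w+)\s*<\s*(\w+)\s*$")


def load_scenario(source) -> DemographicScenario:
    """Load a scenario from a YAML file path, file object, or mapping."""
    if isinstance(source, dict):
        cfg = source
    elif hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    try:
        priors = {}
        for name, p in cfg["parameters"].items():
            priors[name] = PriorSpec(
                name=name,
                shape=p.get("prior", "log-uniform"),
                low=float(p["low"]),
                high=float(p["high"]),
                meanlog=p.get("meanlog"),
                sdlog=p.get("sdlog"),
            )
        events = []
        for ev in cfg.get("events", []):
            kind = ev["type"]
            if kind == "merge":
                events.append(
                    Event("merge", ev["time"], source=ev["source"], target=ev["target"])
                )
            elif kind == "size_change":
                events.append(
                    Event("size_change", ev["time"], deme=ev["deme"], size=ev["size"])
                )
            else:
                raise ScenarioError(f"unknown event type {kind!r}")
        constraints = []
        for c in cfg.get("constraints", []):
            m = _CONSTRAINT_RE.match(c)
            if not m:
                raise ScenarioError(f"cannot parse constraint {c!r} (use 'a < b')")
            constraints.append((m.group(1), m.group(2)))
        return DemographicScenario(
            name=cfg.get("name", "scenario"),
            demes=list(cfg["demes"]),
            sizes=dict(cfg["sizes"]),
            priors=priors,
            events=events,
            constraints=constraints,
            notes=cfg.get("notes", {}),
        )
    except KeyError as e:
        raise ScenarioError(f"missing config key: {e}") from e


def scenario13() -> DemographicScenario:
    """The shipped best-supported divergence scenario (4 Aegean demes)."""
    ref = importlib.resources.files("msatpop") / "data" / "scenario13.yaml"
    with ref.open() as fh:
        return load_scenario(fh)


def scenario13_alternative() -> DemographicScenario:
    """Topology-permuted alternative: scenario13 under the deme relabeling
    N<->NW, NE<->CW. The recent merge joins NE into N (with the t0 size
    change on the merging deme, as in scenario13) and the old merge joins N
    and CW into NW. Same parameters and priors as scenario13, so the two are
    directly comparable in model choice."""
    scn = scenario13()
    events = [
        Event("size_change", "t0", deme="NE", size="Na"),
        Event("merge", "t2", source="NE", target="N"),
        Event("merge", "t3", source="N", target="NW"),
        Event("merge", "t3", source="CW", target="NW"),
        Event("size_change", "t3", deme="NW", size="Na"),
    ]
    return DemographicScenario(
        name="scenario13_alt",
        demes=list(scn.demes),
        sizes=dict(scn.sizes),
        priors=dict(scn.priors),
        events=events,
        constraints=list(scn.constraints),
        notes={"derived_from": "scenario13", "kind": "topology permutation"},
    )


def generation_time_convert(t_generations: float, gen_years: float = 3.0) -> float:
    """Convert a time in generations to years (generation interval 3 y)."""
    if gen_years <= 0:
        raise ValueError("generation interval must be positive")
    return t_generations * gen_years
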