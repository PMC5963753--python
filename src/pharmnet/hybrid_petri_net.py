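"""Deterministic continuous Petri-net engine.

Places carry non-negative real markings; transitions fire continuously with
mass-action or Michaelis-Menten rate laws, modulated by inhibitory arcs.
The marking evolves as the ODE

    dm/dt = sum over transitions (post_weights - pre_weights) * flux

integrated with an adaptive stiff-capable solver.  Negative markings are
prevented by flux gating: rates are evaluated on markings clipped at zero,
so an emptying transition's flux vanishes at the boundary instead of being
clipped after the fact.

Inhibitory-arc semantics (continuous):

* ``hard`` (default): flux is forced to 0 while any inhibitor marking is at
  or above its threshold;
* ``smooth``: flux is multiplied by ``th^h / (th^h + m^h)`` per inhibitory
  arc (Hill modulation, sharpness ``h``); the hard switch is the pointwise
  limit ``h -> inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .errors import DomainError, NetValidationError, SimulationError, StructuralError

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
GRID_POINTS = 200  # output intervals per simulation


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassAction:
    k: float = 1.0


@dataclass(frozen=True)
class MichaelisMenten:
    vmax: float
    km: float


@dataclass(frozen=True)
class Place:
    name: str
    initial_marking: float = 0.0


@dataclass(frozen=True)
class Transition:
    name: str
    rate_law: object = MassAction(1.0)
    #: Source transitions are allowed to have no pre-places (constant influx).
    source: bool = False


@dataclass(frozen=True)
class Arc:
    place: str
    transition: str
    direction: str  # "pre" (place -> transition) or "post"
    weight: float = 1.0


@dataclass(frozen=True)
class InhibitoryArc:
    place: str
    transition: str
    threshold: float = 1.0


@dataclass
class HybridPetriNet:
    places: list = field(default_factory=list)
    transitions: list = field(default_factory=list)
    arcs: list = field(default_factory=list)
    inhibitory_arcs: list = field(default_factory=list)

    # -- queries ------------------------------------------------------------

    def place_names(self) -> list:
        return [p.name for p in self.places]

    def initial_marking(self) -> dict:
        return {p.name: p.initial_marking for p in self.places}

    def pre_arcs(self, transition: str) -> list:
        return [a for a in self.arcs if a.transition == transition and a.direction == "pre"]

    def post_arcs(self, transition: str) -> list:
        return [a for a in self.arcs if a.transition == transition and a.direction == "post"]

    def inhibitors(self, transition: str) -> list:
        return [a for a in self.inhibitory_arcs if a.transition == transition]

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "HybridPetriNet":
        places = [
            Place(p["name"], float(p.get("initial", 0.0))) for p in data.get("places", [])
        ]
        transitions = []
        for t in data.get("transitions", []):
            law_name = t.get("law", "mass_action")
            if law_name == "mass_action":
                law = MassAction(float(t.get("k", 1.0)))
            elif law_name == "michaelis_menten":
                law = MichaelisMenten(float(t["vmax"]), float(t["km"]))
            else:
                raise DomainError(f"unknown rate law {law_name!r}")
            transitions.append(Transition(t["name"], law, bool(t.get("source", False))))
        arcs = [
            Arc(a[0], a[1], a[2], float(a[3]) if len(a) > 3 else 1.0)
            for a in data.get("arcs", [])
        ]
        inhibitory = [
            InhibitoryArc(a[0], a[1], float(a[2]) if len(a) > 2 else 1.0)
            for a in data.get("inhibitory_arcs", [])
        ]
        return cls(places, transitions, arcs, inhibitory)

    @classmethod
    def from_yaml(cls, path) -> "HybridPetriNet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        trans = []
        for t in self.transitions:
            entry: dict = {"name": t.name}
            if isinstance(t.rate_law, MassAction):
                entry.update(law="mass_action", k=t.rate_law.k)
            else:
                entry.update(law="michaelis_menten", vmax=t.rate_law.vmax, km=t.rate_law.km)
            if t.source:
                entry["source"] = True
            trans.append(entry)
        return {
            "places": [{"name": p.name, "initial": p.initial_marking} for p in self.places],
            "transitions": trans,
            "arcs": [[a.place, a.transition, a.direction, a.weight] for a in self.arcs],
            "inhibitory_arcs": [
                [a.place, a.transition, a.threshold] for a in self.inhibitory_arcs
            ],
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_net(net: HybridPetriNet) -> list:
    """Structural violations; empty list iff the net is well formed."""
    violations = []
    seen: set = set()
    for p in net.places:
        if p.name in seen:
            violations.append(f"duplicate place name {p.name!r}")
        seen.add(p.name)
        if p.initial_marking < 0:
            violations.append(f"place {p.name!r}: negative initial marking")
    place_names = {p.name for p in net.places}

    tseen: set = set()
    for t in net.transitions:
        if t.name in tseen:
            violations.append(f"duplicate transition name {t.name!r}")
        tseen.add(t.name)
        if isinstance(t.rate_law, MassAction):
            if t.rate_law.k < 0:
                violations.append(f"transition {t.name!r}: mass-action k < 0")
        elif isinstance(t.rate_law, MichaelisMenten):
            if t.rate_law.vmax < 0:
                violations.append(f"transition {t.name!r}: Vmax < 0")
            if not t.rate_law.km > 0:
                violations.append(f"transition {t.name!r}: Km must be > 0")
        else:
            violations.append(f"transition {t.name!r}: unknown rate law")
    transition_names = {t.name for t in net.transitions}

    for a in net.arcs:
        if a.place not in place_names:
            violations.append(f"arc references unknown place {a.place!r}")
        if a.transition not in transition_names:
            violations.append(f"arc references unknown transition {a.transition!r}")
        if a.direction not in ("pre", "post"):
            violations.append(f"arc {a.place!r}->{a.transition!r}: bad direction {a.direction!r}")
        if not a.weight > 0:
            violations.append(f"arc {a.place!r}->{a.transition!r}: weight must be > 0")
    for a in net.inhibitory_arcs:
        if a.place not in place_names:
            violations.append(f"inhibitory arc references unknown place {a.place!r}")
        if a.transition not in transition_names:
            violations.append(f"inhibitory arc references unknown transition {a.transition!r}")
        if not a.threshold > 0:
            violations.append(
                f"inhibitory arc {a.place!r}-|{a.transition!r}: threshold must be > 0"
            )

    for t in net.transitions:
        pres = net.pre_arcs(t.name)
        if not pres and not t.source:
            violations.append(f"transition {t.name!r} has no pre-places and is not a source")
        if isinstance(t.rate_law, MichaelisMenten) and len(pres) != 1:
            violations.append(
                f"transition {t.name!r}: Michaelis-Menten needs exactly 1 pre-place, "
                f"has {len(pres)}"
            )
    return violations


# ---------------------------------------------------------------------------
# rate evaluation
# ---------------------------------------------------------------------------

def _inhibition_factor(
    marking: Sequence[float],
    inhibitors: Sequence,  # of (place_index, threshold)
    mode: str,
    hill: float,
) -> float:
    if not inhibitors:
        return 1.0
    if mode == "hard":
        for idx, th in inhibitors:
            if marking[idx] >= th:
                return 0.0
        return 1.0
    if mode == "smooth":
        factor = 1.0
        for idx, th in inhibitors:
            m = max(marking[idx], 0.0)
            factor *= th ** hill / (th ** hill + m ** hill)
        return factor
    raise DomainError(f"unknown inhibition mode {mode!r}")


class _CompiledNet:
    """Index-based view of a net for fast repeated rate evaluation."""

    def __init__(self, net: HybridPetriNet, mode: str = "hard", hill: float = 1.0):
        self.net = net
        self.mode = mode
        self.hill = hill
        self.place_index = {p.name: i for i, p in enumerate(net.places)}
        self.n = len(net.places)
        self.transitions = list(net.transitions)
        self.pre: list = []
        self.inhib: list = []
        self.stoich = np.zeros((self.n, len(self.transitions)))
        for j, t in enumerate(self.transitions):
            pre = [(self.place_index[a.place], a.weight) for a in net.pre_arcs(t.name)]
            if isinstance(t.rate_law, MichaelisMenten) and len(pre) != 1:
                raise StructuralError(
                    f"transition {t.name!r}: Michaelis-Menten needs exactly 1 pre-place"
                )
            self.pre.append(pre)
            self.inhib.append(
                [(self.place_index[a.place], a.threshold) for a in net.inhibitors(t.name)]
            )
            for idx, w in pre:
                self.stoich[idx, j] -= w
            for a in net.post_arcs(t.name):
                self.stoich[self.place_index[a.place], j] += a.weight

    def flux(self, j: int, m: np.ndarray) -> float:
        t = self.transitions[j]
        law = t.rate_law
        if isinstance(law, MassAction):
            rate = law.k
            for idx, w in self.pre[j]:
                s = max(m[idx], 0.0)
                rate *= s if w == 1.0 else s ** w
        else:
            idx, _w = self.pre[j][0]
            s = max(m[idx], 0.0)
            rate = law.vmax * s / (law.km + s)
        return rate * _inhibition_factor(m, self.inhib[j], self.mode, self.hill)

    def fluxes(self, m: np.ndarray) -> np.ndarray:
        return np.array([self.flux(j, m) for j in range(len(self.transitions))])

    def rhs(self, t, m):
        with np.errstate(over="ignore", invalid="ignore"):
            dm = self.stoich @ self.fluxes(m)
        if not np.all(np.isfinite(dm)):
            raise SimulationError(
                f"vector field diverged (non-finite flux) at t={t:g}; "
                "the net has unbounded dynamics"
            )
        return dm


def transition_rate(
    net: HybridPetriNet,
    marking: Mapping[str, float],
    transition: str,
    inhibition_mode: str = "hard",
    hill: float = 1.0,
) -> float:
    """Instantaneous flux (tokens per time unit) of one transition."""
    compiled = _CompiledNet(net, inhibition_mode, hill)
    names = net.place_names()
    missing = [n for n in names if n not in marking]
    if missing:
        raise DomainError(f"marking undefined for place(s) {missing}")
    m = np.array([marking[n] for n in names], dtype=float)
    for j, t in enumerate(compiled.transitions):
        if t.name == transition:
            return float(compiled.flux(j, m))
    raise DomainError(f"unknown transition {transition!r}")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time grid plus per-place marking series from one deterministic run."""

    times: np.ndarray
    markings: np.ndarray  # shape (n_places, n_times)
    place_names: list
    metadata: dict = field(default_factory=dict)

    def marking(self, place: str) -> np.ndarray:
        try:
            return self.markings[self.place_names.index(place)]
        except ValueError:
            raise DomainError(f"unknown place {place!r}") from None

    def initial(self, place: str) -> float:
        return float(self.marking(place)[0])

    def final(self, place: str) -> float:
        return float(self.marking(place)[-1])

    def to_dataframe(self):
        """Tidy (time, place, marking) frame."""
        import pandas as pd

        frames = []
        for i, name in enumerate(self.place_names):
            frames.append(
                pd.DataFrame(
                    {"time": self.times, "place": name, "marking": self.markings[i]}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, path=None, places: Iterable[str] | None = None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for name in places or self.place_names:
            ax.plot(self.times, self.marking(name), label=name)
        ax.set_xlabel("time (arbitrary units)")
        ax.set_ylabel("marking (tokens)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def simulate(
    net: HybridPetriNet,
    horizon: float,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_step: float = np.inf,
    inhibition_mode: str = "hard",
    hill: float = 1.0,
    grid_points: int = GRID_POINTS,
) -> Trajectory:
    """Integrate the net over ``[0, horizon]`` on a fixed output grid.

    Deterministic: identical inputs produce identical trajectories.  Raises
    :class:`NetValidationError` on structural violations and
    :class:`SimulationError` when the solver does not converge (a partial
    trajectory is never returned).
    """
    violations = validate_net(net)
    if violations:
        raise NetValidationError(violations)
    if not horizon > 0:
        raise DomainError(f"horizon must be > 0, got {horizon}")

    compiled = _CompiledNet(net, inhibition_mode, hill)
    m0 = np.array([p.initial_marking for p in net.places], dtype=float)
    t_eval = np.linspace(0.0, float(horizon), grid_points + 1)
    sol = solve_ivp(
        compiled.rhs,
        (0.0, float(horizon)),
        m0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        max_step=max_step,
    )
    if not sol.success:
        raise SimulationError(f"solver failed: {sol.message}")
    markings = np.clip(sol.y, 0.0, None)
    return Trajectory(
        times=sol.t,
        markings=markings,
        place_names=net.place_names(),
        metadata={
            "rtol": rtol,
            "atol": atol,
            "max_step": max_step,
            "inhibition_mode": inhibition_mode,
            "hill": hill,
            "n_rhs_evaluations": int(sol.nfev),
        },
    )


def fold_change(traj: Trajectory, place: str, mode: str = "final_over_initial"):
    """Marking ratio relative to the initial level.

    ``final_over_initial`` uses the last grid point, ``peak_over_initial``
    the maximum over the grid.  Returns ``None`` (undefined, not infinity)
    when the initial marking is zero.
    """
    series = traj.marking(place)
    initial = series[0]
    if initial <= 0.0:
        return None
    if mode == "final_over_initial":
        return float(series[-1] / initial)
    if mode == "peak_over_initial":
        return float(series.max() / initial)
    raise DomainError(f"unknown fold-change mode {mode!r}")
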