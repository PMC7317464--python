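"""Temperature-ramp bleaching simulation and the resistance metric.

Every link gets an absolute temperature threshold

    W = T_MMM(host subregion) + T_delta * (tau_symbiont + tau_host) / 2

where T_delta (default 3.0 degC) is the upper thermal limit of the
coral-symbiont association above the local bleaching baseline. The
simulation ramps temperature upward; a link breaks once T >= W (ties break
together), and a host is bleached when it has lost all of its links. The
sweep is event-driven: only the distinct link thresholds matter, so the
response curve is an exact step function.

Resistance R = (temperature at 90% of hosts bleached - temperature at 10%)
normalized by T_delta; crossings use the step function's first-passage
convention, no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import host_nodes
from .tolerance import ToleranceTables, Taxonomy, assign_tolerances

__all__ = [
    "BleachingConfig",
    "BleachingCurve",
    "ResistanceResult",
    "link_weight",
    "assign_link_weights",
    "simulate_bleaching",
    "resistance_from_curve",
    "resistance_ensemble",
    "ensemble_curve",
]

DEFAULT_T_DELTA = 3.0


class MetricUndefinedError(ValueError):
    """The response curve never reaches the level the metric needs."""


@dataclass(frozen=True)
class BleachingConfig:
    t_delta: float = DEFAULT_T_DELTA
    temperature_step: float = 0.01  # reporting grid only; the core is event-driven
    replicates: int = 100
    host_impute_once: bool = False

    def __post_init__(self):
        if self.t_delta <= 0:
            raise ValueError("t_delta must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def link_weight(t_mmm: float, tau_host: float, tau_symbiont: float,
                t_delta: float = DEFAULT_T_DELTA) -> float:
    """Absolute temperature threshold (degC) of one host-symbiont link."""
    for name, tau in (("tau_host", tau_host), ("tau_symbiont", tau_symbiont)):
        if not (0.0 <= tau <= 1.0):
            raise ValueError(f"{name}={tau} outside [0, 1]")
    return t_mmm + t_delta * (tau_symbiont + tau_host) / 2.0


def assign_link_weights(net: nx.Graph, t_delta: float = DEFAULT_T_DELTA) -> None:
    """Set the ``W`` edge attribute from node tolerances and host T_MMM."""
    for u, v, d in net.edges(data=True):
        h, s = (u, v) if net.nodes[u]["kind"] == "host" else (v, u)
        d["W"] = link_weight(
            net.nodes[h]["t_mmm"],
            net.nodes[h]["tolerance"],
            net.nodes[s]["tolerance"],
            t_delta,
        )


@dataclass
class BleachingCurve:
    """Step function: fraction of hosts bleached, right-continuous in T.

    ``temps[i]`` is the i-th event temperature and ``fracs[i]`` the bleached
    fraction for temps[i] <= T < temps[i+1]; below temps[0] the fraction is
    the initial one (normally 0).
    """

    temps: np.ndarray
    fracs: np.ndarray
    n_hosts: int
    initial_fraction: float = 0.0
    first_bleached: list = field(default_factory=list, repr=False)

    @property
    def empty(self) -> bool:
        return self.n_hosts == 0

    def fraction_at(self, t: float) -> float:
        if self.empty or len(self.temps) == 0 or t < self.temps[0]:
            return self.initial_fraction
        i = int(np.searchsorted(self.temps, t, side="right")) - 1
        return float(self.fracs[i])

    def first_crossing(self, level: float) -> float:
        """Smallest event temperature with bleached fraction >= level."""
        if self.initial_fraction >= level:
            return float("-inf")
        idx = np.nonzero(self.fracs >= level)[0]
        if len(idx) == 0:
            raise MetricUndefinedError(f"curve never reaches fraction {level}")
        return float(self.temps[idx[0]])


def simulate_bleaching(net: nx.Graph, t_delta: float = DEFAULT_T_DELTA,
                       rng: np.random.Generator | None = None) -> BleachingCurve:
    """Event-driven upward temperature sweep.

    Requires tolerances on all nodes; link thresholds are (re)computed here.
    All links sharing one threshold break in a single event. Also records
    the host isolation order for susceptibility summaries; hosts isolated in
    the same event are ordered by a uniform shuffle when ``rng`` is given,
    by sorted node id otherwise.
    """
    hosts = host_nodes(net)
    if not hosts:
        return BleachingCurve(np.array([]), np.array([]), 0)
    assign_link_weights(net, t_delta)
    degree = {h: net.degree(h) for h in hosts}
    n_bleached0 = sum(1 for h in hosts if degree[h] == 0)

    events: dict[float, list[str]] = {}
    for u, v, d in net.edges(data=True):
        h = u if net.nodes[u]["kind"] == "host" else v
        events.setdefault(d["W"], []).append(h)

    temps, fracs, order = [], [], []
    n_hosts = len(hosts)
    bleached = n_bleached0
    for w in sorted(events):
        newly = []
        for h in events[w]:
            degree[h] -= 1
            if degree[h] == 0:
                newly.append(h)
        bleached += len(newly)
        newly = sorted(newly)
        if rng is not None:
            rng.shuffle(newly)
        order.extend(newly)
        temps.append(w)
        fracs.append(bleached / n_hosts)
    return BleachingCurve(
        np.array(temps),
        np.array(fracs),
        n_hosts,
        initial_fraction=n_bleached0 / n_hosts,
        first_bleached=order,
    )


def resistance_from_curve(curve: BleachingCurve, t_delta: float = DEFAULT_T_DELTA) -> float:
    """R = [T(90% bleached) - T(10% bleached)] / T_delta, dimensionless."""
    if curve.empty:
        raise MetricUndefinedError("no hosts in network")
    t10 = curve.first_crossing(0.1)
    t90 = curve.first_crossing(0.9)
    if not np.isfinite(t10):
        t10 = float(curve.temps[0]) if len(curve.temps) else 0.0
    return (t90 - t10) / t_delta


@dataclass
class ResistanceResult:
    values: np.ndarray
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n": int(len(self.values)),
            "n_failed": self.n_failed,
            "values": [float(v) for v in self.values],
        }


def _replicate_rngs(seed, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _apply_null(net: nx.Graph, null, rng: np.random.Generator) -> nx.Graph:
    """Apply a per-replicate null transform (kind label or callable)."""
    if null is None:
        return net
    if callable(null):
        return null(net, rng)
    from .nulls import make_null

    return make_null(net, null, rng)


def resistance_ensemble(
    net: nx.Graph,
    tables: ToleranceTables,
    cfg: BleachingConfig = BleachingConfig(),
    seed: int = 0,
    taxonomy: Taxonomy | None = None,
    null: str | None = None,
    return_curves: bool = False,
):
    """Run ``cfg.replicates`` bleaching simulations with fresh imputed draws.

    Each replicate redraws imputed tolerances from its own substream of the
    master seed, so adding replicates never perturbs earlier ones and two
    runs with one master seed are identical. When ``null`` is given
    (shuffled_tolerance | random_tolerance | rbdc | rbndc, or a callable),
    the null construction is re-applied fresh in every replicate after the
    natural tolerances are assigned.
    """
    rngs = _replicate_rngs(seed, cfg.replicates + 1)
    frozen = None
    if cfg.host_impute_once:
        frozen = assign_tolerances(net, tables, taxonomy, rngs[-1])
    values, curves, n_failed = [], [], 0
    for rng in rngs[: cfg.replicates]:
        assign_tolerances(net, tables, taxonomy, rng, frozen_host_imputes=frozen)
        sim_net = _apply_null(net, null, rng)
        curve = simulate_bleaching(sim_net, cfg.t_delta)
        try:
            values.append(resistance_from_curve(curve, cfg.t_delta))
            if return_curves:
                curves.append(curve)
        except MetricUndefinedError:
            n_failed += 1
    result = ResistanceResult(np.asarray(values), n_failed=n_failed)
    return (result, curves) if return_curves else result


def ensemble_curve(curves: list[BleachingCurve], step: float = 0.01,
                   band: tuple[float, float] = (1.5, 98.5)):
    """Average replicate curves on a common temperature grid with bands.

    Returns (grid, mean fraction, lower band, upper band); the default band
    is the central 97% of replicates.
    """
    lo = min(float(c.temps[0]) for c in curves if len(c.temps))
    hi = max(float(c.temps[-1]) for c in curves if len(c.temps))
    grid = np.arange(lo - step, hi + step, step)
    mat = np.array([[c.fraction_at(t) for t in grid] for c in curves])
    return grid, mat.mean(axis=0), np.percentile(mat, band[0], axis=0), np.percentile(mat, band[1], axis=0)
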