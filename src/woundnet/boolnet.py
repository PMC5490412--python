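"""Signed pathway parsing, Boolean networks, and continuous treatment simulation.

A KGML pathway document is reduced to signed regulations (activation /
expression -> +1, inhibition / repression -> -1). Each target gene's update
rule follows the inhibitor-dominant convention

    x_t' = OR(activators of t) AND NOT OR(inhibitors of t)

(nodes with only inhibitors use NOT OR(inhibitors); unregulated nodes are
inputs, constant under synchronous update). The Boolean network is made
continuous by multilinear (BooleCube) interpolation of each rule over the
unit hypercube, optionally composing each input with a Hill function
h(x) = x^n / (x^n + k^n) or its normalized variant h(x)/h(1), giving the ODE

    dx_t/dt = (B~_t(x) - x_t) / tau_t .

A treatment is simulated by fixing the initial (optionally clamped) state of
its target genes, drawing all other genes independently Bernoulli(0.5),
integrating, and counting per gene how often the final state ends on the
opposite side of 0.5 from the initial one across Monte-Carlo repetitions.
Genes are ranked by this switch frequency.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from scipy.integrate import solve_ivp

from .errors import FormatError, UsageError

__all__ = [
    "SignedRegulation",
    "BooleanNetwork",
    "ContinuousModel",
    "SwitchRanking",
    "parse_kgml",
    "assemble",
    "boolean_step",
    "continuous_rate",
    "integrate",
    "simulate_treatment",
    "write_switch_ranking",
]

logger = logging.getLogger(__name__)

ACTIVATING_SUBTYPES = frozenset({"activation", "expression"})
INHIBITING_SUBTYPES = frozenset({"inhibition", "repression"})

METHODS = ("boolecube", "hillcube", "normalized_hillcube")


@dataclass(frozen=True)
class SignedRegulation:
    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class BooleanNetwork:
    """Synchronous Boolean network defined by per-node regulator sets."""

    nodes: tuple[str, ...]
    activators: Mapping[str, frozenset[str]]
    inhibitors: Mapping[str, frozenset[str]]

    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def is_input(self, node: str) -> bool:
        return not self.activators[node] and not self.inhibitors[node]


def _entry_name(entry: etree._Element) -> str:
    """Display name of a KGML entry: the graphics label if present (first
    comma-separated token), else the first whitespace token of the ``name``
    attribute with any "org:" prefix stripped."""
    graphics = entry.find("graphics")
    if graphics is not None and graphics.get("name"):
        return graphics.get("name").split(",")[0].strip()
    name = (entry.get("name") or "").split()[0] if entry.get("name") else ""
    if ":" in name:
        name = name.split(":", 1)[1]
    return name.strip()


def parse_kgml(document: str | bytes | os.PathLike[str]) -> list[SignedRegulation]:
    """Extract signed regulations from a KGML pathway document.

    ``document`` may be XML text/bytes or a path. Relations whose subtype is
    neither activating nor inhibiting are skipped with a logged warning;
    entries of type "group" are expanded to one regulation per component
    (on either side of the relation).
    """
    if isinstance(document, (str, os.PathLike)) and os.path.exists(str(document)):
        with open(document, "rb") as handle:
            data = handle.read()
    else:
        data = document.encode() if isinstance(document, str) else document
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed KGML document: {exc}") from exc

    entries: dict[str, etree._Element] = {}
    for entry in root.findall("entry"):
        entries[entry.get("id")] = entry

    def expand(entry_id: str) -> list[str]:
        if entry_id not in entries:
            raise FormatError(f"relation references unknown entry id {entry_id!r}")
        entry = entries[entry_id]
        if entry.get("type") == "group":
            names = []
            for comp in entry.findall("component"):
                names.extend(expand(comp.get("id")))
            return names
        return [_entry_name(entry)]

    regulations: list[SignedRegulation] = []
    for relation in root.findall("relation"):
        subtypes = {s.get("name") for s in relation.findall("subtype")}
        signs = []
        if subtypes & ACTIVATING_SUBTYPES:
            signs.append(+1)
        if subtypes & INHIBITING_SUBTYPES:
            signs.append(-1)
        if not signs:
            logger.warning(
                "skipping relation %s -> %s with subtypes %s (no signed subtype)",
                relation.get("entry1"), relation.get("entry2"), sorted(filter(None, subtypes)),
            )
            continue
        sources = expand(relation.get("entry1"))
        targets = expand(relation.get("entry2"))
        for sign in signs:
            for src in sources:
                for tgt in targets:
                    if src and tgt:
                        regulations.append(SignedRegulation(src, tgt, sign))
    return regulations


def assemble(regulations: Iterable[SignedRegulation]) -> BooleanNetwork:
    """Build the Boolean network from signed regulations.

    Contradictory pairs (same source and target with both signs) are kept on
    both sides; the AND NOT structure makes the inhibition dominate, which is
    logged. Node order is lexicographic.
    """
    activators: dict[str, set[str]] = {}
    inhibitors: dict[str, set[str]] = {}
    names: set[str] = set()
    for reg in regulations:
        names.add(reg.source)
        names.add(reg.target)
        bucket = activators if reg.sign > 0 else inhibitors
        bucket.setdefault(reg.target, set()).add(reg.source)
    for target in set(activators) & set(inhibitors):
        both = activators[target] & inhibitors[target]
        for src in sorted(both):
            logger.warning(
                "contradictory regulation %s -> %s kept as both; inhibition dominates",
                src, target,
            )
    nodes = tuple(sorted(names))
    return BooleanNetwork(
        nodes=nodes,
        activators={n: frozenset(activators.get(n, ())) for n in nodes},
        inhibitors={n: frozenset(inhibitors.get(n, ())) for n in nodes},
    )


def boolean_step(network: BooleanNetwork, state: Sequence[int]) -> np.ndarray:
    """One synchronous update of every node's rule."""
    state = np.asarray(state)
    if state.shape != (len(network.nodes),):
        raise ValueError(
            f"state length {state.shape} does not match {len(network.nodes)} nodes"
        )
    idx = network.index()
    new = np.empty_like(state)
    for i, node in enumerate(network.nodes):
        acts = network.activators[node]
        inhs = network.inhibitors[node]
        if not acts and not inhs:
            new[i] = state[i]
            continue
        inhibited = any(state[idx[u]] for u in inhs)
        if acts:
            new[i] = int(any(state[idx[u]] for u in acts) and not inhibited)
        else:
            new[i] = int(not inhibited)
    return new


@dataclass(frozen=True)
class ContinuousModel:
    """BooleCube / HillCube continuous relaxation of a Boolean network.

    ``hill_exponent`` (n) sets the steepness and ``hill_threshold`` (k) the
    half-activation point of the Hill response; ``timescale`` (tau) is the
    per-node relaxation time (scalar or one value per node). Defaults follow
    common practice for qualitative pathway simulation: normalized HillCube
    with n = 3, k = 0.5, tau = 1.
    """

    network: BooleanNetwork
    method: str = "normalized_hillcube"
    hill_exponent: float = 3.0
    hill_threshold: float = 0.5
    timescale: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.hill_exponent <= 0 or not 0 < self.hill_threshold < 1:
            raise ValueError("require hill_exponent > 0 and hill_threshold in (0, 1)")
        tau = np.atleast_1d(np.asarray(self.timescale, dtype=float))
        if (tau <= 0).any():
            raise ValueError("timescales must be positive")

    def tau_vector(self) -> np.ndarray:
        tau = np.atleast_1d(np.asarray(self.timescale, dtype=float))
        if tau.size == 1:
            return np.full(len(self.network.nodes), float(tau[0]))
        if tau.size != len(self.network.nodes):
            raise ValueError("timescale must be scalar or one value per node")
        return tau.astype(float)


def _hill(x: np.ndarray, n: float, k: float) -> np.ndarray:
    xn = np.power(np.clip(x, 0.0, 1.0), n)
    return xn / (xn + k**n)


def _transform_inputs(model: ContinuousModel, x: np.ndarray) -> np.ndarray:
    if model.method == "boolecube":
        return x
    h = _hill(x, model.hill_exponent, model.hill_threshold)
    if model.method == "normalized_hillcube":
        h = h / _hill(np.asarray(1.0), model.hill_exponent, model.hill_threshold)
    return h


def _rule_values(model: ContinuousModel, x: np.ndarray) -> np.ndarray:
    """Interpolated rule value B~_t for every node; ``x`` has shape (..., n).

    The OR-of-activators AND-NOT-OR-of-inhibitors rule factorizes over its
    (disjoint) inputs, so its multilinear interpolation is

        (1 - prod_a (1 - h(x_a))) * prod_i (1 - h(x_i)).

    Unregulated nodes interpolate the identity, giving zero net rate.
    """
    network = model.network
    idx = network.index()
    h = _transform_inputs(model, x)
    out = np.empty_like(x)
    for i, node in enumerate(network.nodes):
        acts = [idx[u] for u in sorted(network.activators[node])]
        inhs = [idx[u] for u in sorted(network.inhibitors[node])]
        if not acts and not inhs:
            out[..., i] = x[..., i]
            continue
        value = np.ones(x.shape[:-1])
        if acts:
            value = 1.0 - np.prod(1.0 - h[..., acts], axis=-1)
        if inhs:
            value = value * np.prod(1.0 - h[..., inhs], axis=-1)
        out[..., i] = value
    return out


def continuous_rate(
    model: ContinuousModel, x: np.ndarray, clamp_index: Sequence[int] = ()
) -> np.ndarray:
    """Right-hand side (B~(x) - x) / tau; clamped node rates are zeroed.

    ``x`` may be a single state vector or a batch with shape (..., n); values
    must lie in [0, 1] (a small tolerance absorbs solver overshoot).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(model.network.nodes):
        raise ValueError("state dimension does not match the network")
    if (x < -1e-9).any() or (x > 1 + 1e-9).any():
        raise ValueError("state outside the unit hypercube")
    return _rate_unchecked(model, x, clamp_index)


def _rate_unchecked(
    model: ContinuousModel, x: np.ndarray, clamp_index: Sequence[int] = ()
) -> np.ndarray:
    """Rate on the clipped state; used by the integrator, whose trial steps
    may momentarily leave [0, 1] before being rejected by error control."""
    rate = (_rule_values(model, np.clip(x, 0.0, 1.0)) - x) / model.tau_vector()
    if len(clamp_index):
        rate[..., list(clamp_index)] = 0.0
    return rate


def integrate(
    model: ContinuousModel,
    x0: Sequence[float],
    horizon: float = 10.0,
    clamp: Iterable[str] = (),
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the model on [0, horizon] from ``x0``.

    ``clamp`` names nodes held at their initial value throughout (a sustained
    stimulus). Returns (times, states) with states of shape (n_times, n_nodes).
    """
    x0 = np.asarray(x0, dtype=float)
    idx = model.network.index()
    unknown = [n for n in clamp if n not in idx]
    if unknown:
        raise UsageError(f"clamp names unknown nodes: {unknown}")
    clamp_index = [idx[n] for n in clamp]
    if (x0 < 0).any() or (x0 > 1).any():
        raise ValueError("initial state outside the unit hypercube")

    batch = x0.ndim == 2
    shape = x0.shape

    def rhs(_t: float, flat: np.ndarray) -> np.ndarray:
        return _rate_unchecked(model, flat.reshape(shape), clamp_index).ravel()

    solution = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        x0.ravel(),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not solution.success:
        raise RuntimeError(f"ODE integration failed: {solution.message}")
    states = solution.y.T.reshape((len(solution.t),) + shape)
    if not batch:
        states = states.reshape(len(solution.t), -1)
    return solution.t, states


@dataclass(frozen=True)
class SwitchRanking:
    """Per-gene switch counts over Monte-Carlo treatment simulations."""

    nodes: tuple[str, ...]  # ranked order (treatment targets excluded)
    switch_counts: Mapping[str, int]
    n_simulations: int
    treatment: Mapping[str, int]

    def frequency(self, node: str) -> float:
        return self.switch_counts[node] / self.n_simulations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "switch_count": [self.switch_counts[n] for n in self.nodes],
                "n_sims": self.n_simulations,
                "frequency": [self.frequency(n) for n in self.nodes],
                "rank": np.arange(1, len(self.nodes) + 1),
            }
        )


def simulate_treatment(
    network: BooleanNetwork,
    treatment: Mapping[str, int],
    n_sims: int = 1000,
    seed: int | None = None,
    method: str = "normalized_hillcube",
    horizon: float = 10.0,
    switch_threshold: float = 0.5,
    clamp: bool = False,
    hill_exponent: float = 3.0,
    hill_threshold: float = 0.5,
    timescale: float | Sequence[float] = 1.0,
) -> SwitchRanking:
    """Monte-Carlo treatment simulation with switch-frequency ranking.

    Treatment nodes start at their stated 0/1 value (held fixed throughout if
    ``clamp``); every other node is initialized independently Bernoulli(0.5).
    After integrating to ``horizon``, a gene counts as switched when its
    final value lies strictly on the opposite side of ``switch_threshold``
    from its initial value. Treatment targets are excluded from the ranking,
    which sorts by descending frequency with lexicographic tie-break.
    """
    idx = {n: i for i, n in enumerate(network.nodes)}
    unknown = [n for n in treatment if n not in idx]
    if unknown:
        raise UsageError(f"treatment names unknown nodes: {unknown}")
    if n_sims < 1:
        raise UsageError("n_sims must be >= 1")
    model = ContinuousModel(
        network=network,
        method=method,
        hill_exponent=hill_exponent,
        hill_threshold=hill_threshold,
        timescale=timescale,
    )
    rng = np.random.default_rng(seed)
    n = len(network.nodes)
    x0 = rng.integers(0, 2, size=(n_sims, n)).astype(float)
    for node, value in treatment.items():
        if value not in (0, 1):
            raise UsageError(f"treatment value for {node!r} must be 0 or 1")
        x0[:, idx[node]] = float(value)
    clamp_nodes = tuple(sorted(treatment)) if clamp else ()
    _, states = integrate(
        model, x0, horizon=horizon, clamp=clamp_nodes, t_eval=(0.0, float(horizon))
    )
    final = states[-1]
    before = np.sign(x0 - switch_threshold)
    after = np.sign(final - switch_threshold)
    switched = (before != after) & (before != 0) & (after != 0)
    counts = switched.sum(axis=0)
    ranked = sorted(
        (node for node in network.nodes if node not in treatment),
        key=lambda node: (-counts[idx[node]], node),
    )
    return SwitchRanking(
        nodes=tuple(ranked),
        switch_counts={node: int(counts[idx[node]]) for node in ranked},
        n_simulations=n_sims,
        treatment=dict(treatment),
    )


def write_switch_ranking(ranking: SwitchRanking, path: str | os.PathLike[str]) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)
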