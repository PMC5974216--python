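"""Multi-population network specification and seeded instantiation.

A :class:`NetworkSpec` lists populations (size, neuron parameters,
external drive) and projections (connectivity, weight and delay
distributions). :func:`instantiate` draws a concrete
:class:`NetworkInstance` reproducibly from ``(spec, master_seed)``:
connections are drawn with replacement (multapses allowed), weights and
delays from normal distributions, delays rounded to the grid and clipped
below at the time step.

Random substreams are derived from the master seed by name (projection
label, population initial conditions, drive), so partial
re-instantiation is reproducible and other-language ports can match the
derivation: each substream seeds ``numpy.random.default_rng`` with
``[master_seed, crc32(kind), crc32(name)]``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from spikebench.errors import ConfigurationError, InvalidParameterError
from spikebench.lif_core import NeuronParameters

__all__ = [
    "PopulationSpec",
    "ProjectionSpec",
    "SynapseEntry",
    "NetworkSpec",
    "NetworkInstance",
    "derive_rng",
    "total_synapse_count",
    "instantiate_connections",
    "dc_equivalent",
    "scale_network",
    "instantiate",
]


def derive_rng(master_seed: int, kind: str, name: str) -> np.random.Generator:
    """Named, reproducible random substream for ``(kind, name)``."""
    return np.random.default_rng(
        [int(master_seed), zlib.crc32(kind.encode()), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class PopulationSpec:
    """One neuron population with its external drive.

    Exactly one drive mode is active: Poisson (``nu_ext`` spikes/s with
    per-spike weight ``J_ext`` nA) or DC (``I_DC`` nA).
    """

    name: str
    N: int
    params: NeuronParameters = field(default_factory=NeuronParameters)
    nu_ext: float | None = None
    J_ext: float | None = None
    I_DC: float | None = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise InvalidParameterError(f"population {self.name}: N must be > 0")
        poisson = self.nu_ext is not None
        if poisson and (self.J_ext is None):
            raise ConfigurationError(
                f"population {self.name}: Poisson drive needs both nu_ext and J_ext")
        if poisson == (self.I_DC is not None):
            raise ConfigurationError(
                f"population {self.name}: exactly one drive mode (Poisson or DC) "
                "must be active")

    @property
    def drive_mode(self) -> str:
        return "poisson" if self.nu_ext is not None else "dc"


@dataclass(frozen=True)
class ProjectionSpec:
    """A projection between two populations.

    Connectivity is given either as a pair-connection probability ``p``
    or as an explicit synapse count ``K``. ``weight_mean`` is entered as
    a magnitude (nA); ``inhibitory=True`` flips the sign of every drawn
    weight.
    """

    pre: str
    post: str
    p: float | None = None
    K: int | None = None
    weight_mean: float = 0.0878
    weight_sd: float = 0.0
    inhibitory: bool = False
    delay_mean: float = 1.5
    delay_sd: float = 0.0

    def __post_init__(self) -> None:
        if (self.p is None) == (self.K is None):
            raise ConfigurationError(
                f"projection {self.pre}->{self.post}: give exactly one of p or K")
        if self.p is not None and not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError("p must lie in [0, 1]")
        if self.weight_sd < 0 or self.delay_sd < 0:
            raise InvalidParameterError("weight_sd and delay_sd must be >= 0")
        if self.weight_mean < 0:
            raise InvalidParameterError(
                "weight_mean is a magnitude; use inhibitory=True for sign")


class SynapseEntry(NamedTuple):
    """One synapse: signed weight (nA) and grid-aligned delay (ms).

    Duplicate (source, target) pairs are legal (multapses)."""

    source: int
    target: int
    weight: float
    delay: float


def total_synapse_count(p: float, N_pre: int, N_post: int,
                        method: str = "with-replacement") -> int:
    """Number of synapses realizing pair-connection probability ``p``.

    The default inverts the with-replacement drawing process:
    ``K = round(ln(1-p) / ln(1 - 1/(N_pre*N_post)))`` so that
    ``1 - (1 - 1/(N_pre*N_post))**K = p`` up to rounding of ``K``.
    ``method='binomial'`` uses ``K = round(p * N_pre * N_post)``.
    """
    if not 0.0 <= p < 1.0:
        raise InvalidParameterError("need 0 <= p < 1 (p = 1 diverges)")
    if p == 0.0:
        return 0
    if method == "binomial":
        return int(round(p * N_pre * N_post))
    if method != "with-replacement":
        raise ConfigurationError(f"unknown K-from-p method {method!r}")
    return int(round(math.log1p(-p) / math.log1p(-1.0 / (N_pre * N_post))))


def instantiate_connections(proj: ProjectionSpec, N_pre: int, N_post: int,
                            rng: np.random.Generator, h: float = 0.1,
                            k_method: str = "with-replacement",
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw the synapses of one projection.

    Returns ``(sources, targets, weights, delays)`` arrays of equal
    length ``K``: source and target indices drawn uniformly with
    replacement, weights ~ Normal(mean, sd) with magnitudes clipped at
    zero and the projection sign applied, delays ~ Normal(mean, sd)
    rounded to the grid and clipped below at ``h``.
    """
    if proj.K is not None:
        K = proj.K
    else:
        K = total_synapse_count(proj.p, N_pre, N_post, method=k_method)
    sources = rng.integers(0, N_pre, size=K)
    targets = rng.integers(0, N_post, size=K)
    weights = rng.normal(proj.weight_mean, proj.weight_sd, size=K)
    np.clip(weights, 0.0, None, out=weights)  # sign-crossing draws clipped to 0
    if proj.inhibitory:
        weights = -weights
    delays = rng.normal(proj.delay_mean, proj.delay_sd, size=K)
    delays = np.round(delays / h) * h
    np.clip(delays, h, None, out=delays)  # truncated at the simulation step
    return sources, targets, weights, delays


def dc_equivalent(nu_ext: float, J_ext: float, tau_s: float) -> float:
    """Mean current (nA) of a Poisson drive: ``nu_ext * J_ext * tau_s``
    with ``nu_ext`` in spikes/s, ``J_ext`` in nA and ``tau_s`` in ms."""
    if nu_ext < 0:
        raise InvalidParameterError("nu_ext must be non-negative")
    return nu_ext * J_ext * (tau_s / 1000.0)


@dataclass(frozen=True)
class NetworkSpec:
    """Populations plus projections; the unit serialized to config JSON."""

    populations: tuple[PopulationSpec, ...]
    projections: tuple[ProjectionSpec, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("population names must be unique")
        for proj in self.projections:
            for end in (proj.pre, proj.post):
                if end not in names:
                    raise ConfigurationError(
                        f"projection references unknown population {end!r}")

    @property
    def total_neurons(self) -> int:
        return sum(p.N for p in self.populations)

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown population {name!r}")

    # --- JSON round trip ---------------------------------------------
    def to_dict(self) -> dict:
        pops = []
        for p in self.populations:
            d = {"name": p.name, "N": p.N,
                 "params": vars(p.params).copy()}
            if p.drive_mode == "poisson":
                d["drive"] = {"mode": "poisson", "nu_ext": p.nu_ext,
                              "J_ext": p.J_ext}
            else:
                d["drive"] = {"mode": "dc", "I_DC": p.I_DC}
            pops.append(d)
        projs = []
        for pr in self.projections:
            d = {"pre": pr.pre, "post": pr.post,
                 "weight": {"mean": pr.weight_mean, "sd": pr.weight_sd,
                            "inhibitory": pr.inhibitory},
                 "delay": {"mean": pr.delay_mean, "sd": pr.delay_sd}}
            if pr.p is not None:
                d["p"] = pr.p
            else:
                d["K"] = pr.K
            projs.append(d)
        return {"populations": pops, "projections": projs}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        pops = []
        for pd in d["populations"]:
            params = NeuronParameters(**pd.get("params", {}))
            drive = pd["drive"]
            if drive["mode"] == "poisson":
                pops.append(PopulationSpec(name=pd["name"], N=int(pd["N"]),
                                           params=params,
                                           nu_ext=float(drive["nu_ext"]),
                                           J_ext=float(drive["J_ext"])))
            elif drive["mode"] == "dc":
                pops.append(PopulationSpec(name=pd["name"], N=int(pd["N"]),
                                           params=params,
                                           I_DC=float(drive["I_DC"])))
            else:
                raise ConfigurationError(f"unknown drive mode {drive['mode']!r}")
        projs = []
        for jd in d["projections"]:
            projs.append(ProjectionSpec(
                pre=jd["pre"], post=jd["post"],
                p=jd.get("p"), K=jd.get("K"),
                weight_mean=float(jd["weight"]["mean"]),
                weight_sd=float(jd["weight"]["sd"]),
                inhibitory=bool(jd["weight"].get("inhibitory", False)),
                delay_mean=float(jd["delay"]["mean"]),
                delay_sd=float(jd["delay"]["sd"])))
        return cls(populations=tuple(pops), projections=tuple(projs))


def scale_network(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Scale population sizes by ``factor``, preserving connection
    probabilities and external drive.

    Note: network dynamics are *not* guaranteed invariant under scaling;
    the run manifest records the factor. Explicit synapse counts ``K``
    are scaled by ``factor**2`` to match the probability convention.
    """
    if not 0.0 < factor <= 1.0:
        raise InvalidParameterError("factor must lie in (0, 1]")
    if factor == 1.0:
        return spec
    pops = []
    for p in spec.populations:
        N = int(round(factor * p.N))
        if N == 0:
            raise InvalidParameterError(
                f"factor {factor} reduces population {p.name} to zero neurons")
        pops.append(replace(p, N=N))
    projs = []
    for pr in spec.projections:
        if pr.K is not None:
            projs.append(replace(pr, K=int(round(pr.K * factor ** 2))))
        else:
            projs.append(pr)
    return NetworkSpec(populations=tuple(pops), projections=tuple(projs))


@dataclass
class _ProjectionArrays:
    """Instantiated synapses of one projection, with global neuron ids."""

    spec: ProjectionSpec
    sources: np.ndarray   # global ids
    targets: np.ndarray   # global ids
    weights: np.ndarray   # signed, nA
    delays: np.ndarray    # ms, grid-aligned

    def __len__(self) -> int:
        return len(self.sources)


@dataclass
class NetworkInstance:
    """A concrete network drawn from ``(spec, master_seed)``.

    Neurons carry global ids; ``pop_offsets[name]`` gives the id of the
    first neuron of a population. ``V_init`` holds the per-neuron
    initial membrane potentials (uniform on ``[V_r, theta)``).
    """

    spec: NetworkSpec
    master_seed: int
    h: float
    pop_names: tuple[str, ...]
    pop_offsets: dict
    pop_sizes: dict
    projections: list
    V_init: np.ndarray

    @property
    def total_neurons(self) -> int:
        return int(sum(self.pop_sizes.values()))

    @property
    def total_synapses(self) -> int:
        return int(sum(len(p) for p in self.projections))

    def population_slice(self, name: str) -> slice:
        off = self.pop_offsets[name]
        return slice(off, off + self.pop_sizes[name])

    def iter_synapses(self) -> Iterator[SynapseEntry]:
        for proj in self.projections:
            for s, t, w, d in zip(proj.sources, proj.targets, proj.weights,
                                  proj.delays):
                yield SynapseEntry(int(s), int(t), float(w), float(d))


def instantiate(spec: NetworkSpec, master_seed: int, h: float = 0.1,
                k_method: str = "with-replacement") -> NetworkInstance:
    """Draw a :class:`NetworkInstance` bit-reproducibly from
    ``(spec, master_seed)``."""
    if h <= 0:
        raise InvalidParameterError("h must be positive")
    pop_names = tuple(p.name for p in spec.populations)
    pop_offsets, pop_sizes = {}, {}
    off = 0
    for p in spec.populations:
        pop_offsets[p.name] = off
        pop_sizes[p.name] = p.N
        off += p.N

    projections = []
    for idx, proj in enumerate(spec.projections):
        rng = derive_rng(master_seed, "projection", f"{idx}:{proj.pre}->{proj.post}")
        s, t, w, d = instantiate_connections(
            proj, pop_sizes[proj.pre], pop_sizes[proj.post], rng, h=h,
            k_method=k_method)
        projections.append(_ProjectionArrays(
            spec=proj,
            sources=s + pop_offsets[proj.pre],
            targets=t + pop_offsets[proj.post],
            weights=w, delays=d))

    V_init = np.empty(off)
    for p in spec.populations:
        rng = derive_rng(master_seed, "population-init", p.name)
        sl = slice(pop_offsets[p.name], pop_offsets[p.name] + p.N)
        V_init[sl] = rng.uniform(p.params.V_r, p.params.theta, size=p.N)

    return NetworkInstance(spec=spec, master_seed=master_seed, h=h,
                           pop_names=pop_names, pop_offsets=pop_offsets,
                           pop_sizes=pop_sizes, projections=projections,
                           V_init=V_init)
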