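"""Seeded synthetic inputs, the default 8-population network, and canned
test fixtures.

The default network is an in-house synthetic layered configuration: four
"layers", each with an excitatory and an inhibitory population, balanced
so that DC or Poisson drive produces asynchronous irregular activity at
moderate rates. It stands in for externally supplied full-scale
configurations (whose connectivity matrices are user-provided config,
not part of this package) in tests and desk-scale protocol runs.
"""

from __future__ import annotations

import numpy as np

from spikebench.errors import ConfigurationError, InvalidParameterError
from spikebench.lif_core import NeuronParameters
from spikebench.network_model import (NetworkSpec, PopulationSpec,
                                      ProjectionSpec, dc_equivalent,
                                      scale_network)

__all__ = ["generate_grid_poisson", "default_network_spec", "make_fixture"]


def generate_grid_poisson(rate: float, h: float, duration: float,
                          seed: int | None = None) -> np.ndarray:
    """Per-step Poisson spike counts for grid-constrained input.

    Counts are independent with mean ``rate * h`` (``rate`` in spikes/s,
    ``h`` and ``duration`` in ms); deterministic per seed.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be non-negative")
    if h <= 0 or duration < 0:
        raise InvalidParameterError("h must be positive, duration >= 0")
    n_steps = int(round(duration / h))
    rng = np.random.default_rng(seed)
    return rng.poisson(rate * h / 1000.0, size=n_steps)


#: Layer labels of the default synthetic network.
_LAYERS = ("2/3", "4", "5", "6")

# Per-population external Poisson rates (spikes/s); the DC variant uses
# the mean current of these drives.
_NU_EXT = {
    "2/3E": 10800.0, "2/3I": 10400.0,
    "4E": 11400.0, "4I": 10500.0,
    "5E": 11800.0, "5I": 10450.0,
    "6E": 11000.0, "6I": 10350.0,
}

_J_EXC = 0.0878   # nA, mean excitatory weight (10% relative sd)
_J_INH = 0.3512   # nA magnitude, mean inhibitory weight


def default_network_spec(drive: str = "dc",
                         n_per_population: int = 2500) -> NetworkSpec:
    """The synthetic 8-population layered network.

    ``drive`` selects independent Poisson inputs (``"poisson"``) or the
    DC current equal to their mean (``"dc"``). ``n_per_population`` sets
    the nominal size; use :func:`~spikebench.network_model.scale_network`
    for desk-scale runs.
    """
    if drive not in ("dc", "poisson"):
        raise ConfigurationError("drive must be 'dc' or 'poisson'")
    params = NeuronParameters()
    pops = []
    for layer in _LAYERS:
        for kind in ("E", "I"):
            name = f"{layer}{kind}"
            if drive == "poisson":
                pops.append(PopulationSpec(name=name, N=n_per_population,
                                           params=params,
                                           nu_ext=_NU_EXT[name],
                                           J_ext=_J_EXC))
            else:
                pops.append(PopulationSpec(
                    name=name, N=n_per_population, params=params,
                    I_DC=dc_equivalent(_NU_EXT[name], _J_EXC, params.tau_s)))
    projections = []
    # synthetic connectivity: stronger within a layer than across layers
    nominal = 2500  # probabilities are quoted at this population size
    for pre_layer in _LAYERS:
        for pre_kind in ("E", "I"):
            pre = f"{pre_layer}{pre_kind}"
            for post_layer in _LAYERS:
                for post_kind in ("E", "I"):
                    post = f"{post_layer}{post_kind}"
                    same = pre_layer == post_layer
                    if pre_kind == "E":
                        p = 0.024 if same else 0.012
                        w_mean, w_sd, inh = _J_EXC, 0.1 * _J_EXC, False
                        d_mean, d_sd = 1.5, 0.75
                    else:
                        p = 0.048 if same else 0.008
                        w_mean, w_sd, inh = _J_INH, 0.1 * _J_INH, True
                        d_mean, d_sd = 0.75, 0.375
                    p = p * nominal / n_per_population
                    if p <= 0:
                        continue
                    projections.append(ProjectionSpec(
                        pre=pre, post=post, p=min(p, 1.0),
                        weight_mean=w_mean, weight_sd=w_sd, inhibitory=inh,
                        delay_mean=d_mean, delay_sd=d_sd))
    return NetworkSpec(populations=tuple(pops), projections=tuple(projections))


def make_fixture(name: str, h: float = 0.1):
    """Deterministic canned configurations used across the test suite.

    ``single-spike-response``
        dict with neuron parameters, the per-step input counts carrying a
        single spike, and the input weight; used to compare the membrane
        excursion of the integration schemes and numeric formats.
    ``two-neuron-chain``
        a two-population network where a DC-driven neuron A drives
        neuron B through a single strong synapse with 0.5 ms delay.
    ``toy-8-pop``
        the default synthetic network at 10% scale (250 neurons per
        population), DC drive.
    """
    if name == "single-spike-response":
        n_steps = int(round(50.0 / h))
        counts = np.zeros(n_steps, dtype=np.int64)
        counts[0] = 1
        return {"params": NeuronParameters(), "input_counts": counts,
                "weight": _J_EXC, "h": h, "duration": n_steps * h}
    if name == "two-neuron-chain":
        params = NeuronParameters()
        pops = (
            PopulationSpec(name="A", N=1, params=params, I_DC=0.6),
            PopulationSpec(name="B", N=1, params=params, I_DC=0.0),
        )
        projs = (ProjectionSpec(pre="A", post="B", K=1, weight_mean=50.0,
                                weight_sd=0.0, delay_mean=0.5, delay_sd=0.0),)
        return NetworkSpec(populations=pops, projections=projs)
    if name == "toy-8-pop":
        return scale_network(default_network_spec(drive="dc"), 0.1)
    raise ConfigurationError(f"unknown fixture {name!r}")
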