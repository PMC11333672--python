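"""Construction of the 131-unit motor-loop network.

Layers, response columns and every connection group, with synapse counts
and healthy-condition weights taken from the parameter registry. Columnar
groups connect column i to column i only and are realised with a synapse
multiplicity of 4 (four parallel synapses per connected pair) so that the
audited counts equal the table values; diffuse groups are all-to-all
(striatal interneurons include autapses, 72 x 72 = 5184); the three
input projections use a fixed in-degree of 12 sampled without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    CONNECTION_TABLE,
    COLUMNAR_LAYERS,
    GroupSpec,
    LAYER_SIZES,
    N_COLUMNS,
    NeuronParams,
    BackgroundDrive,
    SOURCE_LAYERS,
)


@dataclass(frozen=True)
class LayerSpec:
    """One layer: global index range and column organisation."""

    name: str
    start: int
    size: int
    n_columns: int

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @property
    def column_size(self) -> int:
        return self.size // self.n_columns


def _layer_table() -> dict[str, LayerSpec]:
    layers: dict[str, LayerSpec] = {}
    start = 0
    for name, size in LAYER_SIZES.items():
        n_cols = N_COLUMNS if name in COLUMNAR_LAYERS else 1
        if size % n_cols:
            raise ValueError(f"layer {name}: size {size} not divisible by {n_cols}")
        layers[name] = LayerSpec(name, start, size, n_cols)
        start += size
    return layers


@dataclass
class ConnectionGroup:
    """A realised connection group: per-synapse endpoint and weight arrays.

    ``pre``/``post`` are global neuron indices of the distinct connected
    pairs; ``multiplicity`` parallel synapses sit on each pair, so the
    effective conductance per presynaptic spike is ``weight * multiplicity``
    and the audited synapse count is ``len(pre) * multiplicity``.
    """

    spec: GroupSpec
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def sign(self) -> str:
        return self.spec.sign

    @property
    def plastic(self) -> bool:
        return self.spec.plastic

    @property
    def realized_count(self) -> int:
        return int(self.pre.size * self.spec.multiplicity)

    def effective_weights(self) -> np.ndarray:
        return self.weight * self.spec.multiplicity


class NetworkModel:
    """Layers, connection groups and per-synapse weights of one network."""

    def __init__(
        self,
        layers: dict[str, LayerSpec],
        groups: dict[str, ConnectionGroup],
        neuron_params: NeuronParams,
        background: BackgroundDrive,
        seed: int,
    ) -> None:
        self.layers = layers
        self.groups = groups
        self.neuron_params = neuron_params
        self.background = background
        self.seed = seed
        self.n_neurons = sum(l.size for l in layers.values())
        self.is_source = np.zeros(self.n_neurons, dtype=bool)
        for name in SOURCE_LAYERS:
            l = layers[name]
            self.is_source[l.start:l.stop] = True

    # -- structure queries ------------------------------------------------

    def layer(self, name: str) -> LayerSpec:
        return self.layers[name]

    def column_of(self, layer: str, neuron_index: int) -> int:
        """1-based response column of a neuron index within a columnar layer."""
        spec = self.layers[layer]
        if spec.n_columns == 1:
            raise ValueError(f"layer {layer!r} is diffuse, not columnar")
        if not 0 <= neuron_index < spec.size:
            raise IndexError(
                f"neuron index {neuron_index} out of range for {layer!r}"
            )
        return neuron_index // spec.column_size + 1

    def plastic_groups(self) -> list[ConnectionGroup]:
        return [g for g in self.groups.values() if g.plastic]

    # -- export -----------------------------------------------------------

    def description(self) -> dict:
        """Structured summary of the build (audit / reproducibility record)."""
        return {
            "seed": int(self.seed),
            "n_neurons": int(self.n_neurons),
            "layers": {n: int(l.size) for n, l in self.layers.items()},
            "groups": {
                g.name: {
                    "count": g.realized_count,
                    "sign": g.sign,
                    "plastic": bool(g.plastic),
                    "weight_mean": float(np.mean(g.weight)),
                    "weight_min": float(np.min(g.weight)),
                    "weight_max": float(np.max(g.weight)),
                }
                for g in self.groups.values()
            },
        }


def column_of(layer_spec: LayerSpec, neuron_index: int) -> int:
    """1-based column id of ``neuron_index`` within a columnar layer."""
    if layer_spec.n_columns == 1:
        raise ValueError(f"layer {layer_spec.name!r} is diffuse, not columnar")
    if not 0 <= neuron_index < layer_spec.size:
        raise IndexError("neuron index out of range")
    return neuron_index // layer_spec.column_size + 1


def _member_indices(layers: dict[str, LayerSpec], name: str) -> np.ndarray:
    """Global indices of a layer, resolving the 'striatum' union."""
    if name == "striatum":
        return np.concatenate(
            [layers["striatum_go"].indices, layers["striatum_nogo"].indices]
        )
    return layers[name].indices


def _wire_group(
    spec: GroupSpec, layers: dict[str, LayerSpec], rng: np.random.Generator
) -> ConnectionGroup:
    src = _member_indices(layers, spec.source)
    tgt = _member_indices(layers, spec.target)

    if spec.mapping == "diffuse":
        pre = np.repeat(src, tgt.size)
        post = np.tile(tgt, src.size)
    elif spec.mapping == "columnar":
        s_layer, t_layer = layers[spec.source], layers[spec.target]
        pres, posts = [], []
        for c in range(N_COLUMNS):
            s_col = s_layer.indices[
                c * s_layer.column_size:(c + 1) * s_layer.column_size
            ]
            t_col = t_layer.indices[
                c * t_layer.column_size:(c + 1) * t_layer.column_size
            ]
            pres.append(np.repeat(s_col, t_col.size))
            posts.append(np.tile(t_col, s_col.size))
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
    elif spec.mapping == "indegree":
        pres, posts = [], []
        for t in tgt:
            chosen = rng.choice(src, size=spec.indegree, replace=False)
            pres.append(np.sort(chosen))
            posts.append(np.full(spec.indegree, t))
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
    else:  # pragma: no cover - registry is fixed
        raise ValueError(f"unknown mapping {spec.mapping!r}")

    if isinstance(spec.weight, tuple):
        lo, hi = spec.weight
        weight = rng.uniform(lo, hi, size=pre.size)
    else:
        weight = np.full(pre.size, float(spec.weight))

    group = ConnectionGroup(spec, pre.astype(np.int64), post.astype(np.int64),
                            weight.astype(np.float64))
    if group.realized_count != spec.count:
        raise ValueError(
            f"group {spec.name}: realized {group.realized_count} synapses, "
            f"expected {spec.count}"
        )
    return group


def build_network(
    seed: int,
    neuron_params: NeuronParams | None = None,
    background: BackgroundDrive | None = None,
) -> NetworkModel:
    """Build and audit one network with seeded initial weights.

    Initial weights of groups specified as uniform ranges (including the
    plastic input projections) are drawn with ``numpy``'s default generator
    seeded by ``seed``; rebuilding with the same seed reproduces identical
    wiring and weights.
    """
    layers = _layer_table()
    rng = np.random.default_rng(seed)
    groups = {
        spec.name: _wire_group(spec, layers, rng) for spec in CONNECTION_TABLE
    }
    net = NetworkModel(
        layers,
        groups,
        neuron_params or NeuronParams(),
        background or BackgroundDrive(),
        seed,
    )
    audit = audit_counts(net)
    bad = audit[~audit["ok"]]
    if len(bad):
        raise ValueError(
            "connection-count audit failed for groups: "
            + ", ".join(bad["group"].tolist())
        )
    return net


def weights_frame(
    network: NetworkModel, plastic_only: bool = True
) -> pd.DataFrame:
    """Per-synapse weight table (group, source id, target id, weight).

    With ``plastic_only`` (default) the table holds just the learnable
    projections; written once per epoch it records a weight trajectory.
    """
    frames = []
    for g in network.groups.values():
        if plastic_only and not g.plastic:
            continue
        frames.append(pd.DataFrame({
            "group": g.name,
            "source": g.pre,
            "target": g.post,
            "weight": g.weight,
        }))
    return pd.concat(frames, ignore_index=True)


def audit_counts(network: NetworkModel) -> pd.DataFrame:
    """Expected vs realized synapse counts for every connection group.

    Expected counts come from the parameter registry; a row fails when the
    realized count differs. Groups missing from the network appear with a
    realized count of 0.
    """
    rows = []
    for spec in CONNECTION_TABLE:
        group = network.groups.get(spec.name)
        realized = group.realized_count if group is not None else 0
        rows.append(
            {
                "group": spec.name,
                "expected": spec.count,
                "realized": realized,
                "ok": realized == spec.count,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "LayerSpec", "ConnectionGroup", "NetworkModel",
    "build_network", "audit_counts", "column_of", "weights_frame",
]
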