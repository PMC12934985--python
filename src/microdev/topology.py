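"""Sub-region topologies: ordered layers and directed spreading edges.

A brain region (hippocampus, cerebellum) is modeled as a small set of
compartments ("layers") connected by directed spreading edges. The special
source label ``EXTERNAL`` denotes influx from outside the region (e.g.
microglia invading the hippocampus through the Cornu Ammonis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

EXTERNAL = "EXTERNAL"

__all__ = [
    "EXTERNAL",
    "RegionTopology",
    "hippocampus_topology",
    "cerebellum_topology",
    "load_topology",
    "save_topology",
]


@dataclass(frozen=True)
class RegionTopology:
    """Ordered layers of a brain region plus directed spreading edges.

    Parameters
    ----------
    region_name : str
        Label for the region (e.g. ``"hippocampus"``).
    layers : tuple of str
        Ordered, unique layer labels.
    edges : tuple of (str, str)
        Directed (source, target) pairs. The source may be ``EXTERNAL``
        (influx from outside the region); the target must be a layer.
    """

    region_name: str
    layers: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if len(set(self.layers)) != len(self.layers):
            raise ValueError(f"duplicate layer labels in {self.layers!r}")
        if EXTERNAL in self.layers:
            raise ValueError(f"{EXTERNAL!r} is reserved and cannot be a layer")
        for src, dst in self.edges:
            if src == dst:
                raise ValueError(f"self-edge {src!r} -> {dst!r} not allowed")
            if src != EXTERNAL and src not in self.layers:
                raise ValueError(f"edge source {src!r} is not a declared layer")
            if dst not in self.layers:
                raise ValueError(f"edge target {dst!r} is not a declared layer")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_index(self, layer: str) -> int:
        try:
            return self.layers.index(layer)
        except ValueError:
            raise KeyError(f"unknown layer {layer!r} in region {self.region_name!r}")

    def internal_edges(self) -> list[tuple[str, str]]:
        """Edges between declared layers (spreading fluxes)."""
        return [(s, d) for s, d in self.edges if s != EXTERNAL]

    def external_edges(self) -> list[tuple[str, str]]:
        """Edges whose source is EXTERNAL (influx terms)."""
        return [(s, d) for s, d in self.edges if s == EXTERNAL]


def hippocampus_topology() -> RegionTopology:
    """Published hippocampal spreading route: EXTERNAL -> CA -> DG.

    Microglia invade from outside the hippocampus into the Cornu Ammonis
    and then spread inward towards the dentate gyrus.
    """
    return RegionTopology(
        region_name="hippocampus",
        layers=("CA", "DG"),
        edges=((EXTERNAL, "CA"), ("CA", "DG")),
    )


def cerebellum_topology() -> RegionTopology:
    """Published cerebellar spreading route: WM -> GL -> ML (outward).

    Microglia in the white matter spread outwardly towards the granular
    layer and then to the molecular layer.
    """
    return RegionTopology(
        region_name="cerebellum",
        layers=("WM", "GL", "ML"),
        edges=(("WM", "GL"), ("GL", "ML")),
    )


def save_topology(topo: RegionTopology, path: str | Path) -> None:
    payload = {
        "region": topo.region_name,
        "layers": list(topo.layers),
        "edges": [list(e) for e in topo.edges],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_topology(path: str | Path) -> RegionTopology:
    payload = json.loads(Path(path).read_text())
    missing = {"region", "layers", "edges"} - set(payload)
    if missing:
        raise ValueError(f"topology file {path} missing keys: {sorted(missing)}")
    return RegionTopology(
        region_name=payload["region"],
        layers=tuple(payload["layers"]),
        edges=tuple(tuple(e) for e in payload["edges"]),
    )
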