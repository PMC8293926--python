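"""Named-node network graph with full forward and backward passes."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer

INPUT = "input"


@dataclass
class Node:
    """One graph node: a layer applied to the outputs of ``inputs``.

    ``downsamples`` marks nodes that reduce spatial resolution (pooling
    or strided convolution); tap enumeration uses it.
    """

    name: str
    layer: Layer
    inputs: list[str] = field(default_factory=lambda: [INPUT])
    downsamples: bool = False


class Network:
    """A DAG of layers; nodes are listed in topological order.

    ``forward`` returns the activation of every node, so intermediate
    feature maps can be harvested without re-running the model, and
    ``backward`` returns the gradient of a scalar objective with
    respect to every activation (and accumulates parameter gradients).
    """

    def __init__(self, nodes: list[Node]):
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        known = {INPUT}
        for n in nodes:
            for src in n.inputs:
                if src not in known:
                    raise ValueError(f"node {n.name!r} references unknown input {src!r}")
            known.add(n.name)
        self.nodes = nodes
        self.by_name = {n.name: n for n in nodes}
        self.output_name = nodes[-1].name

    # -- execution ---------------------------------------------------------

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        acts: dict[str, np.ndarray] = {INPUT: x}
        for n in self.nodes:
            acts[n.name] = n.layer.forward(*(acts[s] for s in n.inputs))
        return acts

    def backward(self, g_output: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate from the final node; call after ``forward``.

        Returns gradients with respect to every node activation
        (including ``"input"``).  Parameter gradients accumulate into
        each layer's ``grads``; call :meth:`zero_grad` first when
        starting a fresh minibatch.
        """
        gacts: dict[str, np.ndarray] = {self.output_name: g_output}
        for n in reversed(self.nodes):
            gy = gacts.get(n.name)
            if gy is None:
                continue
            gxs = n.layer.backward(gy)
            for src, gx in zip(n.inputs, gxs):
                if src in gacts:
                    gacts[src] = gacts[src] + gx
                else:
                    gacts[src] = gx
        return gacts

    # -- parameters --------------------------------------------------------

    def layers(self) -> list[Layer]:
        return [n.layer for n in self.nodes]

    def init_params(self, rng: np.random.Generator) -> None:
        for layer in self.layers():
            layer.init_params(rng)

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def set_trainable(self, flag: bool) -> None:
        for layer in self.layers():
            layer.trainable = flag

    def param_fingerprint(self) -> str:
        """SHA-256 over all parameter bytes, in graph order (bit-exact)."""
        h = hashlib.sha256()
        for n in self.nodes:
            for key in sorted(n.layer.params):
                h.update(n.name.encode())
                h.update(key.encode())
                h.update(np.ascontiguousarray(n.layer.params[key]).tobytes())
        return h.hexdigest()

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"{n.name}/{k}": v.copy()
                for n in self.nodes for k, v in n.layer.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for n in self.nodes:
            for k in n.layer.params:
                n.layer.params[k] = state[f"{n.name}/{k}"].copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return float(loss), g / n
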