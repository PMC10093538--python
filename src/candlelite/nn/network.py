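"""Trainable network interpreting a symbolic NetGraph.

The graph is the single source of truth: every :class:`LayerNode` becomes one
tensor op, and the trainable arrays are enumerable so the symbolic parameter
count can be cross-checked against the instantiated model exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..graphspec import INPUT, NetGraph
from . import ops

__all__ = ["Network"]

_OBJ_PRIOR_BIAS = -4.595  # sigmoid^-1(0.01): start predicting 'background'


class Network:
    """Executable, differentiable instantiation of a NetGraph.

    Parameters are float32 numpy arrays keyed by node id.  ``forward`` runs
    the graph; in training mode activations are cached and ``backward``
    produces gradients for every trainable array.
    """

    def __init__(self, graph: NetGraph, seed: int = 0, dtype=np.float32):
        graph.validate()
        self.graph = graph
        self.dtype = dtype
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.buffers: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for n in graph.nodes:
            if n.kind == "conv2d":
                fan_in = n.in_channels * n.kernel**2
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               (n.out_channels, n.in_channels, n.kernel, n.kernel))
                p = {"w": w.astype(dtype)}
                if n.has_bias:
                    b = np.zeros(n.out_channels, dtype=dtype)
                    if n.id.endswith(("obj_pred", "cls_pred")):
                        b[:] = _OBJ_PRIOR_BIAS
                    p["b"] = b
                self.params[n.id] = p
            elif n.kind == "dwconv2d":
                fan_in = n.kernel**2
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               (n.in_channels, n.kernel, n.kernel))
                self.params[n.id] = {"w": w.astype(dtype)}
            elif n.kind == "batchnorm":
                c = n.out_channels
                self.params[n.id] = {
                    "gamma": np.ones(c, dtype=dtype),
                    "beta": np.zeros(c, dtype=dtype),
                }
                self.buffers[n.id] = {
                    "running_mean": np.zeros(c, dtype=dtype),
                    "running_var": np.ones(c, dtype=dtype),
                }
            elif n.kind == "conv1d_channelwise":
                w = rng.normal(0.0, np.sqrt(1.0 / n.kernel), n.kernel)
                self.params[n.id] = {"w": w.astype(dtype)}
        self._acts: dict[str, np.ndarray] = {}
        self._cache: dict[str, object] = {}
        self._train = False

    # ------------------------------------------------------------------
    def num_params(self) -> int:
        """Number of trainable scalars (buffers excluded)."""
        return sum(a.size for p in self.params.values() for a in p.values())

    def parameter_items(self):
        for nid, p in self.params.items():
            for name, arr in p.items():
                yield f"{nid}/{name}", arr

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Run the graph on a (N, C, H, W) batch; returns the output maps."""
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        self._train = train
        acts: dict[str, np.ndarray] = {INPUT: x.astype(self.dtype, copy=False)}
        self._cache = {}
        for n in self.graph.nodes:
            ins = [acts[i] for i in n.inputs]
            acts[n.id] = self._forward_node(n, ins, train)
        self._acts = acts if train else {}
        return [acts[o] for o in self.graph.outputs]

    def _forward_node(self, n, ins, train):
        k = n.kind
        if k == "conv2d":
            p = self.params[n.id]
            return ops.conv2d_forward(ins[0], p["w"], p.get("b"), n.stride)
        if k == "dwconv2d":
            return ops.dwconv2d_forward(ins[0], self.params[n.id]["w"], n.stride)
        if k == "batchnorm":
            p, bf = self.params[n.id], self.buffers[n.id]
            y, cache = ops.batchnorm_forward(
                ins[0], p["gamma"], p["beta"], bf["running_mean"], bf["running_var"], train
            )
            if train:
                self._cache[n.id] = cache
            return y
        if k == "silu":
            y, s = ops.silu_forward(ins[0])
            if train:
                self._cache[n.id] = s
            return y
        if k == "sigmoid":
            y, _ = ops.sigmoid_forward(ins[0])
            return y
        if k == "maxpool":
            y, arg = ops.maxpool_forward(ins[0], n.kernel)
            if train:
                self._cache[n.id] = arg
            return y
        if k == "upsample2x":
            return ops.upsample2x_forward(ins[0])
        if k == "concat":
            return np.concatenate(ins, axis=1)
        if k == "add":
            return ins[0] + ins[1]
        if k == "mul":
            return ins[0] * ins[1]
        if k == "slice_space_to_depth":
            return ops.space_to_depth_forward(ins[0])
        if k == "global_avg_pool":
            return ops.global_avg_pool_forward(ins[0])
        if k == "conv1d_channelwise":
            return ops.conv1d_channelwise_forward(ins[0], self.params[n.id]["w"])
        raise ValueError(f"unhandled kind {k}")

    # ------------------------------------------------------------------
    def backward(self, out_grads: list[np.ndarray]) -> dict[str, dict[str, np.ndarray]]:
        """Reverse-mode pass; requires a preceding forward(train=True)."""
        if not self._acts:
            raise RuntimeError("backward requires forward(train=True) first")
        gacc: dict[str, np.ndarray] = {}
        for oid, g in zip(self.graph.outputs, out_grads):
            _accum(gacc, oid, g.astype(self.dtype, copy=False))
        grads: dict[str, dict[str, np.ndarray]] = {}
        for n in reversed(self.graph.nodes):
            g = gacc.pop(n.id, None)
            if g is None:
                continue
            ins = [self._acts[i] for i in n.inputs]
            gins, gpar = self._backward_node(n, g, ins)
            if gpar:
                grads[n.id] = gpar
            for iid, gi in zip(n.inputs, gins):
                if iid != INPUT and gi is not None:
                    _accum(gacc, iid, gi)
        return grads

    def _backward_node(self, n, g, ins):
        k = n.kind
        if k == "conv2d":
            p = self.params[n.id]
            gx, gw, gb = ops.conv2d_backward(g, ins[0], p["w"], n.has_bias, n.stride)
            gpar = {"w": gw}
            if gb is not None:
                gpar["b"] = gb
            return [gx], gpar
        if k == "dwconv2d":
            gx, gw = ops.dwconv2d_backward(g, ins[0], self.params[n.id]["w"], n.stride)
            return [gx], {"w": gw}
        if k == "batchnorm":
            gx, ggamma, gbeta = ops.batchnorm_backward(
                g, self.params[n.id]["gamma"], self._cache[n.id], self._train
            )
            return [gx], {"gamma": ggamma, "beta": gbeta}
        if k == "silu":
            return [ops.silu_backward(g, ins[0], self._cache[n.id])], None
        if k == "sigmoid":
            y = self._acts[n.id]
            return [ops.sigmoid_backward(g, y)], None
        if k == "maxpool":
            return [ops.maxpool_backward(g, ins[0], n.kernel, self._cache[n.id])], None
        if k == "upsample2x":
            return [ops.upsample2x_backward(g)], None
        if k == "concat":
            splits = np.cumsum([a.shape[1] for a in ins])[:-1]
            return list(np.split(g, splits, axis=1)), None
        if k == "add":
            return [g, g], None
        if k == "mul":
            a, b = ins
            ga = g * b
            gb = g * a
            if b.shape[2:] == (1, 1) and g.shape[2:] != (1, 1):
                gb = gb.sum(axis=(2, 3), keepdims=True)
            return [ga, gb], None
        if k == "slice_space_to_depth":
            return [ops.space_to_depth_backward(g)], None
        if k == "global_avg_pool":
            h, w = ins[0].shape[2:]
            return [ops.global_avg_pool_backward(g, h, w)], None
        if k == "conv1d_channelwise":
            gx, gw = ops.conv1d_channelwise_backward(g, ins[0], self.params[n.id]["w"])
            return [gx], {"w": gw}
        raise ValueError(f"unhandled kind {k}")

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for nid, p in self.params.items():
            for name, arr in p.items():
                out[f"{nid}/{name}"] = arr
        for nid, bf in self.buffers.items():
            for name, arr in bf.items():
                out[f"{nid}/{name}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for nid, p in self.params.items():
            for name in p:
                p[name] = np.asarray(state[f"{nid}/{name}"], dtype=self.dtype)
        for nid, bf in self.buffers.items():
            for name in bf:
                bf[name] = np.asarray(state[f"{nid}/{name}"], dtype=self.dtype)

    def save(self, path: str | Path, config: dict | None = None) -> None:
        """Flat named-parameter archive plus an optional JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        if config is not None:
            path.with_suffix(".json").write_text(json.dumps(config, indent=2))

    def load(self, path: str | Path) -> None:
        with np.load(Path(path), allow_pickle=False) as state:
            self.load_state_dict(dict(state))


def _accum(acc: dict[str, np.ndarray], key: str, g: np.ndarray) -> None:
    if key in acc:
        acc[key] = acc[key] + g
    else:
        acc[key] = g
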