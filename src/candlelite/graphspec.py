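"""Symbolic computation graphs with exact parameter and FLOP accounting.

Every network in this package — the CSP blocks, the three backbones and the
full detectors — is first described as a :class:`NetGraph`: an ordered DAG of
:class:`LayerNode` records carrying layer kind, kernel, stride and channel
counts.  The same graph drives two consumers:

* the cost auditor (:func:`count_params`, :func:`count_flops`), which
  reproduces the model-size tables exactly, and
* the executable numpy network (:mod:`candlelite.nn.network`), which
  instantiates one tensor op per node.

Keeping a single symbolic source of truth means the parameter counts printed
by the auditor are, by construction, the counts of the trainable scalars of
the runnable model; a test enforces this equivalence.

Counting conventions
--------------------
Parameters: a ``conv2d`` carries ``c_in * k^2 * c_out`` weights (plus
``c_out`` bias terms only for the detection-head prediction convs); a
``dwconv2d`` carries ``c_in * k^2``; a ``batchnorm`` contributes its two
affine vectors (``2 * C``; running statistics are buffers, not parameters);
a channel-wise 1-D attention conv contributes ``k``.  Everything else is
parameter-free.

FLOPs: convolutions cost two ops per multiply-accumulate
(``2 * c_in * k^2 * c_out * H_out * W_out``); batchnorm, silu and sigmoid
cost a configurable per-element constant (default 4 each, i.e. 8 per
Conv-BN-SiLU output element), as does the attention gate's channel
multiply; pooling, upsampling, concat, add and the space-to-depth slice
are counted as free.  This convention reproduces the published per-block
FLOP figures to the printed digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "KINDS",
    "LayerNode",
    "NetGraph",
    "CostReport",
    "GraphError",
    "GraphBuilder",
    "count_params",
    "count_flops",
    "DEFAULT_ELEMENTWISE_COST",
]

#: layer kinds understood by both the auditor and the executor
KINDS = frozenset(
    {
        "conv2d",
        "dwconv2d",
        "batchnorm",
        "silu",
        "sigmoid",
        "maxpool",
        "upsample2x",
        "concat",
        "add",
        "mul",
        "slice_space_to_depth",
        "global_avg_pool",
        "conv1d_channelwise",
    }
)

#: per-element op cost charged for each of batchnorm / silu / sigmoid
DEFAULT_ELEMENTWISE_COST = 4

#: special id denoting the graph input tensor
INPUT = "input"


class GraphError(ValueError):
    """Structural problem in a NetGraph; the message names the node."""


@dataclass(frozen=True)
class LayerNode:
    """One layer of a network, symbolically.

    ``inputs`` lists upstream node ids; the reserved id ``"input"`` refers to
    the graph's input tensor.
    """

    id: str
    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    has_bias: bool = False
    inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GraphError(f"node {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "dwconv2d" and self.in_channels != self.out_channels:
            raise GraphError(
                f"node {self.id!r}: depthwise conv requires in_channels == "
                f"out_channels, got {self.in_channels} != {self.out_channels}"
            )


@dataclass
class CostReport:
    """Exact integer parameter/FLOP totals with a per-node breakdown."""

    params_total: int = 0
    flops_total: int = 0
    per_node: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class NetGraph:
    """Ordered, acyclic collection of layers with declared output nodes."""

    nodes: list[LayerNode] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    input_spec: tuple[int, int, int] | None = None  # (C, H, W)

    def node(self, node_id: str) -> LayerNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def validate(self) -> None:
        """Check ids, topology and channel bookkeeping; raise GraphError."""
        seen: dict[str, LayerNode] = {}
        for n in self.nodes:
            if n.id in seen or n.id == INPUT:
                raise GraphError(f"duplicate or reserved node id {n.id!r}")
            for up in n.inputs:
                if up != INPUT and up not in seen:
                    raise GraphError(
                        f"node {n.id!r}: input {up!r} is undefined or appears "
                        "later in the order"
                    )
            self._check_channels(n, seen)
            seen[n.id] = n
        for out in self.outputs:
            if out not in seen:
                raise GraphError(f"declared output {out!r} is not a node")

    def _in_channels_of(self, up: str, seen: dict[str, LayerNode]) -> int:
        if up == INPUT:
            if self.input_spec is None:
                return -1  # unknown; skip the check
            return self.input_spec[0]
        return seen[up].out_channels

    def _check_channels(self, n: LayerNode, seen: dict[str, LayerNode]) -> None:
        ups = [self._in_channels_of(u, seen) for u in n.inputs]
        if any(c < 0 for c in ups):
            return
        if n.kind == "concat":
            if sum(ups) != n.out_channels:
                raise GraphError(
                    f"node {n.id!r}: concat out_channels {n.out_channels} != "
                    f"sum of inputs {sum(ups)}"
                )
        elif n.kind in ("add", "mul"):
            if len(set(ups)) != 1 or ups[0] != n.out_channels:
                raise GraphError(f"node {n.id!r}: {n.kind} channel mismatch {ups}")
        elif n.kind == "slice_space_to_depth":
            if ups and 4 * ups[0] != n.out_channels:
                raise GraphError(
                    f"node {n.id!r}: space-to-depth must quadruple channels"
                )
        elif ups:
            if ups[0] != n.in_channels:
                raise GraphError(
                    f"node {n.id!r}: declared in_channels {n.in_channels} != "
                    f"upstream out_channels {ups[0]}"
                )

    # ------------------------------------------------------------------
    def shapes(self, input_spec: tuple[int, int, int] | None = None) -> dict[str, tuple[int, int, int]]:
        """Propagate (C, H, W) through the graph.

        Stride-2 layers require even spatial dims; space-to-depth likewise.
        Raises GraphError on any non-integral intermediate size.
        """
        spec = input_spec or self.input_spec
        if spec is None:
            raise GraphError("no input_spec given")
        self.validate()
        shp: dict[str, tuple[int, int, int]] = {INPUT: tuple(spec)}
        for n in self.nodes:
            ins = [shp[u] for u in n.inputs]
            shp[n.id] = _propagate(n, ins)
        shp.pop(INPUT)
        return shp


def _propagate(n: LayerNode, ins: list[tuple[int, int, int]]) -> tuple[int, int, int]:
    if n.kind in ("conv2d", "dwconv2d", "maxpool"):
        (_, h, w) = ins[0]
        if n.stride == 2 and (h % 2 or w % 2):
            raise GraphError(f"node {n.id!r}: odd spatial dims {h}x{w} for stride 2")
        c_out = n.out_channels if n.kind != "maxpool" else ins[0][0]
        return (c_out, h // n.stride, w // n.stride)
    if n.kind in ("batchnorm", "silu", "sigmoid"):
        return ins[0]
    if n.kind == "upsample2x":
        c, h, w = ins[0]
        return (c, 2 * h, 2 * w)
    if n.kind == "concat":
        hs = {(h, w) for (_, h, w) in ins}
        if len(hs) != 1:
            raise GraphError(f"node {n.id!r}: concat spatial mismatch {sorted(hs)}")
        return (sum(c for (c, _, _) in ins), *hs.pop())
    if n.kind in ("add", "mul"):
        # mul allows a (C,1,1) gate broadcast against a (C,H,W) map
        full = max(ins, key=lambda s: s[1] * s[2])
        for s in ins:
            if s[0] != full[0] or (s[1:] != full[1:] and s[1:] != (1, 1)):
                raise GraphError(f"node {n.id!r}: incompatible shapes {ins}")
        return full
    if n.kind == "slice_space_to_depth":
        c, h, w = ins[0]
        if h % 2 or w % 2:
            raise GraphError(f"node {n.id!r}: odd dims {h}x{w} for space-to-depth")
        return (4 * c, h // 2, w // 2)
    if n.kind == "global_avg_pool":
        return (ins[0][0], 1, 1)
    if n.kind == "conv1d_channelwise":
        return ins[0]
    raise GraphError(f"node {n.id!r}: unhandled kind {n.kind!r}")


# ----------------------------------------------------------------------
# cost accounting


def node_params(n: LayerNode) -> int:
    """Trainable scalars contributed by one node."""
    if n.kind == "conv2d":
        p = n.in_channels * n.kernel**2 * n.out_channels
        return p + (n.out_channels if n.has_bias else 0)
    if n.kind == "dwconv2d":
        return n.in_channels * n.kernel**2
    if n.kind == "batchnorm":
        return 2 * n.out_channels
    if n.kind == "conv1d_channelwise":
        return n.kernel
    return 0


def count_params(g: NetGraph) -> CostReport:
    """Exact trainable-parameter count, per node and total."""
    g.validate()
    rep = CostReport()
    for n in g.nodes:
        p = node_params(n)
        rep.per_node[n.id] = {"params": p}
        rep.params_total += p
    return rep


def count_flops(
    g: NetGraph,
    input_spec: tuple[int, int, int] | None = None,
    elementwise_cost: int = DEFAULT_ELEMENTWISE_COST,
) -> CostReport:
    """Exact FLOP count under the package convention (see module docstring).

    ``elementwise_cost`` is charged per output element for each of batchnorm,
    silu and sigmoid; convolutions cost 2 ops per multiply-accumulate.
    """
    shp = g.shapes(input_spec)
    rep = CostReport()
    for n in g.nodes:
        c, h, w = shp[n.id]
        hw = h * w
        if n.kind == "conv2d":
            f = 2 * n.in_channels * n.kernel**2 * n.out_channels * hw
            if n.has_bias:
                f += n.out_channels * hw
        elif n.kind == "dwconv2d":
            f = 2 * n.in_channels * n.kernel**2 * hw
        elif n.kind in ("batchnorm", "silu", "sigmoid", "mul"):
            f = elementwise_cost * c * hw
        elif n.kind == "conv1d_channelwise":
            f = 2 * n.kernel * c * hw
        else:
            f = 0
        p = node_params(n)
        rep.per_node[n.id] = {"params": p, "flops": f}
        rep.params_total += p
        rep.flops_total += f
    return rep


# ----------------------------------------------------------------------
# builder


class GraphBuilder:
    """Incremental NetGraph assembly with unique, hierarchical node ids."""

    def __init__(self) -> None:
        self.nodes: list[LayerNode] = []
        self._ids: set[str] = set()
        self._prefix: list[str] = []

    def scoped(self, name: str) -> "_Scope":
        """Context manager prefixing subsequent node ids with ``name.``."""
        return _Scope(self, name)

    def add(
        self,
        kind: str,
        name: str,
        *,
        inputs: tuple[str, ...] | list[str] | str = (),
        c_in: int = 0,
        c_out: int = 0,
        kernel: int = 1,
        stride: int = 1,
        has_bias: bool = False,
    ) -> str:
        if isinstance(inputs, str):
            inputs = (inputs,)
        nid = ".".join(self._prefix + [name])
        if nid in self._ids:
            raise GraphError(f"duplicate node id {nid!r}")
        self._ids.add(nid)
        self.nodes.append(
            LayerNode(
                id=nid,
                kind=kind,
                in_channels=c_in,
                out_channels=c_out,
                kernel=kernel,
                stride=stride,
                has_bias=has_bias,
                inputs=tuple(inputs),
            )
        )
        return nid

    def graph(
        self,
        outputs: list[str] | tuple[str, ...],
        input_spec: tuple[int, int, int] | None = None,
    ) -> NetGraph:
        g = NetGraph(nodes=list(self.nodes), outputs=list(outputs), input_spec=input_spec)
        g.validate()
        return g


class _Scope:
    def __init__(self, b: GraphBuilder, name: str) -> None:
        self.b, self.name = b, name

    def __enter__(self) -> GraphBuilder:
        self.b._prefix.append(self.name)
        return self.b

    def __exit__(self, *exc) -> None:
        self.b._prefix.pop()
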