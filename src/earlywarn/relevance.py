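"""Backward relevance propagation (deep Taylor decomposition / LRP) for the
bias-free ReLU prediction network, plus the Gradient x Input unified view and
population-level aggregation of explanations.

The explained quantity is the pre-softmax logit of the class of interest: the
initial relevance equals that logit and is redistributed backward layer by
layer.  Intermediate linear layers (convolutions, the dense head, and global
average pooling viewed as a linear layer with uniform positive weights) use
the z+-rule, which distributes relevance only along positive contributions;
the input-adjacent convolution uses the w2-rule, appropriate for real-valued
inputs.  Parameter-free normalization layers are constant per-channel
scalings at inference and pass relevance through unchanged, as do ReLUs
(a dead unit receives zero relevance from above because its activation is
zero).  Under these rules the total relevance at every layer equals the
anchored logit up to the epsilon stabilizer used for near-zero denominators
(conservation), and the all-z-rule composite equals Gradient x Input exactly
on this architecture.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .tcn import (
    TCN,
    CausalConv1d,
    ChannelNorm,
    ReLU,
    SpatialDropout,
    causal_conv,
    causal_conv_input_grad,
)

EPS = 1e-9


def _stabilize(z: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Sign-matched epsilon stabilizer for near-zero denominators."""
    return z + eps * np.where(z >= 0, 1.0, -1.0)


@dataclasses.dataclass
class RelevanceMap:
    """Per-time-step, per-parameter attribution aligned with the input window."""

    relevance: np.ndarray  # (T, F)
    anchored_logit: float
    class_explained: int
    parameter_names: list[str] | None = None

    @property
    def total(self) -> float:
        return float(self.relevance.sum())


@dataclasses.dataclass
class LayerContext:
    """Weights and forward-pass activations recorded for one linear layer."""

    kind: str  # "dense" or "conv"
    weights: np.ndarray
    activations: np.ndarray  # layer inputs a_i
    dilation: int = 1
    input_layer: bool = False


# ---------------------------------------------------------------------------
# local propagation rules
# ---------------------------------------------------------------------------

def _propagate(ctx: LayerContext, relevance_out: np.ndarray, w: np.ndarray, multiply_input: bool):
    """Shared redistribution: R_in = a * W^T (R_out / (W a)) for the given W."""
    a = ctx.activations
    if ctx.kind == "dense":
        z = a @ w
        s = relevance_out / _stabilize(z)
        back = s @ w.T
    elif ctx.kind == "conv":
        z = causal_conv(a[None] if a.ndim == 2 else a, w, ctx.dilation)
        r = relevance_out[None] if relevance_out.ndim == 2 else relevance_out
        s = r / _stabilize(z)
        back = causal_conv_input_grad(s, w, ctx.dilation, a.shape[-2])
        if a.ndim == 2:
            back = back[0]
    else:
        raise ValueError(f"no propagation rule for layer kind {ctx.kind!r}")
    return a * back if multiply_input else back


def lrp_z(ctx: LayerContext, relevance_out: np.ndarray) -> np.ndarray:
    """z-rule (LRP-0): R_{i<-j} = w_ij a_i / (sum_i w_ij a_i) * R_j."""
    return _propagate(ctx, relevance_out, ctx.weights, multiply_input=True)


def lrp_zplus(ctx: LayerContext, relevance_out: np.ndarray) -> np.ndarray:
    """z+-rule (LRP-alpha1beta0): as the z-rule but with w+ = max(w, 0)."""
    return _propagate(ctx, relevance_out, np.maximum(ctx.weights, 0.0), multiply_input=True)


def lrp_w2_input(ctx: LayerContext, relevance_out: np.ndarray) -> np.ndarray:
    """w2-rule for the input-adjacent layer: R_{i<-j} = w_ij^2 / (sum_i w_ij^2) * R_j.

    For convolutions the denominator counts only real (unpadded) input
    positions, so relevance is conserved at the window boundary.
    """
    if not ctx.input_layer:
        raise ValueError("the w2-rule applies only to the input-adjacent layer")
    w2 = ctx.weights**2
    if ctx.kind == "dense":
        s = relevance_out / _stabilize(np.sum(w2, axis=0))
        return s @ w2.T
    ones = np.ones_like(ctx.activations)
    ctx2 = dataclasses.replace(ctx, activations=ones)
    return _propagate(ctx2, relevance_out, w2, multiply_input=False)


def _pool_relevance(pool_input: np.ndarray, relevance_out: np.ndarray) -> np.ndarray:
    """Global average pooling as a linear layer with uniform weights 1/T.

    With non-negative inputs the z- and z+-rules coincide:
    R_{t<-c} = a_tc / sum_t a_tc * R_c.
    """
    denom = _stabilize(pool_input.sum(axis=0))
    return pool_input * (relevance_out / denom)[None, :]


# ---------------------------------------------------------------------------
# composite explanation
# ---------------------------------------------------------------------------

def explain(
    network: TCN,
    matrix: np.ndarray,
    class_c: int = 1,
    method: str = "deep_taylor",
    parameter_names: Sequence[str] | None = None,
) -> RelevanceMap:
    """Backward-propagate the class logit onto the (T, F) input window.

    ``method="deep_taylor"`` (default) uses the z+-rule through dense, pooling
    and intermediate convolutions with the w2-rule at the input layer;
    ``method="z"`` uses the z-rule everywhere (the Gradient x Input-equivalent
    composite).  The input must already be standardized with the model's
    preprocessing state.
    """
    if method not in ("deep_taylor", "z"):
        raise ValueError("method must be 'deep_taylor' or 'z'")
    if network.config.use_bias:
        raise ValueError("relevance propagation requires a bias-free network")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("explain() takes a single (T, F) window")
    logits = network.logits(x[None], training=False)[0]
    anchored = float(logits[class_c])

    rule = lrp_z if method == "z" else lrp_zplus
    # dense head: relevance starts at the anchored logit (softmax is bypassed)
    relevance_logits = np.zeros_like(logits)
    relevance_logits[class_c] = anchored
    ctx = LayerContext("dense", network.dense.w, network.dense.input[0])
    r = rule(ctx, relevance_logits)
    # global average pooling
    r = _pool_relevance(network.gap.input[0], r)
    # temporal block stack, backward
    conv_layers = [l for l in network.conv_stack if isinstance(l, CausalConv1d)]
    first_conv = conv_layers[0]
    for layer in reversed(network.conv_stack):
        if isinstance(layer, (ReLU, SpatialDropout, ChannelNorm)):
            continue  # pass-through: constant scaling / inactive / gating via activations
        ctx = LayerContext(
            "conv",
            layer.w,
            layer.input[0],
            dilation=layer.dilation,
            input_layer=layer is first_conv,
        )
        if layer is first_conv and method == "deep_taylor":
            r = lrp_w2_input(ctx, r)
        else:
            r = rule(ctx, r)
    return RelevanceMap(
        relevance=r,
        anchored_logit=anchored,
        class_explained=class_c,
        parameter_names=list(parameter_names) if parameter_names is not None else None,
    )


def gradient_times_input(network: TCN, matrix: np.ndarray, class_c: int = 1) -> np.ndarray:
    """Elementwise product of the class-logit gradient with the input.

    On this bias-free ReLU architecture (zero baseline) it coincides with the
    all-z-rule relevance composite, which makes it the independent oracle for
    that propagation path.
    """
    x = np.asarray(matrix, dtype=float)
    return network.gradient(x, class_c=class_c) * x


# ---------------------------------------------------------------------------
# population aggregation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GlobalImportance:
    """Population view of explanations over positively labeled patients.

    ``importance`` holds the per-parameter mean relevance over every data point
    (all time steps, all patients), sorted descending; ``points`` is the
    flattened local-explanation summary cloud with values colored by their
    position between the cohort-wide 5th and 95th percentile anchors.
    """

    importance: pd.DataFrame
    points: pd.DataFrame

    def ranked_parameters(self) -> list[str]:
        return self.importance["parameter"].tolist()


def aggregate_population(
    maps: Sequence[RelevanceMap],
    inputs: Sequence[np.ndarray],
    parameter_names: Sequence[str],
) -> GlobalImportance:
    """Aggregate per-patient relevance maps into global parameter importance.

    Temporal variation is deliberately ignored: every (time step, patient)
    data point counts equally.  ``inputs`` carry the (T, F) parameter values
    aligned with each map, used for the local-summary point cloud.
    """
    if not maps:
        raise ValueError("cannot aggregate an empty set of relevance maps")
    if len(maps) != len(inputs):
        raise ValueError("maps and inputs must align")
    rel = np.concatenate([m.relevance for m in maps], axis=0)  # (sum T, F)
    val = np.concatenate([np.asarray(v, dtype=float) for v in inputs], axis=0)
    names = list(parameter_names)
    if rel.shape[1] != len(names):
        raise ValueError("parameter_names does not match map width")

    mean_rel = rel.mean(axis=0)
    importance = (
        pd.DataFrame({"parameter": names, "mean_relevance": mean_rel})
        .sort_values("mean_relevance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    p5 = np.percentile(val, 5, axis=0)
    p95 = np.percentile(val, 95, axis=0)
    span = np.where(p95 > p5, p95 - p5, 1.0)
    color = np.clip((val - p5[None, :]) / span[None, :], 0.0, 1.0)
    points = pd.DataFrame(
        {
            "parameter": np.repeat(names, rel.shape[0]),
            "relevance": rel.T.ravel(),
            "value": val.T.ravel(),
            "value_percentile": color.T.ravel(),
        }
    )
    return GlobalImportance(importance=importance, points=points)


def top_parameters_timeline(
    map_: RelevanceMap, matrix: np.ndarray, k: int = 10
) -> dict:
    """Per-patient explanation export: the k highest-ranking parameters by mean
    relevance, with their per-hour values and relevance scores."""
    if map_.parameter_names is None:
        raise ValueError("relevance map lacks parameter names")
    mean_rel = map_.relevance.mean(axis=0)
    order = np.argsort(-mean_rel, kind="stable")[:k]
    x = np.asarray(matrix, dtype=float)
    return {
        "class_explained": map_.class_explained,
        "anchored_logit": map_.anchored_logit,
        "parameters": [
            {
                "name": map_.parameter_names[i],
                "mean_relevance": float(mean_rel[i]),
                "values": x[:, i].tolist(),
                "relevance": map_.relevance[:, i].tolist(),
            }
            for i in order
        ],
    }
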