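"""The multi-resolution ASPP patch classifier.

Architecture (input: one-channel 56x56 patch):

1. multi-resolution block 1 — parallel 3x3/5x5/7x7 convolutions with NF1
   filters each, half-kernel padding, outputs concatenated (3*NF1 @ 56);
2. shortcut concatenation with the input (3*NF1 + 1 @ 56), 2x2 max-pool;
3. multi-resolution block 2 (3*NF2 @ 28), shortcut concatenation with the
   block's input (3*(NF1 + NF2) + 1 @ 28), 2x2 max-pool;
4. ASPP at 14x14 — five parallel branches (1x1 convolution; 3x3 dilated
   convolutions at rates 2, 3, 4; global average pooling + 1x1 convolution
   + upsample), concatenated to 5*NF3 channels, fused by a 1x1 convolution
   to NF3, batch-normalized and dropped out;
5. a single fully connected layer to 2 logits, softmax cross-entropy.

Every convolution is followed by ReLU then batch normalization (a flag
switches to the more common conv-BN-ReLU order). Weights use Glorot
uniform initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Broadcast2d,
    Conv2d,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2x2,
    Param,
    ReLU,
)

__all__ = ["CNNConfig", "VolumeShape", "MultiResNet", "build_model", "shape_report", "setup_filter_counts"]


@dataclass(frozen=True)
class CNNConfig:
    """Filter counts and structural knobs of the network."""

    nf1: int = 128
    nf2: int = 128
    nf3: int = 128
    kernel_set: tuple[int, ...] = (3, 5, 7)  # w_p = 2p + 1
    atrous_rates: tuple[int, ...] = (2, 3, 4)
    dropout_rate: float = 0.5
    input_size: int = 56
    n_classes: int = 2
    bn_before_relu: bool = False  # conventional conv-BN-ReLU order if True

    def __post_init__(self) -> None:
        if min(self.nf1, self.nf2, self.nf3) < 1:
            raise ValueError("filter counts must be >= 1")
        if any(k % 2 == 0 for k in self.kernel_set):
            raise ValueError("kernel sizes must be odd")
        if any(r < 1 for r in self.atrous_rates):
            raise ValueError("atrous rates must be positive")


@dataclass(frozen=True)
class VolumeShape:
    channels: int
    height: int
    width: int

    @staticmethod
    def of(x: np.ndarray) -> "VolumeShape":
        # internal tensors are channels-last (N, H, W, C)
        return VolumeShape(int(x.shape[3]), int(x.shape[1]), int(x.shape[2]))


def setup_filter_counts(setup: int, nf1: int) -> tuple[int, int, int]:
    """Filter-count relations of the three studied setups.

    Setup 1 shrinks the feature space (NF2 = NF1/2, NF3 = NF1/4), setup 2
    grows it (NF2 = 2*NF1, NF3 = 4*NF2), setup 3 keeps it constant.
    """
    if setup == 1:
        return nf1, max(1, nf1 // 2), max(1, nf1 // 4)
    if setup == 2:
        return nf1, nf1 * 2, nf1 * 8
    if setup == 3:
        return nf1, nf1, nf1
    raise ValueError("setup must be 1, 2 or 3")


class ConvUnit(Layer):
    """Convolution followed by ReLU and batch normalization (or BN-ReLU)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dilation: int = 1,
        bn_before_relu: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "unit",
    ) -> None:
        self.conv = Conv2d(in_channels, out_channels, kernel, dilation=dilation, rng=rng, name=name)
        self.bn = BatchNorm2d(out_channels, name=name)
        self.relu = ReLU()
        order = (self.conv, self.bn, self.relu) if bn_before_relu else (self.conv, self.relu, self.bn)
        self.chain = order

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.chain:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.chain):
            dy = layer.backward(dy)
        return dy


class MultiResBlock(Layer):
    """Parallel multi-resolution convolutions, concatenated along channels."""

    def __init__(
        self,
        in_channels: int,
        nf: int,
        kernel_set: tuple[int, ...],
        bn_before_relu: bool,
        rng: np.random.Generator,
        name: str,
    ) -> None:
        self.branches = [
            ConvUnit(in_channels, nf, k, bn_before_relu=bn_before_relu, rng=rng, name=f"{name}.k{k}")
            for k in kernel_set
        ]
        self.nf = nf

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate([b.forward(x, train) for b in self.branches], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        for i, b in enumerate(self.branches):
            part = dy[..., i * self.nf : (i + 1) * self.nf]
            d = b.backward(np.ascontiguousarray(part))
            dx = d if dx is None else dx + d
        return dx


class ASPP(Layer):
    """Atrous spatial pyramid pooling with five parallel branches."""

    def __init__(
        self,
        in_channels: int,
        nf3: int,
        rates: tuple[int, ...],
        spatial: tuple[int, int],
        dropout_rate: float,
        bn_before_relu: bool,
        rng: np.random.Generator,
        drop_rng: np.random.Generator,
        name: str = "aspp",
    ) -> None:
        self.point = ConvUnit(in_channels, nf3, 1, bn_before_relu=bn_before_relu, rng=rng, name=f"{name}.point")
        self.dilated = [
            ConvUnit(in_channels, nf3, 3, dilation=r, bn_before_relu=bn_before_relu, rng=rng, name=f"{name}.rate{r}")
            for r in rates
        ]
        self.gap = GlobalAvgPool()
        self.pool_conv = ConvUnit(in_channels, nf3, 1, bn_before_relu=bn_before_relu, rng=rng, name=f"{name}.pool")
        self.upsample = Broadcast2d(spatial)
        self.fuse = ConvUnit(5 * nf3, nf3, 1, bn_before_relu=bn_before_relu, rng=rng, name=f"{name}.fuse")
        self.dropout = Dropout(dropout_rate, rng=drop_rng)
        self.nf3 = nf3

    @property
    def n_branches(self) -> int:
        return 2 + len(self.dilated)

    def params(self) -> list[Param]:
        units = [self.point, *self.dilated, self.pool_conv, self.fuse]
        return [p for u in units for p in u.params()]

    def forward(self, x: np.ndarray, train: bool = False, record: dict | None = None) -> np.ndarray:
        if x.shape[1] < 2 * max(u.conv.d for u in self.dilated) + 1:
            raise ValueError("input too small for the largest dilation rate")
        outs = [self.point.forward(x, train)]
        outs += [u.forward(x, train) for u in self.dilated]
        pooled = self.pool_conv.forward(self.gap.forward(x, train), train)
        outs.append(self.upsample.forward(pooled, train))
        cat = np.concatenate(outs, axis=-1)
        if record is not None:
            record["aspp concat"] = VolumeShape.of(cat)
        fused = self.fuse.forward(cat, train)
        return self.dropout.forward(fused, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.dropout.backward(dy)
        dcat = self.fuse.backward(dy)
        nf = self.nf3
        parts = [np.ascontiguousarray(dcat[..., i * nf : (i + 1) * nf]) for i in range(5)]
        dx = self.point.backward(parts[0])
        for u, part in zip(self.dilated, parts[1:4]):
            dx += u.backward(part)
        dpool = self.upsample.backward(parts[4])
        dx += self.gap.backward(self.pool_conv.backward(dpool))
        return dx


class MultiResNet:
    """The full network with explicit forward/backward passes."""

    def __init__(self, config: CNNConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        self.drop_rng = np.random.default_rng(np.random.SeedSequence(seed + 1).spawn(1)[0])
        s = config.input_size
        if s % 4:
            raise ValueError("input size must be divisible by 4 (two 2x2 poolings)")
        bnr = config.bn_before_relu

        self.block1 = MultiResBlock(1, config.nf1, config.kernel_set, bnr, rng, "block1")
        self.pool1 = MaxPool2x2()
        c1 = 3 * config.nf1 + 1
        self.block2 = MultiResBlock(c1, config.nf2, config.kernel_set, bnr, rng, "block2")
        c2 = 3 * config.nf2 + c1  # block2 output + its own input shortcut
        self.pool2 = MaxPool2x2()
        self.aspp = ASPP(
            c2,
            config.nf3,
            config.atrous_rates,
            (s // 4, s // 4),
            config.dropout_rate,
            bnr,
            rng,
            self.drop_rng,
        )
        self.flatten = Flatten()
        self.fc = Linear(config.nf3 * (s // 4) * (s // 4), config.n_classes, rng=rng)

    def params(self) -> list[Param]:
        return (
            self.block1.params()
            + self.block2.params()
            + self.aspp.params()
            + self.fc.params()
        )

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False, record: dict | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError("expected a (batch, 1, size, size) patch tensor")
        if x.shape[1] == 1:  # accept channels-first input at the public boundary
            x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        if record is not None:
            record["input"] = VolumeShape.of(x)
        b1 = self.block1.forward(x, train)
        if record is not None:
            record["block1 output"] = VolumeShape.of(b1)
        c1 = np.concatenate([b1, x], axis=-1)
        if record is not None:
            record["block1 concat"] = VolumeShape.of(c1)
        p1 = self.pool1.forward(c1, train)
        if record is not None:
            record["after first max-pooling"] = VolumeShape.of(p1)
        b2 = self.block2.forward(p1, train)
        if record is not None:
            record["block2 output"] = VolumeShape.of(b2)
        c2 = np.concatenate([b2, p1], axis=-1)
        if record is not None:
            record["block2 concat"] = VolumeShape.of(c2)
        p2 = self.pool2.forward(c2, train)
        if record is not None:
            record["after second max-pooling"] = VolumeShape.of(p2)
        a = self.aspp.forward(p2, train, record=record)
        if record is not None:
            record["aspp output"] = VolumeShape.of(a)
        flat = self.flatten.forward(a, train)
        logits = self.fc.forward(flat, train)
        self._c1_channels = b1.shape[-1]
        self._c2_channels = b2.shape[-1]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dflat = self.fc.backward(dlogits)
        da = self.flatten.backward(dflat)
        dp2 = self.aspp.backward(da)
        dc2 = self.pool2.backward(dp2)
        nb2 = self._c2_channels
        db2 = np.ascontiguousarray(dc2[..., :nb2])
        dp1 = np.ascontiguousarray(dc2[..., nb2:])
        dp1 = dp1 + self.block2.backward(db2)
        dc1 = self.pool1.backward(dp1)
        nb1 = self._c1_channels
        db1 = np.ascontiguousarray(dc1[..., :nb1])
        self.block1.backward(db1)  # gradient w.r.t. the raw input is not needed

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(outs, axis=0)

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        rest = state[len(ps) :]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self) -> list[BatchNorm2d]:
        units = (
            self.block1.branches
            + self.block2.branches
            + [self.aspp.point, *self.aspp.dilated, self.aspp.pool_conv, self.aspp.fuse]
        )
        return [u.bn for u in units]


def build_model(config: CNNConfig, seed: int = 0) -> MultiResNet:
    """Construct the network with Glorot-initialized weights."""
    return MultiResNet(config, seed=seed)


def shape_report(config: CNNConfig, input_size: int | None = None) -> list[tuple[str, VolumeShape]]:
    """Stage-by-stage volume shapes, measured by probing the built model.

    The shapes come from an actual forward pass of a single probe patch,
    not from closed-form arithmetic, so the report reflects what the
    implementation computes.
    """
    if input_size is not None and input_size != config.input_size:
        from dataclasses import replace

        config = replace(config, input_size=input_size)
    model = build_model(config, seed=0)
    probe = np.zeros((1, 1, config.input_size, config.input_size), dtype=np.float32)
    record: dict[str, VolumeShape] = {}
    model.forward(probe, train=False, record=record)
    return list(record.items())
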