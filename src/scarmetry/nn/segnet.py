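"""Encoder-decoder segmentation network.

The encoder is a ResNet-34-style backbone: a 7x7/stride-2 stem *without* the
usual maxpool (removed to help slender structures survive downsampling),
followed by four residual stages, giving feature strides {2, 2, 4, 8, 16}.
The decoder mirrors it with four blocks of (2x nearest upsample where the
stride shrinks, skip concatenation with the matching-stride encoder feature,
two 3x3 conv-BN-ReLU), then a final 2x upsample and a 1x1 convolution with a
per-channel sigmoid. The two output channels are independent probabilities
for the scar and the scale; background is "neither".

``base_width`` and ``blocks`` scale the capacity: the defaults (64, 3-4-6-3)
are the full ResNet-34 configuration; smaller settings train in reasonable
time on a single CPU and are ample for flat-shaded synthetic imagery.
"""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, Layer, ReLU, Sigmoid,
                     UpsampleBilinear2d, UpsampleNearest2d)

__all__ = ["SegNet"]


class _ConvBNReLU:
    def __init__(self, in_c, out_c, k, stride, rng, relu=True):
        self.conv = Conv2d(in_c, out_c, k, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_c)
        self.relu = ReLU() if relu else None

    def forward(self, x, training):
        x = self.conv.forward(x, training)
        x = self.bn.forward(x, training)
        if self.relu is not None:
            x = self.relu.forward(x, training)
        return x

    def backward(self, d):
        if self.relu is not None:
            d = self.relu.backward(d)
        d = self.bn.backward(d)
        return self.conv.backward(d)

    def layers(self):
        out = [self.conv, self.bn]
        if self.relu is not None:
            out.append(self.relu)
        return out


class _BasicBlock:
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    def __init__(self, in_c, out_c, stride, rng):
        self.branch1 = _ConvBNReLU(in_c, out_c, 3, stride, rng)
        self.branch2 = _ConvBNReLU(out_c, out_c, 3, 1, rng, relu=False)
        self.project = None
        if stride != 1 or in_c != out_c:
            self.project = _ConvBNReLU(in_c, out_c, 1, stride, rng, relu=False)
        self.relu_out = ReLU()

    def forward(self, x, training):
        main = self.branch2.forward(self.branch1.forward(x, training), training)
        short = x if self.project is None else self.project.forward(x, training)
        return self.relu_out.forward(main + short, training)

    def backward(self, d):
        d = self.relu_out.backward(d)
        dx = self.branch1.backward(self.branch2.backward(d))
        dx += d if self.project is None else self.project.backward(d)
        return dx

    def layers(self):
        out = self.branch1.layers() + self.branch2.layers() + [self.relu_out]
        if self.project is not None:
            out = out + self.project.layers()
        return out


class _DecoderBlock:
    """Optional 2x upsample, concat with the skip feature, two 3x3 convs."""

    def __init__(self, up_c, skip_c, out_c, rng, upsample=True):
        self.up = UpsampleNearest2d(2) if upsample else None
        self.up_c = up_c
        self.conv1 = _ConvBNReLU(up_c + skip_c, out_c, 3, 1, rng)
        self.conv2 = _ConvBNReLU(out_c, out_c, 3, 1, rng)

    def forward(self, x, skip, training):
        if self.up is not None:
            x = self.up.forward(x, training)
        cat = np.concatenate([x, skip], axis=1)
        return self.conv2.forward(self.conv1.forward(cat, training), training)

    def backward(self, d):
        dcat = self.conv1.backward(self.conv2.backward(d))
        dx, dskip = dcat[:, : self.up_c], dcat[:, self.up_c :]
        if self.up is not None:
            dx = self.up.backward(dx)
        return dx, dskip

    def layers(self):
        out = self.conv1.layers() + self.conv2.layers()
        if self.up is not None:
            out.append(self.up)
        return out


class SegNet:
    def __init__(
        self,
        in_channels: int = 3,
        out_channels: int = 2,
        base_width: int = 64,
        blocks: tuple[int, int, int, int] = (3, 4, 6, 3),
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        w = base_width
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.base_width = base_width
        self.blocks = tuple(blocks)
        self.seed = seed

        self.stem = _ConvBNReLU(in_channels, w, 7, 2, rng)  # stride 2, no maxpool
        widths = (w, 2 * w, 4 * w, 8 * w)
        strides = (1, 2, 2, 2)
        self.stages = []
        in_c = w
        for width, stride, n in zip(widths, strides, blocks):
            stage = []
            for b in range(n):
                stage.append(_BasicBlock(in_c, width, stride if b == 0 else 1, rng))
                in_c = width
            self.stages.append(stage)

        self.dec = [
            _DecoderBlock(8 * w, 4 * w, 4 * w, rng),                  # s16 -> s8
            _DecoderBlock(4 * w, 2 * w, 2 * w, rng),                  # s8  -> s4
            _DecoderBlock(2 * w, w, w, rng),                          # s4  -> s2
            _DecoderBlock(w, w, w, rng, upsample=False),              # s2, skip = stem
        ]
        self.final_up = UpsampleBilinear2d()
        self.head = Conv2d(w, out_channels, 1, bias=True, rng=rng)
        self.sigmoid = Sigmoid()

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, C, H, W) images to (N, out_channels, H, W) probabilities."""
        n, c, h, w = x.shape
        if h % 16 or w % 16:
            raise ValueError(f"input size {h}x{w} must be divisible by 16")
        f_stem = self.stem.forward(x, training)
        feats = []
        f = f_stem
        for stage in self.stages:
            for block in stage:
                f = block.forward(f, training)
            feats.append(f)
        f1, f2, f3, f4 = feats  # strides 2, 4, 8, 16
        d = self.dec[0].forward(f4, f3, training)
        d = self.dec[1].forward(d, f2, training)
        d = self.dec[2].forward(d, f1, training)
        d = self.dec[3].forward(d, f_stem, training)
        d = self.final_up.forward(d, training)
        d = self.head.forward(d, training)
        return self.sigmoid.forward(d, training)

    def backward(self, dprob: np.ndarray) -> None:
        d = self.sigmoid.backward(dprob)
        d = self.head.backward(d)
        d = self.final_up.backward(d)
        d, ds_stem = self.dec[3].backward(d)
        d, ds1 = self.dec[2].backward(d)
        d, ds2 = self.dec[1].backward(d)
        d, ds3 = self.dec[0].backward(d)
        grads_into_stage = [ds1, ds2, ds3, d]  # incoming grad for stage outputs
        g = None
        for si in (3, 2, 1, 0):
            g = grads_into_stage[si] if g is None else g + grads_into_stage[si]
            for block in reversed(self.stages[si]):
                g = block.backward(g)
        self.stem.backward(g + ds_stem)

    # ------------------------------------------------------------------
    def layers(self) -> list[Layer]:
        out = self.stem.layers()
        for stage in self.stages:
            for block in stage:
                out.extend(block.layers())
        for dec in self.dec:
            out.extend(dec.layers())
        out.extend([self.final_up, self.head, self.sigmoid])
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            if isinstance(layer, BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]
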