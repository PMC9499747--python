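"""Dual-head U-Net: tumor segmentation map plus a tumor-class prediction.

The encoder is a stack of two-convolution blocks whose channel width doubles
per block (64, 128, 256, 512, 1024 at the default width), with stride-2 max
pooling after every block except the deepest; a 240-pixel input therefore
shrinks to 15 pixels at the bottleneck. Each decoder block starts with a
stride-2 transposed convolution (kernel 3) and concatenates the matching
encoder feature map through a skip connection before two convolutions. The
segmentation path contains no fully-connected layer; it ends in a 1x1
convolution producing a per-pixel tumor logit. Because a plain U-Net is a
segmenter, the class prediction comes from a second head: global average
pooling of the bottleneck followed by a linear layer and softmax. Dropout
regularises the two deepest encoder blocks.

Training minimises segmentation binary cross-entropy (when masks are given)
plus classification cross-entropy with Adam; it is seeded and fully
deterministic. Everything runs on NumPy — width (``base_channels``) and
input side are exposed so desk-scale training finishes in minutes; the
full-width architecture is inspectable without training via
:func:`describe_architecture`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn


@dataclass
class UNetConfig:
    n_encoder_blocks: int = 5
    n_decoder_blocks: int | None = None  # None -> encoder blocks - 1
    base_channels: int = 64
    deconv_kernel: int = 3
    deconv_stride: int = 2
    dropout_rate: float = 0.5
    n_classes: int = 3
    input_side: int = 256
    in_channels: int = 1
    #: pooling feeding the classification head, over the deepest encoder
    #: block: "avgmax" concatenates global average and global max pooling
    #: (max statistics carry small-lesion contrast that averaging dilutes);
    #: "avg" is plain global average pooling
    class_head: str = "avgmax"

    def resolved_decoder_blocks(self) -> int:
        return (self.n_encoder_blocks - 1 if self.n_decoder_blocks is None
                else self.n_decoder_blocks)

    def validate(self):
        if self.n_encoder_blocks < 2:
            raise ValueError("need at least 2 encoder blocks")
        if self.resolved_decoder_blocks() != self.n_encoder_blocks - 1:
            raise ValueError(
                "decoder blocks must equal encoder blocks - 1 "
                f"({self.n_encoder_blocks - 1}), got {self.n_decoder_blocks}"
            )
        div = 2 ** (self.n_encoder_blocks - 1)
        if self.input_side % div:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by "
                f"2**(n_encoder_blocks-1) = {div}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.class_head not in ("avgmax", "avg"):
            raise ValueError("class_head must be 'avgmax' or 'avg'")


def describe_architecture(cfg: UNetConfig) -> dict:
    """Architecture description without allocating any weights.

    Returns per-block channel widths and spatial sides, the bottleneck
    figures, and structural flags — enough to verify the printed design
    (channel doubling, deepest width, spatial reduction, no dense layer in
    the segmentation path).
    """
    cfg.validate()
    enc_channels = [cfg.base_channels * 2**b for b in range(cfg.n_encoder_blocks)]
    enc_sides = [cfg.input_side // 2**b for b in range(cfg.n_encoder_blocks)]
    dec_channels = enc_channels[-2::-1]
    dec_sides = enc_sides[-2::-1]
    return {
        "n_encoder_blocks": cfg.n_encoder_blocks,
        "n_decoder_blocks": cfg.resolved_decoder_blocks(),
        "encoder_channels": enc_channels,
        "encoder_sides": enc_sides,
        "decoder_channels": dec_channels,
        "decoder_sides": dec_sides,
        "deepest_channels": enc_channels[-1],
        "bottleneck_side": enc_sides[-1],
        "output_side": dec_sides[-1] if dec_sides else enc_sides[-1],
        "deconv_kernel": cfg.deconv_kernel,
        "deconv_stride": cfg.deconv_stride,
        "dropout_blocks": [cfg.n_encoder_blocks - 1, cfg.n_encoder_blocks],
        "dense_in_segmentation_path": False,
        "classification_head": (
            "bottleneck global-average-pool"
            + (" + global-max-pool" if cfg.class_head == "avgmax" else "")
            + " -> linear -> softmax"),
    }


class UNet:
    """Concrete dual-head network; see the module docstring for the layout."""

    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        e = cfg.n_encoder_blocks
        ch = [cfg.base_channels * 2**b for b in range(e)]
        drop_blocks = {e - 2, e - 1}  # two deepest encoder blocks (0-based)

        self.enc_blocks = []
        self.pools = []
        self.bottleneck_dropout = None
        in_ch = cfg.in_channels
        for b in range(e):
            layers = [
                nn.Conv2D(in_ch, ch[b], 3, rng=rng), nn.ReLU(),
                nn.Conv2D(ch[b], ch[b], 3, rng=rng), nn.ReLU(),
            ]
            if b in drop_blocks and cfg.dropout_rate > 0:
                if b == e - 1:
                    # kept out of the block so the classification head can
                    # read the bottleneck before dropout; the segmentation
                    # path still sees the dropped features
                    self.bottleneck_dropout = nn.Dropout(cfg.dropout_rate, rng)
                else:
                    layers.append(nn.Dropout(cfg.dropout_rate, rng))
            self.enc_blocks.append(layers)
            if b < e - 1:
                self.pools.append(nn.MaxPool2())
            in_ch = ch[b]

        self.dec_blocks = []
        for b in range(e - 2, -1, -1):
            up = nn.ConvTranspose2(in_ch, ch[b], cfg.deconv_kernel, rng=rng)
            convs = [
                nn.Conv2D(2 * ch[b], ch[b], 3, rng=rng), nn.ReLU(),
                nn.Conv2D(ch[b], ch[b], 3, rng=rng), nn.ReLU(),
            ]
            self.dec_blocks.append({"up": up, "convs": convs, "ch": ch[b]})
            in_ch = ch[b]

        self.seg_head = nn.Conv2D(ch[0], 1, 1, rng=rng)
        self.gap = nn.GlobalAvgPool()
        self.gmp = nn.GlobalMaxPool() if cfg.class_head == "avgmax" else None
        head_ch = ch[-1] * (2 if cfg.class_head == "avgmax" else 1)
        self.fc = nn.Linear(head_ch, cfg.n_classes, rng=rng)

    def layers(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(blk)
        for dec in self.dec_blocks:
            out.append(dec["up"])
            out.extend(dec["convs"])
        out.extend([self.seg_head, self.fc])
        return out

    def forward(self, x, train=True):
        """Returns (seg_logits (N,1,H,W), class_logits (N,K))."""
        skips = []
        cur = x
        for b, layers in enumerate(self.enc_blocks):
            for ly in layers:
                cur = ly.forward(cur, train=train)
            if b < len(self.enc_blocks) - 1:
                skips.append(cur)
                cur = self.pools[b].forward(cur, train=train)
        pooled = self.gap.forward(cur, train=train)
        if self.gmp is not None:
            pooled = np.concatenate(
                [pooled, self.gmp.forward(cur, train=train)], axis=1)
        class_logits = self.fc.forward(pooled, train=train)
        if self.bottleneck_dropout is not None:
            cur = self.bottleneck_dropout.forward(cur, train=train)
        self._skips = skips
        for i, dec in enumerate(self.dec_blocks):
            cur = dec["up"].forward(cur, train=train)
            skip = skips[-(i + 1)]
            cur = np.concatenate([skip, cur], axis=1)
            for ly in dec["convs"]:
                cur = ly.forward(cur, train=train)
        seg_logits = self.seg_head.forward(cur, train=train)
        return seg_logits, class_logits

    def backward(self, dseg_logits, dclass_logits):
        dskip_grads = [None] * len(self._skips)
        dcur = self.seg_head.backward(dseg_logits)
        dpooled = self.fc.backward(dclass_logits)
        n_ch = self.fc.params["W"].shape[0] // (2 if self.gmp is not None else 1)
        dclass = self.gap.backward(dpooled[:, :n_ch])
        if self.gmp is not None:
            dclass = dclass + self.gmp.backward(dpooled[:, n_ch:])
        for i in range(len(self.dec_blocks) - 1, -1, -1):
            dec = self.dec_blocks[i]
            for ly in reversed(dec["convs"]):
                dcur = ly.backward(dcur)
            ch = dec["ch"]
            dskip_grads[len(self._skips) - 1 - i] = dcur[:, :ch]
            dcur = dec["up"].backward(dcur[:, ch:])
        if self.bottleneck_dropout is not None:
            dcur = self.bottleneck_dropout.backward(dcur)
        dcur = dcur + dclass
        for b in range(len(self.enc_blocks) - 1, -1, -1):
            if b < len(self.enc_blocks) - 1:
                dcur = self.pools[b].backward(dcur)
                dcur = dcur + dskip_grads[b]
            for ly in reversed(self.enc_blocks[b]):
                dcur = ly.backward(dcur)
        return dcur


def build_unet(cfg: UNetConfig, seed: int | None = None) -> UNet:
    """Instantiate a seeded network from its config."""
    return UNet(cfg, np.random.default_rng(seed))


class UNetClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style wrapper training the dual-head U-Net on phantoms.

    ``X`` is an array of greyscale slices, shape ``(n, side, side)``, values
    on [0, 255]; ``y`` are string or integer class labels; ``masks`` (passed
    to :meth:`fit`) are optional binary tumor masks enabling the
    segmentation head.

    Attributes (after fit): ``classes_``, ``model_``, ``history_`` (per-epoch
    classification/segmentation losses), ``config_``.
    """

    def __init__(self, n_encoder_blocks=5, base_channels=64, dropout_rate=0.5,
                 epochs=30, lr=2e-3, batch_size=2, seg_loss_weight=1.0,
                 augment=True, class_head="avgmax", classes=None,
                 random_state=None):
        self.n_encoder_blocks = n_encoder_blocks
        self.base_channels = base_channels
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seg_loss_weight = seg_loss_weight
        self.augment = augment
        self.class_head = class_head
        self.classes = classes
        self.random_state = random_state

    def _prepare(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_images, side, side)")
        return (X / 255.0)[:, None]  # (n, 1, H, W)

    def fit(self, X, y, masks=None):
        Xp = self._prepare(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes is not None:
            missing = set(self.classes) - set(self.classes_)
            if missing:
                raise ValueError(
                    f"classes absent from the training set: {sorted(missing)}"
                )
            self.classes_ = np.asarray(self.classes)
        if self.classes_.size < 2:
            raise ValueError("training needs at least two classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        t = np.array([class_index[c] for c in y])

        cfg = UNetConfig(
            n_encoder_blocks=self.n_encoder_blocks,
            base_channels=self.base_channels,
            dropout_rate=self.dropout_rate,
            n_classes=self.classes_.size,
            input_side=Xp.shape[-1],
            class_head=self.class_head,
        )
        rng = np.random.default_rng(self.random_state)
        self.model_ = UNet(cfg, rng)
        self.config_ = cfg
        self.history_ = []
        if self.epochs == 0:
            return self

        if masks is not None:
            masks = np.asarray(masks, dtype=np.float64)[:, None]
        opt = nn.Adam(self.model_.layers(), lr=self.lr)
        n = Xp.shape[0]
        for epoch in range(self.epochs):
            # cosine decay stabilises the late-training trajectory
            opt.lr = self.lr * 0.5 * (1 + np.cos(np.pi * epoch / self.epochs))
            order = rng.permutation(n)
            cls_losses, seg_losses = [], []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = Xp[idx]
                mb = masks[idx] if masks is not None else None
                if self.augment:
                    # random dihedral-group transforms (rotations by 90
                    # degrees plus flips), applied jointly to image and mask
                    xb = xb.copy()
                    mb = mb.copy() if mb is not None else None
                    for s in range(len(idx)):
                        k = int(rng.integers(0, 4))
                        flip = int(rng.integers(0, 2))
                        if k:
                            xb[s] = np.rot90(xb[s], k, axes=(1, 2))
                        if flip:
                            xb[s] = np.flip(xb[s], axis=2)
                        if mb is not None:
                            if k:
                                mb[s] = np.rot90(mb[s], k, axes=(1, 2))
                            if flip:
                                mb[s] = np.flip(mb[s], axis=2)
                seg_logits, cls_logits = self.model_.forward(xb, train=True)
                cls_loss, dcls = nn.softmax_cross_entropy(cls_logits, t[idx])
                if mb is not None:
                    seg_loss, dseg = nn.sigmoid_bce(seg_logits, mb)
                    dseg = dseg * self.seg_loss_weight
                else:
                    seg_loss, dseg = 0.0, np.zeros_like(seg_logits)
                self.model_.backward(dseg, dcls)
                opt.step()
                cls_losses.append(cls_loss)
                seg_losses.append(seg_loss)
            self.history_.append({
                "epoch": epoch + 1,
                "classification_loss": float(np.mean(cls_losses)),
                "segmentation_loss": float(np.mean(seg_losses)),
            })
        return self

    def _forward_eval(self, X):
        check_is_fitted(self, "model_")
        Xp = self._prepare(X)
        if Xp.shape[-1] != self.config_.input_side:
            raise ValueError(
                f"image side {Xp.shape[-1]} does not match the fitted "
                f"input side {self.config_.input_side}"
            )
        return self.model_.forward(Xp, train=False)

    def predict_proba(self, X):
        _, cls_logits = self._forward_eval(X)
        return nn.softmax(cls_logits)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_seg(self, X):
        """Per-pixel tumor probability maps in [0, 1], shape (n, side, side)."""
        from scipy.special import expit

        seg_logits, _ = self._forward_eval(X)
        return expit(seg_logits[:, 0])
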