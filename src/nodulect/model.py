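"""Two-branch fusion classifier: 3D residual CNN + radiomics MLP.

The visual branch is a 3D ResNet-50-style backbone (7x7x7 stride-2 stem,
3x3x3 stride-2 max pool, four bottleneck stages repeated 3/4/6/3, global
average pooling, linear projection to 256); the radiomics branch is an
MLP mapping the 107-d feature vector to 256.  The two embeddings are
concatenated (512-d), passed through dropout and a single-logit sigmoid
prediction layer.

The nominal stage geometry (128 -> 56 -> 28 -> 14 -> 7 feature-map
sides) corresponds to a 256^3 input; the backbone is fully
convolutional, so any input side with the same stride pattern works and
the parameter count does not depend on it.  ``width_multiplier`` scales
channel counts for desk-scale experiments.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .augment import AugmentPolicy, augment_cube

__all__ = ["FusionModelConfig", "FusionNet", "FusionNoduleClassifier",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class FusionModelConfig:
    """Architecture hyperparameters (defaults follow the nominal design)."""

    input_side: int = 64
    stage_blocks: Tuple[int, int, int, int] = (3, 4, 6, 3)
    stage_channels: Tuple[Tuple[int, int], ...] = ((64, 256), (128, 512), (256, 1024), (512, 2048))
    stem_channels: int = 64
    width_multiplier: float = 1.0
    radiomics_dim: int = 107
    branch_dim: int = 256
    dropout: float = 0.5
    use_radiomics: bool = True

    @property
    def fused_dim(self) -> int:
        return 2 * self.branch_dim if self.use_radiomics else self.branch_dim

    def scaled(self, c: int) -> int:
        return max(1, int(round(c * self.width_multiplier)))


def _walk(layer: nn.Layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for child in layer.layers:
            yield from _walk(child)
    elif isinstance(layer, nn.Bottleneck):
        yield from _walk(layer.main)
        if layer.skip is not None:
            yield from _walk(layer.skip)


class FusionNet:
    """The assembled network with explicit forward/backward passes."""

    def __init__(self, cfg: FusionModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)

        stem_c = cfg.scaled(cfg.stem_channels)
        layers: List[nn.Layer] = [
            nn.Conv3d(1, stem_c, 7, stride=2, pad=3, rng=rng, dtype=dtype),
            nn.BatchNorm3d(stem_c, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool3d(3, stride=2, pad=1),
        ]
        cin = stem_c
        for stage_idx, (n_blocks, (cmid, cout)) in enumerate(zip(cfg.stage_blocks, cfg.stage_channels)):
            cmid, cout = cfg.scaled(cmid), cfg.scaled(cout)
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                layers.append(nn.Bottleneck(cin, cmid, cout, stride=stride, rng=rng, dtype=dtype))
                cin = cout
        layers.append(nn.GlobalAvgPool())
        self.visual = nn.Sequential(*layers)
        self.fc_vis = nn.Linear(cin, cfg.branch_dim, rng=rng, dtype=dtype)

        if cfg.use_radiomics:
            self.mlp: nn.Sequential | None = nn.Sequential(
                nn.Linear(cfg.radiomics_dim, cfg.branch_dim, rng=rng, dtype=dtype), nn.ReLU(),
                nn.Linear(cfg.branch_dim, cfg.branch_dim, rng=rng, dtype=dtype), nn.ReLU(),
            )
        else:
            self.mlp = None
        self.dropout = nn.Dropout(cfg.dropout, rng=rng)
        self.head = nn.Linear(cfg.fused_dim, 1, rng=rng, dtype=dtype)

    # ------------------------------------------------------------------
    def roots(self) -> List[nn.Layer]:
        roots = [self.visual, self.fc_vis, self.head]
        if self.mlp is not None:
            roots.insert(2, self.mlp)
        return roots

    def forward(self, cubes: np.ndarray, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for (N, S, S, S) cubes and (N, radiomics_dim) features."""
        cubes = np.asarray(cubes, dtype=self.dtype)
        feats = np.asarray(feats, dtype=self.dtype)
        if not (np.all(np.isfinite(cubes)) and np.all(np.isfinite(feats))):
            raise ValueError("non-finite network inputs")
        if cubes.ndim == 4:
            cubes = cubes[:, None]
        if feats.shape[1] != self.cfg.radiomics_dim:
            raise ValueError(
                f"feature dimension {feats.shape[1]} != radiomics_dim {self.cfg.radiomics_dim}")
        v = self.fc_vis.forward(self.visual.forward(cubes, train=train), train=train)
        self.visual_embedding_ = v
        if self.mlp is not None:
            r = self.mlp.forward(feats, train=train)
            self.radiomics_embedding_ = r
            fused = np.concatenate([v, r], axis=1)
        else:
            self.radiomics_embedding_ = None
            fused = v
        fused = self.dropout.forward(fused, train=train)
        return self.head.forward(fused, train=train)[:, 0]

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits[:, None].astype(self.dtype))
        g = self.dropout.backward(g)
        if self.mlp is not None:
            gv, gr = np.split(g, 2, axis=1)
            self.mlp.backward(gr)
        else:
            gv = g
        self.visual.backward(self.fc_vis.backward(gv))

    def predict_proba(self, cubes: np.ndarray, feats: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Malignancy probabilities in eval mode (deterministic)."""
        out = []
        for i in range(0, len(feats), batch_size):
            z = self.forward(cubes[i:i + batch_size], feats[i:i + batch_size], train=False)
            out.append(nn.sigmoid(z))
        return np.concatenate(out)

    # ------------------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, root in enumerate(self.roots()):
            for name, layer, key in root.named_params(f"root{i}."):
                state[name] = layer.params[key].copy()
            for j, lay in enumerate(_walk(root)):
                if isinstance(lay, nn.BatchNorm3d):
                    state[f"bn{i}.{j}.mean"] = lay.running_mean.copy()
                    state[f"bn{i}.{j}.var"] = lay.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, root in enumerate(self.roots()):
            for name, layer, key in root.named_params(f"root{i}."):
                layer.params[key] = state[name].astype(layer.params[key].dtype).copy()
            for j, lay in enumerate(_walk(root)):
                if isinstance(lay, nn.BatchNorm3d):
                    lay.running_mean = state[f"bn{i}.{j}.mean"].copy()
                    lay.running_var = state[f"bn{i}.{j}.var"].copy()

    def n_params(self) -> int:
        return sum(layer.params[key].size
                   for root in self.roots() for _, layer, key in root.named_params())


def save_checkpoint(path: str, net: FusionNet) -> None:
    """Serialise weights plus the full config (echoed as JSON)."""
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(net.cfg)).encode(), dtype=np.uint8).copy()
    np.savez(path if path.endswith(".npz") else path + ".npz", **state)


def load_checkpoint(path: str, expected: FusionModelConfig | None = None) -> FusionNet:
    """Rebuild a network from a checkpoint; refuses config mismatches."""
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    cfg_d = json.loads(bytes(data["__config__"]).decode())
    cfg_d["stage_blocks"] = tuple(cfg_d["stage_blocks"])
    cfg_d["stage_channels"] = tuple(tuple(c) for c in cfg_d["stage_channels"])
    cfg = FusionModelConfig(**cfg_d)
    if expected is not None and cfg != expected:
        raise ValueError("checkpoint config does not match the expected model config")
    net = FusionNet(cfg)
    net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net


class FusionNoduleClassifier(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator around :class:`FusionNet`.

    ``X`` is a tuple ``(cubes, features)``: gray cubes of shape
    ``(n, side, side, side)`` on the 0..255 scale (scaled internally to
    [0, 1]) and a ``(n, radiomics_dim)`` feature matrix (standardised
    internally with train-set statistics).  ``y`` holds 0 = benign,
    1 = malignant.

    Training follows the printed recipe: Adam (beta1 0.9, beta2 0.999),
    initial learning rate 1e-3 multiplied by 0.9 every 10 epochs, batch
    size 16, dropout 0.5, binary cross-entropy, with class-conditional
    cube augmentation re-drawn each epoch; the weights retained are the
    ones with the best validation accuracy.
    """

    def __init__(self, input_side: int = 64, width_multiplier: float = 1.0,
                 radiomics_dim: int = 107, branch_dim: int = 256, dropout: float = 0.5,
                 epochs: int = 100, batch_size: int = 16, lr: float = 1e-3,
                 lr_decay: float = 0.9, lr_step: int = 10,
                 beta1: float = 0.9, beta2: float = 0.999,
                 val_fraction: float = 0.2, augment: bool = True,
                 use_radiomics: bool = True,
                 policy: AugmentPolicy | None = None, random_state: int = 0) -> None:
        self.input_side = input_side
        self.width_multiplier = width_multiplier
        self.radiomics_dim = radiomics_dim
        self.branch_dim = branch_dim
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_step = lr_step
        self.beta1 = beta1
        self.beta2 = beta2
        self.val_fraction = val_fraction
        self.augment = augment
        self.use_radiomics = use_radiomics
        self.policy = policy
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> FusionModelConfig:
        return FusionModelConfig(
            input_side=self.input_side, width_multiplier=self.width_multiplier,
            radiomics_dim=self.radiomics_dim, branch_dim=self.branch_dim,
            dropout=self.dropout, use_radiomics=self.use_radiomics,
        )

    @staticmethod
    def _unpack(X) -> Tuple[np.ndarray, np.ndarray]:
        cubes, feats = X
        cubes = np.asarray(cubes, dtype=np.float64)
        feats = np.asarray(feats, dtype=np.float64)
        if cubes.ndim != 4 or cubes.shape[0] != feats.shape[0]:
            raise ValueError("X must be (cubes (n,s,s,s), features (n,d)) with matching n")
        return cubes, feats

    def fit(self, X, y) -> "FusionNoduleClassifier":
        from .train_eval import lr_at_epoch  # local import: train_eval imports this module

        cubes, feats = self._unpack(X)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes to train the fusion classifier")
        if cubes.shape[1] != self.input_side:
            raise ValueError(f"cube side {cubes.shape[1]} != input_side {self.input_side}")
        rng = np.random.default_rng(self.random_state)

        # feature standardisation on the training statistics
        self.feat_mean_ = feats.mean(axis=0)
        self.feat_std_ = feats.std(axis=0)
        self.feat_std_[self.feat_std_ == 0] = 1.0
        feats_n = (feats - self.feat_mean_) / self.feat_std_
        cubes_n = cubes / 255.0

        n = len(y)
        # stratified holdout used only to pick the retained weights
        if self.val_fraction > 0 and n >= 10:
            val_idx: List[int] = []
            for c in self.classes_:
                idx_c = np.flatnonzero(y == c)
                idx_c = idx_c[rng.permutation(len(idx_c))]
                k = max(1, int(round(self.val_fraction * len(idx_c))))
                val_idx.extend(idx_c[:k])
            val_mask = np.zeros(n, dtype=bool)
            val_mask[val_idx] = True
        else:
            val_mask = np.zeros(n, dtype=bool)
        tr = np.flatnonzero(~val_mask)
        va = np.flatnonzero(val_mask)

        net = FusionNet(self._config(), rng=np.random.default_rng(rng.integers(2 ** 31)))
        opt = nn.Adam(net.roots(), lr=self.lr, beta1=self.beta1, beta2=self.beta2)
        self.n_params_ = net.n_params()
        policy = self.policy or AugmentPolicy()
        aug_rng = np.random.default_rng(rng.integers(2 ** 31))

        self.history_ = {"loss": [], "train_acc": [], "val_acc": [], "lr": []}
        best_acc, best_state, best_epoch = -1.0, None, -1
        for epoch in range(self.epochs):
            lr = lr_at_epoch(self.lr, epoch, decay=self.lr_decay, step=self.lr_step)
            order = tr[rng.permutation(len(tr))]
            losses = []
            for i in range(0, len(order), self.batch_size):
                batch = order[i:i + self.batch_size]
                cb = cubes_n[batch]
                if self.augment:
                    cb = np.stack([
                        augment_cube(c, int(lbl), policy, aug_rng)
                        for c, lbl in zip(cb, y[batch])
                    ])
                z = net.forward(cb, feats_n[batch], train=True)
                loss, gz = nn.bce_with_logits(z, y[batch])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training loss became non-finite at epoch {epoch}")
                losses.append(loss)
                net.backward(gz)
                opt.step(lr)

            p_tr = net.predict_proba(cubes_n[tr], feats_n[tr], self.batch_size)
            train_acc = float(np.mean((p_tr >= 0.5) == (y[tr] == 1)))
            if len(va):
                p_va = net.predict_proba(cubes_n[va], feats_n[va], self.batch_size)
                val_acc = float(np.mean((p_va >= 0.5) == (y[va] == 1)))
            else:
                val_acc = train_acc
            self.history_["loss"].append(float(np.mean(losses)))
            self.history_["train_acc"].append(train_acc)
            self.history_["val_acc"].append(val_acc)
            self.history_["lr"].append(lr)
            if val_acc > best_acc:
                best_acc, best_epoch = val_acc, epoch
                best_state = net.state_dict()

        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.best_val_accuracy_ = best_acc
        return self

    # ------------------------------------------------------------------
    def _scores(self, X) -> np.ndarray:
        cubes, feats = self._unpack(X)
        feats_n = (feats - self.feat_mean_) / self.feat_std_
        return self.net_.predict_proba(cubes / 255.0, feats_n, self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        s = self._scores(X)
        return np.column_stack([1.0 - s, s])

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        return (self._scores(X) >= 0.5).astype(np.int64)

    def save(self, path: str) -> None:
        save_checkpoint(path, self.net_)
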