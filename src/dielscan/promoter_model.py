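"""Convolutional-recurrent model of rhythmicity from promoter sequence.

The architecture follows the DanQ family: a 1-D convolution over one-hot
DNA (valid mode; exponential first-layer activation by default),
max-pooling, a bidirectional LSTM over the pooled positions, a
position-invariant max+mean temporal readout, and a dense head that
regresses three
continuous rhythmicity labels per promoter: relative amplitude (A/M),
-log10 of the rhythmicity p-value (capped), and the cosinor R^2.  Labels
are standardized internally during training so no single output dominates
the summed mean-squared-error loss.

Trained first-layer filters are converted to sequence motifs by
activation alignment: subsequences at positions where a filter activates
at >= half its maximum are stacked into a position frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MotifPFM
from .nn import Adam, Tensor, concat

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "one_hot_encode",
    "p_transform",
    "PromoterRhythmNet",
    "train_model",
    "predict",
    "conv_activations",
    "filters_to_motifs",
    "motif_match_score",
    "iupac_to_pfm",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def one_hot_encode(seq: str) -> np.ndarray:
    """One-hot encode DNA to a 4 x L matrix; N becomes a 0.25 column."""
    out = np.zeros((4, len(seq)), dtype=np.float64)
    for j, ch in enumerate(seq.upper()):
        if ch == "N":
            out[:, j] = 0.25
        elif ch in _BASE_INDEX:
            out[_BASE_INDEX[ch], j] = 1.0
        else:
            raise ValueError(f"invalid base {ch!r} at position {j}")
    return out


def p_transform(p, cap: float = 20.0) -> np.ndarray:
    """-log10(p) capped, the label transform for the p-value output."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.minimum(-np.log10(p), cap)


@dataclass
class ModelConfig:
    """Desk-scale defaults: trainable in minutes on one CPU while keeping
    the conv -> pool -> BiLSTM -> dense topology."""

    seq_len: int = 1500
    n_filters: int = 32
    filter_width: int = 13
    pool_width: int = 6
    recurrent_units: int = 16
    dense_units: int = 32
    n_outputs: int = 3
    conv_activation: str = "exp"  # "exp" sharpens filter motifs; or "relu"
    epochs: int = 20
    learning_rate: float = 7e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.n_outputs != 3:
            raise ValueError("the model regresses exactly 3 labels")
        if self.filter_width > self.seq_len:
            raise ValueError("filter wider than the sequence")


class PromoterRhythmNet:
    """conv -> max-pool -> BiLSTM -> max+mean readout -> dense head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        F, W = config.n_filters, config.filter_width
        H, D = config.recurrent_units, config.dense_units

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=shape))

        self.conv_w = glorot(4 * W, F, (4 * W, F))
        self.conv_b = Tensor(np.zeros(F))
        self.lstm = {}
        for d in ("fwd", "bwd"):
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias
            self.lstm[d] = {
                "Wx": glorot(F, 4 * H, (F, 4 * H)),
                "Wh": glorot(H, 4 * H, (H, 4 * H)),
                "b": Tensor(b),
            }
        self.n_steps = (config.seq_len - W + 1) // config.pool_width
        self.w1 = glorot(4 * H, D, (4 * H, D))
        self.b1 = Tensor(np.zeros(D))
        self.w2 = glorot(D, config.n_outputs, (D, config.n_outputs))
        self.b2 = Tensor(np.zeros(config.n_outputs))
        self._patch_index = self._build_patch_index(config.seq_len, W)

    @staticmethod
    def _build_patch_index(L: int, W: int) -> np.ndarray:
        """(P, 4W) flat indices into a flattened (4, L) one-hot array."""
        P = L - W + 1
        # flat index of base c at offset k from position p is p + c*L + k
        base = (np.arange(4)[:, None] * L
                + np.arange(W)[None, :]).reshape(-1)
        return np.arange(P)[:, None] + base[None, :]

    def parameters(self) -> list[Tensor]:
        out = [self.conv_w, self.conv_b, self.w1, self.b1, self.w2,
               self.b2]
        for d in ("fwd", "bwd"):
            out += [self.lstm[d]["Wx"], self.lstm[d]["Wh"],
                    self.lstm[d]["b"]]
        return out

    def _lstm_pass(self, steps: list[Tensor],
                   direction: str) -> list[Tensor]:
        """Run one LSTM direction; returns the hidden state at every
        position, in temporal order."""
        H = self.config.recurrent_units
        p = self.lstm[direction]
        B = steps[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        order = steps if direction == "fwd" else steps[::-1]
        states = []
        for x_t in order:
            z = x_t @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = z[:, :H].sigmoid()
            f = z[:, H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            states.append(h)
        return states if direction == "fwd" else states[::-1]

    def forward(self, X: np.ndarray) -> Tensor:
        """X is a (B, 4, L) one-hot batch; returns a (B, 3) Tensor."""
        cfg = self.config
        B, _, L = X.shape
        if L != cfg.seq_len:
            raise ValueError(f"expected sequences of length {cfg.seq_len}")
        flat = Tensor(X.reshape(B, 4 * L))
        patches = flat[:, self._patch_index]          # (B, P, 4W)
        P = patches.shape[1]
        pre = (patches.reshape(B * P, 4 * cfg.filter_width) @ self.conv_w
               + self.conv_b)
        # an exponential first-layer activation concentrates gradient on
        # the strongest sequence matches, which drives filters toward
        # whole motifs; ReLU is available as an alternative
        act = pre.exp() if cfg.conv_activation == "exp" else pre.relu()
        conv = act.reshape(B, P, cfg.n_filters)
        T = P // cfg.pool_width
        pooled = conv[:, : T * cfg.pool_width, :].reshape(
            B, T, cfg.pool_width, cfg.n_filters).max(axis=2)
        steps = [pooled[:, t, :] for t in range(T)]
        states = [concat([hf, hb], axis=1) for hf, hb in
                  zip(self._lstm_pass(steps, "fwd"),
                      self._lstm_pass(steps, "bwd"))]
        # position-invariant readout: max and mean over time of the
        # BiLSTM output (a motif may sit anywhere in the promoter)
        stacked = concat([s.reshape(B, 1, 2 * self.config.recurrent_units)
                          for s in states], axis=1)
        feat = concat([stacked.max(axis=1), stacked.mean(axis=1)], axis=1)
        hidden = (feat @ self.w1 + self.b1).relu()
        return hidden @ self.w2 + self.b2

    def predict_array(self, X: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        outs = []
        for lo in range(0, len(X), batch_size):
            outs.append(self.forward(X[lo:lo + batch_size]).data)
        return np.concatenate(outs, axis=0)


@dataclass
class TrainedModel:
    model: PromoterRhythmNet
    config: ModelConfig
    history: pd.DataFrame
    label_mean: np.ndarray
    label_std: np.ndarray
    train_genotypes: list = field(default_factory=list)
    val_genotypes: list = field(default_factory=list)


def _genotype_split(genotypes, rng, val_genotypes=None):
    unique = sorted(set(genotypes))
    if len(unique) < 2:
        raise ValueError("need >= 2 genotypes for a genotype-level split")
    if val_genotypes is None:
        n_val = max(1, round(len(unique) / 4))
        val_genotypes = sorted(
            rng.choice(unique, size=n_val, replace=False).tolist())
    val_set = set(val_genotypes)
    genotypes = np.asarray(genotypes)
    val_mask = np.isin(genotypes, list(val_set))
    if val_mask.all() or not val_mask.any():
        raise ValueError("genotype split left train or validation empty")
    return ~val_mask, val_mask, sorted(set(unique) - val_set), \
        sorted(val_set)


def train_model(sequences, labels, genotypes, config: ModelConfig,
                val_genotypes=None) -> TrainedModel:
    """Train the promoter model with a genotype-level train/val split.

    ``sequences`` are DNA strings (all of ``config.seq_len``), ``labels``
    an (n, 3) array of (relative amplitude, -log10 p capped, R^2), and
    ``genotypes`` the genotype each promoter allele comes from (alleles
    of one genotype never straddle the split).
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != 3:
        raise ValueError("labels must be (n, 3)")
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    rng = np.random.default_rng(config.seed)
    train_mask, val_mask, train_g, val_g = _genotype_split(
        genotypes, rng, val_genotypes)

    X = np.stack([one_hot_encode(s) for s in sequences])
    mean = labels[train_mask].mean(axis=0)
    std = labels[train_mask].std(axis=0)
    std = np.where(std > 1e-8, std, 1.0)
    Y = (labels - mean) / std

    Xtr, Ytr = X[train_mask], Y[train_mask]
    Xva, Yva = X[val_mask], Y[val_mask]

    model = PromoterRhythmNet(config)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    hist = []
    n_tr = len(Xtr)
    for epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        losses = []
        for lo in range(0, n_tr, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            pred = model.forward(Xtr[idx])
            diff = pred - Tensor(Ytr[idx])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_pred = model.predict_array(Xva)
        val_loss = float(np.mean((val_pred - Yva) ** 2))
        hist.append((epoch, float(np.mean(losses)), val_loss))
    history = pd.DataFrame(hist, columns=["epoch", "train_loss",
                                          "val_loss"])
    return TrainedModel(model, config, history, mean, std, train_g, val_g)


def predict(trained: TrainedModel, sequences) -> np.ndarray:
    """Predicted labels on the original (unstandardized) scale."""
    X = np.stack([one_hot_encode(s) for s in sequences])
    z = trained.model.predict_array(X)
    return z * trained.label_std + trained.label_mean


def conv_activations(model: PromoterRhythmNet,
                     X: np.ndarray) -> np.ndarray:
    """First-layer activations, (B, P, n_filters); plain numpy."""
    cfg = model.config
    B = X.shape[0]
    flat = X.reshape(B, 4 * cfg.seq_len)
    patches = flat[:, model._patch_index]
    act = patches @ model.conv_w.data + model.conv_b.data
    if cfg.conv_activation == "exp":
        return np.exp(np.clip(act, -60.0, 60.0))
    return np.maximum(act, 0.0)


def filters_to_motifs(model, sequences, activation_fraction: float = 0.5,
                      min_sites: int = 10, pseudocount: float = 1.0,
                      batch_size: int = 64) -> list[MotifPFM]:
    """Convert trained convolutional filters to sequence motifs.

    Each filter is scanned over the sequences; the filter-width
    subsequences at positions activating at >= ``activation_fraction``
    of that filter's maximum are stacked into a position frequency
    matrix with a pseudocount.  Filters with fewer than ``min_sites``
    activating positions are dropped.
    """
    if isinstance(model, TrainedModel):
        model = model.model
    if len(sequences) < 1:
        raise ValueError("no sequences given")
    cfg = model.config
    W, F = cfg.filter_width, cfg.n_filters
    X = np.stack([one_hot_encode(s) for s in sequences])

    maxima = np.zeros(F)
    for lo in range(0, len(X), batch_size):
        act = conv_activations(model, X[lo:lo + batch_size])
        maxima = np.maximum(maxima, act.max(axis=(0, 1)))
    if np.all(maxima == 0):
        raise ValueError("filters never activate; is the model trained?")

    counts = np.zeros((F, 4, W))
    n_sites = np.zeros(F, dtype=int)
    for lo in range(0, len(X), batch_size):
        chunk = X[lo:lo + batch_size]
        act = conv_activations(model, chunk)
        for f in range(F):
            if maxima[f] <= 0:
                continue
            b_idx, p_idx = np.nonzero(
                act[:, :, f] >= activation_fraction * maxima[f])
            for b, p in zip(b_idx, p_idx):
                counts[f] += chunk[b, :, p:p + W]
                n_sites[f] += 1

    motifs = []
    for f in range(F):
        if n_sites[f] < min_sites:
            continue
        mat = counts[f] + pseudocount
        mat /= mat.sum(axis=0, keepdims=True)
        motifs.append(MotifPFM(mat, name=f"filter{f}",
                               n_sites=int(n_sites[f])))
    return motifs


def iupac_to_pfm(pattern: str, name: str = "") -> MotifPFM:
    """IUPAC consensus to a PFM, uniform over the allowed bases."""
    cols = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r}")
        col = np.zeros(4)
        for b in IUPAC[ch]:
            col[_BASE_INDEX[b]] = 1.0
        cols.append(col / col.sum())
    return MotifPFM(np.column_stack(cols), name=name or pattern)


def _column_corr(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx < 1e-12 or ny < 1e-12:
        return 0.0
    return float(xc @ yc / (nx * ny))


def motif_match_score(pfm: MotifPFM, reference,
                      min_overlap: int = 5) -> float:
    """Best mean per-column Pearson correlation over all ungapped
    alignments of the PFM against the reference (both strands)."""
    if isinstance(reference, str):
        reference = iupac_to_pfm(reference)
    q = pfm.matrix
    best = -np.inf
    for ref in (reference.matrix, reference.reverse_complement().matrix):
        wq, wr = q.shape[1], ref.shape[1]
        for shift in range(-(wr - min_overlap), wq - min_overlap + 1):
            lo = max(0, shift)
            hi = min(wq, shift + wr)
            if hi - lo < min_overlap:
                continue
            cols = [
                _column_corr(q[:, i], ref[:, i - shift])
                for i in range(lo, hi)
            ]
            best = max(best, float(np.mean(cols)))
    if not np.isfinite(best):
        raise ValueError("no alignment with sufficient overlap")
    return best


def labels_from_rhythm(rhythm: pd.DataFrame, cap: float = 20.0
                       ) -> pd.DataFrame:
    """(relamp, -log10 p capped, R^2) labels from a rhythmicity scan,
    indexed by (gene_id, genotype_id); rows with undefined relative
    amplitude are dropped."""
    df = rhythm.set_index(["gene_id", "genotype_id"])
    out = pd.DataFrame({
        "relamp": df["relamp"],
        "neglog10_p": p_transform(df["pvalue"].to_numpy(), cap=cap),
        "r2": df["r2"],
    })
    return out.dropna()
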