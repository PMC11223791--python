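"""The Siamese regressor and its training loop, prediction and scanning drivers.

Two weight-shared sub-networks score the forward (WT->Mut) and reverse
(Mut->WT) directions of the same variant; the reported prediction is
``(f - r) / 2`` and training minimizes the anti-symmetric loss

    loss = log cosh((f - r)/2 - y) + |f + r|

which is zero exactly when ``f = y`` and ``r = -y``.  Each sub-network
combines a graph-convolutional branch over the interface graph, a
convolution + transformer-encoder branch over the cutoff-scanning
signature, and dense layers over the tabular features; branches can be
switched off individually for ablation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Parameter, Tensor, concat
from .features import Normalizer
from .interface import interface_residues
from .pipeline import DirectionInputs, FeatureDataset, FeaturePipeline, PairFeatures
from .structures import ComplexStructure, MutationSpec, THREE_TO_ONE

AA20 = sorted("ACDEFGHIKLMNPQRSTVWY")


class SpecError(ValueError):
    """Invalid mutation list for a prediction driver."""


class ConfigError(ValueError):
    """Model configuration without any enabled branch."""


def antisymmetric_loss(f: float, r: float, y: float) -> float:
    """Anti-symmetric contrastive loss (numerically stable log-cosh form)."""
    f, r, y = float(f), float(r), float(y)
    if not np.all(np.isfinite([f, r, y])):
        raise ValueError("antisymmetric_loss requires finite inputs")
    x = (f - r) / 2.0 - y
    # clamp at 0: the stable form can round to -1e-16 for tiny |x|
    logcosh = max(0.0, abs(x) + np.log1p(np.exp(-2.0 * abs(x))) - np.log(2.0))
    return logcosh + abs(f + r)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and component switches; defaults are package choices."""

    gcn_hidden: tuple[int, ...] = (64, 64)
    gcn_out: int = 32
    sig_channels: int = 32
    sig_kernel: int = 3
    transformer_heads: int = 4
    transformer_ff: int = 64
    use_conv: bool = True
    use_transformer: bool = True
    dense_hidden: tuple[int, ...] = (128, 128)
    dense_out: int = 32
    head_hidden: tuple[int, ...] = (64,)
    learning_rate: float = 3e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    use_gcn: bool = True
    use_signature: bool = True
    use_dense: bool = True
    weighted_adjacency: bool = True

    def __post_init__(self) -> None:
        if not (self.use_gcn or self.use_signature or self.use_dense):
            raise ConfigError("at least one branch must be enabled")
        if self.transformer_heads < 1 or self.sig_channels % self.transformer_heads:
            raise ConfigError("sig_channels must be divisible by transformer_heads")


@dataclass
class SiamesePrediction:
    f: float  # forward-direction sub-network output (kcal/mol)
    r: float  # reverse-direction sub-network output (kcal/mol)

    @property
    def reported(self) -> float:
        return (self.f - self.r) / 2.0


class SiameseNetwork:
    """Weight-shared sub-network applied to each direction's inputs."""

    def __init__(self, config: ModelConfig, embed_dim: int, n_cutoffs: int, tab_dim: int):
        self.config = config
        self.embed_dim = embed_dim
        self.n_cutoffs = n_cutoffs
        self.tab_dim = tab_dim
        self.params: dict[str, Parameter] = {}
        rng = np.random.default_rng(config.seed)
        c = config

        def glorot(name, shape):
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            fan_out = shape[-1]
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.params[name] = Parameter(rng.uniform(-bound, bound, size=shape))

        def zeros(name, shape):
            self.params[name] = Parameter(np.zeros(shape))

        if c.use_gcn:
            prev = embed_dim
            for i, width in enumerate(c.gcn_hidden):
                glorot(f"gcn_w{i}", (prev, width))
                zeros(f"gcn_b{i}", (width,))
                prev = width
            glorot("gcn_wo", (prev, c.gcn_out))
            zeros("gcn_bo", (c.gcn_out,))
        if c.use_signature:
            in_ch = 36
            if c.use_conv:
                glorot("sig_conv_w", (c.sig_kernel * in_ch, c.sig_channels))
            else:
                glorot("sig_conv_w", (in_ch, c.sig_channels))
            zeros("sig_conv_b", (c.sig_channels,))
            if c.use_transformer:
                d, h = c.sig_channels, c.transformer_heads
                dh = d // h
                for i in range(h):
                    glorot(f"attn_wq{i}", (d, dh))
                    glorot(f"attn_wk{i}", (d, dh))
                    glorot(f"attn_wv{i}", (d, dh))
                    glorot(f"attn_wo{i}", (dh, d))
                glorot("ff_w1", (d, c.transformer_ff))
                zeros("ff_b1", (c.transformer_ff,))
                glorot("ff_w2", (c.transformer_ff, d))
                zeros("ff_b2", (d,))
        if c.use_dense:
            prev = tab_dim
            for i, width in enumerate(c.dense_hidden):
                glorot(f"dense_w{i}", (prev, width))
                zeros(f"dense_b{i}", (width,))
                prev = width
            glorot("dense_wo", (prev, c.dense_out))
            zeros("dense_bo", (c.dense_out,))
        head_in = (c.gcn_out if c.use_gcn else 0) \
            + (c.sig_channels if c.use_signature else 0) \
            + (c.dense_out if c.use_dense else 0)
        prev = head_in
        for i, width in enumerate(c.head_hidden):
            glorot(f"head_w{i}", (prev, width))
            zeros(f"head_b{i}", (width,))
            prev = width
        glorot("head_wo", (prev, 1))
        zeros("head_bo", (1,))

    # -- forward -----------------------------------------------------------

    def _gcn_branch(self, x: np.ndarray, a_norm: np.ndarray) -> Tensor:
        c = self.config
        if x.shape[0] == 0:
            return Tensor(np.zeros(c.gcn_out))
        h = Tensor(x)
        a = Tensor(a_norm)
        for i in range(len(c.gcn_hidden)):
            h = (a @ h @ self.params[f"gcn_w{i}"] + self.params[f"gcn_b{i}"]).relu()
        pooled = h.mean(axis=0)
        return (pooled @ self.params["gcn_wo"] + self.params["gcn_bo"]).relu()

    def _signature_branch(self, sig: np.ndarray) -> Tensor:
        c = self.config
        s = sig.reshape(self.n_cutoffs, 36)
        if c.use_conv:
            pad = c.sig_kernel // 2
            padded = np.pad(s, ((pad, pad), (0, 0)))
            unfolded = np.stack([
                padded[i:i + c.sig_kernel].reshape(-1) for i in range(self.n_cutoffs)
            ])  # (L, kernel*36); constant input, so unfolding outside the graph
            h = (Tensor(unfolded) @ self.params["sig_conv_w"] + self.params["sig_conv_b"]).relu()
        else:
            h = (Tensor(s) @ self.params["sig_conv_w"] + self.params["sig_conv_b"]).relu()
        if c.use_transformer:
            d, nheads = c.sig_channels, c.transformer_heads
            x = h
            ln = x.layer_norm()
            attn = None
            for i in range(nheads):
                q = ln @ self.params[f"attn_wq{i}"]
                k = ln @ self.params[f"attn_wk{i}"]
                v = ln @ self.params[f"attn_wv{i}"]
                scores = (q @ k.T) * (1.0 / np.sqrt(d // nheads))
                o = scores.softmax(axis=-1) @ v @ self.params[f"attn_wo{i}"]
                attn = o if attn is None else attn + o
            x = x + attn
            ln2 = x.layer_norm()
            ff = (ln2 @ self.params["ff_w1"] + self.params["ff_b1"]).relu()
            ff = ff @ self.params["ff_w2"] + self.params["ff_b2"]
            h = x + ff
        return h.mean(axis=0)

    def _dense_branch(self, tab: np.ndarray) -> Tensor:
        c = self.config
        h = Tensor(tab)
        for i in range(len(c.dense_hidden)):
            h = (h @ self.params[f"dense_w{i}"] + self.params[f"dense_b{i}"]).relu()
        return h @ self.params["dense_wo"] + self.params["dense_bo"]

    def subnetwork(self, inputs: "NormalizedInputs") -> Tensor:
        c = self.config
        branches = []
        if c.use_gcn:
            branches.append(self._gcn_branch(inputs.node_features, inputs.adjacency_norm))
        if c.use_signature:
            branches.append(self._signature_branch(inputs.signature))
        if c.use_dense:
            branches.append(self._dense_branch(inputs.tabular))
        h = concat(branches)
        for i in range(len(c.head_hidden)):
            h = (h @ self.params[f"head_w{i}"] + self.params[f"head_b{i}"]).relu()
        out = h @ self.params["head_wo"] + self.params["head_bo"]
        return out.reshape(())

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]


@dataclass
class NormalizedInputs:
    node_features: np.ndarray
    adjacency_norm: np.ndarray
    signature: np.ndarray
    tabular: np.ndarray


@dataclass
class TrainState:
    """Trained parameters plus everything needed to reproduce predictions."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    tab_normalizer: Normalizer
    sig_normalizer: Normalizer
    tabular_columns: list[str]
    signature_columns: list[str]
    embed_dim: int
    n_cutoffs: int
    train_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)

    def network(self) -> SiameseNetwork:
        net = SiameseNetwork(self.config, self.embed_dim, self.n_cutoffs,
                             len(self.tabular_columns))
        for name, value in self.params.items():
            net.params[name].data = value.copy()
        return net

    # -- persistence (single-file npz container) ----------------------------

    def save(self, path: str) -> None:
        meta = {
            "config": asdict(self.config),
            "tabular_columns": self.tabular_columns,
            "signature_columns": self.signature_columns,
            "embed_dim": self.embed_dim,
            "n_cutoffs": self.n_cutoffs,
            "train_history": self.train_history,
            "val_history": self.val_history,
            "schema_version": 1,
        }
        arrays = {f"param__{k}": v for k, v in self.params.items()}
        arrays["tab_mean"] = self.tab_normalizer.mean
        arrays["tab_scale"] = self.tab_normalizer.scale
        arrays["sig_mean"] = self.sig_normalizer.mean
        arrays["sig_scale"] = self.sig_normalizer.scale
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainState":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg = meta["config"]
        for key in ("gcn_hidden", "dense_hidden", "head_hidden"):
            cfg[key] = tuple(cfg[key])
        params = {
            k[len("param__"):]: data[k] for k in data.files if k.startswith("param__")
        }
        return cls(
            config=ModelConfig(**cfg),
            params=params,
            tab_normalizer=Normalizer(mean=data["tab_mean"], scale=data["tab_scale"]),
            sig_normalizer=Normalizer(mean=data["sig_mean"], scale=data["sig_scale"]),
            tabular_columns=meta["tabular_columns"],
            signature_columns=meta["signature_columns"],
            embed_dim=meta["embed_dim"],
            n_cutoffs=meta["n_cutoffs"],
            train_history=meta["train_history"],
            val_history=meta["val_history"],
        )


def _normalize_inputs(state_or_normalizers, pair: PairFeatures) -> tuple[NormalizedInputs, NormalizedInputs]:
    tabn, sign = state_or_normalizers

    def one(d: DirectionInputs) -> NormalizedInputs:
        return NormalizedInputs(
            node_features=d.node_features,
            adjacency_norm=d.adjacency_norm,
            signature=np.nan_to_num(sign.transform(d.signature)),
            tabular=np.nan_to_num(tabn.transform(d.tabular)),
        )

    return one(pair.forward), one(pair.reverse)


def forward_pass(net: SiameseNetwork, normalizers, pair: PairFeatures) -> SiamesePrediction:
    """Numeric (no-gradient) Siamese evaluation of one pair."""
    fwd, rev = _normalize_inputs(normalizers, pair)
    f = net.subnetwork(fwd)
    r = net.subnetwork(rev)
    return SiamesePrediction(f=float(f.data), r=float(r.data))


class TrainingError(ValueError):
    pass


def train(
    config: ModelConfig,
    dataset: FeatureDataset,
    train_ids: set[str] | None = None,
    val_ids: set[str] | None = None,
) -> TrainState:
    """Mini-batch Adam on the anti-symmetric loss over forward/reverse pairs.

    ``train_ids``/``val_ids`` select record ids from the dataset (default:
    train on everything).  Feature normalization statistics are fitted on
    the training rows only, both directions pooled.  Deterministic for a
    given config seed.
    """
    pairs = dataset.pairs
    if train_ids is None:
        train_pairs = list(pairs)
    else:
        train_pairs = [p for p in pairs if p.record_id in train_ids]
    if not train_pairs:
        raise TrainingError("empty training fold")
    val_pairs = [p for p in pairs if val_ids and p.record_id in val_ids]

    tab_rows = np.array([d.tabular for p in train_pairs for d in (p.forward, p.reverse)])
    sig_rows = np.array([d.signature for p in train_pairs for d in (p.forward, p.reverse)])
    tabn = Normalizer.fit(tab_rows, columns=dataset.tabular_columns)
    sign = Normalizer.fit(sig_rows, columns=dataset.signature_columns)

    net = SiameseNetwork(config, dataset.embed_dim, dataset.n_cutoffs,
                         len(dataset.tabular_columns))
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    normalized = [_normalize_inputs((tabn, sign), p) for p in train_pairs]
    labels = [p.y for p in train_pairs]
    val_normalized = [_normalize_inputs((tabn, sign), p) for p in val_pairs]

    train_history, val_history = [], []
    n = len(train_pairs)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            losses = []
            for idx in batch:
                fwd, rev = normalized[idx]
                f = net.subnetwork(fwd)
                r = net.subnetwork(rev)
                y = labels[idx]
                losses.append(((f - r) / 2.0 - y).logcosh() + (f + r).abs())
            total = concat([ls.reshape(1) for ls in losses]).mean()
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += float(total.data) * len(batch)
        train_history.append(epoch_loss / n)
        if val_pairs:
            vloss = np.mean([
                antisymmetric_loss(
                    float(net.subnetwork(fwd).data), float(net.subnetwork(rev).data), p.y
                )
                for (fwd, rev), p in zip(val_normalized, val_pairs)
            ])
            val_history.append(float(vloss))

    return TrainState(
        config=config,
        params={k: p.data.copy() for k, p in net.params.items()},
        tab_normalizer=tabn,
        sig_normalizer=sign,
        tabular_columns=dataset.tabular_columns,
        signature_columns=dataset.signature_columns,
        embed_dim=dataset.embed_dim,
        n_cutoffs=dataset.n_cutoffs,
        train_history=train_history,
        val_history=val_history,
    )


# ---------------------------------------------------------------------------
# Prediction drivers
# ---------------------------------------------------------------------------


def predict_pair(state: TrainState, pair: PairFeatures,
                 net: SiameseNetwork | None = None) -> SiamesePrediction:
    net = net or state.network()
    return forward_pass(net, (state.tab_normalizer, state.sig_normalizer), pair)


def predict_single(
    state: TrainState,
    structure: ComplexStructure,
    spec: MutationSpec,
    pipeline: FeaturePipeline,
    mutant: ComplexStructure | None = None,
    net: SiameseNetwork | None = None,
) -> SiamesePrediction:
    pair = pipeline.featurize(structure, [spec], mutant=mutant)
    return predict_pair(state, pair, net=net)


def predict_multiple(
    state: TrainState,
    structure: ComplexStructure,
    specs: list[MutationSpec],
    pipeline: FeaturePipeline,
    net: SiameseNetwork | None = None,
) -> float:
    """Additive multi-mutation prediction: exact sum of single predictions,
    each computed against the original wild-type structure."""
    if not specs:
        raise SpecError("empty mutation list")
    keys = [s.residue_key for s in specs]
    if len(set(keys)) != len(keys):
        raise SpecError("duplicate positions in multi-mutation variant")
    net = net or state.network()
    total = 0.0
    for spec in sorted(specs, key=lambda s: (s.residue_key, s.mut_aa)):
        total += predict_single(state, structure, spec, pipeline, net=net).reported
    return total


def alanine_scan(
    state: TrainState,
    structure: ComplexStructure,
    pipeline: FeaturePipeline,
) -> pd.DataFrame:
    """Predict X->A for every non-alanine interface residue (glycine included)."""
    rows = _scan(state, structure, pipeline, targets=lambda wt: [] if wt == "A" else ["A"])
    return rows


def saturation_scan(
    state: TrainState,
    structure: ComplexStructure,
    pipeline: FeaturePipeline,
) -> pd.DataFrame:
    """Predict all 19 substitutions for every interface residue."""
    return _scan(state, structure, pipeline,
                 targets=lambda wt: [a for a in AA20 if a != wt])


def _scan(state, structure, pipeline, targets) -> pd.DataFrame:
    iface = sorted(interface_residues(structure, pipeline.interface_cutoff))
    if not iface:
        raise SpecError("structure has no interface residues")
    net = state.network()
    rows = []
    for key in iface:
        wt = THREE_TO_ONE.get(structure.residue_name(key))
        if wt is None:
            continue
        for mut in targets(wt):
            spec = MutationSpec(chain_id=key.chain_id, wt_aa=wt,
                                position=key.residue_seq, mut_aa=mut,
                                insertion_code=key.insertion_code)
            pred = predict_single(state, structure, spec, pipeline, net=net)
            rows.append({
                "chain": key.chain_id, "position": key.residue_seq,
                "insertion_code": key.insertion_code, "wt": wt, "mut": mut,
                "predicted_ddg": pred.reported,
            })
    return pd.DataFrame(rows)


def enumerate_multi(
    state: TrainState,
    structure: ComplexStructure,
    pipeline: FeaturePipeline,
    side: set[str],
    order: int = 2,
    top_k: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enumerate all ``order``-fold variants on one side of the interface.

    Returns (top increases, top decreases) ranked tables, each capped at
    ``top_k`` rows, with deterministic lexicographic tie-breaking.
    """
    from itertools import combinations, product

    if order not in (2, 3):
        raise SpecError("order must be 2 or 3")
    iface = [k for k in sorted(interface_residues(structure, pipeline.interface_cutoff))
             if k.chain_id in side]
    if len(iface) < order:
        raise SpecError(f"only {len(iface)} interface positions on side {sorted(side)}")
    net = state.network()
    # score each single substitution once; additivity makes combos exact sums
    singles: dict[tuple, float] = {}
    for key in iface:
        wt = THREE_TO_ONE.get(structure.residue_name(key))
        if wt is None:
            continue
        for mut in [a for a in AA20 if a != wt]:
            spec = MutationSpec(chain_id=key.chain_id, wt_aa=wt,
                                position=key.residue_seq, mut_aa=mut,
                                insertion_code=key.insertion_code)
            singles[(key, mut)] = predict_single(
                state, structure, spec, pipeline, net=net).reported
    positions = sorted({k for k, _ in singles})
    rows = []
    for combo in combinations(positions, order):
        muts_per_pos = [[m for (k, m) in singles if k == pos] for pos in combo]
        for muts in product(*muts_per_pos):
            total = sum(singles[(pos, m)] for pos, m in zip(combo, muts))
            label = "; ".join(
                f"{pos.chain_id} "
                f"{THREE_TO_ONE[structure.residue_name(pos)]}{pos.residue_seq}{m}"
                for pos, m in zip(combo, muts)
            )
            rows.append({"mutations": label, "predicted_ddg": total})
    df = pd.DataFrame(rows)
    inc = df.sort_values(["predicted_ddg", "mutations"],
                         ascending=[False, True]).head(top_k).reset_index(drop=True)
    dec = df.sort_values(["predicted_ddg", "mutations"],
                         ascending=[True, True]).head(top_k).reset_index(drop=True)
    return inc, dec


def ablation_configs(base: ModelConfig) -> dict[str, ModelConfig]:
    """Baseline plus one config per single-branch deactivation."""
    out = {"baseline": base}
    for name, switch in (("no_gcn", "use_gcn"), ("no_signature", "use_signature"),
                         ("no_dense", "use_dense")):
        if not getattr(base, switch):
            continue
        enabled = sum(getattr(base, s) for s in ("use_gcn", "use_signature", "use_dense"))
        if enabled < 2:
            raise ConfigError("ablation would leave zero branches")
        out[name] = replace(base, **{switch: False})
    return out
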