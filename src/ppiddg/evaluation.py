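"""Seven-metric evaluation reports, anti-symmetry diagnostics, permutation
feature importance and the component-ablation harness.

The error conventions: RMSE and MAE are the usual root-mean-square and mean
absolute errors; the mean signed error is oriented as ``prediction - truth``
(so a positive value means systematic over-prediction).  Rank correlations
use tie-corrected conventions (Kendall tau-b, average-rank Spearman).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import stats

from .model import ModelConfig, TrainState, ablation_configs, predict_pair, train
from .pipeline import FeatureDataset


class ShapeError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class MetricReport:
    r_squared: float
    pearson: float
    spearman: float
    kendall: float
    rmse: float
    mae: float
    mse_signed: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def regression_metrics(y_true, y_pred) -> MetricReport:
    """The seven evaluation statistics for predicted vs experimental values.

    ``r_squared`` is ``1 - SS_res / SS_tot`` (can be negative); with constant
    truth the correlations are NaN sentinels while errors are still reported.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ShapeError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ShapeError("need at least 2 observations")
    resid = y_pred - y_true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    mse_signed = float(np.mean(resid))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        pearson = spearman = kendall = r2 = np.nan
        if np.ptp(y_true) > 0:
            r2 = 1.0 - float(np.sum(resid**2) / np.sum((y_true - y_true.mean())**2))
    else:
        pearson = float(stats.pearsonr(y_true, y_pred).statistic)
        spearman = float(stats.spearmanr(y_true, y_pred).statistic)
        kendall = float(stats.kendalltau(y_true, y_pred, variant="b").statistic)
        r2 = 1.0 - float(np.sum(resid**2) / np.sum((y_true - y_true.mean())**2))
    return MetricReport(r_squared=r2, pearson=pearson, spearman=spearman,
                        kendall=kendall, rmse=rmse, mae=mae,
                        mse_signed=mse_signed, n=int(y_true.size))


@dataclass
class AntisymmetryReport:
    """Bias of the Siamese outputs plus direction-stratified sub-reports."""

    bias: float  # mean(f + r) over pairs; 0 for a perfectly anti-symmetric model
    n_pairs: int
    decrease: MetricReport | None = None  # labels y <= 0
    increase: MetricReport | None = None  # labels y > 0


def antisymmetry_report(predictions, labels) -> AntisymmetryReport:
    """Diagnostics over paired (f, r) predictions with forward labels.

    ``predictions`` is a sequence of (f, r) tuples or objects with ``f``/``r``
    attributes, one per forward record.
    """
    fr = []
    for p in predictions:
        try:
            fr.append((float(p.f), float(p.r)))
        except AttributeError:
            if len(p) != 2:
                raise PairingError("each prediction must pair a forward and reverse output")
            fr.append((float(p[0]), float(p[1])))
    labels = np.asarray(labels, dtype=float)
    if len(fr) != labels.size:
        raise PairingError("predictions and labels differ in length")
    fr_arr = np.array(fr)
    bias = float((fr_arr[:, 0] + fr_arr[:, 1]).mean())
    reported = (fr_arr[:, 0] - fr_arr[:, 1]) / 2.0
    dec_mask = labels <= 0
    inc_mask = ~dec_mask

    def subset(mask):
        if mask.sum() < 2:
            return None
        return regression_metrics(labels[mask], reported[mask])

    return AntisymmetryReport(bias=bias, n_pairs=len(fr),
                              decrease=subset(dec_mask), increase=subset(inc_mask))


def _predictions(state: TrainState, dataset: FeatureDataset) -> np.ndarray:
    net = state.network()
    return np.array([predict_pair(state, p, net=net).reported for p in dataset.pairs])


def permutation_importance(
    state: TrainState,
    dataset: FeatureDataset,
    column: str,
    seed: int = 0,
) -> float:
    """Pearson after shuffling one feature column minus the baseline Pearson.

    The column is permuted across records (the same permutation applied to
    the forward and reverse direction rows, preserving within-record
    direction consistency).
    """
    block, idx = dataset.column_index(column)  # raises KeyError for unknown columns
    y = dataset.labels()
    baseline = float(stats.pearsonr(y, _predictions(state, dataset)).statistic)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset.pairs))
    shuffled = copy.deepcopy(dataset)
    for direction in ("forward", "reverse"):
        values = np.array([
            getattr(p, direction).signature[idx] if block == "signature"
            else getattr(p, direction).tabular[idx]
            for p in dataset.pairs
        ])
        for p_new, v in zip(shuffled.pairs, values[perm]):
            target = getattr(p_new, direction)
            if block == "signature":
                target.signature[idx] = v
            else:
                target.tabular[idx] = v
    permuted = float(stats.pearsonr(y, _predictions(state, shuffled)).statistic)
    return permuted - baseline


def ablation_suite(
    base_config: ModelConfig,
    dataset: FeatureDataset,
    train_ids: set[str],
    test_ids: set[str],
) -> dict[str, MetricReport]:
    """Retrain with each branch deactivated in turn; report held-out metrics."""
    reports = {}
    test_pairs = [p for p in dataset.pairs if p.record_id in test_ids]
    y = np.array([p.y for p in test_pairs])
    for name, config in ablation_configs(base_config).items():
        state = train(config, dataset, train_ids=train_ids)
        net = state.network()
        preds = np.array([predict_pair(state, p, net=net).reported for p in test_pairs])
        reports[name] = regression_metrics(y, preds)
    return reports
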