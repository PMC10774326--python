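"""Percentile scaling, maximum-dissimilarity selection and SOM clustering.

Coastal cells are clustered in the space of a small set of selected
indicators. Indicators are first rescaled so 0 maps to the minimum and 1
to the 99.9th percentile (robust to outliers: extreme values exceed 1
rather than compressing the bulk). A self-organizing map with k neurons
on a rows x cols lattice (default 13 x 13, k = 169) is then trained
online, starting from k maximally dissimilar data rows so the initial
neurons span the parameter space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# percentile scaler
# ---------------------------------------------------------------------------
@dataclass
class ScalerParams:
    """Per-indicator minimum and 99.9th percentile, in indicator units."""

    min: dict
    p999: dict

    @property
    def columns(self) -> list:
        return list(self.min)

    def to_dict(self) -> dict:
        return {"min": dict(self.min), "p999": dict(self.p999)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(min=dict(d["min"]), p999=dict(d["p999"]))


def fit_scaler(table: pd.DataFrame, columns=None) -> ScalerParams:
    """Fit the percentile scaler on the finite values of each column."""
    columns = list(columns) if columns is not None else list(table.columns)
    mins, p999s = {}, {}
    for col in columns:
        vals = table[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"indicator {col!r} has fewer than 2 finite values")
        mins[col] = float(np.min(vals))
        p999s[col] = float(np.percentile(vals, 99.9, method="linear"))
        if p999s[col] == mins[col]:
            warnings.warn(
                f"indicator {col!r} is degenerate (p99.9 == min); scaled values are all 0",
                RuntimeWarning,
                stacklevel=2,
            )
    return ScalerParams(min=mins, p999=p999s)


def transform(params: ScalerParams, table: pd.DataFrame) -> pd.DataFrame:
    """Scale columns to z = (x - min) / (p99.9 - min); values above the
    99.9th percentile map above 1 (no clipping)."""
    out = {}
    for col in params.columns:
        x = table[col].to_numpy(dtype=float)
        span = params.p999[col] - params.min[col]
        out[col] = np.zeros_like(x) if span == 0 else (x - params.min[col]) / span
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# maximum-dissimilarity subset selection
# ---------------------------------------------------------------------------
def maxdiss_select(data: np.ndarray, k: int) -> np.ndarray:
    """Greedy MaxMin selection of ``k`` row indices.

    The first row maximizes the total Euclidean distance to all rows;
    each next row maximizes the minimum distance to the selected set.
    Deterministic, with exact ties broken by ascending row index.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    if k > n:
        raise ValueError(f"cannot select k={k} rows from n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    # seed: row with maximum summed distance to every row (np.argmax -> lowest tie index)
    total = np.zeros(n)
    for i in range(n):
        total += np.linalg.norm(data - data[i], axis=1)
    selected = [int(np.argmax(total))]
    min_dist = np.linalg.norm(data - data[selected[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(data - data[nxt], axis=1))
    return np.asarray(selected, dtype=int)


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------
@dataclass
class SOMConfig:
    """Training schedule for the online SOM.

    Neighborhood radius sigma and learning rate eta decay linearly from
    their initial to final values over the training steps. The lattice is
    a rectangular grid of rows x cols neurons (hexagonal rendering of the
    lattice is cosmetic); the neighborhood kernel uses Euclidean distance
    on integer (row, col) coordinates.
    """

    rows: int = 13
    cols: int = 13
    n_epochs: int = 200
    sigma_initial: float | None = None  # default max(rows, cols) / 2
    # the final radius ends well below one lattice step: late training is
    # near-quantizer refinement, so the quantization error of a well-spread
    # (MaxDiss) initialization is recovered rather than smoothed away;
    # 200 epochs leave enough refinement steps after the ordering phase
    sigma_final: float = 0.2
    eta_initial: float = 0.5
    eta_final: float = 0.01
    seed: int = 0

    @property
    def k(self) -> int:
        return self.rows * self.cols

    @property
    def sigma0(self) -> float:
        return self.sigma_initial if self.sigma_initial is not None else max(self.rows, self.cols) / 2.0


@dataclass
class SOMModel:
    """Trained map: k neurons in scaled indicator space on a 2-D lattice."""

    neurons: np.ndarray          # (k, d)
    lattice: np.ndarray          # (k, 2) integer (row, col) per neuron
    config: SOMConfig
    qe_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def lattice_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(data: np.ndarray, init: np.ndarray, config: SOMConfig) -> SOMModel:
    """Online SOM training with seeded per-epoch shuffling.

    Per sample: the best-matching unit b is the nearest neuron; every
    neuron j moves toward the sample with gain
    eta(t) * exp(-lat_dist(j, b)^2 / (2 sigma(t)^2)).
    Fully deterministic given the config seed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    bad = ~np.isfinite(data).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite input rows at positions {np.flatnonzero(bad).tolist()}")
    init = np.asarray(init, dtype=float)
    if init.ndim == 1:
        init = init[:, None]
    if init.shape != (config.k, data.shape[1]):
        raise ValueError(f"init shape {init.shape} != (k, d) = ({config.k}, {data.shape[1]})")

    neurons = init.copy()
    lat = lattice_coords(config.rows, config.cols)
    # squared lattice distances between all neuron pairs, reused every step
    lat_d2 = ((lat[:, None, :] - lat[None, :, :]) ** 2).sum(axis=2)
    rng = np.random.default_rng(config.seed)
    n = data.shape[0]
    total_steps = max(config.n_epochs * n - 1, 1)
    qe_hist = [quantization_error_points(neurons, data)]
    step = 0
    for _ in range(config.n_epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / total_steps
            sigma = config.sigma0 + (config.sigma_final - config.sigma0) * frac
            eta = config.eta_initial + (config.eta_final - config.eta_initial) * frac
            x = data[i]
            b = int(np.argmin(((neurons - x) ** 2).sum(axis=1)))
            h = eta * np.exp(-lat_d2[:, b] / (2.0 * sigma * sigma))
            neurons += h[:, None] * (x - neurons)
            step += 1
        qe_hist.append(quantization_error_points(neurons, data))
    return SOMModel(neurons=neurons, lattice=lat.astype(int), config=config,
                    qe_history=np.asarray(qe_hist))


def bmu_indices(neurons: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Best-matching unit per row (Euclidean; ties to the lowest index)."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != neurons.shape[1]:
        raise ValueError(f"dimension mismatch: data d={data.shape[1]}, neurons d={neurons.shape[1]}")
    d2 = ((data[:, None, :] - neurons[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def quantization_error_points(neurons: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance of rows to their best-matching neurons."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    b = bmu_indices(neurons, data)
    return float(np.mean(np.linalg.norm(data - neurons[b], axis=1)))


@dataclass
class ClusterAssignment:
    """Map row id -> neuron index, plus per-neuron member lists."""

    bmu: pd.Series               # index: row ids; values: neuron index
    k: int

    def members(self) -> dict:
        out = {j: [] for j in range(self.k)}
        for rid, j in self.bmu.items():
            out[int(j)].append(rid)
        return out


def assign_clusters(model: SOMModel, data: pd.DataFrame | np.ndarray) -> ClusterAssignment:
    """Assign each row to its nearest neuron. Accepts a DataFrame (row ids
    kept) or an array (positional ids)."""
    if isinstance(data, pd.DataFrame):
        idx = data.index
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        idx = pd.RangeIndex(arr.shape[0])
    b = bmu_indices(model.neurons, arr)
    return ClusterAssignment(bmu=pd.Series(b, index=idx, name="cluster"), k=model.config.k)


def quantization_error(model: SOMModel, data: pd.DataFrame | np.ndarray) -> float:
    arr = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    return quantization_error_points(model.neurons, arr)
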