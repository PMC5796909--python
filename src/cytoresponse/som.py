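"""Self-organizing map for expression response profiles.

A rectangular-grid SOM trained online: codebooks are initialized on the
plane of the first two principal components, the learning rate decays
linearly, and updates use a Gaussian neighborhood whose radius shrinks from
half the larger grid dimension to one. The final gene-to-node assignment is
the globally nearest codebook under Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SOMModel:
    grid: tuple                 # (rows, cols)
    codebooks: np.ndarray       # (rows*cols, n_features)
    assignments: pd.Series      # gene -> node index (row-major)
    feature_names: list
    epochs: int
    seed: int

    def node_coords(self):
        r, c = self.grid
        return np.array([(i // c, i % c) for i in range(r * c)], dtype=float)

    def assign(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.codebooks[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def _pca_init(X, grid, rng):
    r, c = grid
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    sd = Xc.std(axis=0).mean() + 1e-12
    gi = np.linspace(-2, 2, r)
    gj = np.linspace(-2, 2, c)
    code = np.empty((r * c, X.shape[1]))
    for i in range(r):
        for j in range(c):
            vec = gi[i] * vt[0] + (gj[j] * vt[1] if vt.shape[0] > 1 else 0.0)
            code[i * c + j] = X.mean(axis=0) + sd * vec
    code += rng.normal(0, 1e-6, size=code.shape)
    return code


def fit_som(profile: pd.DataFrame, grid=(10, 10), epochs=100, seed=0,
            lr=(0.05, 0.01)):
    """Train a SOM on a gene x condition log2 FC matrix.

    ``profile`` rows are genes; a fixed seed gives identical codebooks across
    runs. Requires at least as many genes as nodes and a grid with >= 2
    nodes.
    """
    r, c = grid
    if r * c < 2:
        raise ValueError("grid must have at least 2 nodes")
    X = profile.to_numpy(dtype=float)
    if X.shape[0] < r * c:
        raise ValueError("need at least as many genes as SOM nodes")
    rng = np.random.default_rng(seed)
    code = _pca_init(X, grid, rng)
    coords = np.array([(i // c, i % c) for i in range(r * c)], dtype=float)
    radius0 = max(r, c) / 2.0
    n = X.shape[0]
    total_steps = epochs * n
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        for idx in order:
            frac = step / max(total_steps - 1, 1)
            alpha = lr[0] + (lr[1] - lr[0]) * frac
            radius = radius0 + (1.0 - radius0) * frac
            x = X[idx]
            bmu = ((code - x) ** 2).sum(axis=1).argmin()
            d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * radius**2))
            code += alpha * h[:, None] * (x - code)
            step += 1
    d2 = ((X[:, None, :] - code[None, :, :]) ** 2).sum(axis=2)
    assign = pd.Series(d2.argmin(axis=1), index=profile.index, name="node")
    return SOMModel(grid=grid, codebooks=code, assignments=assign,
                    feature_names=list(profile.columns), epochs=epochs,
                    seed=seed)


def summarize_som(model: SOMModel, profile: pd.DataFrame, condition=None):
    """Per-node mean FC for one condition (or all) over assigned genes.

    Nodes with no assigned genes are reported as missing, not zero.
    """
    cols = [condition] if condition is not None else list(profile.columns)
    n_nodes = model.grid[0] * model.grid[1]
    out = pd.DataFrame(np.nan, index=pd.RangeIndex(n_nodes, name="node"),
                       columns=cols)
    grouped = profile[cols].groupby(model.assignments).mean()
    out.loc[grouped.index] = grouped
    return out
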